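"""Categorical codebook for the recipient roster.

The default codebook covers the 13 sociodemographic and health-related
variables recorded for public-assistance recipients aged 65 or older
(age group, nationality, living arrangement, disability/disease,
hospitalization history, long-term care certification, working status,
previous assistance use, reason for starting assistance, facility-admission
history, housing type, and median-split bands of working income and
pension).  Every variable is categorical; one level per individual.

Level codes are stable snake_case identifiers; display labels carry the
human-readable text used in reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable


class CodebookError(ValueError):
    """Raised when a codebook definition or lookup is invalid."""


@dataclass(frozen=True)
class Level:
    code: str
    label: str


@dataclass(frozen=True)
class Codebook:
    """Ordered variables, each with an ordered list of coded levels."""

    variables: tuple[str, ...]
    levels: dict[str, tuple[Level, ...]] = field(repr=False)

    def __post_init__(self) -> None:
        for var in self.variables:
            if var not in self.levels:
                raise CodebookError(f"variable {var!r} has no level list")
            codes = [lv.code for lv in self.levels[var]]
            if len(set(codes)) != len(codes):
                raise CodebookError(f"duplicate level codes in variable {var!r}")
            if not codes:
                raise CodebookError(f"variable {var!r} has an empty level list")

    # -- lookups ----------------------------------------------------------

    def level_codes(self, variable: str) -> list[str]:
        try:
            return [lv.code for lv in self.levels[variable]]
        except KeyError:
            raise CodebookError(f"unknown variable {variable!r}") from None

    def label(self, variable: str, code: str) -> str:
        for lv in self.levels[variable]:
            if lv.code == code:
                return lv.label
        raise CodebookError(f"unknown level {code!r} for variable {variable!r}")

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    @property
    def n_levels_total(self) -> int:
        return sum(len(self.levels[v]) for v in self.variables)

    def column_labels(self) -> list[str]:
        """``variable:level`` labels in codebook order (one-hot column order)."""
        return [f"{v}:{lv.code}" for v in self.variables for lv in self.levels[v]]

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            v: {"levels": [{"code": lv.code, "label": lv.label} for lv in self.levels[v]]}
            for v in self.variables
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, ensure_ascii=False)

    @classmethod
    def from_dict(cls, d: dict) -> "Codebook":
        variables = tuple(d)
        levels = {
            v: tuple(Level(e["code"], e.get("label", e["code"])) for e in d[v]["levels"])
            for v in variables
        }
        return cls(variables=variables, levels=levels)

    @classmethod
    def from_json(cls, path) -> "Codebook":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def default(cls) -> "Codebook":
        return default_codebook()


def _levels(pairs: Iterable[tuple[str, str]]) -> tuple[Level, ...]:
    return tuple(Level(code, label) for code, label in pairs)


#: Roster CSV column order (id and sex precede the 13 codebook variables).
ROSTER_COLUMNS = [
    "id",
    "sex",
    "age_group",
    "nationality",
    "living_alone",
    "disability_disease",
    "hospitalization",
    "ltc_status",
    "working",
    "previous_pa",
    "reason_start",
    "facility_admission",
    "house_type",
    "income_band",
    "pension_band",
]

SEXES = ("male", "female")


_DEFAULT = {
    "age_group": _levels(
        [("age_65_74", "65-74"), ("age_75_84", "75-84"), ("age_85_over", "85 and over")]
    ),
    "nationality": _levels([("japanese", "Japanese"), ("foreign", "Foreign")]),
    "living_alone": _levels([("yes", "Yes"), ("no", "No")]),
    "disability_disease": _levels(
        [
            ("physical_disability", "Physical disability"),
            ("mental_disability", "Mental disability"),
            ("intellectual_disability", "Intellectual disability"),
            ("psychiatric_disorder", "Psychiatric disorder"),
            ("other_physical_diseases", "Other physical diseases"),
            ("alcohol_dependency", "Alcoholic dependency"),
            ("none", "None"),
        ]
    ),
    "hospitalization": _levels([("yes", "Yes"), ("no", "No")]),
    "ltc_status": _levels(
        [
            ("support_need", "Support need"),
            ("long_term_care_need", "Long-term care need"),
            ("none", "None"),
        ]
    ),
    "working": _levels([("yes", "Yes"), ("no", "No")]),
    "previous_pa": _levels([("yes", "Yes"), ("no", "No")]),
    "reason_start": _levels(
        [
            ("decreased_income", "Decreased income"),
            ("disease", "Disease"),
            ("unemployment", "Unemployment"),
            ("divorce_bereavement", "Divorce/bereavement"),
            ("other_reasons", "Other reasons"),
        ]
    ),
    "facility_admission": _levels([("yes", "Yes"), ("no", "No")]),
    "house_type": _levels(
        [
            ("rental_house", "Rental house"),
            ("public_house", "Public house"),
            ("own_house", "Own house"),
            ("other_houses", "Other houses"),
        ]
    ),
    "income_band": _levels(
        [("above_median", "Above median"), ("below_median", "Below median"), ("none", "None")]
    ),
    "pension_band": _levels(
        [("above_median", "Above median"), ("below_median", "Below median"), ("none", "None")]
    ),
}


def default_codebook() -> Codebook:
    """The 13-variable, 37-level codebook of the source roster."""
    return Codebook(variables=tuple(_DEFAULT), levels=dict(_DEFAULT))


# ---------------------------------------------------------------------------
# Published per-sex level counts of the source population (the printed
# descriptive table).  These counts are inputs to the synthetic preset and to
# exact-count roster reconstruction; each variable's counts sum to the
# stratum size (1,483 men, 1,682 women).
# ---------------------------------------------------------------------------

TABLE1_N = {"male": 1483, "female": 1682}

#: variable -> level code -> (male count, female count)
TABLE1_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "age_group": {"age_65_74": (905, 734), "age_75_84": (513, 698), "age_85_over": (65, 250)},
    "nationality": {"japanese": (1462, 1650), "foreign": (21, 32)},
    "living_alone": {"yes": (1082, 1186), "no": (401, 496)},
    "disability_disease": {
        "physical_disability": (140, 130),
        "mental_disability": (65, 55),
        "intellectual_disability": (2, 4),
        "psychiatric_disorder": (39, 87),
        "other_physical_diseases": (325, 333),
        "alcohol_dependency": (12, 2),
        "none": (900, 1071),
    },
    "hospitalization": {"yes": (77, 100), "no": (1406, 1582)},
    "ltc_status": {
        "support_need": (74, 120),
        "long_term_care_need": (255, 385),
        "none": (1154, 1177),
    },
    "working": {"yes": (138, 121), "no": (1345, 1561)},
    "previous_pa": {"yes": (214, 240), "no": (1269, 1442)},
    "reason_start": {
        "decreased_income": (762, 859),
        "disease": (383, 368),
        "unemployment": (131, 128),
        "divorce_bereavement": (43, 61),
        "other_reasons": (164, 266),
    },
    "facility_admission": {"yes": (62, 97), "no": (1421, 1585)},
    "house_type": {
        "rental_house": (988, 912),
        "public_house": (353, 561),
        "own_house": (2, 5),
        "other_houses": (140, 204),
    },
    "income_band": {"above_median": (34, 30), "below_median": (35, 31), "none": (1414, 1621)},
    "pension_band": {"above_median": (239, 416), "below_median": (241, 417), "none": (1003, 849)},
}

#: Per-sex medians (yen/month) over strictly positive amounts, as published.
TABLE1_MEDIANS = {
    "working_income": {"male": 35373, "female": 43858},
    "pension": {"male": 61670, "female": 45708},
}


def table1_marginals(sex: str) -> dict[str, dict[str, float]]:
    """Exact level proportions count/N for one sex, in codebook order."""
    if sex not in SEXES:
        raise CodebookError(f"unknown sex {sex!r}; expected one of {SEXES}")
    j = SEXES.index(sex)
    n = TABLE1_N[sex]
    cb = default_codebook()
    out: dict[str, dict[str, float]] = {}
    for var in cb.variables:
        out[var] = {code: TABLE1_COUNTS[var][code][j] / n for code in cb.level_codes(var)}
    return out
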