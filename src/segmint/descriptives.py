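"""Baseline descriptive statistics for a recipient roster.

Reproduces the style of the study population table: per-sex counts and
percentages for every level of every variable, and the median-split
banding of monthly working income and pension (computed over strictly
positive amounts, zero amounts coded "none").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codebook import SEXES, TABLE1_COUNTS, Codebook, default_codebook
from .encoding import RosterError, validate_roster


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of the printed table).

    Python's built-in ``round`` rounds half to even, which disagrees with
    printed percentages on exact .x5 boundaries.
    """
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass
class DescriptiveTable:
    """Per-sex level counts and percentages, plus optional banding medians."""

    table: pd.DataFrame  # columns: sex, variable, level, count, percentage
    footnotes: dict[str, dict[str, float]] = field(default_factory=dict)

    def percentage(self, sex: str, variable: str, level: str) -> float:
        df = self.table
        row = df[(df.sex == sex) & (df.variable == variable) & (df.level == level)]
        if len(row) != 1:
            raise KeyError(f"no unique row for ({sex}, {variable}, {level})")
        return float(row["percentage"].iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def descriptive_table(
    roster: pd.DataFrame, codebook: Codebook | None = None
) -> DescriptiveTable:
    """Counts and percentages per sex x variable x level.

    Percentages are ``100 * count / N_sex`` rounded half-away-from-zero to
    one decimal.  An empty stratum yields zero counts with percentages set
    to NaN (flagged undefined rather than fabricated).
    """
    codebook = codebook or default_codebook()
    validate_roster(roster, codebook)
    if "sex" not in roster.columns:
        raise RosterError("roster has no 'sex' column")
    rows = []
    for sex in SEXES:
        sub = roster[roster["sex"] == sex]
        n = len(sub)
        for var in codebook.variables:
            counts = sub[var].value_counts()
            for code in codebook.level_codes(var):
                c = int(counts.get(code, 0))
                pct = round_half_away(100.0 * c / n, 1) if n > 0 else float("nan")
                rows.append((sex, var, code, c, pct))
    return DescriptiveTable(
        table=pd.DataFrame(rows, columns=["sex", "variable", "level", "count", "percentage"])
    )


def median_band(amounts: pd.Series, sex: pd.Series) -> pd.Series:
    """Band monthly amounts (yen) into above_median / below_median / none per sex.

    Zero amounts are coded ``none``.  The median is computed per sex over
    strictly positive amounts only; amounts strictly above it band
    ``above_median`` and amounts at or below it band ``below_median``
    (ties go below — this reproduces the published near-even split where
    the below count exceeds the above count by one).
    """
    amounts = pd.Series(amounts).astype(float)
    if (amounts < 0).any():
        raise ValueError("amounts must be >= 0")
    sex = pd.Series(sex)
    out = pd.Series(["none"] * len(amounts), index=amounts.index, dtype=object)
    for s in sex.unique():
        mask = (sex == s) & (amounts > 0)
        if not mask.any():
            continue
        med = amounts[mask].median()
        out[mask & (amounts > med)] = "above_median"
        out[mask & (amounts <= med)] = "below_median"
    return out


def banding_medians(amounts: pd.Series, sex: pd.Series) -> dict[str, float]:
    """Per-sex medians over positive amounts (the table-footnote values)."""
    amounts = pd.Series(amounts).astype(float)
    sex = pd.Series(sex)
    out = {}
    for s in sex.unique():
        pos = amounts[(sex == s) & (amounts > 0)]
        if len(pos):
            out[str(s)] = float(pos.median())
    return out


def roster_from_counts(
    counts: dict[str, dict[str, tuple[int, int]]] | None = None,
    codebook: Codebook | None = None,
) -> pd.DataFrame:
    """Deterministic roster whose per-sex level counts equal a published table.

    Each variable's column is filled block-wise (first ``count`` rows get
    the first level, and so on), independently per variable: marginal
    counts are exact while the joint distribution is arbitrary, which is
    all a descriptive table depends on.  Defaults to the study table
    (1,483 men and 1,682 women).
    """
    counts = counts or TABLE1_COUNTS
    codebook = codebook or default_codebook()
    frames = []
    for j, sex in enumerate(SEXES):
        n = sum(v[j] for v in counts[codebook.variables[0]].values())
        data: dict[str, list] = {
            "id": [f"{sex[0]}{i + 1:05d}" for i in range(n)],
            "sex": [sex] * n,
        }
        for var in codebook.variables:
            per_level = [counts[var][code][j] for code in codebook.level_codes(var)]
            if sum(per_level) != n:
                raise ValueError(f"counts for {var!r} sum to {sum(per_level)}, expected {n}")
            col = np.repeat(codebook.level_codes(var), per_level)
            data[var] = list(col)
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)
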