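"""Mixed-methods integration: concordance classification and the joint display.

After the quantitative phase produces cluster profiles, caseworkers are
shown each profile and asked whether they can think of recipients with
those characteristics.  Their yes/no answers enter as a responses CSV
(``cluster_id,interviewee_id,could_recall``), and each cluster's verdict
is classified as:

* ``concordance`` — every interviewee could recall such recipients;
* ``partial_concordance`` — some could and some could not;
* ``discordance`` — none could.

The joint display aligns each cluster's quantitative profile with the
qualitative verdict in a single table.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .characterize import ClusterProfile, profile_summary

CONCORDANCE = "concordance"
PARTIAL = "partial_concordance"
DISCORDANCE = "discordance"


@dataclass(frozen=True)
class InterviewResponse:
    cluster_id: int
    interviewee_id: str
    could_recall: bool


def classify_concordance(responses: list[bool]) -> str:
    """All true -> concordance; none true -> discordance; otherwise partial."""
    if len(responses) == 0:
        raise ValueError("cannot classify an empty response list")
    if all(responses):
        return CONCORDANCE
    if not any(responses):
        return DISCORDANCE
    return PARTIAL


def read_responses(path) -> pd.DataFrame:
    """Load a responses CSV; booleans accept true/false (any case) and 1/0."""
    df = pd.read_csv(path)
    required = {"cluster_id", "interviewee_id", "could_recall"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"responses CSV is missing column(s) {sorted(missing)}")
    if df.duplicated(["cluster_id", "interviewee_id"]).any():
        raise ValueError("duplicate (cluster_id, interviewee_id) response")
    truthy = {"true": True, "1": True, "false": False, "0": False}
    df["could_recall"] = (
        df["could_recall"].astype(str).str.strip().str.lower().map(truthy)
    )
    if df["could_recall"].isna().any():
        raise ValueError("could_recall values must be true/false or 1/0")
    return df


def joint_display(
    profiles: list[ClusterProfile],
    responses: pd.DataFrame,
    sex: str,
) -> pd.DataFrame:
    """One row per cluster: profile summary, response tallies, and verdict."""
    rows = []
    for p in profiles:
        sub = responses[responses["cluster_id"] == p.cluster_id]
        if len(sub) == 0:
            raise ValueError(f"no interview responses for cluster {p.cluster_id}")
        answers = list(sub["could_recall"].astype(bool))
        rows.append(
            {
                "sex": sex,
                "cluster_id": p.cluster_id,
                "profile_summary": profile_summary(p),
                "n_yes": int(sum(answers)),
                "n_respondents": len(answers),
                "verdict": classify_concordance(answers),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sex", "cluster_id", "profile_summary", "n_yes", "n_respondents", "verdict"],
    )
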