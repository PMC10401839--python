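"""Affiliation probabilities, cluster profiles, and parameter-recovery matching.

A fitted model induces, for every variable-level and every individual, a
posterior distribution over clusters — the affiliation probabilities.
Levels whose affiliation to a cluster reaches a threshold tau characterize
that cluster; the working threshold is 0.55, strictly above 0.5 so that no
level can simultaneously characterize two clusters (at 0.50 a level could
sit in one cluster while "the remaining 0.50" sits in another).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from .encoding import CooccurrenceMatrix
from .plsa import PlsaModel, class_conditionals, responsibilities
from .synthetic import GroundTruth

#: Affiliation threshold used to read off cluster characteristics.
DEFAULT_TAU = 0.55


@dataclass
class AffiliationTable:
    """Posterior cluster distributions for variable-levels and individuals.

    ``var_affil[v, k] = P(v|z_k)P(z_k) / sum_j P(v|z_j)P(z_j)``; rows sum
    to 1.  ``ind_affil`` is the analogous posterior from P(i|z).
    """

    var_affil: np.ndarray
    ind_affil: np.ndarray
    column_labels: list[str] = field(default_factory=list)
    row_ids: list = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.var_affil.shape[1]

    def to_long_frame(self) -> pd.DataFrame:
        """Long format ``entity_type, entity, cluster, affiliation``."""
        recs = []
        for v, label in enumerate(self.column_labels):
            for k in range(self.K):
                recs.append(("variable", label, k + 1, self.var_affil[v, k]))
        for i, rid in enumerate(self.row_ids):
            for k in range(self.K):
                recs.append(("individual", str(rid), k + 1, self.ind_affil[i, k]))
        return pd.DataFrame(recs, columns=["entity_type", "entity", "cluster", "affiliation"])


@dataclass
class ClusterProfile:
    """Levels affiliated with one cluster at >= tau, with their affiliation values."""

    cluster_id: int
    levels: list[tuple[str, float]]  # (column label, affiliation), descending
    n_members: int

    def to_dict(self) -> dict:
        return {
            "cluster": self.cluster_id,
            "n_members": self.n_members,
            "levels": [
                {
                    "variable": lbl.split(":", 1)[0],
                    "level": lbl.split(":", 1)[1],
                    "affiliation": round(float(a), 6),
                }
                for lbl, a in self.levels
            ],
        }


def _posterior(weights: np.ndarray, cond: np.ndarray, kind: str) -> np.ndarray:
    joint = cond * weights[None, :]
    denom = joint.sum(axis=1, keepdims=True)
    zero = (denom <= 0).ravel()
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} {kind}(s) with zero total mass; assigning uniform affiliation",
            RuntimeWarning,
            stacklevel=3,
        )
        joint[zero] = 1.0
        denom = joint.sum(axis=1, keepdims=True)
    return joint / denom


def affiliation(model: PlsaModel) -> AffiliationTable:
    """Posterior cluster distributions A(z|v) and A(z|i) from a fitted model."""
    model.validate()
    return AffiliationTable(
        var_affil=_posterior(model.pz, model.pv_z, "variable-level"),
        ind_affil=_posterior(model.pz, model.pi_z, "individual"),
        column_labels=list(model.column_labels),
        row_ids=list(model.row_ids),
    )


def characterize(affil: AffiliationTable, tau: float = DEFAULT_TAU) -> list[ClusterProfile]:
    """Per-cluster profiles: levels with affiliation >= tau (inclusive), descending.

    A cluster may legitimately have no level reaching tau; it is emitted
    empty with a warning so downstream reports still cover every cluster.
    """
    if not 0 < tau <= 1:
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    members = np.bincount(np.argmax(affil.ind_affil, axis=1), minlength=affil.K)
    profiles = []
    for k in range(affil.K):
        a = affil.var_affil[:, k]
        idx = np.nonzero(a >= tau)[0]
        order = idx[np.argsort(-a[idx], kind="stable")]
        levels = [(affil.column_labels[v], float(a[v])) for v in order]
        if not levels:
            warnings.warn(
                f"cluster {k + 1}: no variable-level reaches affiliation {tau}",
                RuntimeWarning,
                stacklevel=2,
            )
        profiles.append(
            ClusterProfile(cluster_id=k + 1, levels=levels, n_members=int(members[k]))
        )
    return profiles


def profiles_to_json(profiles: list[ClusterProfile], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([p.to_dict() for p in profiles], fh, indent=2)


def profile_summary(profile: ClusterProfile, top: int = 5) -> str:
    """Compact one-line description, e.g. for the joint display."""
    parts = [f"{lbl} ({a:.2f})" for lbl, a in profile.levels[:top]]
    return "; ".join(parts) if parts else "(no level above threshold)"


def plot_affiliation_heatmap(affil: AffiliationTable, ax=None):
    """Heatmap of A(z|v) over variable-levels x clusters (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(
            figsize=(2 + 0.8 * affil.K, 0.25 * len(affil.column_labels) + 1)
        )
    im = ax.imshow(affil.var_affil, aspect="auto", vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(affil.K), [f"z{k + 1}" for k in range(affil.K)])
    ax.set_yticks(range(len(affil.column_labels)), affil.column_labels, fontsize=6)
    ax.set_xlabel("cluster")
    ax.figure.colorbar(im, ax=ax, label="affiliation probability")
    return ax


# ---------------------------------------------------------------------------
# parameter recovery against a synthetic ground truth
# ---------------------------------------------------------------------------


def match_clusters(
    fitted: PlsaModel,
    matrix: CooccurrenceMatrix,
    truth: GroundTruth,
    sex: str,
) -> tuple[tuple[int, ...], float]:
    """Align fitted clusters with generating segments; return (permutation, mean TV).

    The fitted per-cluster level distributions are the class-conditional
    estimates (posterior-weighted aggregation; see
    :func:`segmint.plsa.class_conditionals`).  The permutation minimizes
    the mean total-variation distance, averaged over the 13 variables and
    the K clusters, against the generator's theta for the given sex.
    ``permutation[k]`` is the true segment index (0-based) matched to
    fitted cluster k.  Exhaustive search for K <= 8, Hungarian assignment
    (exact for this separable objective) above.
    """
    spec = truth.spec
    if fitted.K != spec.k_true:
        raise ValueError(f"fitted K={fitted.K} does not match ground truth k_true={spec.k_true}")
    K = fitted.K
    _, theta_fit = class_conditionals(fitted, matrix)
    cost = np.zeros((K, K))
    for var in spec.codebook.variables:
        fit_block = theta_fit[var]  # (K, L)
        true_block = np.stack(
            [np.asarray(seg[var], dtype=float) for seg in spec.level_probs[sex]]
        )
        cost += 0.5 * np.abs(fit_block[:, None, :] - true_block[None, :, :]).sum(axis=2)
    cost /= spec.codebook.n_variables
    if K <= 8:
        perm = min(
            permutations(range(K)), key=lambda p: sum(cost[i, p[i]] for i in range(K))
        )
    else:
        from scipy.optimize import linear_sum_assignment

        rows, cols = linear_sum_assignment(cost)
        perm = tuple(int(cols[np.argsort(rows)][i]) for i in range(K))
    error = float(np.mean([cost[i, perm[i]] for i in range(K)]))
    return tuple(perm), error


def segment_accuracy(
    fitted: PlsaModel, truth: GroundTruth, perm: tuple[int, ...]
) -> float:
    """Fraction of individuals whose hard assignment matches their true segment."""
    sub = truth.assignments.set_index("id").loc[[str(r) for r in fitted.row_ids]]
    true_lab = sub["true_segment"].to_numpy() - 1
    hard = np.argmax(responsibilities(fitted), axis=1)
    mapped = np.asarray(perm)[hard]
    return float(np.mean(mapped == true_lab))
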