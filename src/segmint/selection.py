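"""Sweep the cluster number K and select a working model.

For each K in a range (2..10 by default, 5 restarts each) the sweep fits
the mixture and records two families of penalized criteria:

* ``aic`` / ``bic`` on the joint co-occurrence log-likelihood with the full
  symmetric parameter count ``(K-1) + K(I-1) + K(V-1)``.  These document
  the raw fit, but the ``K(I-1)`` individual-membership parameters grow
  with the sample, so these columns are monotone in K on realistic data
  and cannot locate a finite optimum.
* ``aic_class`` / ``bic_class`` on the folded class-marginal likelihood
  (individual parameters profiled out) with the cluster-level count
  ``(K-1) + K * sum_j (L_j - 1)``.  This is the classical latent-class
  criterion and is the default basis for choosing K.

Cluster size enters through ``min_cluster_n``, the smallest cluster under
hard assignment (argmax posterior membership); a floor on it excludes
degenerate solutions from candidacy.  The final "interpretability" check
is explicitly a human step: callers are expected to show the ranked table
and candidate profiles rather than trust any single criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import CooccurrenceMatrix
from .plsa import FitConfig, PlsaModel, class_marginal_loglik, fit_plsa, responsibilities


class SelectionError(ValueError):
    """Raised when selection is impossible (e.g. no candidate passes the floor)."""


def count_parameters(K: int, I: int, V: int) -> int:
    """Free parameters of the full symmetric parameterization: (K-1) + K(I-1) + K(V-1)."""
    if K < 1 or I < 1 or V < 1:
        raise SelectionError(f"K, I, V must all be >= 1, got ({K}, {I}, {V})")
    return (K - 1) + K * (I - 1) + K * (V - 1)


def count_class_parameters(K: int, level_counts: list[int]) -> int:
    """Cluster-level parameters of the folded model: (K-1) + K * sum_j (L_j - 1)."""
    return (K - 1) + K * sum(L - 1 for L in level_counts)


@dataclass
class SelectionPolicy:
    """How the working K is chosen from a sweep table.

    criterion : "bic" or "aic".
    scope : "class" scores the folded class-marginal likelihood (default);
        "joint" scores the raw co-occurrence likelihood with the full
        parameter count (documented as monotone in K; kept for inspection).
    min_cluster_n_floor : smallest admissible hard-assigned cluster size.
    tie_tolerance : criterion differences within this are ties, resolved
        toward smaller K.
    """

    criterion: str = "bic"
    scope: str = "class"
    min_cluster_n_floor: int = 10
    tie_tolerance: float = 0.0

    def validate(self) -> None:
        if self.criterion not in ("bic", "aic"):
            raise SelectionError(f"criterion must be 'bic' or 'aic', got {self.criterion!r}")
        if self.scope not in ("class", "joint"):
            raise SelectionError(f"scope must be 'class' or 'joint', got {self.scope!r}")
        if self.tie_tolerance < 0:
            raise SelectionError("tie_tolerance must be >= 0")

    @property
    def column(self) -> str:
        return self.criterion if self.scope == "joint" else f"{self.criterion}_class"


@dataclass
class ModelSelectionTable:
    """Per-K sweep results plus the fitted best-of-restarts models."""

    table: pd.DataFrame
    models: dict[int, PlsaModel] = field(default_factory=dict)

    COLUMNS = [
        "k",
        "loglik",
        "n_params",
        "aic",
        "bic",
        "loglik_class",
        "n_params_class",
        "aic_class",
        "bic_class",
        "min_cluster_mass",
        "min_cluster_n",
        "seed_best",
    ]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def hard_assignment_sizes(model: PlsaModel) -> np.ndarray:
    """Cluster sizes under argmax posterior membership (ties to the lower label)."""
    r = responsibilities(model)
    return np.bincount(np.argmax(r, axis=1), minlength=model.K)


def sweep_k(
    matrix: CooccurrenceMatrix,
    k_min: int = 2,
    k_max: int = 10,
    config: FitConfig | None = None,
    r_convention: str = "tokens",
) -> ModelSelectionTable:
    """Fit best-of-restarts models for each K in [k_min, k_max] and tabulate criteria.

    ``r_convention`` sets the BIC sample size for the joint-likelihood
    column: "tokens" uses the total co-occurrence count R = I x n_variables
    (the likelihood is over co-occurrence events); "individuals" uses I.
    The folded class criteria always use I, the number of rows the folded
    likelihood is a product over.
    """
    I, V = matrix.shape
    if not (1 <= k_min <= k_max):
        raise SelectionError(f"need 1 <= k_min <= k_max, got ({k_min}, {k_max})")
    if k_max > min(I, V):
        raise SelectionError(f"k_max={k_max} exceeds min(I={I}, V={V})")
    if r_convention not in ("tokens", "individuals"):
        raise SelectionError(f"unknown r_convention {r_convention!r}")
    config = config or FitConfig()
    R = float(matrix.n.sum()) if r_convention == "tokens" else float(I)
    level_counts = [sl.stop - sl.start for sl in matrix.var_slices.values()]
    rows = []
    models: dict[int, PlsaModel] = {}
    for K in range(k_min, k_max + 1):
        try:
            model = fit_plsa(matrix, K, config)
        except Exception as exc:
            raise SelectionError(f"fit failed at K={K}: {exc}") from exc
        d = count_parameters(K, I, V)
        d_class = count_class_parameters(K, level_counts)
        ll_class = class_marginal_loglik(model, matrix)
        sizes = hard_assignment_sizes(model)
        rows.append(
            {
                "k": K,
                "loglik": model.loglik,
                "n_params": d,
                "aic": -2.0 * model.loglik + 2.0 * d,
                "bic": -2.0 * model.loglik + d * np.log(R),
                "loglik_class": ll_class,
                "n_params_class": d_class,
                "aic_class": -2.0 * ll_class + 2.0 * d_class,
                "bic_class": -2.0 * ll_class + d_class * np.log(I),
                "min_cluster_mass": float(model.pz.min()),
                "min_cluster_n": int(sizes.min()),
                "seed_best": model.seed,
            }
        )
        models[K] = model
    return ModelSelectionTable(
        table=pd.DataFrame(rows, columns=ModelSelectionTable.COLUMNS), models=models
    )


def select_k(table: ModelSelectionTable | pd.DataFrame, policy: SelectionPolicy | None = None) -> int:
    """Smallest-K argmin of the policy criterion among rows passing the size floor.

    Ties within ``policy.tie_tolerance`` go to the smaller K.  Raises
    :class:`SelectionError` if the table is empty or no row passes the
    floor (advising to lower it).
    """
    policy = policy or SelectionPolicy()
    policy.validate()
    df = table.table if isinstance(table, ModelSelectionTable) else table
    if len(df) == 0:
        raise SelectionError("selection table is empty")
    candidates = df[df["min_cluster_n"] >= policy.min_cluster_n_floor]
    if len(candidates) == 0:
        raise SelectionError(
            f"no K has min_cluster_n >= {policy.min_cluster_n_floor}; "
            "lower min_cluster_n_floor"
        )
    col = policy.column
    if col not in df.columns:
        raise SelectionError(f"criterion column {col!r} missing from table")
    best = candidates[col].min()
    within = candidates[candidates[col] <= best + policy.tie_tolerance]
    return int(within["k"].min())


def top_candidates(
    table: ModelSelectionTable | pd.DataFrame, policy: SelectionPolicy | None = None, n: int = 3
) -> pd.DataFrame:
    """The ``n`` best rows by the policy criterion (floor applied), for human review."""
    policy = policy or SelectionPolicy()
    policy.validate()
    df = table.table if isinstance(table, ModelSelectionTable) else table
    candidates = df[df["min_cluster_n"] >= policy.min_cluster_n_floor]
    return candidates.sort_values(policy.column).head(n).reset_index(drop=True)


def check_nesting(table: ModelSelectionTable | pd.DataFrame, tol: float = 1e-6) -> None:
    """Warn if the best joint loglik ever drops as K grows (finite restarts can miss)."""
    df = table.table if isinstance(table, ModelSelectionTable) else table
    ll = df.sort_values("k")["loglik"].to_numpy()
    drops = np.nonzero(np.diff(ll) < -tol)[0]
    for i in drops:
        warnings.warn(
            f"best log-likelihood decreased from K={int(df['k'].iloc[i])} to "
            f"K={int(df['k'].iloc[i + 1])}; consider more restarts",
            RuntimeWarning,
            stacklevel=2,
        )
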