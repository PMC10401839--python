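"""Probabilistic latent semantic analysis fitted by EM.

The aspect model expresses the joint distribution over individuals ``i``
and variable-levels ``v`` as a mixture over latent clusters ``z``::

    P(i, v) = sum_z P(z) P(i|z) P(v|z)

fitted to a binary co-occurrence matrix ``n(i, v)`` by maximizing the
log-likelihood ``L = sum_{i,v} n(i,v) * ln P(i,v)`` with the EM algorithm.
The E-step computes responsibilities ``P(z|i,v)`` over observed cells only
(zero cells contribute nothing to L, and restricting to the support makes
one iteration O(nnz * K)); the M-step renormalizes responsibility-weighted
counts.  Multiple restarts from random (flat-Dirichlet) initializations are
needed because exactly symmetric starts are EM fixed points that collapse
all clusters onto the independence solution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix

from .encoding import CooccurrenceMatrix


class PlsaError(ValueError):
    """Raised for dimension mismatches or broken probability floors."""


@dataclass
class FitConfig:
    """EM control parameters.

    max_iter / tol : stop when the relative log-likelihood change
        ``|dL| / |L|`` falls below ``tol`` or after ``max_iter`` iterations.
    n_restarts : independent EM chains from distinct seeded initializations;
        the chain with the highest final log-likelihood wins (default 5).
    seed : root seed; restart ``r`` uses ``seed + r``.
    floor : probability floor substituted for exact zeros after each M-step
        (numerical guard; zeros cannot arise for cells on the support, so
        this only protects degenerate inputs).
    """

    max_iter: int = 500
    tol: float = 1e-8
    n_restarts: int = 5
    seed: int = 0
    floor: float = 1e-12

    def validate(self) -> None:
        if self.max_iter < 1:
            raise PlsaError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.tol <= 0:
            raise PlsaError(f"tol must be > 0, got {self.tol}")
        if self.n_restarts < 1:
            raise PlsaError(f"n_restarts must be >= 1, got {self.n_restarts}")


@dataclass
class PlsaModel:
    """Fitted mixture parameters with fit metadata.

    ``pz`` sums to 1; each column of ``pi_z`` (I x K) and ``pv_z`` (V x K)
    sums to 1.  ``loglik`` is the natural-log likelihood on the training
    matrix; ``seed`` is the winning chain's initialization seed.
    """

    K: int
    pz: np.ndarray
    pi_z: np.ndarray
    pv_z: np.ndarray
    loglik: float = np.nan
    n_iter: int = 0
    seed: int | None = None
    converged: bool = False
    row_ids: list = field(default_factory=list)
    column_labels: list = field(default_factory=list)

    def validate(self) -> None:
        if self.pz.shape != (self.K,):
            raise PlsaError("pz has wrong shape")
        if self.pi_z.ndim != 2 or self.pi_z.shape[1] != self.K:
            raise PlsaError("pi_z has wrong shape")
        if self.pv_z.ndim != 2 or self.pv_z.shape[1] != self.K:
            raise PlsaError("pv_z has wrong shape")
        for name, arr in (("pz", self.pz), ("pi_z", self.pi_z), ("pv_z", self.pv_z)):
            if np.any(arr < 0) or np.any(arr > 1):
                raise PlsaError(f"{name} has entries outside [0, 1]")
        if abs(self.pz.sum() - 1.0) > 1e-10:
            raise PlsaError("pz does not sum to 1")
        for name, arr in (("pi_z", self.pi_z), ("pv_z", self.pv_z)):
            if np.max(np.abs(arr.sum(axis=0) - 1.0)) > 1e-10:
                raise PlsaError(f"columns of {name} do not sum to 1")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "k": self.K,
            "pz": self.pz.tolist(),
            "pi_z": self.pi_z.tolist(),
            "pv_z": self.pv_z.tolist(),
            "loglik": float(self.loglik),
            "n_iter": int(self.n_iter),
            "seed": self.seed,
            "converged": bool(self.converged),
            "row_ids": [str(r) for r in self.row_ids],
            "column_labels": list(self.column_labels),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "PlsaModel":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            K=d["k"],
            pz=np.asarray(d["pz"], dtype=float),
            pi_z=np.asarray(d["pi_z"], dtype=float),
            pv_z=np.asarray(d["pv_z"], dtype=float),
            loglik=d["loglik"],
            n_iter=d["n_iter"],
            seed=d["seed"],
            converged=d["converged"],
            row_ids=d["row_ids"],
            column_labels=d["column_labels"],
        )


# ---------------------------------------------------------------------------
# internals on raw arrays (fit-time hot path)
# ---------------------------------------------------------------------------


def _support(matrix: CooccurrenceMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(rows, cols, weights) of the nonzero cells."""
    rows, cols = np.nonzero(matrix.n)
    w = matrix.n[rows, cols].astype(float)
    return rows, cols, w


def _cell_probs(pz, pi_z, pv_z, rows, cols) -> np.ndarray:
    """P(i_t, v_t) for each observed cell t."""
    return np.einsum("tk,tk,k->t", pi_z[rows], pv_z[cols], pz, optimize=True)


def _loglik(pz, pi_z, pv_z, rows, cols, w) -> float:
    if len(rows) == 0:
        return 0.0
    s = _cell_probs(pz, pi_z, pv_z, rows, cols)
    if np.any(s <= 0):
        raise PlsaError(
            "observed cell with zero modeled probability (probability floor broken)"
        )
    return float(w @ np.log(s))


def _em_update(pz, pi_z, pv_z, rows, cols, w, shape, floor):
    """One EM iteration; returns (pz', pi_z', pv_z', loglik-before-update)."""
    I, V = shape
    K = len(pz)
    s = _cell_probs(pz, pi_z, pv_z, rows, cols)
    if np.any(s <= 0):
        raise PlsaError(
            "observed cell with zero modeled probability (probability floor broken)"
        )
    ll = float(w @ np.log(s))
    # responsibilities folded into sparse products:
    #   pi_acc[i,k] = P(z=k)P(i|k) * sum_v n(i,v) P(v|k) / s(i,v)
    T = csr_matrix((w / s, (rows, cols)), shape=(I, V))
    pi_acc = pi_z * pz[None, :] * (T @ pv_z)
    pv_acc = pv_z * pz[None, :] * (T.T @ pi_z)
    pz_acc = pi_acc.sum(axis=0)
    total = pz_acc.sum()
    if total <= 0:
        raise PlsaError("empty support: nothing to update")
    pz_new = pz_acc / total
    pi_new = _normalize_columns(pi_acc, floor)
    pv_new = _normalize_columns(pv_acc, floor)
    pz_new = np.where(pz_new <= 0, floor, pz_new)
    pz_new = pz_new / pz_new.sum()
    return pz_new, pi_new, pv_new, ll


def _normalize_columns(acc: np.ndarray, floor: float) -> np.ndarray:
    # floor only exact zeros: keeps EM ascent intact to rounding error while
    # guarding against log(0) on degenerate inputs
    acc = np.where(acc <= 0, floor, acc)
    return acc / acc.sum(axis=0, keepdims=True)


def _random_init(K: int, I: int, V: int, rng: np.random.Generator):
    pz = np.full(K, 1.0 / K)
    pi_z = rng.dirichlet(np.ones(I), size=K).T  # columns are Dirichlet(1) draws
    pv_z = rng.dirichlet(np.ones(V), size=K).T
    return pz, pi_z, pv_z


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def log_likelihood(model: PlsaModel, matrix: CooccurrenceMatrix) -> float:
    """``sum_{i,v} n(i,v) ln sum_z P(z)P(i|z)P(v|z)``; zero cells contribute nothing."""
    I, V = matrix.shape
    if model.pi_z.shape[0] != I or model.pv_z.shape[0] != V:
        raise PlsaError(
            f"model dimensions ({model.pi_z.shape[0]} x {model.pv_z.shape[0]}) "
            f"do not match matrix ({I} x {V})"
        )
    rows, cols, w = _support(matrix)
    return _loglik(model.pz, model.pi_z, model.pv_z, rows, cols, w)


def em_step(model: PlsaModel, matrix: CooccurrenceMatrix, floor: float = 1e-12) -> PlsaModel:
    """One E+M iteration; returns a new normalized model (never mutates the input)."""
    I, V = matrix.shape
    if model.pi_z.shape[0] != I or model.pv_z.shape[0] != V:
        raise PlsaError("model dimensions do not match matrix")
    rows, cols, w = _support(matrix)
    pz, pi_z, pv_z, _ = _em_update(
        model.pz, model.pi_z, model.pv_z, rows, cols, w, (I, V), floor
    )
    return PlsaModel(
        K=model.K,
        pz=pz,
        pi_z=pi_z,
        pv_z=pv_z,
        loglik=_loglik(pz, pi_z, pv_z, rows, cols, w),
        n_iter=model.n_iter + 1,
        seed=model.seed,
        converged=model.converged,
        row_ids=model.row_ids,
        column_labels=model.column_labels,
    )


def _run_chain(rows, cols, w, shape, K, seed, config):
    rng = np.random.default_rng(seed)
    I, V = shape
    pz, pi_z, pv_z = _random_init(K, I, V, rng)
    prev_ll = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        pz, pi_z, pv_z, ll_before = _em_update(
            pz, pi_z, pv_z, rows, cols, w, shape, config.floor
        )
        if np.isfinite(prev_ll) and abs(ll_before - prev_ll) <= config.tol * abs(prev_ll):
            converged = True
            break
        prev_ll = ll_before
    final_ll = _loglik(pz, pi_z, pv_z, rows, cols, w)
    return pz, pi_z, pv_z, final_ll, n_iter, converged


def fit_plsa(matrix: CooccurrenceMatrix, K: int, config: FitConfig | None = None) -> PlsaModel:
    """Best-of-restarts EM fit of a K-cluster model.

    Each restart ``r`` initializes from seed ``config.seed + r`` and iterates
    until the relative log-likelihood change drops below ``config.tol`` or
    ``max_iter`` is hit (non-convergence yields ``converged=False`` plus a
    warning, not an error).  The chain with the highest final log-likelihood
    is returned, with its seed and iteration count recorded.
    """
    config = config or FitConfig()
    config.validate()
    I, V = matrix.shape
    if K < 1:
        raise PlsaError(f"K must be >= 1, got {K}")
    if I == 0 or V == 0:
        raise PlsaError("matrix is empty")
    if K > I or K > V:
        raise PlsaError(f"K={K} exceeds matrix dimensions ({I} individuals, {V} levels)")
    rows, cols, w = _support(matrix)
    best = None
    for r in range(config.n_restarts):
        seed = config.seed + r
        pz, pi_z, pv_z, ll, n_iter, converged = _run_chain(
            rows, cols, w, (I, V), K, seed, config
        )
        if best is None or ll > best[3]:
            best = (pz, pi_z, pv_z, ll, n_iter, converged, seed)
    pz, pi_z, pv_z, ll, n_iter, converged, seed = best
    if not converged:
        warnings.warn(
            f"EM did not converge within {config.max_iter} iterations (K={K}, seed={seed})",
            RuntimeWarning,
            stacklevel=2,
        )
    return PlsaModel(
        K=K,
        pz=pz,
        pi_z=pi_z,
        pv_z=pv_z,
        loglik=ll,
        n_iter=n_iter,
        seed=seed,
        converged=converged,
        row_ids=list(matrix.row_ids),
        column_labels=list(matrix.column_labels),
    )


def saturated_loglik(matrix: CooccurrenceMatrix) -> float:
    """Upper bound ``sum n ln(n/R)`` attained by the saturated cell distribution."""
    rows, cols, w = _support(matrix)
    if len(w) == 0:
        return 0.0
    R = w.sum()
    return float(w @ np.log(w / R))


def responsibilities(model: PlsaModel) -> np.ndarray:
    """Posterior cluster membership A(z|i) per individual: P(i|z)P(z) renormalized."""
    r = model.pi_z * model.pz[None, :]
    denom = r.sum(axis=1, keepdims=True)
    uniform = np.full_like(r, 1.0 / model.K)
    return np.where(denom > 0, r / np.where(denom > 0, denom, 1.0), uniform)


def _folded_em(
    model: PlsaModel,
    matrix: CooccurrenceMatrix,
    max_iter: int,
    tol: float,
) -> tuple[float, np.ndarray, dict[str, np.ndarray], np.ndarray]:
    """EM on the folded latent-class model, warm-started from the fit.

    Folds the per-individual parameters out of the joint model: classes
    keep only weights pi_k and per-variable level distributions theta_k,
    and each row's membership is the Bayes posterior under those.
    Initialized at the fitted posterior memberships A(z|i) and iterated to
    convergence.  Returns ``(loglik, weights, theta, memberships)``.
    """
    I = matrix.shape[0]
    r = responsibilities(model)
    levels = {var: np.argmax(matrix.n[:, sl], axis=1) for var, sl in matrix.var_slices.items()}
    n_levels = {var: sl.stop - sl.start for var, sl in matrix.var_slices.items()}
    prev = -np.inf
    ll = 0.0
    pi = np.full(model.K, 1.0 / model.K)
    theta: dict[str, np.ndarray] = {}
    for _ in range(max_iter):
        pi = np.maximum(r.sum(axis=0) / I, 1e-300)
        logp = np.tile(np.log(pi)[None, :], (I, 1))
        for var, lev in levels.items():
            acc = np.zeros((n_levels[var], model.K))
            np.add.at(acc, lev, r)
            acc = np.maximum(acc, 1e-12)
            acc /= acc.sum(axis=0, keepdims=True)
            theta[var] = acc.T  # (K, L)
            logp += np.log(acc[lev, :])
        mx = logp.max(axis=1)
        ll = float(np.sum(mx + np.log(np.exp(logp - mx[:, None]).sum(axis=1))))
        r = np.exp(logp - mx[:, None])
        r /= r.sum(axis=1, keepdims=True)
        if abs(ll - prev) <= tol * abs(ll):
            break
        prev = ll
    return ll, pi / pi.sum(), theta, r


def class_conditionals(
    model: PlsaModel,
    matrix: CooccurrenceMatrix,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Cluster weights and per-variable level distributions implied by the fit.

    These are the folded latent-class maximum-likelihood estimates
    (posterior-weighted aggregation of the one-hot data, refined by EM from
    the fitted memberships; see :func:`_folded_em`).  They are the
    consistent estimator of a generating segment's level distribution —
    the raw ``pv_z`` columns are sharpened by the per-individual
    parameters and overstate within-cluster concentration, while the
    unrefined one-step aggregate inherits whatever softness the joint
    fit's memberships carry.

    Returns ``(weights, {variable: (K, L_var) array})``.
    """
    _, pi, theta, _ = _folded_em(model, matrix, max_iter, tol)
    return pi, theta


def class_marginal_loglik(
    model: PlsaModel,
    matrix: CooccurrenceMatrix,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> float:
    """Marginal log-likelihood of the rows under the folded latent-class model.

    The joint-likelihood parameterization carries one membership vector per
    individual, a parameter count that grows with the sample; penalized
    criteria computed on it are dominated by those incidental parameters.
    This value is ``sum_i ln sum_k pi_k prod_j theta_k(x_ij)`` at the
    folded-model MLE — a likelihood whose dimension does not grow with the
    sample, suitable for AIC/BIC.
    """
    ll, _, _, _ = _folded_em(model, matrix, max_iter, tol)
    return ll


def loglik_trace(
    matrix: CooccurrenceMatrix, K: int, seed: int, n_iter: int, floor: float = 1e-12
) -> np.ndarray:
    """Log-likelihood after each of ``n_iter`` EM iterations from one seeded init."""
    rows, cols, w = _support(matrix)
    I, V = matrix.shape
    rng = np.random.default_rng(seed)
    pz, pi_z, pv_z = _random_init(K, I, V, rng)
    out = []
    for _ in range(n_iter):
        pz, pi_z, pv_z, _ = _em_update(pz, pi_z, pv_z, rows, cols, w, (I, V), floor)
        out.append(_loglik(pz, pi_z, pv_z, rows, cols, w))
    return np.asarray(out)
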