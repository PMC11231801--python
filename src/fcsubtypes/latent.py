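"""Sparse canonical correlation between connectome edges and symptom scores.

The statistical core of the package.  Ordinal neuropsychiatric symptom
(NPS) scores are first decorrelated by PCA; the PC scores and the edge
view are then linked by sparse CCA solved as an L1-penalized rank-1
matrix decomposition (PMD) of the standardized cross-product
``C = X'Y`` with deflation:

    maximize  u' C v   s.t.  ||u||_2 <= 1, ||v||_2 <= 1,
                             ||u||_1 <= c1, ||v||_1 <= c2

via alternating soft-thresholded updates, where ``c1 = penalty_x *
sqrt(p)`` and ``c2 = penalty_y * sqrt(q)`` (PMA-style scaling, penalty in
(0, 1]).  This diagonal-penalized formulation treats the within-view
covariances as identity — the appropriate simplification when the edge
view has far more features than participants.

Inference: hyperparameters are chosen by the mean held-out Pearson
correlation of paired canonical variates in k-fold CV (PCA refit inside
every fold); significance comes from a permutation test that shuffles
participant rows of one view and refits the full model, with
Benjamini-Hochberg FDR across components.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PCAModel",
    "SCCAHyperparams",
    "SCCAModel",
    "LatentModel",
    "CVResult",
    "PermutationResult",
    "PMDResult",
    "fit_pca",
    "pmd_rank1",
    "fit_scca",
    "fit_latent",
    "cv_select",
    "permutation_test",
    "bh_fdr",
    "impute_nps",
    "support_recovery",
]


class ZeroDirectionError(ValueError):
    """The cross-product carries no signal (all zeros)."""


# --------------------------------------------------------------------------
# PCA on the symptom view


@dataclass
class PCAModel:
    """Frozen PCA of the NPS view: centering plus orthonormal loadings."""

    mean_: np.ndarray
    components_: np.ndarray            # k x q, rows orthonormal
    explained_variance_ratio_: np.ndarray
    n_components: int

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[1] != self.mean_.size:
            raise ValueError(
                f"expected {self.mean_.size} columns, got {x.shape[1]}"
            )
        return (x - self.mean_) @ self.components_.T


def fit_pca(
    nps: np.ndarray,
    variance_threshold: float = 0.8,
    n_components: int | None = None,
) -> PCAModel:
    """PCA of the symptom matrix, keeping the smallest component count
    whose cumulative explained-variance ratio exceeds ``variance_threshold``
    (or exactly ``n_components`` when given).

    Constant columns are harmless (they carry zero variance after
    centering); missing values are not accepted — impute first.
    """
    nps = np.asarray(nps, dtype=float)
    if nps.ndim != 2 or nps.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 participants")
    if np.isnan(nps).any():
        raise ValueError("missing entries present; run impute_nps first")
    if n_components is None:
        if not (0.0 < variance_threshold <= 1.0):
            raise ValueError("variance_threshold must lie in (0, 1]")
    full = PCA(svd_solver="full").fit(nps)
    evr = full.explained_variance_ratio_
    if n_components is None:
        k = int(np.searchsorted(np.cumsum(evr), variance_threshold) + 1)
        k = min(k, evr.size)
    else:
        if not (1 <= n_components <= min(nps.shape)):
            raise ValueError("n_components out of range")
        k = n_components
    return PCAModel(
        mean_=full.mean_.copy(),
        components_=full.components_[:k].copy(),
        explained_variance_ratio_=evr[:k].copy(),
        n_components=k,
    )


def impute_nps(nps: np.ndarray, mode: str = "zero") -> tuple[np.ndarray, int]:
    """Fill missing NPS entries.

    ``zero`` treats a missing domain as symptom-absent (score 0) — the
    default, consistent with an at-least-one-symptom inclusion rule;
    ``median`` substitutes the per-domain median of observed scores.
    Returns the imputed matrix and the number of filled cells.
    """
    nps = np.asarray(nps, dtype=float).copy()
    mask = np.isnan(nps)
    count = int(mask.sum())
    if count:
        if mode == "zero":
            nps[mask] = 0.0
        elif mode == "median":
            med = np.nanmedian(nps, axis=0)
            med = np.where(np.isnan(med), 0.0, med)
            nps[mask] = np.broadcast_to(med, nps.shape)[mask]
        else:
            raise ValueError(f"unknown imputation mode {mode!r}")
    return nps, count


# --------------------------------------------------------------------------
# Penalized rank-1 matrix decomposition


def _l1_unit_direction(w: np.ndarray, c: float) -> np.ndarray:
    """argmax of u'w over the set {||u||_2 <= 1, ||u||_1 <= c}.

    The maximizer is soft-threshold-then-L2-normalize, with threshold 0
    when the plain normalized vector is already feasible and otherwise
    the unique threshold at which the L1 constraint becomes active.
    That threshold is found in closed form: with magnitudes sorted
    descending, the L1/L2 ratio of the thresholded vector is piecewise
    smooth between consecutive magnitudes, and on the segment where m
    coordinates survive the active-constraint condition
    ``(S_m - m t)^2 = c^2 (Q_m - 2 S_m t + m t^2)`` is a quadratic in
    the threshold t (S_m, Q_m cumulative sum / sum of squares).
    """
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise ZeroDirectionError("cannot orient a zero vector")
    u = w / nrm
    if np.abs(u).sum() <= c:
        return u
    a = np.sort(np.abs(w))[::-1]
    p = a.size
    S = np.cumsum(a)
    Q = np.cumsum(a**2)
    m = np.arange(1, p + 1, dtype=float)
    A = m * (m - c**2)
    B = -2.0 * S * (m - c**2)
    Cq = S**2 - c**2 * Q
    disc = np.maximum(B**2 - 4.0 * A * Cq, 0.0)
    lam = None
    with np.errstate(divide="ignore", invalid="ignore"):
        sqrt_disc = np.sqrt(disc)
        roots = np.stack([(-B - sqrt_disc) / (2.0 * A),
                          (-B + sqrt_disc) / (2.0 * A)])
    upper = a
    lower = np.append(a[1:], 0.0)
    eps = 1e-12 * max(a[0], 1.0)
    ok = (roots >= lower - eps) & (roots < upper + eps) & np.isfinite(roots)
    for side, seg in np.argwhere(ok):
        t = float(np.clip(roots[side, seg], 0.0, a[0]))
        mm = seg + 1.0
        l1 = S[seg] - mm * t
        l2sq = Q[seg] - 2.0 * S[seg] * t + mm * t * t
        if l1 <= 0 or l2sq <= 0:
            continue
        if abs(l1 / np.sqrt(l2sq) - c) < 1e-6 * c:
            lam = t
            break
    if lam is None:  # numerically degenerate segment: bisection fallback
        lo, hi = 0.0, float(a[0])
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            s = np.maximum(a - mid, 0.0)
            l2 = np.sqrt((s**2).sum())
            if l2 == 0 or s.sum() / l2 > c:
                lo = mid
            else:
                hi = mid
        lam = hi
    s = np.sign(w) * np.maximum(np.abs(w) - lam, 0.0)
    return s / np.linalg.norm(s)


@dataclass
class PMDResult:
    u: np.ndarray
    v: np.ndarray
    d: float
    n_iter: int
    converged: bool
    objective_trace: np.ndarray


def pmd_rank1(
    C: np.ndarray,
    c1: float,
    c2: float,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> PMDResult:
    """Leading penalized singular triplet of a cross-product matrix.

    Alternates the closed-form L1/L2-constrained updates for ``u`` and
    ``v`` from the leading right singular vector of ``C``; the objective
    ``u'Cv`` is non-decreasing across iterations.  With both penalties at
    their upper bounds the constraints are inactive and the result is the
    ordinary leading singular triplet.

    Non-convergence within ``max_iter`` is flagged, not raised.
    """
    C = np.asarray(C, dtype=float)
    p, q = C.shape
    if not (1.0 <= c1 <= np.sqrt(p) + 1e-12):
        raise ValueError(f"c1 must lie in [1, sqrt(p)={np.sqrt(p):.3f}]")
    if not (1.0 <= c2 <= np.sqrt(q) + 1e-12):
        raise ValueError(f"c2 must lie in [1, sqrt(q)={np.sqrt(q):.3f}]")
    if not np.any(C):
        raise ZeroDirectionError("cross-product matrix is identically zero")

    # deterministic start: leading right singular vector
    v = np.linalg.svd(C, full_matrices=False)[2][0]
    u = np.zeros(p)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        u_new = _l1_unit_direction(C @ v, c1)
        v_new = _l1_unit_direction(C.T @ u_new, c2)
        trace.append(float(u_new @ C @ v_new))
        delta = max(np.abs(u_new - u).max(), np.abs(v_new - v).max())
        u, v = u_new, v_new
        if delta < tol:
            converged = True
            break
    d = float(u @ C @ v)
    if d < 0:  # orient the triplet to a non-negative singular value
        u, d = -u, -d
    return PMDResult(u=u, v=v, d=d, n_iter=it, converged=converged,
                     objective_trace=np.asarray(trace))


# --------------------------------------------------------------------------
# Sparse CCA with deflation


@dataclass(frozen=True)
class SCCAHyperparams:
    """PMA-scaled penalties plus model sizes.

    ``penalty_x``/``penalty_y`` in (0, 1] multiply sqrt(dimension) to give
    the L1 bounds; ``n_components`` is the number of deflation rounds;
    ``n_pcs`` the number of symptom principal components entering the fit.
    """

    penalty_x: float = 0.6
    penalty_y: float = 0.6
    n_components: int = 2
    n_pcs: int = 7

    def __post_init__(self) -> None:
        for name in ("penalty_x", "penalty_y"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be >= 1")


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    scale = x.std(axis=0, ddof=1)
    scale = np.where(scale == 0, 1.0, scale)
    return (x - mean) / scale, mean, scale


@dataclass
class SCCAModel:
    """Fitted sparse CCA: paired sparse weights, canonical correlations,
    singular values, covariance-explained fractions, and the view
    standardization needed to freeze the transform."""

    u: np.ndarray                      # p x K
    v: np.ndarray                      # q x K
    d: np.ndarray                      # K singular values (>= 0)
    r: np.ndarray                      # K canonical correlations
    cov_explained: np.ndarray          # d / sum(d)
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray
    hyperparams: SCCAHyperparams
    sign_flips: np.ndarray             # +/-1 orientation applied per component
    converged: np.ndarray
    n_iter: np.ndarray

    @property
    def n_components(self) -> int:
        return self.u.shape[1]

    def transform_x(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.x_mean.size:
            raise ValueError(
                f"edge view: expected {self.x_mean.size} features, got {x.shape[-1]}"
            )
        return ((x - self.x_mean) / self.x_scale) @ self.u

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if y.shape[-1] != self.y_mean.size:
            raise ValueError(
                f"symptom view: expected {self.y_mean.size} features, got {y.shape[-1]}"
            )
        return ((y - self.y_mean) / self.y_scale) @ self.v


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def fit_scca(
    X: np.ndarray,
    Y: np.ndarray,
    hp: SCCAHyperparams,
    standardize: bool = True,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> SCCAModel:
    """Fit K sparse canonical components by PMD with deflation.

    Component 1 is the penalized leading triplet of ``C = X'Y`` (views
    column-standardized, sample SD with ddof=1); subsequent components
    come from the rank-1-deflated residual ``C - d u v'``.  Each pair is
    sign-oriented so its largest-magnitude symptom-side weight is
    positive (canonical directions are sign-indeterminate; the flip is
    recorded).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("views must have the same number of rows")
    p, q = X.shape[1], Y.shape[1]
    K = hp.n_components
    if K > min(p, q):
        raise ValueError(f"n_components={K} exceeds min(p, q)={min(p, q)}")

    if standardize:
        Xs, x_mean, x_scale = _standardize(X)
        Ys, y_mean, y_scale = _standardize(Y)
    else:
        Xs, x_mean, x_scale = X, np.zeros(p), np.ones(p)
        Ys, y_mean, y_scale = Y, np.zeros(q), np.ones(q)

    C = Xs.T @ Ys
    c1 = hp.penalty_x * np.sqrt(p)
    c2 = hp.penalty_y * np.sqrt(q)
    c1 = max(c1, 1.0)  # PMA lower bound: the L1 ball must contain a unit vector
    c2 = max(c2, 1.0)

    U = np.zeros((p, K))
    V = np.zeros((q, K))
    d = np.zeros(K)
    r = np.zeros(K)
    flips = np.ones(K)
    conv = np.zeros(K, dtype=bool)
    iters = np.zeros(K, dtype=int)
    for k in range(K):
        res = pmd_rank1(C, c1, c2, tol=tol, max_iter=max_iter)
        u, v = res.u, res.v
        # orientation: largest-|weight| symptom-side loading positive
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            u, v = -u, -v
            flips[k] = -1.0
        U[:, k], V[:, k], d[k] = u, v, res.d
        conv[k], iters[k] = res.converged, res.n_iter
        r[k] = _safe_corr(Xs @ u, Ys @ v)
        C = C - res.d * np.outer(res.u, res.v)
        if not np.any(C):  # fully explained; remaining components stay zero
            K_eff = k + 1
            U, V, d, r = U[:, :K_eff], V[:, :K_eff], d[:K_eff], r[:K_eff]
            flips, conv, iters = flips[:K_eff], conv[:K_eff], iters[:K_eff]
            break

    total = d.sum()
    cov_explained = d / total if total > 0 else np.zeros_like(d)
    return SCCAModel(
        u=U, v=V, d=d, r=r, cov_explained=cov_explained,
        x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, y_scale=y_scale,
        hyperparams=hp, sign_flips=flips, converged=conv, n_iter=iters,
    )


# --------------------------------------------------------------------------
# The frozen end-to-end transform (PCA + sCCA)


@dataclass
class LatentModel:
    """Frozen discovery-fitted transform: NPS imputation + PCA + sCCA.

    ``transform`` maps raw edges and raw NPS scores to paired latent
    scores; applying it to the training data reproduces the fit-time
    scores exactly, which is what replication transfer relies on.
    """

    pca: PCAModel
    scca: SCCAModel
    imputation: str = "zero"
    version: str = "0.1.0"

    def transform(self, edges: np.ndarray, nps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        nps_filled, _ = impute_nps(nps, self.imputation)
        pcs = self.pca.transform(nps_filled)
        return self.scca.transform_x(edges), self.scca.transform_y(pcs)

    def to_json(self) -> str:
        m = self.scca
        doc = {
            "version": self.version,
            "imputation": self.imputation,
            "pca": {
                "mean": self.pca.mean_.tolist(),
                "components": self.pca.components_.tolist(),
                "explained_variance_ratio": self.pca.explained_variance_ratio_.tolist(),
                "n_components": self.pca.n_components,
            },
            "scca": {
                "u": m.u.tolist(), "v": m.v.tolist(),
                "d": m.d.tolist(), "r": m.r.tolist(),
                "cov_explained": m.cov_explained.tolist(),
                "x_mean": m.x_mean.tolist(), "x_scale": m.x_scale.tolist(),
                "y_mean": m.y_mean.tolist(), "y_scale": m.y_scale.tolist(),
                "sign_flips": m.sign_flips.tolist(),
                "converged": m.converged.tolist(),
                "n_iter": m.n_iter.tolist(),
                "hyperparams": {
                    "penalty_x": m.hyperparams.penalty_x,
                    "penalty_y": m.hyperparams.penalty_y,
                    "n_components": m.hyperparams.n_components,
                    "n_pcs": m.hyperparams.n_pcs,
                },
            },
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "LatentModel":
        doc = json.loads(text)
        pca = PCAModel(
            mean_=np.asarray(doc["pca"]["mean"]),
            components_=np.asarray(doc["pca"]["components"]),
            explained_variance_ratio_=np.asarray(doc["pca"]["explained_variance_ratio"]),
            n_components=doc["pca"]["n_components"],
        )
        s = doc["scca"]
        scca = SCCAModel(
            u=np.asarray(s["u"]), v=np.asarray(s["v"]),
            d=np.asarray(s["d"]), r=np.asarray(s["r"]),
            cov_explained=np.asarray(s["cov_explained"]),
            x_mean=np.asarray(s["x_mean"]), x_scale=np.asarray(s["x_scale"]),
            y_mean=np.asarray(s["y_mean"]), y_scale=np.asarray(s["y_scale"]),
            hyperparams=SCCAHyperparams(**s["hyperparams"]),
            sign_flips=np.asarray(s["sign_flips"]),
            converged=np.asarray(s["converged"], dtype=bool),
            n_iter=np.asarray(s["n_iter"], dtype=int),
        )
        return cls(pca=pca, scca=scca, imputation=doc["imputation"],
                   version=doc["version"])


def fit_latent(
    edges: np.ndarray,
    nps: np.ndarray,
    hp: SCCAHyperparams,
    imputation: str = "zero",
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> LatentModel:
    """Fit the full discovery transform: impute -> PCA(n_pcs) -> sCCA."""
    nps_filled, _ = impute_nps(nps, imputation)
    pca = fit_pca(nps_filled, n_components=hp.n_pcs)
    pcs = pca.transform(nps_filled)
    scca = fit_scca(edges, pcs, hp, tol=tol, max_iter=max_iter)
    return LatentModel(pca=pca, scca=scca, imputation=imputation)


# --------------------------------------------------------------------------
# Cross-validated hyperparameter selection


@dataclass
class CVResult:
    """Per-fold held-out canonical-variate correlations over the grid."""

    table: pd.DataFrame                # n_pcs, penalty, fold, component, test_r
    means: pd.DataFrame                # n_pcs, penalty, component, mean_r
    best_n_pcs: int
    best_penalty: float
    fold_models: list | None = None


def cv_select(
    edges: np.ndarray,
    nps: np.ndarray,
    n_pcs_grid: Sequence[int] = (5, 6, 7, 8),
    penalty_grid: Sequence[float] = (0.4, 0.6, 0.8),
    n_folds: int = 10,
    n_components: int = 1,
    imputation: str = "zero",
    seed: int = 0,
    return_models: bool = False,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> CVResult:
    """Grid search by mean held-out correlation of the first variate pair.

    Strict hygiene: imputation statistics, PCA, standardization and sCCA
    are all fit on training participants only; held-out participants are
    only ever transformed.  Ties break toward the smaller penalty, then
    fewer PCs.
    """
    edges = np.asarray(edges, dtype=float)
    nps = np.asarray(nps, dtype=float)
    if len(n_pcs_grid) == 0 or len(penalty_grid) == 0:
        raise ValueError("hyperparameter grid is empty")
    n = edges.shape[0]
    if n < n_folds:
        raise ValueError("need at least one participant per fold")
    folds = list(KFold(n_splits=n_folds, shuffle=True, random_state=seed).split(edges))
    if min(len(te) for _, te in folds) < 3:
        raise ValueError("a fold has fewer than 3 participants")

    rows = []
    models: list = []
    for n_pcs in n_pcs_grid:
        for pen in penalty_grid:
            hp = SCCAHyperparams(
                penalty_x=pen, penalty_y=pen,
                n_components=n_components, n_pcs=n_pcs,
            )
            for f, (tr, te) in enumerate(folds):
                model = fit_latent(edges[tr], nps[tr], hp,
                                   imputation=imputation, tol=tol,
                                   max_iter=max_iter)
                xs, ys = model.transform(edges[te], nps[te])
                for k in range(model.scca.n_components):
                    rows.append(
                        {"n_pcs": n_pcs, "penalty": pen, "fold": f,
                         "component": k + 1,
                         "test_r": _safe_corr(xs[:, k], ys[:, k])}
                    )
                if return_models:
                    models.append({"n_pcs": n_pcs, "penalty": pen,
                                   "fold": f, "model": model})
    table = pd.DataFrame(rows)
    means = (
        table.groupby(["n_pcs", "penalty", "component"], as_index=False)["test_r"]
        .mean()
        .rename(columns={"test_r": "mean_r"})
    )
    first = means[means["component"] == 1].copy()
    # highest mean r; ties -> smaller penalty, then fewer PCs
    first = first.sort_values(
        ["mean_r", "penalty", "n_pcs"], ascending=[False, True, True]
    )
    best = first.iloc[0]
    return CVResult(
        table=table, means=means,
        best_n_pcs=int(best["n_pcs"]), best_penalty=float(best["penalty"]),
        fold_models=models if return_models else None,
    )


# --------------------------------------------------------------------------
# Permutation inference and FDR


@dataclass
class PermutationResult:
    observed_r: np.ndarray
    null_r: np.ndarray                 # n_perm x K
    p: np.ndarray                      # one-sided, add-one corrected
    q: np.ndarray                      # BH-FDR across components


def _cv_statistic(
    X: np.ndarray, Y: np.ndarray, hp: SCCAHyperparams,
    folds: list, tol: float, max_iter: int,
) -> np.ndarray:
    """Mean held-out correlation of paired variates per component."""
    vals = np.zeros((len(folds), hp.n_components))
    for f, (tr, te) in enumerate(folds):
        m = fit_scca(X[tr], Y[tr], hp, tol=tol, max_iter=max_iter)
        xs, ys = m.transform_x(X[te]), m.transform_y(Y[te])
        for k in range(m.n_components):
            vals[f, k] = _safe_corr(xs[:, k], ys[:, k])
    return vals.mean(axis=0)


def permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    hp: SCCAHyperparams,
    n_perm: int = 1000,
    seed: int = 0,
    statistic: str = "cv",
    cv_folds: int = 10,
    tol: float = 1e-7,
    max_iter: int = 200,
) -> PermutationResult:
    """Permutation null for the canonical correlations.

    Each permutation shuffles the participant rows of ``Y`` only
    (equivalent, under exchangeability, to shuffling both views) and
    refits the full sparse CCA at the given hyperparameters.  One-sided
    p-values use the add-one correction p = (1 + #{null >= obs}) /
    (1 + n_perm); q-values are Benjamini-Hochberg across components.

    ``statistic`` controls what is recorded per (re)fit:

    * ``"cv"`` (default): the mean held-out Pearson correlation of the
      paired variates over ``cv_folds`` folds, the same quantity used to
      report model performance.  With many more edges than participants
      an unrestricted refit can overfit a shuffled cohort as easily as
      the real one, so in-sample correlations carry almost no signal;
      held-out correlations restore power.
    * ``"insample_r"``: the in-sample canonical correlation of the full
      refit (one fit per permutation; cheap, valid under the null).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if statistic not in ("cv", "insample_r"):
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    K = hp.n_components
    if statistic == "cv":
        folds = list(
            KFold(n_splits=cv_folds, shuffle=True, random_state=seed).split(X)
        )
        observed = _cv_statistic(X, Y, hp, folds, tol, max_iter)
        null = np.zeros((n_perm, K))
        for b in range(n_perm):
            perm = rng.permutation(Y.shape[0])
            null[b] = _cv_statistic(X, Y[perm], hp, folds, tol, max_iter)
    else:
        obs_model = fit_scca(X, Y, hp, tol=tol, max_iter=max_iter)
        observed = obs_model.r.copy()
        null = np.zeros((n_perm, K))
        for b in range(n_perm):
            perm = rng.permutation(Y.shape[0])
            m = fit_scca(X, Y[perm], hp, tol=tol, max_iter=max_iter)
            null[b, : m.n_components] = m.r
    p = (1.0 + (null >= observed).sum(axis=0)) / (1.0 + n_perm)
    return PermutationResult(observed_r=observed, null_r=null, p=p,
                             q=bh_fdr(p))


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


# --------------------------------------------------------------------------
# Recovery diagnostics


def support_recovery(
    u_hat: np.ndarray,
    u_true: np.ndarray,
    method: str = "top",
) -> tuple[float, float]:
    """Recall and precision of the recovered sparse support.

    ``method='top'`` (default) scores the s largest-|weight| fitted
    coordinates against the true support of size s — the right notion
    under PMA-style penalties, where the L1 bound is typically saturated
    and many coordinates carry tiny nonzero weight.  ``method='nonzero'``
    uses the raw nonzero pattern.
    """
    u_hat = np.asarray(u_hat, dtype=float).ravel()
    u_true = np.asarray(u_true, dtype=float).ravel()
    true_sup = set(np.flatnonzero(u_true != 0).tolist())
    if not true_sup:
        raise ValueError("true weight vector has empty support")
    if method == "top":
        s = len(true_sup)
        est = set(np.argsort(-np.abs(u_hat))[:s].tolist())
    elif method == "nonzero":
        est = set(np.flatnonzero(u_hat != 0).tolist())
    else:
        raise ValueError(f"unknown method {method!r}")
    if not est:
        return 0.0, 0.0
    hit = len(est & true_sup)
    return hit / len(true_sup), hit / len(est)
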