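"""miRNA–taxon association: CLR, sparse PLS, CIM, permutation FDR.

Counts are mapped to real space with a centered log-ratio transform (after
adding a pseudocount of 1), the two blocks are linked with a sparse partial
least squares (sPLS) regression, and the miRNA × taxon similarity matrix of
the clustered image map (CIM) is formed as the dot product of the two
feature-to-component correlation matrices.  Significance is attached by
shuffling the miRNA rows of the first correlation matrix, recomputing the
CIM many times, and counting permuted values that exceed the observed
magnitude; Benjamini–Hochberg adjustment is applied over all entries.

The sPLS follows the mixOmics formulation: per component, alternating
soft-thresholded singular directions of XᵀY with the soft threshold set at
the (keep+1)-th largest loading magnitude, regression-mode deflation of
both blocks on the X-score, and column standardisation before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import CountMatrix

__all__ = [
    "ClrMatrix",
    "SplsModel",
    "CimResult",
    "clr_transform",
    "spls_fit",
    "cim_matrix",
    "component_correlations",
    "permutation_pvalues",
    "bh_adjust",
    "correlate",
]


@dataclass
class ClrMatrix:
    """Centered log-ratio values (rows sum to 0) with their feature labels."""

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        row_sums = np.abs(self.values.sum(axis=1))
        if np.any(row_sums > 1e-9 * max(self.values.shape[1], 1)):
            raise ValueError("clr rows must sum to 0")


@dataclass
class SplsModel:
    """Fitted sparse PLS: loadings, X-scores and the standardisation used."""

    ncomp: int
    keep_x: list[int]
    keep_y: list[int]
    loadings_x: np.ndarray  # features_X × ncomp, unit norm columns
    loadings_y: np.ndarray  # features_Y × ncomp, unit norm columns
    scores: np.ndarray      # samples × ncomp (X latent components)
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray
    converged: list[bool] = field(default_factory=list)


@dataclass
class CimResult:
    """CIM similarity values with permutation p and BH q, feature-labeled."""

    values: pd.DataFrame  # miRNA × taxon
    p: pd.DataFrame
    q: pd.DataFrame
    n_iterations: int
    seed: int


def clr_transform(matrix: CountMatrix, pseudocount: float = 1.0) -> ClrMatrix:
    """clr(x)_ij = ln(x_ij + c) − mean_j ln(x_i· + c)."""
    counts = np.asarray(matrix.counts, dtype=float)
    if pseudocount <= 0 and np.any(counts + pseudocount <= 0):
        raise ValueError("pseudocount must make all counts positive")
    logs = np.log(counts + pseudocount)
    values = logs - logs.mean(axis=1, keepdims=True)
    return ClrMatrix(values, list(matrix.sample_ids), list(matrix.feature_ids),
                     pseudocount)


def _standardise(values: np.ndarray, label: str):
    mean = values.mean(axis=0)
    scale = values.std(axis=0, ddof=1)
    zero = np.flatnonzero(scale == 0)
    if zero.size:
        raise ValueError(
            f"{label}: constant column(s) at indices {zero.tolist()} "
            "cannot be scaled"
        )
    return (values - mean) / scale, mean, scale


def _soft_threshold_keep(v: np.ndarray, keep: int) -> np.ndarray:
    """Keep the ``keep`` largest-|·| entries, soft-shrunk at the cut value.

    Ties at the cut are broken by feature index (earlier kept), making the
    result deterministic.
    """
    p = v.size
    if keep >= p:
        return v.copy()
    order = np.lexsort((np.arange(p), -np.abs(v)))  # by |v| desc, then index
    kept = order[:keep]
    cut = np.abs(v[order[keep]])
    out = np.zeros_like(v)
    out[kept] = np.sign(v[kept]) * np.maximum(np.abs(v[kept]) - cut, 0.0)
    if not np.any(out):
        # all survivors tied with the cut: fall back to hard selection so the
        # direction is not lost
        out[kept] = v[kept]
    return out


def spls_fit(
    x: ClrMatrix,
    y: ClrMatrix,
    ncomp: int = 2,
    keep_x: int | list[int] = 20,
    keep_y: int | list[int] = 20,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> SplsModel:
    """Fit regression-mode sparse PLS of Y on X."""
    if x.sample_ids != y.sample_ids:
        raise ValueError("X and Y must share the same samples in order")
    n, p = x.values.shape
    q = y.values.shape[1]
    if ncomp > min(n, p, q):
        raise ValueError("ncomp exceeds data dimensions")
    keep_x = [keep_x] * ncomp if isinstance(keep_x, int) else list(keep_x)
    keep_y = [keep_y] * ncomp if isinstance(keep_y, int) else list(keep_y)

    xs, x_mean, x_scale = _standardise(x.values, "X")
    ys, y_mean, y_scale = _standardise(y.values, "Y")

    u_all = np.zeros((p, ncomp))
    v_all = np.zeros((q, ncomp))
    scores = np.zeros((n, ncomp))
    converged = []
    xd, yd = xs.copy(), ys.copy()
    for h in range(ncomp):
        m = xd.T @ yd
        # SVD initialisation
        u_svd, _, vt_svd = np.linalg.svd(m, full_matrices=False)
        u, v = u_svd[:, 0], vt_svd[0]
        ok = False
        for _ in range(max_iter):
            u_new = _soft_threshold_keep(m @ v, keep_x[h])
            u_new /= np.linalg.norm(u_new)
            v_new = _soft_threshold_keep(m.T @ u_new, keep_y[h])
            v_new /= np.linalg.norm(v_new)
            if (np.linalg.norm(u_new - u) < tol
                    and np.linalg.norm(v_new - v) < tol):
                u, v = u_new, v_new
                ok = True
                break
            u, v = u_new, v_new
        if not ok:
            warnings.warn(
                f"sPLS component {h + 1} did not converge in {max_iter} "
                "iterations",
                RuntimeWarning,
            )
        converged.append(ok)
        xi = xd @ u
        denom = xi @ xi
        # regression-mode deflation of both blocks on the X-score
        xd = xd - np.outer(xi, (xi @ xd) / denom)
        yd = yd - np.outer(xi, (xi @ yd) / denom)
        u_all[:, h], v_all[:, h], scores[:, h] = u, v, xi
    return SplsModel(
        ncomp, keep_x, keep_y, u_all, v_all, scores,
        x_mean, x_scale, y_mean, y_scale, converged,
    )


def _corr_with_scores(values: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson r of each column of ``values`` with each score column.

    Zero-variance columns yield NaN rows (reported, not fatal)."""
    vc = values - values.mean(axis=0)
    sc = scores - scores.mean(axis=0)
    v_sd = vc.std(axis=0)
    s_sd = sc.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (vc.T @ sc) / len(vc) / np.outer(v_sd, s_sd)
    return corr


def component_correlations(
    x: ClrMatrix, y: ClrMatrix, model: SplsModel
) -> tuple[np.ndarray, np.ndarray]:
    """(C_X, C_Y): correlations of X / Y features with the X-scores."""
    c_x = _corr_with_scores(x.values, model.scores)
    c_y = _corr_with_scores(y.values, model.scores)
    return c_x, c_y


def cim_matrix(x: ClrMatrix, y: ClrMatrix, model: SplsModel) -> pd.DataFrame:
    """CIM = C_X · C_Yᵀ, labeled miRNA × taxon."""
    c_x, c_y = component_correlations(x, y, model)
    bad_x = np.flatnonzero(np.isnan(c_x).all(axis=1))
    bad_y = np.flatnonzero(np.isnan(c_y).all(axis=1))
    if bad_x.size or bad_y.size:
        warnings.warn(
            f"zero-variance features set to NA: X {bad_x.tolist()}, "
            f"Y {bad_y.tolist()}",
            RuntimeWarning,
        )
    return pd.DataFrame(c_x @ c_y.T, index=x.feature_ids, columns=y.feature_ids)


def permutation_pvalues(
    c_x: np.ndarray,
    c_y: np.ndarray,
    observed_cim: np.ndarray,
    n_iter: int = 100_000,
    seed: int = 0,
    two_sided: bool = True,
    smoothed: bool = False,
) -> np.ndarray:
    """Permutation p-values by shuffling the miRNA rows of C_X.

    p[i,j] = #(|CIM*[i,j]| ≥ |observed[i,j]|) / n_iter (raw counts divided
    by iterations; ``smoothed`` uses (count+1)/(n_iter+1) instead).
    ``two_sided=False`` compares signed values.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be ≥ 1")
    rng = np.random.default_rng(seed)
    c_x = np.asarray(c_x)
    c_y = np.asarray(c_y)
    obs = np.abs(observed_cim) if two_sided else np.asarray(observed_cim)
    counts = np.zeros_like(obs, dtype=np.int64)
    for _ in range(n_iter):
        perm = rng.permutation(c_x.shape[0])
        cim = c_x[perm] @ c_y.T
        if two_sided:
            cim = np.abs(cim)
        counts += cim >= obs
    if smoothed:
        return (counts + 1) / (n_iter + 1)
    return counts / n_iter


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, any input shape."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    flat = p.ravel()
    m = flat.size
    order = np.argsort(flat, kind="stable")
    ranked = flat[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.reshape(p.shape)


def correlate(
    mirna_counts: CountMatrix,
    taxon_counts: CountMatrix,
    ncomp: int = 2,
    keep_x: int = 20,
    keep_y: int = 20,
    n_perm: int = 100_000,
    seed: int = 0,
    pseudocount: float = 1.0,
    two_sided: bool = True,
) -> CimResult:
    """End-to-end association: clr → sPLS → CIM → permutation p → BH q."""
    x = clr_transform(mirna_counts, pseudocount)
    y = clr_transform(taxon_counts, pseudocount)
    keep_x = min(keep_x, len(x.feature_ids))
    keep_y = min(keep_y, len(y.feature_ids))
    model = spls_fit(x, y, ncomp, keep_x, keep_y)
    c_x, c_y = component_correlations(x, y, model)
    cim = cim_matrix(x, y, model)
    p = permutation_pvalues(
        c_x, c_y, cim.to_numpy(), n_iter=n_perm, seed=seed, two_sided=two_sided
    )
    q = bh_adjust(p)
    idx, cols = cim.index, cim.columns
    return CimResult(
        cim,
        pd.DataFrame(p, index=idx, columns=cols),
        pd.DataFrame(q, index=idx, columns=cols),
        n_perm,
        seed,
    )
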