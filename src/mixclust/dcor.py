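"""Bias-corrected generalized distance correlation between variables ("dcor").

Dependence between two variables of arbitrary scale is measured by a
generalized distance correlation: each variable induces an n x n matrix
of pairwise distances between samples under a metric matching its scale
(discrete 0/1 for nominal/binary, |x_i - x_j| for quantitative,
midrank differences for ordinal).  Products of double-centered distance
matrices yield a sample distance covariance, which is severely biased;
a U-statistic style correction based on modified matrices A* removes
the small-sample bias:

    U~_kl = (n-3)/n * ( sum_ij A*_ij B*_ij - n/(n-2) * sum_i A*_ii B*_ii )

with, for the k-th variable,

    A*_ij = n/(n-1) * (A_ij - d_ij/n)            for i != j,
    A*_ii = n/(n-1) * (rowmean_i - grandmean),

where A is the double-centered distance matrix.  The bias-corrected
U~_kl may be negative.  Normalizing gives the generalized distance
correlation used here:

    R~_kl = sign(U~_kl) * sqrt(|U~_kl|) / (U~_kk * U~_ll)^(1/4)

a correlation-scale quantity with R~_kk = 1 whose square is
|U~_kl| / sqrt(U~_kk * U~_ll).  Note that while U~ itself is exactly
mean-zero under independence, the concave sign-sqrt transform gives R~
a small negative finite-sample bias there.  Because the
Euclidean and discrete metrics are of strongly negative type, R~
converges to 0 if and only if the two variables are independent, and
``d_kl := 1 - R~_kl`` is a meaningful dissimilarity for clustering mixed
variables (it can slightly exceed 1 when R~ < 0; negative values are
propagated, not truncated).  R~ is invariant to rescaling any variable's
metric by a positive constant.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import rankdata

from .mixedio import (
    DegenerateVariableWarning,
    DistanceMatrix,
    MixedDataError,
    MixedDataset,
    VariableSpec,
)

__all__ = [
    "per_variable_distances",
    "double_center",
    "modified_distance_matrix",
    "bias_corrected_dcov",
    "dcor_coefficient",
    "dcor_distance_matrix",
]

_VAR_EPS = 1e-12


def per_variable_distances(x, spec: VariableSpec) -> np.ndarray:
    """n x n sample-sample distances induced by one variable.

    nominal/binary: discrete metric; quantitative: absolute difference;
    ordinal: absolute midrank difference (ranks over the given values,
    so callers subsetting to complete cases get subset ranks).
    """
    if spec.scale == "quantitative":
        v = np.asarray(x, dtype=float)
        return np.abs(v[:, None] - v[None, :])
    if spec.scale == "ordinal":
        codes = np.array([spec.levels.index(str(v)) for v in x], dtype=float)
        r = rankdata(codes, method="average")
        return np.abs(r[:, None] - r[None, :])
    lab = np.array([str(v) for v in x])
    return (lab[:, None] != lab[None, :]).astype(float)


def double_center(dmat: np.ndarray) -> np.ndarray:
    """A_ij = d_ij - rowmean_i - colmean_j + grandmean."""
    d = np.asarray(dmat, dtype=float)
    rm = d.mean(axis=1)
    return d - rm[:, None] - rm[None, :] + d.mean()


def modified_distance_matrix(dmat: np.ndarray) -> np.ndarray:
    """The modified matrix A* entering the bias-corrected covariance."""
    d = np.asarray(dmat, dtype=float)
    n = d.shape[0]
    rm = d.mean(axis=1)
    gm = d.mean()
    a = d - rm[:, None] - rm[None, :] + gm
    astar = (n / (n - 1)) * (a - d / n)
    np.fill_diagonal(astar, (n / (n - 1)) * (rm - gm))
    return astar


def _ucov_from_star(astar: np.ndarray, bstar: np.ndarray) -> float:
    n = astar.shape[0]
    total = float((astar * bstar).sum())
    diag = float((np.diag(astar) * np.diag(bstar)).sum())
    return ((n - 3) / n) * (total - (n / (n - 2)) * diag)


def bias_corrected_dcov(dk: np.ndarray, dl: np.ndarray) -> float:
    """Bias-corrected squared sample distance covariance U~_kl.

    Requires n >= 4 (the correction carries factors n-2 and n-3); the
    result may be negative.
    """
    dk = np.asarray(dk, dtype=float)
    dl = np.asarray(dl, dtype=float)
    n = dk.shape[0]
    if dk.shape != (n, n) or dl.shape != (n, n):
        raise MixedDataError("distance matrices must be square and same size")
    if n < 4:
        raise MixedDataError("bias-corrected distance covariance requires n >= 4")
    return _ucov_from_star(modified_distance_matrix(dk), modified_distance_matrix(dl))


def dcor_coefficient(dk: np.ndarray, dl: np.ndarray) -> float:
    """Generalized distance correlation R~_kl of two distance matrices."""
    ukl = bias_corrected_dcov(dk, dl)
    ukk = bias_corrected_dcov(dk, dk)
    ull = bias_corrected_dcov(dl, dl)
    if ukk <= _VAR_EPS or ull <= _VAR_EPS:
        warnings.warn(
            "degenerate (near-constant) variable; distance correlation set to 0",
            DegenerateVariableWarning,
            stacklevel=2,
        )
        return 0.0
    return float(np.sign(ukl) * np.sqrt(abs(ukl)) / (ukk * ull) ** 0.25)


def _complete_pair_distance(
    d: MixedDataset, name_k: str, name_l: str
) -> float:
    """1 - R~ for one pair on its pairwise-complete observations."""
    ok = (~d.missing_mask[name_k] & ~d.missing_mask[name_l]).to_numpy()
    if int(ok.sum()) < 4:
        raise MixedDataError(
            f"pair ({name_k!r}, {name_l!r}) has fewer than 4 complete observations"
        )
    xk = d.values_of(name_k)[ok]
    xl = d.values_of(name_l)[ok]
    dk = per_variable_distances(xk, d.spec(name_k))
    dl = per_variable_distances(xl, d.spec(name_l))
    return 1.0 - dcor_coefficient(dk, dl)


def dcor_distance_matrix(d: MixedDataset) -> DistanceMatrix:
    """Variable x variable dissimilarities ``d_kl = 1 - R~_kl``.

    With complete data the modified matrices A* are computed once per
    variable and all pairs are formed by inner products; with missing
    data each pair falls back to its pairwise-complete subset (ordinal
    ranks recomputed on the subset).
    """
    if d.p < 2:
        raise MixedDataError("need at least two variables")
    names = d.var_names
    p = d.p
    if not d.missing_mask.to_numpy().any():
        n = d.n
        if n < 4:
            raise MixedDataError("bias-corrected distance covariance requires n >= 4")
        flat = np.empty((p, n * n))
        diag = np.empty((p, n))
        for idx, name in enumerate(names):
            astar = modified_distance_matrix(
                per_variable_distances(d.values_of(name), d.spec(name))
            )
            flat[idx] = astar.ravel()
            diag[idx] = np.diag(astar)
        u = ((n - 3) / n) * (flat @ flat.T - (n / (n - 2)) * (diag @ diag.T))
        var = np.diag(u).copy()
        degenerate = var <= _VAR_EPS
        if degenerate.any():
            warnings.warn(
                f"degenerate variable(s) {list(np.array(names)[degenerate])}; "
                "distance correlation set to 0",
                DegenerateVariableWarning,
                stacklevel=2,
            )
        safe = np.where(degenerate, 1.0, var)
        r = np.sign(u) * np.sqrt(np.abs(u)) / np.outer(safe, safe) ** 0.25
        r[degenerate, :] = 0.0
        r[:, degenerate] = 0.0
        np.fill_diagonal(r, np.where(degenerate, 0.0, 1.0))
        dist = 1.0 - r
    else:
        dist = np.zeros((p, p))
        for a in range(p):
            for b in range(a + 1, p):
                dist[a, b] = dist[b, a] = _complete_pair_distance(
                    d, names[a], names[b]
                )
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(labels=names, values=dist, method="dcor")
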