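"""Variable-variable similarity by combining association measures ("ama").

Pairwise similarities between variables are chosen by the data-type
combination of the pair:

* quantitative vs quantitative/ordinal: absolute Spearman correlation;
* ordinal vs ordinal, quantitative/ordinal vs binary: absolute
  Goodman-Kruskal gamma, ``|(n_c - n_d) / (n_c + n_d)|`` over concordant
  and discordant observation pairs;
* quantitative/ordinal vs nominal: the nominal factor is turned into an
  ordered factor by sorting its categories by the mean midrank of the
  partner variable, gated by a Kruskal-Wallis pre-test at level alpha
  (on a non-significant test the coefficient is computed on the original
  category order, which behaves like a random ordering);
* nominal/binary vs nominal/binary: the cross-table is "diagonalized"
  (category orders rearranged to concentrate counts on the diagonal,
  maximizing |gamma|), gated by a chi-square pre-test of association.

All coefficients lie in [0, 1].  The assembled similarity matrix S need
not be positive semidefinite; it is repaired to the nearest PSD
unit-diagonal matrix S' so that, by Gower's theorem, the distances
``d_kl = sqrt(1 - s'_kl)`` are Euclidean (hence metric).

Missing data are handled by pairwise-complete observations for every
coefficient and pre-test.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
from scipy import stats

from ._psd import nearest_psd_correlation
from .mixedio import (
    DegenerateVariableWarning,
    DistanceMatrix,
    MixedDataError,
    MixedDataset,
    SimilarityMatrix,
)

__all__ = [
    "AmaConfig",
    "CrossTab",
    "spearman_similarity",
    "gk_gamma",
    "gamma_from_values",
    "order_categories_by_response",
    "nominal_vs_ranked_similarity",
    "diagonalize_crosstab",
    "nominal_nominal_similarity",
    "ama_similarity_matrix",
    "nearest_psd_projection",
    "ama_distance_matrix",
]


@dataclasses.dataclass(frozen=True)
class AmaConfig:
    """Tuning knobs of the association-measures method.

    ``alpha`` is the significance level of the Kruskal-Wallis and
    chi-square pre-tests gating category reordering (default 0.05);
    ``max_exhaustive_categories`` caps the exact permutation search in
    cross-table diagonalization (default 6; above it a reciprocal
    mean-score heuristic is used).
    """

    alpha: float = 0.05
    max_exhaustive_categories: int = 6

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise MixedDataError("alpha must lie strictly between 0 and 1")


# -- Goodman-Kruskal gamma --------------------------------------------------


def _concordance_counts(counts: np.ndarray) -> tuple[float, float]:
    """Concordant/discordant observation-pair counts of a cross-table."""
    c = np.asarray(counts, dtype=float)
    r, k = c.shape
    # conc[i, j] = sum of c over rows > i and cols > j
    pad = np.zeros((r + 1, k + 1))
    pad[:r, :k] = c
    suff = np.cumsum(np.cumsum(pad[::-1, ::-1], axis=0), axis=1)[::-1, ::-1]
    conc = suff[1:, 1:]
    # disc[i, j] = sum of c over rows > i and cols < j
    rowsuff = np.cumsum(c[::-1, :], axis=0)[::-1, :]
    below = np.vstack([rowsuff[1:, :], np.zeros((1, k))])
    disc = np.hstack([np.zeros((r, 1)), np.cumsum(below, axis=1)[:, :-1]])
    n_c = float((c * conc).sum())
    n_d = float((c * disc).sum())
    return n_c, n_d


@dataclasses.dataclass
class CrossTab:
    """Contingency table with category labels and pair concordance counts."""

    row_levels: list[str]
    col_levels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.row_levels), len(self.col_levels)):
            raise MixedDataError("cross-table shape does not match labels")
        if (self.counts < 0).any():
            raise MixedDataError("cross-table counts must be nonnegative")

    @classmethod
    def from_values(
        cls,
        x,
        y,
        row_order: list[str] | None = None,
        col_order: list[str] | None = None,
    ) -> "CrossTab":
        x = [str(v) for v in x]
        y = [str(v) for v in y]
        rows = [c for c in (row_order or _first_appearance(x)) if c in set(x)]
        cols = [c for c in (col_order or _first_appearance(y)) if c in set(y)]
        ri = {c: i for i, c in enumerate(rows)}
        ci = {c: i for i, c in enumerate(cols)}
        counts = np.zeros((len(rows), len(cols)))
        np.add.at(counts, ([ri[v] for v in x], [ci[v] for v in y]), 1.0)
        return cls(rows, cols, counts)

    @property
    def n_c(self) -> float:
        return _concordance_counts(self.counts)[0]

    @property
    def n_d(self) -> float:
        return _concordance_counts(self.counts)[1]


def _first_appearance(values) -> list[str]:
    seen: list[str] = []
    for v in values:
        if v not in seen:
            seen.append(v)
    return seen


def gk_gamma(t: CrossTab) -> float:
    """Goodman-Kruskal gamma ``(n_c - n_d)/(n_c + n_d)`` in [-1, 1]."""
    n_c, n_d = _concordance_counts(t.counts)
    if n_c + n_d == 0:
        warnings.warn(
            "no concordant or discordant pairs; gamma set to 0",
            DegenerateVariableWarning,
            stacklevel=2,
        )
        return 0.0
    return (n_c - n_d) / (n_c + n_d)


def gamma_from_values(x: np.ndarray, y: np.ndarray) -> float:
    """Gamma computed directly from two ordered numeric vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    prod = sx * sy
    n_c = np.count_nonzero(prod > 0) // 2
    n_d = np.count_nonzero(prod < 0) // 2
    if n_c + n_d == 0:
        warnings.warn(
            "no concordant or discordant pairs; gamma set to 0",
            DegenerateVariableWarning,
            stacklevel=2,
        )
        return 0.0
    return (n_c - n_d) / (n_c + n_d)


# -- rank correlations ------------------------------------------------------


def spearman_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Absolute Spearman correlation (Pearson correlation of midranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    nx = np.sqrt(cx @ cx)
    ny = np.sqrt(cy @ cy)
    if nx == 0.0 or ny == 0.0:
        warnings.warn(
            "constant variable; Spearman similarity set to 0",
            DegenerateVariableWarning,
            stacklevel=2,
        )
        return 0.0
    return float(abs(cx @ cy) / (nx * ny))


# -- nominal vs ranked ------------------------------------------------------


def order_categories_by_response(
    x, y: np.ndarray, categories: list[str] | None = None
) -> list[str]:
    """Sort categories of ``x`` ascending by mean midrank of ``y``.

    Ties keep the original relative order; categories left empty after
    missing-value removal are dropped with a warning.
    """
    x = np.array([str(v) for v in x])
    y = np.asarray(y, dtype=float)
    cats = categories or _first_appearance(x)
    ranks = stats.rankdata(y)
    means = []
    kept = []
    for c in cats:
        sel = x == c
        if not sel.any():
            warnings.warn(
                f"category {c!r} empty after missing removal; dropped",
                DegenerateVariableWarning,
                stacklevel=2,
            )
            continue
        kept.append(c)
        means.append(float(ranks[sel].mean()))
    order = np.argsort(np.asarray(means), kind="stable")
    return [kept[i] for i in order]


def nominal_vs_ranked_similarity(
    x,
    y: np.ndarray,
    y_scale: str = "quantitative",
    cfg: AmaConfig | None = None,
    categories: list[str] | None = None,
) -> float:
    """Association of a nominal factor with a quantitative/ordinal variable.

    A Kruskal-Wallis test screens for any location difference of ``y``
    across the categories of ``x``.  If significant at ``cfg.alpha`` the
    categories are reordered by mean midrank of ``y`` before computing
    |Spearman| (quantitative ``y``) or |gamma| (ordinal ``y``);
    otherwise the coefficient is computed on the original order.
    """
    cfg = cfg or AmaConfig()
    x = np.array([str(v) for v in x])
    y = np.asarray(y, dtype=float)
    cats = [c for c in (categories or _first_appearance(x)) if (x == c).any()]
    if len(cats) < 2:
        warnings.warn(
            "fewer than two nominal categories on complete cases; similarity 0",
            DegenerateVariableWarning,
            stacklevel=2,
        )
        return 0.0
    groups = [y[x == c] for c in cats]
    try:
        _, p = stats.kruskal(*groups)
    except ValueError:  # all observations identical
        p = 1.0
    order = (
        order_categories_by_response(x, y, categories=cats)
        if p < cfg.alpha
        else cats
    )
    pos = {c: float(i) for i, c in enumerate(order)}
    scores = np.array([pos[v] for v in x])
    if y_scale == "quantitative":
        return spearman_similarity(scores, y)
    return abs(gamma_from_values(scores, y))


# -- nominal vs nominal -----------------------------------------------------


def _abs_gamma_counts(counts: np.ndarray) -> float:
    n_c, n_d = _concordance_counts(counts)
    return abs(n_c - n_d) / (n_c + n_d) if n_c + n_d else 0.0


def diagonalize_crosstab(t: CrossTab, cfg: AmaConfig | None = None) -> CrossTab:
    """Reorder both category sets to concentrate counts on the diagonal.

    The factor with fewer categories is permuted exhaustively (capped at
    ``max_exhaustive_categories``); for each permutation its categories
    are scored by their position and the other factor's categories are
    ordered ascending by the count-weighted mean score of their cells.
    The arrangement maximizing |gamma| wins; ties keep the first
    permutation in lexicographic order.  Above the cap, categories start
    ordered by frequency and two rounds of reciprocal mean-score
    reordering are applied.
    """
    cfg = cfg or AmaConfig()
    c = t.counts
    r, k = c.shape
    transposed = r > k
    m = c.T if transposed else c
    small = m.shape[0]

    def _order_other(mp: np.ndarray) -> np.ndarray:
        scores = np.arange(mp.shape[0], dtype=float)
        margins = mp.sum(axis=0)
        mean = (scores @ mp) / np.where(margins > 0, margins, 1.0)
        mean = np.where(margins > 0, mean, np.inf)
        return np.argsort(mean, kind="stable")

    if small <= cfg.max_exhaustive_categories:
        best: tuple[float, tuple[int, ...], np.ndarray] | None = None
        for perm in itertools.permutations(range(small)):
            mp = m[list(perm), :]
            other = _order_other(mp)
            g = _abs_gamma_counts(mp[:, other])
            if best is None or g > best[0] + 1e-12:
                best = (g, perm, other)
        _, perm, other = best
        small_order = list(perm)
        other_order = list(other)
    else:
        small_order = list(np.argsort(-m.sum(axis=1), kind="stable"))
        other_order = list(range(m.shape[1]))
        for _ in range(2):
            other_order = list(_order_other(m[small_order, :]))
            # reorder the small side by mean position of the other side
            mt = m[np.ix_(small_order, other_order)].T
            small_order = [small_order[i] for i in _order_other(mt)]
    if transposed:
        row_order, col_order = other_order, small_order
    else:
        row_order, col_order = small_order, other_order
    return CrossTab(
        [t.row_levels[i] for i in row_order],
        [t.col_levels[j] for j in col_order],
        c[np.ix_(row_order, col_order)],
    )


def _chi2_pvalue(counts: np.ndarray) -> float:
    """Pearson chi-square test of independence, no continuity correction."""
    c = np.asarray(counts, dtype=float)
    n = c.sum()
    expected = np.outer(c.sum(axis=1), c.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(expected > 0, (c - expected) ** 2 / expected, 0.0).sum()
    dof = (c.shape[0] - 1) * (c.shape[1] - 1)
    if dof <= 0:
        return 1.0
    return float(stats.chi2.sf(stat, dof))


def nominal_nominal_similarity(
    x,
    y,
    cfg: AmaConfig | None = None,
    x_categories: list[str] | None = None,
    y_categories: list[str] | None = None,
) -> float:
    """Association of two nominal/binary factors via gated diagonalization."""
    cfg = cfg or AmaConfig()
    t = CrossTab.from_values(x, y, row_order=x_categories, col_order=y_categories)
    if len(t.row_levels) < 2 or len(t.col_levels) < 2:
        warnings.warn(
            "degenerate contingency table (single-category margin); similarity 0",
            DegenerateVariableWarning,
            stacklevel=2,
        )
        return 0.0
    if _chi2_pvalue(t.counts) < cfg.alpha:
        t = diagonalize_crosstab(t, cfg)
    return _abs_gamma_counts(t.counts)


# -- matrix assembly --------------------------------------------------------

_RANKED = {"quantitative", "ordinal"}


def _pair_similarity(
    sa: str,
    sb: str,
    xa: np.ndarray,
    xb: np.ndarray,
    la,
    lb,
    cats_a,
    cats_b,
    cfg: AmaConfig,
) -> float:
    """Dispatch one variable pair; xa/xb numeric codes, la/lb raw labels."""
    pair = tuple(sorted((sa, sb)))
    if pair in (("quantitative", "quantitative"), ("ordinal", "quantitative")):
        return spearman_similarity(xa, xb)
    if pair in (
        ("ordinal", "ordinal"),
        ("binary", "quantitative"),
        ("binary", "ordinal"),
    ):
        return abs(gamma_from_values(xa, xb))
    if "nominal" in pair and (sa in _RANKED or sb in _RANKED):
        if sa == "nominal":
            return nominal_vs_ranked_similarity(
                la, xb, y_scale=sb, cfg=cfg, categories=cats_a
            )
        return nominal_vs_ranked_similarity(
            lb, xa, y_scale=sa, cfg=cfg, categories=cats_b
        )
    # nominal/binary vs nominal/binary
    return nominal_nominal_similarity(
        la, lb, cfg=cfg, x_categories=cats_a, y_categories=cats_b
    )


def ama_similarity_matrix(
    d: MixedDataset, cfg: AmaConfig | None = None
) -> SimilarityMatrix:
    """Assemble the variable x variable similarity matrix (pre-projection)."""
    cfg = cfg or AmaConfig()
    if d.p < 2:
        raise MixedDataError("need at least two variables")
    names = d.var_names
    scales = {s.name: s.scale for s in d.specs}
    cats = {s.name: list(s.levels) if s.levels else None for s in d.specs}
    codes = {n: d.codes(n) for n in names}
    labels = {n: d.frame[n].to_numpy() for n in names}
    miss = {n: d.missing_mask[n].to_numpy() for n in names}
    p = d.p
    s = np.eye(p)
    for a in range(p):
        for b in range(a + 1, p):
            na, nb = names[a], names[b]
            ok = ~(miss[na] | miss[nb])
            if int(ok.sum()) < 3:
                warnings.warn(
                    f"pair ({na!r}, {nb!r}) has fewer than 3 complete "
                    "observations; similarity 0",
                    DegenerateVariableWarning,
                    stacklevel=2,
                )
                val = 0.0
            else:
                val = _pair_similarity(
                    scales[na],
                    scales[nb],
                    codes[na][ok],
                    codes[nb][ok],
                    labels[na][ok],
                    labels[nb][ok],
                    cats[na],
                    cats[nb],
                    cfg,
                )
            s[a, b] = s[b, a] = val
    return SimilarityMatrix(labels=names, values=s, method="ama")


def nearest_psd_projection(
    s: SimilarityMatrix, tol: float = 1e-7, max_iter: int = 100
) -> SimilarityMatrix:
    """Project a similarity matrix onto the nearest PSD correlation matrix."""
    repaired = nearest_psd_correlation(s.values, tol=tol, max_iter=max_iter)
    return SimilarityMatrix(labels=s.labels, values=repaired, method=s.method)


def ama_distance_matrix(
    d: MixedDataset, cfg: AmaConfig | None = None
) -> DistanceMatrix:
    """Euclidean variable distances ``d_kl = sqrt(1 - s'_kl)``.

    ``S'`` is the PSD-projected similarity matrix, so by Gower's theorem
    the returned distances are Euclidean and satisfy the triangle
    inequality.
    """
    s = nearest_psd_projection(ama_similarity_matrix(d, cfg))
    dist = np.sqrt(np.clip(1.0 - s.values, 0.0, None))
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(labels=s.labels, values=dist, method="ama")
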