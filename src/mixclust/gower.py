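"""Gower similarity and distance between samples of mixed-type data.

The Gower coefficient combines per-variable similarity scores into a
weighted average over the variables on which both samples are observed:

    s(x_i, x_j) = sum_k s_k(x_ik, x_jk) * delta_k * w_k
                  / sum_k delta_k * w_k

with availability indicator ``delta_k = 0`` when either cell is missing
and optional nonnegative weights ``w_k``.  Per-variable scores are

* qualitative (nominal/binary): 1 on agreement, 0 otherwise;
* quantitative: ``1 - |x_ik - x_jk| / R_k`` with observed range ``R_k``;
* ordinal (rank-based extension after Podani):
  ``1 - |r_k(x_ik) - r_k(x_jk)| / (max_m r_k(x_mk) - min_m r_k(x_mk))``
  where ranks are midranks over the nonmissing observations.

Distances are ``d = 1 - s`` in [0, 1].  Degenerate variables (zero range
or a single observed ordinal rank) carry no information and contribute
``delta = 0`` to every pair, with a warning.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.stats import rankdata

from .mixedio import (
    DegenerateVariableWarning,
    DistanceMatrix,
    MixedDataError,
    MixedDataset,
    SimilarityMatrix,
    VariableSpec,
)

__all__ = ["GowerContext", "variable_score", "gower_similarity_matrix", "gower_distance_matrix"]


@dataclasses.dataclass
class GowerContext:
    """Per-variable statistics required to score a pair of samples.

    ``ranges`` maps quantitative variable names to the observed range
    R_k; ``ranks`` maps ordinal names to (value -> midrank) lookups with
    the observed (min, max) rank; ``degenerate`` names variables that
    contribute ``delta = 0`` everywhere.
    """

    ranges: dict[str, float]
    ranks: dict[str, tuple[dict[str, float], float, float]]
    degenerate: set[str]

    @classmethod
    def from_dataset(cls, d: MixedDataset) -> "GowerContext":
        ranges: dict[str, float] = {}
        ranks: dict[str, tuple[dict[str, float], float, float]] = {}
        degenerate: set[str] = set()
        for spec in d.specs:
            col = d.frame[spec.name]
            if spec.scale == "quantitative":
                vals = col.dropna().to_numpy(dtype=float)
                r = float(vals.max() - vals.min()) if vals.size else 0.0
                ranges[spec.name] = r
                if r == 0.0:
                    degenerate.add(spec.name)
            elif spec.scale == "ordinal":
                obs = col.dropna()
                if obs.empty:
                    degenerate.add(spec.name)
                    ranks[spec.name] = ({}, 0.0, 0.0)
                    continue
                codes = np.array(
                    [spec.levels.index(v) for v in obs], dtype=float
                )
                mid = rankdata(codes, method="average")
                lookup: dict[str, float] = {}
                for v, r in zip(obs, mid):
                    lookup[v] = float(r)
                rmin, rmax = float(mid.min()), float(mid.max())
                ranks[spec.name] = (lookup, rmin, rmax)
                if rmax == rmin:
                    degenerate.add(spec.name)
            # qualitative variables always score agreement, even if constant
        for name in sorted(degenerate):
            warnings.warn(
                f"variable {name!r} is degenerate; excluded from Gower scores",
                DegenerateVariableWarning,
                stacklevel=3,
            )
        return cls(ranges=ranges, ranks=ranks, degenerate=degenerate)


def variable_score(
    x_i: object, x_j: object, spec: VariableSpec, ctx: GowerContext
) -> float | None:
    """Score one variable for one sample pair; ``None`` when delta = 0."""

    def _missing(v: object) -> bool:
        return v is None or (isinstance(v, float) and np.isnan(v))

    if _missing(x_i) or _missing(x_j) or spec.name in ctx.degenerate:
        return None
    if spec.scale == "quantitative":
        return 1.0 - abs(float(x_i) - float(x_j)) / ctx.ranges[spec.name]
    if spec.scale == "ordinal":
        lookup, rmin, rmax = ctx.ranks[spec.name]
        return 1.0 - abs(lookup[str(x_i)] - lookup[str(x_j)]) / (rmax - rmin)
    return 1.0 if str(x_i) == str(x_j) else 0.0


def _score_and_delta(d: MixedDataset, spec: VariableSpec, ctx: GowerContext):
    """Vectorized (n x n) score and availability matrices for one variable."""
    n = d.n
    miss = d.missing_mask[spec.name].to_numpy()
    avail = ~miss
    delta = np.outer(avail, avail).astype(float)
    if spec.name in ctx.degenerate:
        return np.zeros((n, n)), np.zeros((n, n))
    if spec.scale == "quantitative":
        v = d.frame[spec.name].to_numpy(dtype=float)
        v = np.where(miss, 0.0, v)
        score = 1.0 - np.abs(v[:, None] - v[None, :]) / ctx.ranges[spec.name]
    elif spec.scale == "ordinal":
        lookup, rmin, rmax = ctx.ranks[spec.name]
        r = np.array(
            [lookup.get(v, 0.0) if v is not None else 0.0 for v in d.frame[spec.name]],
            dtype=float,
        )
        score = 1.0 - np.abs(r[:, None] - r[None, :]) / (rmax - rmin)
    else:
        codes = d.codes(spec.name)
        codes = np.where(miss, -1.0, codes)
        score = (codes[:, None] == codes[None, :]).astype(float)
    return score * delta, delta


def gower_similarity_matrix(d: MixedDataset) -> SimilarityMatrix:
    """Weighted Gower similarity between all sample pairs."""
    if d.n < 2:
        raise MixedDataError("need at least two samples")
    ctx = GowerContext.from_dataset(d)
    n = d.n
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for spec in d.specs:
        if spec.weight == 0.0:
            continue
        score, delta = _score_and_delta(d, spec, ctx)
        num += spec.weight * score
        den += spec.weight * delta
    bad = (den == 0.0) & ~np.eye(n, dtype=bool)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise MixedDataError(
            f"samples {d.sample_ids[i]!r} and {d.sample_ids[j]!r} share no "
            "comparable variable (all delta = 0)"
        )
    with np.errstate(invalid="ignore"):
        s = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), 1.0)
    np.fill_diagonal(s, 1.0)
    s = np.clip(0.5 * (s + s.T), 0.0, 1.0)
    return SimilarityMatrix(labels=d.sample_ids, values=s, method="gower")


def gower_distance_matrix(d: MixedDataset) -> DistanceMatrix:
    """Gower distances ``d = 1 - s`` between all sample pairs."""
    s = gower_similarity_matrix(d)
    dist = 1.0 - s.values
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(labels=s.labels, values=dist, method="gower")
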