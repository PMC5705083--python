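"""Synthetic mixed-type data generators and clustering study runners.

Two validation designs are emulated:

1. *Correlated pair*: a bivariate normal sample with imposed Pearson
   correlation rho, where either variable can be replaced by a
   quantile-cut categorized copy in "perfect agreement" with its parent
   (binary = median cut, K categories = cuts at the j/K quantiles, so
   the categorization preserves exactly the ordering information).
   Ordinal copies keep the cut order as level order; nominal copies get
   a seeded random level order.

2. *Two variable groups*: p variables split into two equal groups, each
   drawn from a multivariate normal whose within-group correlations
   decay linearly in index distance from a maximum rho down to 0
   (Toeplitz-like per group).  Optionally a random fraction of the
   inter-group correlations is set to 0.5 ("noise").  The assembled
   target matrix is repaired to the nearest PSD correlation matrix when
   indefinite.  A random fraction of variables is then categorized by
   quantile cuts with K drawn uniformly from 2..8, ordinal or nominal
   with probability 1/2 each, keeping the true variable grouping intact.

The study runner clusters the variables of each replicate with the
mixed-data methods (ama, dcor) and two baselines -- Euclidean distance
on the pre-categorization quantitative data, and simple matching on
median-binarized data -- then cuts the Ward dendrogram at k = 2 and
scores recovery of the true groups by the misclassification rate.

Reproducibility: one root seed; replicate r uses the child stream
``SeedSequence(seed, spawn_key=(r,))`` so studies are reproducible and
parallelizable.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from ._psd import nearest_psd_correlation
from .ama import AmaConfig, ama_distance_matrix
from .cluster import (
    ConfusionTable,
    cut_clusters,
    hierarchical_cluster,
    misclassification_rate,
)
from .dcor import dcor_distance_matrix
from .mixedio import (
    DegenerateVariableWarning,
    DistanceMatrix,
    MixedDataError,
    MixedDataset,
    VariableSpec,
)

__all__ = [
    "SimulationConfig",
    "replicate_rng",
    "correlated_pair",
    "build_target_correlation",
    "TwoGroupSample",
    "two_group_dataset",
    "binarize_median",
    "simple_matching_distance",
    "run_variable_clustering_study",
    "random_mixed_dataset",
    "STUDY_METHODS",
]

STUDY_METHODS = ("ama", "dcor", "euclidean_quantitative", "binarized_matching")


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for both simulation designs.

    Defaults follow the central two-group setting (50 samples, 100
    variables, within-group maximal correlation 0.5, 20% inter-group
    noise correlations of 0.5, half of the variables categorized,
    category counts 2..8, 100 replicates).
    """

    seed: int = 0
    n: int = 50
    p: int = 100
    rho: float = 0.5
    noise_fraction: float = 0.2
    categorical_fraction: float = 0.5
    k_range: tuple[int, int] = (2, 8)
    replicates: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise MixedDataError("rho must lie in [0, 1)")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise MixedDataError("noise_fraction must lie in [0, 1]")
        if not 0.0 <= self.categorical_fraction <= 1.0:
            raise MixedDataError("categorical_fraction must lie in [0, 1]")
        if not 2 <= self.k_range[0] <= self.k_range[1]:
            raise MixedDataError("invalid category-count range")


def replicate_rng(seed: int, rep: int) -> np.random.Generator:
    """Child RNG for replicate ``rep`` of the study with root ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(rep,)))


# -- categorization helpers -------------------------------------------------


def _quantile_cut(v: np.ndarray, k: int) -> np.ndarray:
    """Cut at the j/K empirical quantiles; balanced when K divides n."""
    if k < 2:
        raise MixedDataError("need at least 2 categories")
    n = v.size
    ranks = rankdata(v, method="ordinal")  # 1..n, ties broken by order
    return np.ceil(ranks * k / n).astype(int) - 1  # 0..k-1


def _categorize(
    v: np.ndarray, scale: str, k: int, rng: np.random.Generator, name: str
) -> tuple[np.ndarray, VariableSpec]:
    """Quantile-categorized copy of a quantitative vector."""
    cut = _quantile_cut(v, k)
    level_names = [f"c{j + 1}" for j in range(k)]
    if scale == "nominal":
        assign = rng.permutation(k)  # scramble which label holds which cut
        labels = np.array([level_names[assign[c]] for c in cut], dtype=object)
        spec = VariableSpec(name=name, scale="nominal")
    elif scale == "binary":
        labels = np.array([level_names[c] for c in cut], dtype=object)
        spec = VariableSpec(name=name, scale="binary", levels=tuple(level_names))
    else:
        labels = np.array([level_names[c] for c in cut], dtype=object)
        spec = VariableSpec(name=name, scale="ordinal", levels=tuple(level_names))
    return labels, spec


# -- design 1: correlated pair ---------------------------------------------


def correlated_pair(
    cfg: SimulationConfig,
    type_x: str = "quantitative",
    type_y: str = "quantitative",
    k_categories: int = 4,
    rng: np.random.Generator | None = None,
) -> MixedDataset:
    """Two-variable dataset with imposed Pearson correlation ``cfg.rho``.

    The bivariate normal parents have population correlation rho; a
    requested categorical scale replaces the parent by its quantile-cut
    copy in perfect agreement (binary: median cut; ordinal/nominal:
    ``k_categories`` cuts).
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence(cfg.seed))
    z = rng.standard_normal((cfg.n, 2))
    x = z[:, 0]
    y = cfg.rho * z[:, 0] + np.sqrt(1.0 - cfg.rho**2) * z[:, 1]
    cols: dict[str, np.ndarray] = {}
    specs: list[VariableSpec] = []
    for name, parent, scale in (("x", x, type_x), ("y", y, type_y)):
        if scale == "quantitative":
            cols[name] = parent
            specs.append(VariableSpec(name=name, scale="quantitative"))
        else:
            k = 2 if scale == "binary" else k_categories
            labels, spec = _categorize(parent, scale, k, rng, name)
            cols[name] = labels
            specs.append(spec)
    frame = pd.DataFrame(cols, index=[f"s{i + 1}" for i in range(cfg.n)])
    return MixedDataset(frame, specs)


# -- design 2: two variable groups ------------------------------------------


def build_target_correlation(
    p: int, rho: float, noise_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Target correlation matrix of the two-group design (pre-repair).

    Within each group of size g = p/2, corr(a, b) = rho * (1 - |a-b| /
    (g-1)); inter-group correlations are 0 except a random
    ``noise_fraction`` of them (sampled symmetrically without
    replacement) set to 0.5.
    """
    if p % 2:
        raise MixedDataError("p must be even (two equal variable groups)")
    g = p // 2
    target = np.eye(p)
    idx = np.arange(g)
    decay = rho * (1.0 - np.abs(idx[:, None] - idx[None, :]) / (g - 1))
    block = np.where(np.eye(g, dtype=bool), 1.0, decay)
    target[:g, :g] = block
    target[g:, g:] = block
    if noise_fraction > 0:
        pairs = [(i, g + j) for i in range(g) for j in range(g)]
        n_noise = int(round(noise_fraction * len(pairs)))
        chosen = rng.choice(len(pairs), size=n_noise, replace=False)
        for c in chosen:
            i, j = pairs[c]
            target[i, j] = target[j, i] = 0.5
    return target


class TwoGroupSample(NamedTuple):
    """A two-group replicate: mixed dataset, quantitative parent, truth."""

    dataset: MixedDataset
    parent: MixedDataset
    groups: np.ndarray


def two_group_dataset(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> TwoGroupSample:
    """Draw one replicate of the two-group variable clustering design."""
    rng = rng or np.random.default_rng(np.random.SeedSequence(cfg.seed))
    p, n = cfg.p, cfg.n
    target = build_target_correlation(p, cfg.rho, cfg.noise_fraction, rng)
    repaired = nearest_psd_correlation(target)
    w, v = np.linalg.eigh(repaired)
    if w.min() < -1e-6:
        raise MixedDataError("correlation structure infeasible after PSD repair")
    root = v * np.sqrt(np.clip(w, 0.0, None))
    data = rng.standard_normal((n, p)) @ root.T
    names = [f"v{j + 1}" for j in range(p)]
    parent_frame = pd.DataFrame(
        data, index=[f"s{i + 1}" for i in range(n)], columns=names
    )
    parent_specs = [VariableSpec(name=nm, scale="quantitative") for nm in names]
    parent = MixedDataset(parent_frame, parent_specs)

    n_cat = int(round(cfg.categorical_fraction * p))
    cat_vars = rng.choice(p, size=n_cat, replace=False)
    frame = parent_frame.copy().astype(object)
    specs = list(parent_specs)
    lo, hi = cfg.k_range
    for j in sorted(cat_vars):
        k = int(rng.integers(lo, hi + 1))
        scale = "ordinal" if rng.random() < 0.5 else "nominal"
        labels, spec = _categorize(data[:, j], scale, k, rng, names[j])
        frame[names[j]] = labels
        specs[j] = spec
    dataset = MixedDataset(frame, specs)
    groups = np.repeat([0, 1], p // 2)
    return TwoGroupSample(dataset=dataset, parent=parent, groups=groups)


# -- baselines --------------------------------------------------------------


def binarize_median(d: MixedDataset) -> MixedDataset:
    """Median-cut binarization of every variable.

    Quantitative/ordinal: values at or below the median map to "low".
    Nominal: most frequent category vs rest (ties by level order).
    Binary variables pass through; constant variables are dropped with a
    warning.
    """
    cols: dict[str, np.ndarray] = {}
    specs: list[VariableSpec] = []
    for spec in d.specs:
        name = spec.name
        if spec.scale == "binary":
            obs = d.frame[name].dropna()
            if obs.nunique() < 2:
                warnings.warn(
                    f"constant variable {name!r} dropped in binarization",
                    DegenerateVariableWarning,
                    stacklevel=2,
                )
                continue
            cols[name] = d.values_of(name)
            specs.append(spec)
            continue
        if spec.scale == "nominal":
            obs = d.frame[name].dropna()
            freq: dict[str, int] = {lev: 0 for lev in spec.levels or ()}
            for v in obs:
                freq[v] = freq.get(v, 0) + 1
            top = max(freq, key=lambda lev: (freq[lev], -list(freq).index(lev)))
            codes = d.codes(name)
            binary = np.where(
                np.isnan(codes),
                None,
                np.where(
                    np.array([v == top if v is not None else False
                              for v in d.values_of(name)]),
                    "low",
                    "high",
                ),
            )
        else:
            codes = d.codes(name)
            med = np.nanmedian(codes)
            binary = np.where(
                np.isnan(codes), None, np.where(codes <= med, "low", "high")
            )
        observed = {v for v in binary if v is not None}
        if len(observed) < 2:
            warnings.warn(
                f"constant variable {name!r} dropped in binarization",
                DegenerateVariableWarning,
                stacklevel=2,
            )
            continue
        cols[name] = binary.astype(object)
        specs.append(VariableSpec(name=name, scale="binary", levels=("low", "high")))
    if not specs:
        raise MixedDataError("binarization dropped every variable")
    frame = pd.DataFrame(cols, index=d.sample_ids)[[s.name for s in specs]]
    return MixedDataset(frame, specs)


def simple_matching_distance(
    d: MixedDataset, axis: str = "samples"
) -> DistanceMatrix:
    """Proportion of mismatching positions between binary vectors.

    ``axis="samples"`` compares rows, ``axis="variables"`` columns; all
    variables must carry the ``binary`` scale tag.  Positions missing in
    either vector are excluded from the proportion.
    """
    if axis not in ("samples", "variables"):
        raise MixedDataError("axis must be 'samples' or 'variables'")
    non_binary = [s.name for s in d.specs if s.scale != "binary"]
    if non_binary:
        raise MixedDataError(f"non-binary variable(s): {non_binary}")
    codes = np.column_stack([d.codes(nm) for nm in d.var_names])
    if axis == "variables":
        codes = codes.T
        labels = d.var_names
    else:
        labels = d.sample_ids
    ok = ~np.isnan(codes)
    filled = np.where(ok, codes, -1.0)
    m = codes.shape[0]
    dist = np.zeros((m, m))
    both = ok.astype(float) @ ok.astype(float).T
    # mismatches among jointly observed positions
    for a in range(m):
        joint = ok[a][None, :] & ok
        mism = (filled[a][None, :] != filled) & joint
        dist[a] = mism.sum(axis=1)
    if (both == 0).any() and m > 1:
        raise MixedDataError("a pair of vectors shares no observed position")
    dist = dist / np.where(both > 0, both, 1.0)
    dist = 0.5 * (dist + dist.T)
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(labels=list(labels), values=dist, method="simple_matching")


# -- study runner -----------------------------------------------------------


def _euclidean_variable_distance(parent: MixedDataset) -> DistanceMatrix:
    cols = parent.frame.to_numpy(dtype=float).T
    dist = squareform(pdist(cols, metric="euclidean"))
    return DistanceMatrix(labels=parent.var_names, values=dist, method="euclidean")


def run_variable_clustering_study(
    cfg: SimulationConfig,
    methods: Sequence[str] = STUDY_METHODS,
    ama_cfg: AmaConfig | None = None,
) -> pd.DataFrame:
    """MCR of two-group recovery per replicate and method (tidy table).

    For each replicate a two-group dataset is drawn; each method's
    variable distance matrix is Ward-clustered and cut at k = 2, and the
    assignment is scored against the true groups.  The Euclidean
    baseline sees the pre-categorization quantitative data; the
    binarized baseline sees the median-binarized quantitative data.
    """
    unknown = [m for m in methods if m not in STUDY_METHODS]
    if unknown:
        raise MixedDataError(f"unknown method(s): {unknown}")
    ama_cfg = ama_cfg or AmaConfig()
    rows = []
    for rep in range(cfg.replicates):
        rng = replicate_rng(cfg.seed, rep)
        sample = two_group_dataset(cfg, rng=rng)
        for method in methods:
            if method == "ama":
                dmat = ama_distance_matrix(sample.dataset, ama_cfg)
            elif method == "dcor":
                dmat = dcor_distance_matrix(sample.dataset)
            elif method == "euclidean_quantitative":
                dmat = _euclidean_variable_distance(sample.parent)
            else:
                dmat = simple_matching_distance(
                    binarize_median(sample.parent), axis="variables"
                )
            tree = hierarchical_cluster(dmat, linkage="ward")
            assignment = cut_clusters(tree, 2)
            table = ConfusionTable.from_labels(sample.groups, assignment)
            rows.append(
                {
                    "replicate": rep,
                    "method": method,
                    "mcr": misclassification_rate(table),
                    "seed": cfg.seed,
                }
            )
    return pd.DataFrame(rows)


# -- generic random mixed data (for property tests and stress checks) -------


def random_mixed_dataset(
    rng: np.random.Generator,
    n: int = 20,
    p: int = 4,
    missing_fraction: float = 0.0,
    max_categories: int = 5,
) -> MixedDataset:
    """A random mixed-type dataset with all four scales represented.

    Scales cycle through quantitative/ordinal/nominal/binary (shuffled),
    categorical variables get 2..max_categories levels with every level
    observed at least once, quantitative variables are standard normal.
    """
    scales = [SCALES_CYCLE[j % 4] for j in range(p)]
    rng.shuffle(scales)
    cols: dict[str, np.ndarray] = {}
    specs: list[VariableSpec] = []
    for j, scale in enumerate(scales):
        name = f"v{j + 1}"
        if scale == "quantitative":
            cols[name] = rng.standard_normal(n)
            specs.append(VariableSpec(name=name, scale="quantitative"))
            continue
        k = 2 if scale == "binary" else int(rng.integers(2, max_categories + 1))
        k = min(k, n)
        level_names = tuple(f"c{i + 1}" for i in range(k))
        codes = np.concatenate(
            [np.arange(k), rng.integers(0, k, size=n - k)]
        )
        rng.shuffle(codes)
        cols[name] = np.array([level_names[c] for c in codes], dtype=object)
        specs.append(
            VariableSpec(
                name=name,
                scale=scale,
                levels=level_names if scale != "nominal" else None,
            )
        )
    frame = pd.DataFrame(cols, index=[f"s{i + 1}" for i in range(n)])
    ds = MixedDataset(frame, specs)
    if missing_fraction > 0:
        mask = rng.random((n, p)) < missing_fraction
        # never blank an entire column
        for j in range(p):
            if mask[:, j].all():
                mask[rng.integers(0, n), j] = False
        f = ds.frame.copy()
        arr = f.to_numpy(dtype=object)
        arr[mask] = None
        f = pd.DataFrame(arr, index=f.index, columns=f.columns)
        ds = MixedDataset(f, ds.specs)
    return ds


SCALES_CYCLE = ("quantitative", "ordinal", "nominal", "binary")
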