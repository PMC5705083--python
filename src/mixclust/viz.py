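"""Integrative visualization of mixed-type data.

Three displays built on the package's distance matrices:

* :func:`mixed_heatmap` -- samples x variables heatmap with dendrograms
  on both axes and one color family per scale: blue sequential for
  quantitative rows (min-max scaled per row), green sequential for
  ordinal rows (by level order), discrete reds for nominal rows, and
  white cells for missing values.  Limited to 200 variable rows.
* :func:`variable_similarity_heatmap` -- symmetric variable-similarity
  heatmap ordered by a dendrogram; darker blue = stronger association.
* :func:`similarity_scatter` -- for a chosen outcome and predictor,
  every other variable is placed at (similarity to predictor,
  similarity to outcome); the anchors themselves sit at
  (s(outcome, predictor), 1) and (1, s(outcome, predictor)).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # headless rendering

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib import cm
from scipy.cluster import hierarchy as sch

from .cluster import LinkageTree
from .mixedio import (
    MixedDataError,
    MixedDataset,
    SimilarityMatrix,
    VariableSpec,
)

__all__ = [
    "MAX_HEATMAP_VARIABLES",
    "heatmap_rgba",
    "mixed_heatmap",
    "ordered_similarity",
    "variable_similarity_heatmap",
    "scatter_coordinates",
    "similarity_scatter",
]

MAX_HEATMAP_VARIABLES = 200

_MISSING_RGBA = (1.0, 1.0, 1.0, 1.0)  # white


def _row_rgba(values: np.ndarray, spec: VariableSpec, codes: np.ndarray) -> np.ndarray:
    """RGBA colors of one variable row (length n)."""
    n = len(codes)
    out = np.tile(np.array(_MISSING_RGBA), (n, 1))
    ok = ~np.isnan(codes)
    if not ok.any():
        return out
    if spec.scale == "quantitative":
        v = codes[ok]
        span = v.max() - v.min()
        frac = (v - v.min()) / span if span > 0 else np.full(v.shape, 0.5)
        out[ok] = cm.Blues(0.15 + 0.85 * frac)
    elif spec.scale == "ordinal":
        k = max(len(spec.levels or ()) - 1, 1)
        out[ok] = cm.Greens(0.15 + 0.85 * codes[ok] / k)
    else:  # nominal / binary: discrete reds
        k = max(len(spec.levels or ()), 2)
        shades = cm.Reds(np.linspace(0.25, 0.95, k))
        out[ok] = shades[codes[ok].astype(int)]
    return out


def heatmap_rgba(
    d: MixedDataset,
    var_order: Sequence[int] | None = None,
    sample_order: Sequence[int] | None = None,
) -> np.ndarray:
    """(p, n, 4) RGBA array of the mixed heatmap body; missing = white."""
    var_order = list(var_order) if var_order is not None else list(range(d.p))
    sample_order = (
        list(sample_order) if sample_order is not None else list(range(d.n))
    )
    rows = []
    for j in var_order:
        spec = d.specs[j]
        codes = d.codes(spec.name)
        rows.append(_row_rgba(d.values_of(spec.name), spec, codes)[sample_order])
    return np.stack(rows)


def _check_tree(tree: LinkageTree, labels: Sequence[str], what: str) -> None:
    if sorted(tree.labels) != sorted(labels):
        raise MixedDataError(f"{what} tree labels do not match the data")


def _plot_dendrogram(ax, tree: LinkageTree, orientation: str) -> None:
    if tree.n_leaves > 1:
        sch.dendrogram(
            tree.linkage,
            ax=ax,
            orientation=orientation,
            no_labels=True,
            color_threshold=0.0,
            above_threshold_color="black",
        )
    ax.set_axis_off()


def mixed_heatmap(
    d: MixedDataset,
    sample_tree: LinkageTree,
    var_tree: LinkageTree,
    path: str | Path,
) -> Path:
    """Render the integrative heatmap (variables x samples) to ``path``."""
    if d.p > MAX_HEATMAP_VARIABLES:
        raise MixedDataError(
            f"heatmap is limited to {MAX_HEATMAP_VARIABLES} variables (got {d.p})"
        )
    _check_tree(sample_tree, d.sample_ids, "sample")
    _check_tree(var_tree, d.var_names, "variable")
    sample_pos = {lab: i for i, lab in enumerate(d.sample_ids)}
    var_pos = {lab: i for i, lab in enumerate(d.var_names)}
    sample_order = [sample_pos[sample_tree.labels[i]] for i in sample_tree.leaf_order()]
    var_order = [var_pos[var_tree.labels[i]] for i in var_tree.leaf_order()]
    body = heatmap_rgba(d, var_order=var_order, sample_order=sample_order)

    fig = plt.figure(figsize=(10, max(4, 0.25 * d.p + 2)))
    gs = fig.add_gridspec(
        2, 2, width_ratios=[1, 4], height_ratios=[1, 4], wspace=0.02, hspace=0.02
    )
    _plot_dendrogram(fig.add_subplot(gs[0, 1]), sample_tree, "top")
    _plot_dendrogram(fig.add_subplot(gs[1, 0]), var_tree, "left")
    ax = fig.add_subplot(gs[1, 1])
    ax.imshow(body, aspect="auto", interpolation="nearest")
    ax.set_yticks(range(len(var_order)))
    ax.set_yticklabels([d.var_names[j] for j in var_order], fontsize=7)
    ax.yaxis.tick_right()
    ax.set_xticks([])
    handles = [
        plt.Rectangle((0, 0), 1, 1, color=cm.Blues(0.7), label="quantitative"),
        plt.Rectangle((0, 0), 1, 1, color=cm.Greens(0.7), label="ordinal"),
        plt.Rectangle((0, 0), 1, 1, color=cm.Reds(0.7), label="nominal/binary"),
        plt.Rectangle((0, 0), 1, 1, facecolor="white", edgecolor="grey",
                      label="missing"),
    ]
    ax.legend(handles=handles, loc="upper left", bbox_to_anchor=(0.0, -0.02),
              ncol=4, fontsize=7, frameon=False)
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def ordered_similarity(S: SimilarityMatrix, tree: LinkageTree) -> pd.DataFrame:
    """Similarity matrix reordered to the tree's dendrogram leaf order."""
    if sorted(S.labels) != sorted(tree.labels):
        raise MixedDataError("similarity matrix and tree labels differ")
    pos = {lab: i for i, lab in enumerate(S.labels)}
    order = [pos[tree.labels[i]] for i in tree.leaf_order()]
    vals = S.values[np.ix_(order, order)]
    labs = [S.labels[i] for i in order]
    return pd.DataFrame(vals, index=labs, columns=labs)


def variable_similarity_heatmap(
    S: SimilarityMatrix, tree: LinkageTree, path: str | Path
) -> Path:
    """Symmetric similarity heatmap (darker blue = stronger association)."""
    frame = ordered_similarity(S, tree)
    fig = plt.figure(figsize=(8, 8))
    gs = fig.add_gridspec(
        2, 2, width_ratios=[1, 4], height_ratios=[1, 4], wspace=0.02, hspace=0.02
    )
    _plot_dendrogram(fig.add_subplot(gs[0, 1]), tree, "top")
    _plot_dendrogram(fig.add_subplot(gs[1, 0]), tree, "left")
    ax = fig.add_subplot(gs[1, 1])
    im = ax.imshow(
        frame.to_numpy(), cmap="Blues", vmin=0.0, vmax=1.0,
        aspect="auto", interpolation="nearest",
    )
    ax.set_xticks(range(len(frame)))
    ax.set_xticklabels(frame.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(frame)))
    ax.set_yticklabels(frame.index, fontsize=7)
    ax.yaxis.tick_right()
    fig.colorbar(im, ax=ax, shrink=0.6, label="similarity")
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def scatter_coordinates(
    S: SimilarityMatrix, outcome: str, predictor: str
) -> pd.DataFrame:
    """Plot coordinates: x = similarity to predictor, y = to outcome."""
    if outcome == predictor:
        raise MixedDataError("outcome and predictor must differ")
    for lab in (outcome, predictor):
        if lab not in S.labels:
            raise MixedDataError(f"unknown label {lab!r}")
    frame = S.to_frame()
    s_op = float(frame.loc[outcome, predictor])
    records = []
    for lab in S.labels:
        if lab == outcome:
            x, y = s_op, 1.0
        elif lab == predictor:
            x, y = 1.0, s_op
        else:
            x = float(frame.loc[lab, predictor])
            y = float(frame.loc[lab, outcome])
        records.append({"variable": lab, "x": x, "y": y})
    return pd.DataFrame.from_records(records).set_index("variable")


def similarity_scatter(
    S: SimilarityMatrix,
    outcome: str,
    predictor: str,
    path: str | Path,
    specs: Sequence[VariableSpec] | None = None,
) -> pd.DataFrame:
    """Predictor-outcome similarity scatter; returns plotted coordinates.

    Point text is the variable name; with ``specs`` given, numerical
    variables are drawn black and categorical ones purple.
    """
    coords = scatter_coordinates(S, outcome, predictor)
    kind = {}
    if specs is not None:
        kind = {
            s.name: ("numerical" if s.scale == "quantitative" else "categorical")
            for s in specs
        }
    fig, ax = plt.subplots(figsize=(7, 7))
    for lab, row in coords.iterrows():
        color = "purple" if kind.get(lab) == "categorical" else "black"
        ax.text(row["x"], row["y"], str(lab), color=color,
                ha="center", va="center", fontsize=9)
    ax.set_xlim(-0.05, 1.1)
    ax.set_ylim(-0.05, 1.1)
    ax.set_xlabel(f"similarity to predictor ({predictor})")
    ax.set_ylabel(f"similarity to outcome ({outcome})")
    ax.grid(True, alpha=0.3)
    fig.savefig(Path(path), dpi=120, bbox_inches="tight")
    plt.close(fig)
    return coords
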