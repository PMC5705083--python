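"""Data model for mixed-type sample x variable tables.

A *mixed-type* table holds variables measured on different scales at the
same time: quantitative (real-valued), ordinal (ordered categories),
nominal (unordered categories) and binary (two categories).  This module
defines the typed containers used throughout the package --
:class:`VariableSpec`, :class:`MixedDataset`, :class:`SimilarityMatrix`
and :class:`DistanceMatrix` -- together with plain-text readers/writers
for tables, variable specifications and square labeled matrices.

Conventions
-----------
* Rows are samples, columns are variables; the first table column holds
  unique sample identifiers.
* Missing cells are encoded by configurable tokens (default: the empty
  string and ``"NA"``, case-sensitive) and tracked by a boolean mask.
* Binary variables are stored like nominal variables with two levels;
  the ``"binary"`` scale tag only routes coefficient selection in the
  association-measures (ama) method.
* Undeclared nominal/binary level order is the order of first appearance
  in the data, which keeps all downstream computations deterministic.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SCALES",
    "DEFAULT_MISSING_TOKENS",
    "MixedDataError",
    "DegenerateVariableWarning",
    "VariableSpec",
    "MixedDataset",
    "SimilarityMatrix",
    "DistanceMatrix",
    "read_mixed_table",
    "write_square_matrix",
    "read_square_matrix",
    "summarize_dataset",
]

SCALES = ("quantitative", "ordinal", "nominal", "binary")
DEFAULT_MISSING_TOKENS = ("", "NA")


class MixedDataError(ValueError):
    """Raised on invalid mixed-data input (bad spec, bad cell, bad matrix)."""


class DegenerateVariableWarning(UserWarning):
    """A variable carries no usable information (constant, empty, ...)."""


@dataclasses.dataclass(frozen=True)
class VariableSpec:
    """Scale declaration for a single variable.

    Parameters
    ----------
    name
        Unique variable name (column header).
    scale
        One of ``"quantitative"``, ``"ordinal"``, ``"nominal"``,
        ``"binary"``.
    levels
        Ordered category labels.  Required for ordinal variables
        (low to high); optional for nominal/binary where it fixes the
        storage order of levels.
    weight
        Nonnegative Gower weight ``w_k`` (default 1).
    """

    name: str
    scale: str
    levels: tuple[str, ...] | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise MixedDataError(
                f"variable {self.name!r}: unknown scale {self.scale!r}; "
                f"expected one of {SCALES}"
            )
        if self.levels is not None:
            levels = tuple(str(v) for v in self.levels)
            object.__setattr__(self, "levels", levels)
            if len(set(levels)) != len(levels):
                raise MixedDataError(
                    f"variable {self.name!r}: duplicate levels {levels}"
                )
        if self.scale == "ordinal" and not self.levels:
            raise MixedDataError(
                f"ordinal variable {self.name!r} requires an ordered level list"
            )
        if self.scale == "binary" and self.levels is not None and len(self.levels) > 2:
            raise MixedDataError(
                f"binary variable {self.name!r} declares {len(self.levels)} levels"
            )
        if not np.isfinite(self.weight) or self.weight < 0:
            raise MixedDataError(
                f"variable {self.name!r}: weight must be a nonnegative real"
            )

    @property
    def is_categorical(self) -> bool:
        return self.scale != "quantitative"


class MixedDataset:
    """A typed sample x variable table with missingness mask.

    Quantitative columns are stored as float (NaN = missing); categorical
    columns as strings (None/NaN = missing).  Observed categorical values
    are validated against the declared (or first-appearance) level order.
    """

    def __init__(self, frame: pd.DataFrame, specs: Sequence[VariableSpec]):
        frame = frame.copy()
        specs = list(specs)
        if frame.shape[0] < 1 or frame.shape[1] < 1:
            raise MixedDataError("dataset needs at least one sample and one variable")
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise MixedDataError("duplicate variable names in spec")
        if list(frame.columns) != names:
            raise MixedDataError("frame columns do not match spec order/names")
        ids = [str(i) for i in frame.index]
        if len(set(ids)) != len(ids):
            raise MixedDataError("duplicate sample IDs")
        frame.index = pd.Index(ids, name="sample")

        resolved: list[VariableSpec] = []
        for spec in specs:
            col = frame[spec.name]
            if spec.scale == "quantitative":
                try:
                    frame[spec.name] = pd.to_numeric(col)
                except (ValueError, TypeError) as exc:
                    raise MixedDataError(
                        f"quantitative variable {spec.name!r}: non-numeric cell ({exc})"
                    ) from exc
                resolved.append(spec)
                continue
            vals = col.astype("object").where(col.notna(), None)
            observed: list[str] = []
            for v in vals:
                if v is None:
                    continue
                v = str(v)
                if v not in observed:
                    observed.append(v)
            if spec.levels is not None:
                unknown = [v for v in observed if v not in spec.levels]
                if unknown:
                    raise MixedDataError(
                        f"variable {spec.name!r}: value(s) {unknown} not in "
                        f"declared levels {spec.levels}"
                    )
                levels = spec.levels
            else:
                levels = tuple(observed)
            if spec.scale == "binary" and len(observed) > 2:
                raise MixedDataError(
                    f"binary variable {spec.name!r} has {len(observed)} "
                    f"observed categories: {observed}"
                )
            frame[spec.name] = vals.map(lambda v: None if v is None else str(v))
            resolved.append(dataclasses.replace(spec, levels=levels))
        self.frame = frame
        self.specs = resolved
        self._spec_by_name = {s.name: s for s in resolved}

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        return self.frame.shape[0]

    @property
    def p(self) -> int:
        return self.frame.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def var_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.frame.isna()

    def spec(self, name: str) -> VariableSpec:
        return self._spec_by_name[name]

    def values_of(self, name: str) -> np.ndarray:
        """Raw column values (float for quantitative, object otherwise)."""
        return self.frame[name].to_numpy()

    def codes(self, name: str) -> np.ndarray:
        """Numeric encoding of a column as float (NaN = missing).

        Quantitative columns return their values; categorical columns
        return level codes 0..K-1 following the level order (ordinal:
        low to high).
        """
        spec = self._spec_by_name[name]
        col = self.frame[name]
        if spec.scale == "quantitative":
            return col.to_numpy(dtype=float)
        lookup = {lev: float(i) for i, lev in enumerate(spec.levels or ())}
        return np.array(
            [np.nan if v is None or v != v else lookup[v] for v in col],
            dtype=float,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MixedDataset(n={self.n}, p={self.p})"


def _check_square(labels: Sequence[str], values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    m = len(labels)
    if values.shape != (m, m):
        raise MixedDataError(f"matrix shape {values.shape} does not match {m} labels")
    if len(set(labels)) != m:
        raise MixedDataError("duplicate matrix labels")
    if not np.all(np.isfinite(values)):
        raise MixedDataError("matrix entries must be finite")
    if not np.allclose(values, values.T, atol=1e-8, rtol=0.0):
        raise MixedDataError("matrix is not symmetric")
    return 0.5 * (values + values.T)


@dataclasses.dataclass
class SimilarityMatrix:
    """Labeled symmetric similarity matrix with unit diagonal."""

    labels: list[str]
    values: np.ndarray
    method: str = ""

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = _check_square(self.labels, self.values)
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-8):
            raise MixedDataError("similarity matrix must have unit diagonal")
        np.fill_diagonal(self.values, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclasses.dataclass
class DistanceMatrix:
    """Labeled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    method: str = ""

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = _check_square(self.labels, self.values)
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-8):
            raise MixedDataError("distance matrix must have zero diagonal")
        if np.min(self.values) < -1e-9:
            raise MixedDataError("distance matrix has negative entries")
        np.fill_diagonal(self.values, 0.0)
        np.clip(self.values, 0.0, None, out=self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# -- IO ---------------------------------------------------------------------


def _table_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def _parse_spec_file(spec_path: Path) -> list[VariableSpec]:
    spec_df = pd.read_csv(
        spec_path, sep="\t", dtype=str, keep_default_na=False, comment="#"
    )
    required = {"variable", "scale"}
    if not required.issubset(spec_df.columns):
        raise MixedDataError(
            f"spec file must have columns 'variable' and 'scale'; got "
            f"{list(spec_df.columns)}"
        )
    specs = []
    for _, row in spec_df.iterrows():
        levels_field = str(row.get("levels", "") or "").strip()
        levels = tuple(s.strip() for s in levels_field.split(",")) if levels_field else None
        weight_field = str(row.get("weight", "") or "").strip()
        weight = float(weight_field) if weight_field else 1.0
        specs.append(
            VariableSpec(
                name=str(row["variable"]),
                scale=str(row["scale"]).strip(),
                levels=levels,
                weight=weight,
            )
        )
    return specs


def read_mixed_table(
    table_path: str | Path,
    spec_path: str | Path,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
) -> MixedDataset:
    """Read a delimited sample x variable table plus its variable spec.

    The table must have a header row and a unique sample-ID first column;
    the spec file (TSV with columns ``variable, scale, levels, weight``)
    must list every variable column of the table.  Cells equal to a
    missing token (case-sensitive; default ``""`` and ``"NA"``) and
    unparseable quantitative cells become missing values.
    """
    table_path = Path(table_path)
    specs = _parse_spec_file(Path(spec_path))
    raw = pd.read_csv(
        table_path,
        sep=_table_sep(table_path),
        dtype=str,
        keep_default_na=False,
        index_col=0,
    )
    spec_names = [s.name for s in specs]
    missing_cols = [c for c in raw.columns if c not in spec_names]
    if missing_cols:
        raise MixedDataError(f"table columns without spec entry: {missing_cols}")
    unknown = [n for n in spec_names if n not in raw.columns]
    if unknown:
        raise MixedDataError(f"unknown variable(s) in spec: {unknown}")
    raw = raw[spec_names]
    tokens = set(missing_tokens)
    frame = raw.map(lambda v: None if v in tokens else v)
    for spec in specs:
        if spec.scale == "quantitative":
            frame[spec.name] = pd.to_numeric(frame[spec.name], errors="coerce")
    return MixedDataset(frame, specs)


def write_square_matrix(
    m: SimilarityMatrix | DistanceMatrix, path: str | Path
) -> None:
    """Write a labeled square matrix as TSV (header row + label column).

    Entries are printed with 17 significant digits so a read/write round
    trip reproduces them beyond 12 significant digits.
    """
    _check_square(m.labels, m.values)  # re-validate defensively
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join([""] + list(m.labels)) + "\n")
        for label, row in zip(m.labels, m.values):
            fh.write(label + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_square_matrix(
    path: str | Path, kind: str = "distance", method: str = ""
) -> SimilarityMatrix | DistanceMatrix:
    """Read a TSV square matrix written by :func:`write_square_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    labels = [str(x) for x in df.index]
    if labels != [str(x) for x in df.columns]:
        raise MixedDataError("row labels do not match column labels")
    cls = DistanceMatrix if kind == "distance" else SimilarityMatrix
    return cls(labels=labels, values=df.to_numpy(dtype=float), method=method)


def summarize_dataset(d: MixedDataset) -> pd.DataFrame:
    """Per-variable report: scale, #categories, #missing, range, degeneracy."""
    records = []
    for spec in d.specs:
        col = d.frame[spec.name]
        n_missing = int(col.isna().sum())
        rec: dict[str, object] = {
            "variable": spec.name,
            "scale": spec.scale,
            "n_missing": n_missing,
            "weight": spec.weight,
        }
        if spec.scale == "quantitative":
            vals = col.dropna().to_numpy(dtype=float)
            rec["n_categories"] = np.nan
            if vals.size:
                rec["min"] = float(vals.min())
                rec["max"] = float(vals.max())
                rec["range"] = float(vals.max() - vals.min())
                degenerate = vals.max() == vals.min()
            else:
                rec["min"] = rec["max"] = rec["range"] = np.nan
                degenerate = True
        else:
            observed = col.dropna().unique()
            rec["n_categories"] = len(observed)
            rec["min"] = rec["max"] = rec["range"] = np.nan
            degenerate = len(observed) < 2
        if degenerate:
            warnings.warn(
                f"variable {spec.name!r} is degenerate (constant or empty)",
                DegenerateVariableWarning,
                stacklevel=2,
            )
        rec["degenerate"] = degenerate
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("variable")
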