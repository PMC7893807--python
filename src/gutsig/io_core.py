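"""Domain types, invariant enforcement, and tabular/tree readers and writers.

All tables travel as thin validated wrappers around :class:`pandas.DataFrame`
with samples as rows. Trees are :class:`skbio.TreeNode` objects validated at
read time; distance matrices reuse :class:`skbio.stats.distance.DistanceMatrix`,
which already enforces symmetry, hollowness and non-negativity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import skbio
from skbio.stats.distance import DistanceMatrix

__all__ = [
    "AbundanceTable",
    "CohortMetadata",
    "BrainVolumeTable",
    "ContingencyTable2x2",
    "DistanceMatrix",
    "GutsigError",
    "ValidationError",
    "CARS_ITEM_GRID",
    "CARS_ITEM_NAMES",
    "read_abundance_table",
    "read_metadata",
    "read_brain_volumes",
    "read_newick",
    "read_distance_matrix",
    "write_distance_matrix",
    "metadata_to_frame",
    "write_metadata",
    "write_results",
    "read_results",
]


class GutsigError(Exception):
    """Base class for all package errors."""


class ValidationError(GutsigError):
    """An input violated a documented invariant."""


# CARS items are scored on a 1-4 scale in half-point steps.
CARS_ITEM_GRID = tuple(1.0 + 0.5 * k for k in range(7))
CARS_ITEM_NAMES = tuple(f"cars{i}" for i in range(1, 16))

_REL_ROWSUM_TOL = 1e-6


@dataclass(frozen=True)
class AbundanceTable:
    """Samples x genera abundance matrix, counts or relative abundances.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by sample id, columns by genus id. Non-negative.
    mode : {"counts", "relative"}
        In ``relative`` mode every row must sum to 1 within 1e-6.
    """

    data: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise ValidationError(f"unknown abundance mode {self.mode!r}")
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate genus ids: {dups}")
        values = df.to_numpy(dtype=float)
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"missing abundance value at sample {df.index[r]!r}, genus {df.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {df.index[r]!r}, genus {df.columns[c]!r}"
            )
        if self.mode == "relative":
            sums = values.sum(axis=1)
            bad = np.where(np.abs(sums - 1.0) > _REL_ROWSUM_TOL)[0]
            if bad.size:
                raise ValidationError(
                    f"row sum != 1 for sample {df.index[bad[0]]!r} (sum={sums[bad[0]]:.6g})"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def genus_ids(self) -> list[str]:
        return [str(g) for g in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_relative(self) -> "AbundanceTable":
        """Total-sum scale each sample to proportions.

        Raises
        ------
        ValidationError
            If the table is already relative or a sample row sums to zero.
        """
        if self.mode == "relative":
            raise ValidationError("table is already in relative mode")
        values = self.values
        sums = values.sum(axis=1)
        zero = np.where(sums == 0)[0]
        if zero.size:
            raise ValidationError(
                f"sample {self.data.index[zero[0]]!r} has zero total abundance"
            )
        rel = pd.DataFrame(
            values / sums[:, None], index=self.data.index, columns=self.data.columns
        )
        return AbundanceTable(rel, mode="relative")

    def subset_genera(
        self, genera: Sequence[str], renormalize: bool = False
    ) -> "AbundanceTable":
        """Restrict to ``genera`` (order preserved), optionally renormalizing rows.

        Renormalization requires every sample to have nonzero total over the
        subset and yields a relative-mode table.
        """
        missing = [g for g in genera if g not in self.data.columns]
        if missing:
            raise ValidationError(f"genera absent from table: {missing}")
        sub = self.data.loc[:, list(genera)]
        if not renormalize:
            return AbundanceTable(sub, mode=self.mode)
        sums = sub.to_numpy(dtype=float).sum(axis=1)
        zero = np.where(sums == 0)[0]
        if zero.size:
            raise ValidationError(
                f"sample {sub.index[zero[0]]!r} has zero total over the genus subset"
            )
        return AbundanceTable(sub.div(sums, axis=0), mode="relative")

    def write(self, path) -> None:
        self.data.rename_axis("sample_id").to_csv(path, sep="\t")


@dataclass
class CohortMetadata:
    """Per-sample behavioral and demographic record.

    ``ados_total`` may be missing (None); analyses needing it drop the sample.
    ``severity`` is derived from ``cars_total`` (see :mod:`gutsig.cars_scoring`).
    """

    sample_id: str
    cars_items: tuple[float, ...]
    cars_total: float
    ados_total: float | None = None
    age_years: float | None = None
    sex: str | None = None
    severity: str | None = None

    def __post_init__(self) -> None:
        if len(self.cars_items) != 15:
            raise ValidationError(
                f"sample {self.sample_id!r}: expected 15 CARS items, got {len(self.cars_items)}"
            )
        for name, v in zip(CARS_ITEM_NAMES, self.cars_items):
            if not any(math.isclose(v, g, abs_tol=1e-9) for g in CARS_ITEM_GRID):
                raise ValidationError(
                    f"sample {self.sample_id!r}: item {name} value {v} is off the 1-4 half-point grid"
                )
        if abs(self.cars_total - sum(self.cars_items)) > 1e-9:
            raise ValidationError(
                f"sample {self.sample_id!r}: cars_total {self.cars_total} != sum of items "
                f"{sum(self.cars_items)}"
            )
        if self.ados_total is not None and not (self.ados_total >= 0):
            raise ValidationError(f"sample {self.sample_id!r}: ados_total must be >= 0")
        if self.age_years is not None and not (self.age_years > 0):
            raise ValidationError(f"sample {self.sample_id!r}: age_years must be > 0")
        if self.sex is not None and self.sex not in ("female", "male"):
            raise ValidationError(f"sample {self.sample_id!r}: sex must be female/male")
        if self.severity is not None and self.severity not in ("severe", "mild_moderate"):
            raise ValidationError(f"sample {self.sample_id!r}: bad severity flag")


@dataclass(frozen=True)
class BrainVolumeTable:
    """Samples x brain regions volume table (mm^3). Missing values permitted."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValidationError("duplicate sample or region ids in brain volume table")
        values = df.to_numpy(dtype=float)
        finite = np.isfinite(values)
        if (values[finite] <= 0).any():
            raise ValidationError("brain volumes must be positive (mm^3)")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def region_ids(self) -> list[str]:
        return [str(r) for r in self.data.columns]

    def write(self, path) -> None:
        self.data.rename_axis("sample_id").to_csv(path, sep="\t")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 contingency table; rows are groups, columns outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"cell {name} must be a non-negative integer")
        arr = self.to_array()
        if (arr.sum(axis=0) == 0).all() or (arr.sum(axis=1) == 0).all():
            raise ValidationError("contingency table needs a nonzero row and column")

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", index_col=0, dtype=None)
    except pd.errors.ParserError as exc:  # ragged rows carry a line number
        raise ValidationError(f"malformed TSV {path}: {exc}") from exc


def read_abundance_table(path, transposed: bool = False, mode: str | None = None) -> AbundanceTable:
    """Read a genus abundance TSV (samples as rows unless ``transposed``).

    Counts are auto-detected when every value is a whole number; pass
    ``mode`` explicitly to override.
    """
    df = _read_tsv(path)
    if transposed:
        df = df.T
    df = df.astype(float)
    if mode is None:
        values = df.to_numpy()
        mode = "counts" if np.allclose(values, np.round(values)) else "relative"
    return AbundanceTable(df, mode=mode)


_REQUIRED_META_COLS = CARS_ITEM_NAMES + ("cars_total",)


def read_metadata(path) -> list[CohortMetadata]:
    """Read the per-sample metadata TSV into validated records."""
    df = _read_tsv(path)
    missing = [c for c in _REQUIRED_META_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata missing required columns: {missing}")
    records = []
    for sid, row in df.iterrows():
        ados = row.get("ados_total")
        age = row.get("age_years")
        records.append(
            CohortMetadata(
                sample_id=str(sid),
                cars_items=tuple(float(row[c]) for c in CARS_ITEM_NAMES),
                cars_total=float(row["cars_total"]),
                ados_total=None if ados is None or pd.isna(ados) else float(ados),
                age_years=None if age is None or pd.isna(age) else float(age),
                sex=row.get("sex") if isinstance(row.get("sex"), str) else None,
                severity=row.get("severity") if isinstance(row.get("severity"), str) else None,
            )
        )
    return records


def metadata_to_frame(records: Iterable[CohortMetadata]) -> pd.DataFrame:
    """Flatten metadata records into a DataFrame indexed by sample id."""
    rows = {}
    for r in records:
        row: dict[str, object] = dict(zip(CARS_ITEM_NAMES, r.cars_items))
        row["cars_total"] = r.cars_total
        row["ados_total"] = np.nan if r.ados_total is None else r.ados_total
        row["age_years"] = np.nan if r.age_years is None else r.age_years
        row["sex"] = r.sex
        row["severity"] = r.severity
        rows[r.sample_id] = row
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")


def write_metadata(records: Iterable[CohortMetadata], path) -> None:
    metadata_to_frame(records).to_csv(path, sep="\t")


def read_brain_volumes(path) -> BrainVolumeTable:
    return BrainVolumeTable(_read_tsv(path).astype(float))


def read_newick(path) -> skbio.TreeNode:
    """Read and validate a rooted Newick tree with branch lengths.

    Every leaf must carry a unique label; branch lengths must be
    non-negative (a missing root length is treated as 0).
    """
    tree = skbio.TreeNode.read(str(path), format="newick")
    return validate_tree(tree)


def validate_tree(tree: skbio.TreeNode) -> skbio.TreeNode:
    names = [t.name for t in tree.tips()]
    if any(n is None for n in names):
        raise ValidationError("tree has an unlabeled leaf")
    if len(set(names)) != len(names):
        raise ValidationError("tree leaf labels are not unique")
    for node in tree.traverse():
        if node.length is None:
            if node.is_root():
                node.length = 0.0
            else:
                raise ValidationError(f"node {node.name!r} lacks a branch length")
        elif node.length < 0:
            raise ValidationError(f"negative branch length at node {node.name!r}")
    return tree


def read_distance_matrix(path) -> DistanceMatrix:
    df = _read_tsv(path).astype(float)
    return DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).rename_axis("sample_id").to_csv(
        path, sep="\t"
    )


# ---------------------------------------------------------------------------
# Structured reports
# ---------------------------------------------------------------------------

def write_results(report: Mapping, path, tsv_path=None) -> None:
    """Write a report as JSON plus an optional flat TSV of statistic rows.

    The flat TSV collects every dict in the report that looks like a test
    result (has ``statistic`` and ``p`` keys), one row per result.
    """
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    if tsv_path is not None:
        rows = []

        def collect(prefix: str, obj) -> None:
            if isinstance(obj, Mapping):
                if "statistic" in obj and ("p" in obj or "p_perm" in obj):
                    row = {"name": prefix}
                    row.update({k: obj[k] for k in obj if not isinstance(obj[k], (dict, list))})
                    rows.append(row)
                else:
                    for k, v in obj.items():
                        collect(f"{prefix}.{k}" if prefix else str(k), v)

        collect("", report)
        pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def read_results(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
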