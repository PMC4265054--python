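"""Tabular I/O and imputation for expression matrices, cycle series and gene sets.

All matrices are genes-in-rows, tab-separated, with a ``gene_id`` header
column and sample ids in the header row.  Missing values are written as
``NA``; on read, an empty field or ``NA``/``NaN`` is treated as missing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_NA_TOKENS = {"", "NA", "NaN", "nan", "na"}


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 expression ratios (M-values).

    Parameters
    ----------
    gene_ids, sample_ids
        Unique row / column identifiers.
    values
        ``(m, n)`` float array of M-values; missing entries are NaN and
        mirrored in ``missing_mask``.
    pvalues
        Optional matched ``(m, n)`` array of per-gene p-values in [0, 1].
    missing_mask
        Boolean ``(m, n)`` array, True where the value is missing.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    pvalues: np.ndarray | None = None
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m, n = self.values.shape
        if len(self.gene_ids) != m or len(self.sample_ids) != n:
            raise ValueError(
                f"id lists ({len(self.gene_ids)}, {len(self.sample_ids)}) do not "
                f"match matrix shape {self.values.shape}"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise ValueError("missing_mask shape does not match values")
        if self.pvalues is not None:
            self.pvalues = np.asarray(self.pvalues, dtype=float)
            if self.pvalues.shape != self.values.shape:
                raise ValueError("pvalues shape does not match values")
            finite = self.pvalues[np.isfinite(self.pvalues)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("pvalues must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def is_complete(self) -> bool:
        return not bool(self.missing_mask.any())

    def impute(self, k: int = 10) -> "ExpressionMatrix":
        """Return a copy with missing entries filled by KNN imputation."""
        filled = impute_missing(np.where(self.missing_mask, np.nan, self.values), k=k)
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            values=filled,
            pvalues=None if self.pvalues is None else self.pvalues.copy(),
            missing_mask=np.zeros_like(self.missing_mask),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class CellCycleSeries:
    """Cell-cycle time course: genes x timepoints, M-values relative to t = 0."""

    gene_ids: list[str]
    timepoints_min: np.ndarray
    values: np.ndarray
    cycle_duration_min: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timepoints_min = np.asarray(self.timepoints_min, dtype=float)
        _check_unique(self.gene_ids, "gene")
        if self.timepoints_min.ndim != 1 or self.timepoints_min.size < 4:
            raise ValueError("need at least 4 timepoints")
        if self.timepoints_min[0] != 0:
            raise ValueError("first timepoint must be 0 (M-values are relative to t = 0)")
        if not np.all(np.diff(self.timepoints_min) > 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.cycle_duration_min < self.timepoints_min[-1]:
            raise ValueError("cycle_duration_min must cover the last timepoint")
        if self.values.shape != (len(self.gene_ids), self.timepoints_min.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)}, {self.timepoints_min.size})"
            )

    @property
    def n_timepoints(self) -> int:
        return self.timepoints_min.size


@dataclass
class GeneSet:
    """A named set of gene identifiers."""

    name: str
    members: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.members = set(self.members)
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# matrix read / write


def _parse_table(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}: header must contain gene_id plus sample columns")
        sample_ids = header[1:]
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) == 1 and fields[0] == "":
                continue  # trailing blank line
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected {len(header)}"
                )
            gene_ids.append(fields[0])
            row = []
            for j, cell in enumerate(fields[1:], start=1):
                if cell in _NA_TOKENS:
                    row.append(np.nan)
                else:
                    try:
                        row.append(float(cell))
                    except ValueError as exc:
                        raise ValueError(
                            f"{path}: non-numeric cell at line {lineno}, column {j + 1}: {cell!r}"
                        ) from exc
            rows.append(row)
    _check_unique(gene_ids, "gene")
    _check_unique(sample_ids, "sample")
    return gene_ids, sample_ids, np.asarray(rows, dtype=float)


def read_expression_matrix(
    path: str | Path, pvalue_path: str | Path | None = None
) -> ExpressionMatrix:
    """Read a TSV expression matrix (and optionally a matched p-value matrix)."""
    gene_ids, sample_ids, values = _parse_table(path)
    pvalues = None
    if pvalue_path is not None:
        p_genes, p_samples, pvalues = _parse_table(pvalue_path)
        if p_genes != gene_ids or p_samples != sample_ids:
            raise ValueError("p-value matrix ids do not match expression matrix ids")
        if pvalues.shape != values.shape:
            raise ValueError("p-value matrix shape does not match expression matrix")
    return ExpressionMatrix(gene_ids, sample_ids, values, pvalues=pvalues)


def write_expression_matrix(
    m: ExpressionMatrix, path: str | Path, float_format: str = "%.8g"
) -> None:
    """Write a TSV expression matrix; missing entries become ``NA``."""
    path = Path(path)
    vals = np.where(m.missing_mask, np.nan, m.values)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(m.sample_ids) + "\n")
        for gid, row in zip(m.gene_ids, vals):
            cells = ["NA" if np.isnan(v) else float_format % v for v in row]
            fh.write(gid + "\t" + "\t".join(cells) + "\n")


def read_cycle_series(path: str | Path, meta_path: str | Path) -> CellCycleSeries:
    """Read a cycle time course: TSV matrix plus a JSON sidecar with the geometry."""
    gene_ids, sample_ids, values = _parse_table(path)
    with open(meta_path, encoding="utf-8") as fh:
        meta = json.load(fh)
    return CellCycleSeries(
        gene_ids=gene_ids,
        timepoints_min=np.asarray(meta["timepoints_min"], dtype=float),
        values=values,
        cycle_duration_min=float(meta["cycle_duration_min"]),
    )


def write_cycle_series(series: CellCycleSeries, path: str | Path, meta_path: str | Path) -> None:
    m = ExpressionMatrix(
        gene_ids=series.gene_ids,
        sample_ids=[f"t{int(t)}" for t in series.timepoints_min],
        values=series.values,
    )
    write_expression_matrix(m, path)
    with open(meta_path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "timepoints_min": [float(t) for t in series.timepoints_min],
                "cycle_duration_min": float(series.cycle_duration_min),
            },
            fh,
        )
        fh.write("\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read GMT-style gene sets: name TAB description TAB member TAB member ..."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: gene set has no members")
            members = {f for f in fields[2:] if f}
            if not members:
                raise ValueError(f"line {lineno}: gene set has no members")
            sets.append(GeneSet(name=fields[0], members=members))
    return sets


def write_gene_sets(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write(s.name + "\t\t" + "\t".join(sorted(s.members)) + "\n")


# ---------------------------------------------------------------------------
# KNN imputation

def impute_missing(values: np.ndarray, k: int = 10) -> np.ndarray:
    """Fill missing (NaN) entries by k-nearest-neighbour row imputation.

    For each gene (row) with missing entries, neighbours are ranked by
    Euclidean distance over the columns observed in both rows, scaled by the
    fraction of columns used (so sparsely co-observed pairs are not unfairly
    favoured).  Each hole is replaced by the mean of the k nearest
    neighbours' observed values in that column; if none of the k neighbours
    observes the column, the column mean is used instead.

    Observed entries are never altered.  A row with no observed values is an
    error; if fewer than ``k`` usable neighbours exist, the column mean is
    used with a logged warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = np.array(values, dtype=float)
    obs = ~np.isnan(values)
    if values.ndim != 2:
        raise ValueError("values must be 2-D")
    if not obs.all(axis=1).any() and np.isnan(values).any():
        pass  # handled per-row below
    empty_rows = np.where(~obs.any(axis=1))[0]
    if empty_rows.size:
        raise ValueError(f"row {empty_rows[0]} is entirely missing; cannot impute")
    if obs.all():
        return values

    col_means = np.nanmean(values, axis=0)
    out = values.copy()
    n_rows, n_cols = values.shape
    for i in range(n_rows):
        holes = np.where(~obs[i])[0]
        if holes.size == 0:
            continue
        # scaled Euclidean distance to every other row over co-observed columns
        dists = np.full(n_rows, np.inf)
        for j in range(n_rows):
            if j == i:
                continue
            both = obs[i] & obs[j]
            n_both = int(both.sum())
            if n_both == 0:
                continue
            d = values[i, both] - values[j, both]
            dists[j] = np.sqrt(np.sum(d * d) / n_both)
        order = np.argsort(dists, kind="stable")
        usable = order[np.isfinite(dists[order])]
        if usable.size < k:
            logger.warning(
                "row %d: only %d usable neighbours (< k=%d); falling back to column means",
                i, usable.size, k,
            )
            out[i, holes] = col_means[holes]
            continue
        nn = usable[:k]
        for c in holes:
            vals = values[nn, c]
            vals = vals[~np.isnan(vals)]
            out[i, c] = vals.mean() if vals.size else col_means[c]
    return out
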