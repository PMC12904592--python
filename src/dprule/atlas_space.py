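"""Developmental space: from a single-cell embryo atlas to per-gene activity fractions.

The developmental signature of a gene is defined on a grid of developmental
coordinates, each coordinate being a (cell type, embryo-time bin) pair.  For
every gene the entry at a coordinate is the fraction of cells sampled there in
which the gene is *active* (UMI count at or above a configurable threshold).
Rows of the resulting matrix are the developmental vectors g_D used by the
similarity analysis.

The atlas is read from the GEO-style triplet layout: a MatrixMarket counts
file plus sidecar TSVs annotating cells (cell type, estimated embryo time in
minutes) and genes.  Cells lacking a cell-type or time annotation are retained
in the atlas but excluded from the developmental space.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionAtlas",
    "CoordinateAssignment",
    "DevelopmentalMatrix",
    "read_atlas",
    "binarize_activity",
    "assign_coordinates",
    "build_developmental_matrix",
    "stage_profile",
]


@dataclass
class ExpressionAtlas:
    """UMI counts (cells x genes) with per-cell annotations.

    ``cell_type`` entries may be ``None`` and ``embryo_time`` entries NaN for
    unannotated cells; such cells are flagged unusable for coordinate
    assignment but are kept in the matrix.
    """

    counts: sp.csr_matrix
    cell_ids: list
    gene_ids: list
    cell_type: np.ndarray
    embryo_time: np.ndarray
    lineage: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells or len(self.gene_ids) != n_genes:
            raise ValueError(
                f"annotation lengths ({len(self.cell_ids)} cells, "
                f"{len(self.gene_ids)} genes) do not match counts shape {self.counts.shape}"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell_ids are not unique")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts contain negative entries")
        self.cell_type = np.asarray(self.cell_type, dtype=object)
        self.embryo_time = np.asarray(self.embryo_time, dtype=float)
        if self.cell_type.shape[0] != n_cells or self.embryo_time.shape[0] != n_cells:
            raise ValueError("per-cell annotation arrays must have one entry per cell")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def annotated(self) -> np.ndarray:
        """Boolean mask of cells usable for coordinate assignment."""
        has_type = np.array([t is not None and t == t for t in self.cell_type])
        return has_type & np.isfinite(self.embryo_time)


@dataclass
class CoordinateAssignment:
    """Per-cell developmental coordinate: (cell type, stage bin index).

    ``stage`` is -1 for cells mapped to the null coordinate (missing cell type
    or embryo time); those cells are excluded downstream.
    """

    cell_type: np.ndarray
    stage: np.ndarray
    stage_edges: np.ndarray
    n_below: int = 0
    n_above: int = 0

    @property
    def n_stages(self) -> int:
        return len(self.stage_edges) - 1

    @property
    def valid(self) -> np.ndarray:
        return self.stage >= 0


@dataclass
class DevelopmentalMatrix:
    """Genes x developmental coordinates matrix of activity fractions."""

    values: np.ndarray
    gene_ids: list
    coordinates: list  # list of (cell_type, stage_index) tuples
    n_cells_per_coordinate: np.ndarray
    stage_edges: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.coordinates)):
            raise ValueError("values shape does not match gene/coordinate lists")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("developmental matrix entries must lie in [0, 1]")

    @property
    def labels(self) -> list:
        return [f"{t}|{s}" for t, s in self.coordinates]

    @property
    def stages(self) -> list:
        return sorted({s for _, s in self.coordinates})

    @property
    def cell_types(self) -> list:
        return sorted({t for t, _ in self.coordinates})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.labels)

    def save(self, prefix: str | Path) -> None:
        """Write the matrix as TSV plus a JSON sidecar with bin edges and counts."""
        prefix = Path(prefix)
        self.to_frame().to_csv(prefix.with_suffix(".tsv"), sep="\t", float_format="%.10g")
        sidecar = {
            "stage_edges": None if self.stage_edges is None else list(map(float, self.stage_edges)),
            "coordinates": [[t, int(s)] for t, s in self.coordinates],
            "n_cells_per_coordinate": [int(n) for n in self.n_cells_per_coordinate],
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_atlas(
    matrix_path: str | Path,
    cell_annotation_path: str | Path,
    gene_annotation_path: str | Path,
    *,
    cell_id_col: str = "cell_id",
    gene_id_col: str = "gene_id",
    cell_type_col: str = "cell_type",
    time_col: str = "embryo_time",
    lineage_col: str | None = None,
) -> ExpressionAtlas:
    """Read a MatrixMarket counts triplet with cell/gene TSV sidecars.

    The matrix must be cells x genes with rows matching the cell TSV and
    columns matching the gene TSV; a dimension mismatch is fatal.
    """
    counts = sp.csr_matrix(mmread(str(matrix_path)))
    cells = pd.read_csv(cell_annotation_path, sep="\t", dtype=str)
    genes = pd.read_csv(gene_annotation_path, sep="\t", dtype=str)
    if counts.shape != (len(cells), len(genes)):
        hint = ""
        if counts.shape == (len(genes), len(cells)):
            hint = " (the matrix appears transposed: rows must be cells)"
        raise ValueError(
            f"dimension mismatch between {matrix_path} {counts.shape}, "
            f"{cell_annotation_path} ({len(cells)} rows) and "
            f"{gene_annotation_path} ({len(genes)} rows){hint}"
        )
    for col in (cell_id_col, cell_type_col, time_col):
        if col not in cells.columns:
            raise ValueError(f"cell annotation file {cell_annotation_path} lacks column {col!r}")
    if gene_id_col not in genes.columns:
        raise ValueError(f"gene annotation file {gene_annotation_path} lacks column {gene_id_col!r}")

    raw_time = cells[time_col]
    time = pd.to_numeric(raw_time, errors="coerce")
    bad = time.isna() & raw_time.notna() & (raw_time.str.strip() != "")
    if bad.any():
        row = int(np.flatnonzero(bad.values)[0])
        raise ValueError(
            f"unparseable embryo time {raw_time.iloc[row]!r} at row {row + 2} "
            f"of {cell_annotation_path}"
        )
    if (time.dropna() < 0).any():
        raise ValueError(f"negative embryo time in {cell_annotation_path}")

    cell_type = cells[cell_type_col].where(cells[cell_type_col].notna(), None)
    cell_type = np.array(
        [None if (t is None or str(t).strip() == "") else str(t) for t in cell_type],
        dtype=object,
    )
    lineage = None
    if lineage_col is not None and lineage_col in cells.columns:
        lineage = cells[lineage_col].to_numpy(dtype=object)

    n_unusable = int((~pd.notna(cell_type)).sum() + time.isna().sum())
    if n_unusable:
        logger.info("atlas: %d cell annotations missing (cells kept, flagged unusable)", n_unusable)

    return ExpressionAtlas(
        counts=counts,
        cell_ids=cells[cell_id_col].tolist(),
        gene_ids=genes[gene_id_col].tolist(),
        cell_type=cell_type,
        embryo_time=time.to_numpy(dtype=float),
        lineage=lineage,
    )


def binarize_activity(atlas: ExpressionAtlas | sp.spmatrix, min_count: int = 1) -> sp.csr_matrix:
    """Binary activity matrix: 1 iff UMI count >= ``min_count``.

    ``min_count=1`` (presence of any UMI) is the default activity criterion.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = atlas.counts if isinstance(atlas, ExpressionAtlas) else atlas
    out = sp.csr_matrix(counts, copy=True)
    out.data = (out.data >= min_count).astype(np.int8)
    out.eliminate_zeros()
    return out


def assign_coordinates(atlas: ExpressionAtlas, stage_edges: Sequence[float]) -> CoordinateAssignment:
    """Map each annotated cell to (cell type, half-open time bin [e_j, e_{j+1})).

    Times below the first edge or at/above the last edge are clamped to the
    first/last bin with a logged warning count.  Cells missing either
    annotation get the null coordinate (stage -1).
    """
    edges = np.asarray(stage_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("stage_edges must be a strictly increasing list of at least two values")
    n_bins = len(edges) - 1
    stage = np.full(atlas.n_cells, -1, dtype=int)
    usable = atlas.annotated
    t = atlas.embryo_time[usable]
    idx = np.searchsorted(edges, t, side="right") - 1
    n_below = int((idx < 0).sum())
    n_above = int((idx >= n_bins).sum())
    idx = np.clip(idx, 0, n_bins - 1)
    stage[usable] = idx
    if n_below or n_above:
        logger.warning(
            "assign_coordinates: %d cells below first edge, %d at/above last edge (clamped)",
            n_below,
            n_above,
        )
    cell_type = atlas.cell_type.copy()
    cell_type[~usable] = None
    return CoordinateAssignment(
        cell_type=cell_type, stage=stage, stage_edges=edges, n_below=n_below, n_above=n_above
    )


def uniform_stage_edges(atlas: ExpressionAtlas, n_bins: int = 12) -> np.ndarray:
    """Uniform embryo-time grid over the observed time range (default 12 bins)."""
    t = atlas.embryo_time[np.isfinite(atlas.embryo_time)]
    if t.size == 0:
        raise ValueError("no finite embryo times in atlas")
    lo, hi = float(t.min()), float(t.max())
    if hi <= lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)  # keep the max inside the last bin
    return edges


def build_developmental_matrix(
    active: sp.spmatrix,
    coords: CoordinateAssignment,
    min_cells: int = 1,
    gene_ids: Sequence | None = None,
) -> DevelopmentalMatrix:
    """Per-gene activity fractions at each surviving developmental coordinate.

    value[g, c] = (# cells at c active for g) / (# cells at c).  Coordinates
    with fewer than ``min_cells`` cells are dropped.  Column order is
    deterministic: cell type lexicographic, then stage order.
    """
    active = sp.csr_matrix(active)
    if active.shape[0] != len(coords.stage):
        raise ValueError("coordinate assignment is not aligned with the activity matrix rows")
    valid = coords.valid
    keys = pd.DataFrame(
        {"cell_type": coords.cell_type[valid].astype(str), "stage": coords.stage[valid]},
        index=np.flatnonzero(valid),
    )
    if keys.empty:
        raise ValueError("no cells with a usable (cell type, stage) coordinate")
    groups = keys.groupby(["cell_type", "stage"], sort=True).indices
    coord_list, rows, sizes = [], [], []
    for key in sorted(groups):
        members = keys.index.values[groups[key]]
        if len(members) < min_cells:
            continue
        coord_list.append((key[0], int(key[1])))
        rows.append(members)
        sizes.append(len(members))
    if not coord_list:
        raise ValueError(
            f"no developmental coordinate has at least min_cells={min_cells} cells"
        )
    # indicator (coords x cells) scaled by 1/n_c, so P @ active gives fractions
    n_coords = len(coord_list)
    indptr = np.zeros(n_coords + 1, dtype=int)
    indices = np.concatenate(rows)
    data = np.concatenate([np.full(len(r), 1.0 / len(r)) for r in rows])
    indptr[1:] = np.cumsum(sizes)
    pooling = sp.csr_matrix((data, indices, indptr), shape=(n_coords, active.shape[0]))
    values = np.asarray((pooling @ active).todense()).T  # genes x coords
    values = np.clip(values, 0.0, 1.0)
    if gene_ids is None:
        gene_ids = list(range(active.shape[1]))
    return DevelopmentalMatrix(
        values=values,
        gene_ids=list(gene_ids),
        coordinates=coord_list,
        n_cells_per_coordinate=np.array(sizes, dtype=int),
        stage_edges=coords.stage_edges,
    )


def stage_profile(dev: DevelopmentalMatrix, activity_threshold: float = 0.0) -> pd.DataFrame:
    """Fraction of observed cell types expressing each gene at each stage.

    For gene g and stage s: (# cell types with dev value > activity_threshold
    at (type, s)) / (# cell types observed at s).  The default threshold 0
    counts a cell type as expressing when any of its sampled cells is active;
    a higher threshold demands that fraction of the coordinate's cells, which
    suppresses sporadic background activity.  A stage with zero observed cell
    types would yield a missing column (cannot arise from
    build_developmental_matrix).
    """
    if not dev.coordinates:
        raise ValueError("developmental matrix has no coordinates")
    stages = dev.stages
    out = np.full((len(dev.gene_ids), len(stages)), np.nan)
    for j, s in enumerate(stages):
        cols = [i for i, (_, st) in enumerate(dev.coordinates) if st == s]
        if not cols:
            continue
        out[:, j] = (dev.values[:, cols] > activity_threshold).sum(axis=1) / len(cols)
    return pd.DataFrame(out, index=dev.gene_ids, columns=stages)
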