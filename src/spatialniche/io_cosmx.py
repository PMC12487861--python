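"""Reading and writing CosMx-style flat files and tabular pipeline outputs.

The flat-file dialect is the vendor export of a spatial molecular imager
run: a set of gzip-compressed CSV files sharing ``fov`` / ``cell_ID`` key
columns. The mandatory trio is the expression matrix (cells as rows, genes
as columns), the per-FOV global tile origins, and the per-cell metadata
(local centroid coordinates plus optional cell-type annotation). Polygon
and transcript-location files are parsed when present but carried as opaque
extras; nothing downstream consumes them.

Coordinate convention: a cell's global position is ``FOV origin + local
centroid``, multiplied by ``coordinate_scale`` (micrometres per raw unit).
Axes are Cartesian with y increasing upward. The default scale of 1.0 means
"the export is already in micrometres"; distance thresholds downstream
(e.g. the 20 um Near/Far cut) are only meaningful once coordinates are in
micrometres, so set the scale explicitly if the export is in pixels.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyMatrixError, MissingFileError, OrphanCellsError

EXPR_FILE = "exprMat_file.csv.gz"
FOV_FILE = "fov_positions_file.csv.gz"
META_FILE = "metadata_file.csv.gz"
POLYGON_FILE = "polygons.csv.gz"
TX_FILE = "tx_file.csv.gz"

MANDATORY_FILES = (EXPR_FILE, FOV_FILE, META_FILE)
OPTIONAL_FILES = (POLYGON_FILE, TX_FILE)

#: columns of the canonical per-cell table
CELL_COLUMNS = ("cell_id", "fov", "x", "y", "label")


@dataclass
class SpatialDataset:
    """In-memory container for one multi-FOV spatial run.

    Attributes
    ----------
    cells:
        One row per cell with columns ``cell_id`` (unique string), ``fov``,
        ``x``/``y`` (global micrometres) and ``label`` (cell-type name or NA).
    counts:
        Raw transcript counts, genes x cells, column order matching ``cells``.
    gene_names:
        Ordered feature names (biological genes and control probes alike).
    fov_offsets:
        Global tile origin per FOV in micrometres, indexed by FOV identifier.
    extras:
        Opaque side tables (polygons, transcript locations) keyed by name.
    """

    cells: pd.DataFrame
    counts: np.ndarray
    gene_names: list[str]
    fov_offsets: pd.DataFrame
    extras: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated container invariant."""
        if list(self.cells.columns) != list(CELL_COLUMNS):
            raise ValueError(f"cells columns must be {CELL_COLUMNS}")
        if self.cells["cell_id"].duplicated().any():
            dupes = self.cells.loc[self.cells["cell_id"].duplicated(), "cell_id"]
            raise ValueError(f"duplicate cell ids: {sorted(set(dupes))[:5]}")
        if self.counts.shape != (self.n_genes, self.n_cells):
            raise ValueError(
                f"counts shape {self.counts.shape} != (genes={self.n_genes}, cells={self.n_cells})"
            )
        if len(self.gene_names) != len(set(self.gene_names)):
            raise ValueError("gene names must be unique")
        if self.counts.size and (
            (self.counts < 0).any() or not np.issubdtype(self.counts.dtype, np.integer)
        ):
            raise ValueError("counts must be non-negative integers")
        xy = self.cells[["x", "y"]].to_numpy(dtype=float)
        if xy.size and not np.isfinite(xy).all():
            raise ValueError("cell coordinates must be finite")
        missing_fovs = set(self.cells["fov"]) - set(self.fov_offsets.index)
        if missing_fovs:
            raise ValueError(f"FOVs without offsets: {sorted(missing_fovs)}")

    def counts_frame(self) -> pd.DataFrame:
        """Counts as a genes x cells DataFrame labelled with ids."""
        return pd.DataFrame(
            self.counts, index=list(self.gene_names), columns=list(self.cells["cell_id"])
        )

    def labels(self) -> pd.Series:
        """Per-cell label Series indexed by cell id (NA where unannotated)."""
        return self.cells.set_index("cell_id")["label"]

    def subset_cells(self, keep_mask: np.ndarray) -> "SpatialDataset":
        keep_mask = np.asarray(keep_mask, dtype=bool)
        return SpatialDataset(
            cells=self.cells.loc[keep_mask].reset_index(drop=True),
            counts=self.counts[:, keep_mask],
            gene_names=list(self.gene_names),
            fov_offsets=self.fov_offsets.copy(),
            extras=dict(self.extras),
        )

    def subset_genes(self, keep_mask: np.ndarray) -> "SpatialDataset":
        keep_mask = np.asarray(keep_mask, dtype=bool)
        kept = [g for g, k in zip(self.gene_names, keep_mask) if k]
        return SpatialDataset(
            cells=self.cells.copy(),
            counts=self.counts[keep_mask, :],
            gene_names=kept,
            fov_offsets=self.fov_offsets.copy(),
            extras=dict(self.extras),
        )

    def equals(self, other: "SpatialDataset") -> bool:
        """Exact equality of cells, counts, gene order and FOV offsets."""
        if self.gene_names != other.gene_names:
            return False
        if not np.array_equal(self.counts, other.counts):
            return False
        try:
            pd.testing.assert_frame_equal(self.cells, other.cells)
            pd.testing.assert_frame_equal(
                self.fov_offsets.sort_index(), other.fov_offsets.sort_index()
            )
        except AssertionError:
            return False
        return True


def _read_gz_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, compression="gzip")


def _write_gz_csv(df: pd.DataFrame, path: Path) -> None:
    # mtime=0 keeps repeated writes byte-identical for determinism checks
    text = df.to_csv(index=False)
    with open(path, "wb") as fh:
        with gzip.GzipFile(fileobj=fh, mode="wb", filename="", mtime=0) as gz:
            gz.write(text.encode("utf-8"))


def _find_column(df: pd.DataFrame, *candidates: str) -> str:
    lower = {c.lower(): c for c in df.columns}
    for cand in candidates:
        if cand.lower() in lower:
            return lower[cand.lower()]
    raise ValueError(f"none of the expected columns {candidates} found in {list(df.columns)}")


def read_flat_files(directory, coordinate_scale: float = 1.0) -> SpatialDataset:
    """Read a flat-file directory into a :class:`SpatialDataset`.

    Parameters
    ----------
    directory:
        Folder holding the vendor-named gzip CSV files.
    coordinate_scale:
        Micrometres per raw coordinate unit; global position is
        ``(origin + local) * coordinate_scale``.

    Raises
    ------
    MissingFileError
        If a mandatory file is absent.
    OrphanCellsError
        If the metadata and expression matrix disagree on the cell set.
    """
    directory = Path(directory)
    for fname in MANDATORY_FILES:
        if not (directory / fname).exists():
            raise MissingFileError(fname, str(directory))

    expr = _read_gz_csv(directory / EXPR_FILE)
    fov_positions = _read_gz_csv(directory / FOV_FILE)
    meta = _read_gz_csv(directory / META_FILE)

    expr_fov = _find_column(expr, "fov")
    expr_cell = _find_column(expr, "cell_ID", "cell_id", "cell")
    gene_cols = [c for c in expr.columns if c not in (expr_fov, expr_cell)]
    if not gene_cols or expr.empty:
        raise EmptyMatrixError(f"expression matrix in {directory} has no genes or no cells")

    meta_fov = _find_column(meta, "fov")
    meta_cell = _find_column(meta, "cell_ID", "cell_id", "cell")
    meta_x = _find_column(meta, "CenterX_local_px", "x_local_px", "x_local", "x")
    meta_y = _find_column(meta, "CenterY_local_px", "y_local_px", "y_local", "y")
    label_col = None
    for cand in ("cell_type", "cellType", "label"):
        if cand in meta.columns:
            label_col = cand
            break

    pos_fov = _find_column(fov_positions, "fov")
    pos_x = _find_column(fov_positions, "x_global_px", "x_global", "x")
    pos_y = _find_column(fov_positions, "y_global_px", "y_global", "y")
    offsets_raw = (
        fov_positions.set_index(pos_fov)[[pos_x, pos_y]]
        .rename(columns={pos_x: "x", pos_y: "y"})
        .astype(float)
    )
    offsets_raw.index.name = "fov"
    offsets = offsets_raw * coordinate_scale

    def global_id(frame, fov_col, cell_col):
        return frame[fov_col].astype(str) + "_" + frame[cell_col].astype(str)

    meta_ids = global_id(meta, meta_fov, meta_cell)
    expr_ids = global_id(expr, expr_fov, expr_cell)
    meta_only = set(meta_ids) - set(expr_ids)
    if meta_only:
        raise OrphanCellsError(meta_only, "in metadata but absent from expression matrix")
    expr_only = set(expr_ids) - set(meta_ids)
    if expr_only:
        raise OrphanCellsError(expr_only, "in expression matrix but absent from metadata")

    # metadata row order is canonical; align expression columns to it
    expr_by_id = expr.set_index(expr_ids)
    counts = expr_by_id.loc[meta_ids, gene_cols].to_numpy()
    counts = np.rint(counts).astype(np.int64)

    fov_of_cell = meta[meta_fov]
    origin = offsets_raw.loc[fov_of_cell].to_numpy(dtype=float)
    local = meta[[meta_x, meta_y]].to_numpy(dtype=float)
    global_xy = (origin + local) * coordinate_scale

    cells = pd.DataFrame(
        {
            "cell_id": meta_ids.to_numpy(),
            "fov": fov_of_cell.to_numpy(),
            "x": global_xy[:, 0],
            "y": global_xy[:, 1],
            "label": meta[label_col] if label_col else pd.Series([pd.NA] * len(meta)),
        }
    )
    cells["label"] = cells["label"].astype("object")
    cells.loc[cells["label"].isna(), "label"] = pd.NA

    extras = {}
    for fname in OPTIONAL_FILES:
        if (directory / fname).exists():
            extras[fname.split(".", 1)[0]] = _read_gz_csv(directory / fname)

    ds = SpatialDataset(
        cells=cells,
        counts=counts.T,
        gene_names=list(gene_cols),
        fov_offsets=offsets,
        extras=extras,
    )
    ds.validate()
    return ds


def write_flat_files(dataset: SpatialDataset, directory, coordinate_scale: float = 1.0) -> None:
    """Export a dataset as the vendor flat-file trio (plus any extras).

    Local centroids are recovered as ``global / scale - origin``; with the
    default scale of 1.0 a write/read cycle reproduces the dataset exactly.
    Output is byte-deterministic (gzip mtime pinned to zero).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dataset.validate()

    offsets_raw = dataset.fov_offsets / coordinate_scale
    fov_tbl = offsets_raw.reset_index().rename(columns={"x": "x_global_px", "y": "y_global_px"})
    _write_gz_csv(fov_tbl, directory / FOV_FILE)

    fov_of_cell = dataset.cells["fov"]
    origin = offsets_raw.loc[fov_of_cell].to_numpy(dtype=float)
    local = dataset.cells[["x", "y"]].to_numpy(dtype=float) / coordinate_scale - origin
    # cell_ID must be unique within its FOV; strip the "<fov>_" prefix we add on read
    cell_ID = [
        cid[len(str(fov)) + 1 :] if cid.startswith(f"{fov}_") else cid
        for cid, fov in zip(dataset.cells["cell_id"], fov_of_cell)
    ]
    meta = pd.DataFrame(
        {
            "fov": fov_of_cell.to_numpy(),
            "cell_ID": cell_ID,
            "CenterX_local_px": local[:, 0],
            "CenterY_local_px": local[:, 1],
            "cell_type": dataset.cells["label"].to_numpy(),
        }
    )
    _write_gz_csv(meta, directory / META_FILE)

    expr = pd.DataFrame(dataset.counts.T, columns=list(dataset.gene_names))
    expr.insert(0, "cell_ID", cell_ID)
    expr.insert(0, "fov", fov_of_cell.to_numpy())
    _write_gz_csv(expr, directory / EXPR_FILE)

    for name, table in dataset.extras.items():
        _write_gz_csv(table, directory / f"{name}.csv.gz")


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a labelled 2-D table as CSV (row labels in the first column)."""
    if matrix.index.duplicated().any() or matrix.columns.duplicated().any():
        raise ValueError("matrix row and column labels must be unique")
    matrix.to_csv(path, index=True)


def read_matrix(path) -> pd.DataFrame:
    """Read back a matrix written by :func:`write_matrix`."""
    return pd.read_csv(path, index_col=0)
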