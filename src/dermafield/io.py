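"""Data model and on-disk formats for seqFISH-style spatial sections.

A section is a *cell table* — one row per segmented cell with centroid
coordinates in pixels, sample/section labels, an optional cell-type
annotation and a surface flag — aligned row-for-row with a cells x genes
matrix of nonnegative integer transcript counts.

Conventions
-----------
* Pixels are the only internal unit. The coordinate origin is the top-left
  corner of the section image and ``y_px`` increases downward, i.e. from
  the keratinized outer surface into the dermis, so ``y_px`` doubles as a
  depth proxy. The instrument does not document an axis convention; this
  one is an explicit package choice and all depth-dependent results
  inherit it.
* Micron conversion happens only at reporting time through a
  :class:`PixelScale` (default 0.1 um/px, from the instrument's segmentation
  expansion of 15 px ~ 1.5 um; the alternative 0.103 um/px implied by
  400 px ~ 41.2 um is available as :data:`PIXEL_SCALE_41UM`).
* On disk: cell tables are UTF-8 TSV with a header; count matrices are
  Matrix Market coordinate files with plain-text row (cell id) and column
  (gene symbol) name files; run parameters are JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "PixelScale",
    "PIXEL_SCALE_DEFAULT",
    "PIXEL_SCALE_41UM",
    "SpatialDataset",
    "read_cell_table",
    "read_count_matrix",
    "write_dataset",
    "read_dataset",
    "px_to_um",
]

REQUIRED_COLUMNS = ("cell_id", "x_px", "y_px")

#: Optional cell-table columns and the default used when a file omits them.
OPTIONAL_DEFAULTS: Mapping[str, object] = {
    "sample_id": "sample1",
    "section_id": "section1",
    "cell_type": "unlabeled",
    "surface_flag": False,
}


@dataclass(frozen=True)
class PixelScale:
    """Linear scale of the section image, microns per pixel."""

    um_per_px: float = 0.1

    def __post_init__(self) -> None:
        if not np.isfinite(self.um_per_px) or self.um_per_px <= 0:
            raise ValueError(f"um_per_px must be positive, got {self.um_per_px}")


PIXEL_SCALE_DEFAULT = PixelScale(0.1)
#: Scale implied by a 400 px neighborhood radius spanning 41.2 um.
PIXEL_SCALE_41UM = PixelScale(0.103)


def px_to_um(d_px: float | np.ndarray, scale: PixelScale = PIXEL_SCALE_DEFAULT):
    """Convert a nonnegative pixel distance to microns."""
    arr = np.asarray(d_px, dtype=float)
    if np.any(arr < 0):
        raise ValueError("distances must be nonnegative")
    out = arr * scale.um_per_px
    return float(out) if np.isscalar(d_px) or out.ndim == 0 else out


def _validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    cells = cells.copy()
    for col in REQUIRED_COLUMNS:
        if col not in cells.columns:
            raise ValueError(f"cell table is missing required column {col!r}")
    cells["cell_id"] = cells["cell_id"].astype(str)
    for col in ("x_px", "y_px"):
        coerced = pd.to_numeric(cells[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(coerced.to_numpy(dtype=float)))
        if bad.size:
            raise ValueError(
                f"non-numeric or non-finite {col} at row index "
                f"{[int(i) for i in bad[:5]]}"
            )
        cells[col] = coerced.astype(float)
    for col, default in OPTIONAL_DEFAULTS.items():
        if col not in cells.columns:
            cells[col] = default
    cells["surface_flag"] = cells["surface_flag"].astype(bool)
    cells["cell_type"] = cells["cell_type"].astype(str)
    # uniqueness within each section
    for section, grp in cells.groupby("section_id", sort=False):
        dup = grp["cell_id"][grp["cell_id"].duplicated()].unique()
        if dup.size:
            raise ValueError(
                f"duplicate cell_id in section {section!r}: {sorted(dup)[:5]}"
            )
    return cells.reset_index(drop=True)


@dataclass
class SpatialDataset:
    """One or more seqFISH sections: cell table plus aligned count matrix.

    ``counts`` rows align 1:1 with ``cells`` rows; ``genes`` names the
    columns. ``total_transcripts`` in the cell table is kept consistent
    with the matrix row sums (recomputed on construction when a matrix is
    present).
    """

    cells: pd.DataFrame
    counts: sp.csr_matrix | None = None
    genes: list[str] | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cells = _validate_cell_table(self.cells)
        if self.counts is not None:
            self.counts = sp.csr_matrix(self.counts)
            if self.genes is None:
                raise ValueError("genes must accompany a count matrix")
            self.genes = [str(g) for g in self.genes]
            if len(set(self.genes)) != len(self.genes):
                raise ValueError("gene names must be unique")
            if self.counts.shape != (len(self.cells), len(self.genes)):
                raise ValueError(
                    f"count matrix shape {self.counts.shape} does not match "
                    f"{len(self.cells)} cells x {len(self.genes)} genes"
                )
            if self.counts.nnz and self.counts.data.min() < 0:
                raise ValueError("count matrix has negative entries")
            if not np.issubdtype(self.counts.dtype, np.integer):
                data = self.counts.data
                if not np.allclose(data, np.round(data)):
                    raise ValueError("count matrix entries must be integers")
                self.counts = self.counts.astype(np.int64)
            self.cells["total_transcripts"] = np.asarray(
                self.counts.sum(axis=1)
            ).ravel()
        elif "total_transcripts" not in self.cells.columns:
            self.cells["total_transcripts"] = 0
        self.cells["total_transcripts"] = self.cells["total_transcripts"].astype(
            np.int64
        )

    # -- convenience -----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of x/y centroids in pixels."""
        return self.cells[["x_px", "y_px"]].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray | pd.Series) -> "SpatialDataset":
        """Row-subset cells and counts together (boolean or index mask)."""
        mask = np.asarray(mask)
        cells = self.cells.loc[mask].reset_index(drop=True) if mask.dtype == bool else self.cells.iloc[mask].reset_index(drop=True)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        counts = self.counts[idx] if self.counts is not None else None
        return SpatialDataset(cells, counts, list(self.genes) if self.genes else None, dict(self.params))

    def cells_of_type(self, cell_type: str | Iterable[str]) -> pd.DataFrame:
        types = {cell_type} if isinstance(cell_type, str) else set(cell_type)
        return self.cells[self.cells["cell_type"].isin(types)]

    def equals(self, other: "SpatialDataset") -> bool:
        if not self.cells.reset_index(drop=True).equals(other.cells.reset_index(drop=True)):
            return False
        if (self.counts is None) != (other.counts is None):
            return False
        if self.counts is not None:
            if self.genes != other.genes:
                return False
            if (self.counts != other.counts).nnz != 0:
                return False
        return True


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_cell_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read and validate a delimited cell table.

    Requires a header naming at least ``cell_id``, ``x_px`` and ``y_px``;
    unknown columns are preserved, missing optional columns are filled with
    their declared defaults. Duplicate ids or non-numeric coordinates are
    hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cells = pd.read_csv(
        path, sep=sep, dtype={"cell_id": str}, float_precision="round_trip"
    )
    return _validate_cell_table(cells)


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    return path.with_suffix(".rows.txt"), path.with_suffix(".cols.txt")


def read_count_matrix(
    path: str | Path,
    format: str = "mtx",
    cell_ids: list[str] | None = None,
) -> tuple[sp.csr_matrix, list[str], list[str]]:
    """Read a count matrix as ``(matrix, cell_ids, genes)``.

    ``mtx`` expects a Matrix Market coordinate file with companion
    ``<stem>.rows.txt`` (cell ids) and ``<stem>.cols.txt`` (gene symbols)
    files; ``dense`` expects a TSV with gene header and cell ids in the
    first column. When ``cell_ids`` is given, the file's row ordering must
    match it exactly.
    """
    path = Path(path)
    if format == "mtx":
        mat = sp.csr_matrix(mmread(path))
        rows_path, cols_path = _sidecar_paths(path)
        ids = rows_path.read_text().splitlines()
        genes = cols_path.read_text().splitlines()
    elif format == "dense":
        df = pd.read_csv(path, sep="\t", index_col=0)
        mat = sp.csr_matrix(df.to_numpy())
        ids = [str(i) for i in df.index]
        genes = [str(c) for c in df.columns]
    else:
        raise ValueError(f"unknown count-matrix format {format!r}")
    if mat.nnz and mat.data.min() < 0:
        raise ValueError("count matrix has negative entries")
    mat = mat.astype(np.int64)
    if cell_ids is not None and list(cell_ids) != list(ids):
        offenders = [i for i in ids if i not in set(cell_ids)][:5]
        missing = [i for i in cell_ids if i not in set(ids)][:5]
        raise ValueError(
            "count-matrix cell ids do not match the cell table; first "
            f"unexpected: {offenders}, first missing: {missing}"
        )
    return mat, list(ids), list(genes)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_dataset(dataset: SpatialDataset, out_dir: str | Path) -> dict:
    """Write a dataset to ``out_dir`` and return a checksum manifest.

    Emits ``cells.tsv``, a Matrix Market ``counts.mtx`` with
    ``counts.rows.txt`` / ``counts.cols.txt`` sidecars, and — when the
    dataset carries run parameters — ``params.json``. The manifest (also
    saved as ``manifest.json``) lists every written file with its SHA-256
    checksum; identical datasets produce identical checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    cells_path = out / "cells.tsv"
    # %.17g round-trips IEEE doubles exactly
    dataset.cells.to_csv(cells_path, sep="\t", index=False, float_format="%.17g")
    written.append(cells_path)

    mtx_path = out / "counts.mtx"
    counts = dataset.counts if dataset.counts is not None else sp.csr_matrix(
        (dataset.n_cells, 0), dtype=np.int64
    )
    mmwrite(mtx_path, sp.coo_matrix(counts), field="integer")
    written.append(mtx_path)
    rows_path, cols_path = _sidecar_paths(mtx_path)
    rows_path.write_text("\n".join(dataset.cells["cell_id"]) + ("\n" if dataset.n_cells else ""))
    cols_path.write_text("\n".join(dataset.genes or []) + ("\n" if dataset.genes else ""))
    written.extend([rows_path, cols_path])

    if dataset.params:
        params_path = out / "params.json"
        params_path.write_text(json.dumps(dataset.params, indent=2, sort_keys=True))
        written.append(params_path)

    manifest = {p.name: _sha256(p) for p in written}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def read_dataset(in_dir: str | Path) -> SpatialDataset:
    """Inverse of :func:`write_dataset`."""
    in_dir = Path(in_dir)
    cells = read_cell_table(in_dir / "cells.tsv")
    mtx_path = in_dir / "counts.mtx"
    counts = None
    genes: list[str] | None = None
    if mtx_path.exists():
        counts, ids, genes = read_count_matrix(mtx_path, "mtx", list(cells["cell_id"]))
        if counts.shape[1] == 0:
            counts, genes = None, None
    params_path = in_dir / "params.json"
    params = json.loads(params_path.read_text()) if params_path.exists() else {}
    return SpatialDataset(cells, counts, genes, params)
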