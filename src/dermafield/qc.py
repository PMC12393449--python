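"""Quality filtering and expression normalization.

Filtering keeps cells with at least 50 detected transcripts; cells flagged
as belonging to the keratinized outer surface — where transcription drops
with keratinocyte differentiation — pass at a lenient minimum of 10.
Both thresholds are inclusive minima.

Normalization is the standard log1p of counts rescaled to a fixed per-cell
total (10,000 by default), so each cell's profile is invariant to its
library size and zero counts map exactly to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import theilslopes
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import SpatialDataset

__all__ = [
    "QCReport",
    "qc_filter",
    "log_normalize",
    "select_variable_genes",
    "row_scale_joint",
]


@dataclass
class QCReport:
    n_input: int
    n_kept: int
    n_removed_low_count: int
    n_removed_surface_low: int
    min_transcripts: int
    surface_min: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def qc_filter(
    dataset: SpatialDataset,
    min_transcripts: int = 50,
    surface_min: int = 10,
) -> tuple[SpatialDataset, QCReport]:
    """Drop low-count cells; surface-flagged cells use the lenient minimum.

    A cell is retained when ``total_transcripts >= min_transcripts``, or
    ``>= surface_min`` if its ``surface_flag`` is set. Idempotent.
    """
    if surface_min > min_transcripts:
        raise ValueError(
            f"surface_min ({surface_min}) must not exceed min_transcripts "
            f"({min_transcripts}): the surface threshold is the lenient one"
        )
    total = dataset.cells["total_transcripts"].to_numpy()
    surface = dataset.cells["surface_flag"].to_numpy(dtype=bool)
    keep = np.where(surface, total >= surface_min, total >= min_transcripts)
    report = QCReport(
        n_input=dataset.n_cells,
        n_kept=int(keep.sum()),
        n_removed_low_count=int((~keep & ~surface).sum()),
        n_removed_surface_low=int((~keep & surface).sum()),
        min_transcripts=min_transcripts,
        surface_min=surface_min,
    )
    return dataset.subset(keep), report


def log_normalize(
    counts: SpatialDataset | sp.spmatrix | np.ndarray,
    genes: list[str] | None = None,
    cell_ids: list[str] | None = None,
    scale_total: float = 1e4,
) -> pd.DataFrame:
    """log1p(count * scale_total / cell_total) as a cells x genes DataFrame.

    Accepts a :class:`SpatialDataset` (ids and gene names taken from it) or
    a bare matrix. Cells with zero total are an error — they should have
    been removed by :func:`qc_filter`.
    """
    if isinstance(counts, SpatialDataset):
        if counts.counts is None:
            raise ValueError("dataset has no count matrix")
        genes = counts.genes
        cell_ids = list(counts.cells["cell_id"])
        counts = counts.counts
    mat = np.asarray(
        counts.todense() if sp.issparse(counts) else counts, dtype=float
    )
    totals = mat.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [cell_ids[i] for i in zero[:5]] if cell_ids else list(zero[:5])
        raise ValueError(f"cells with zero total counts: {names}")
    normed = np.log1p(mat * (scale_total / totals[:, None]))
    return pd.DataFrame(
        normed,
        index=pd.Index(cell_ids, name="cell_id") if cell_ids else None,
        columns=genes,
    )


def _trend_residuals(lx: np.ndarray, ly: np.ndarray) -> np.ndarray:
    """Residuals of ly from a leverage-robust lowess trend on lx.

    Local regression follows leverage points: a hypervariable gene whose
    mean sits at the edge of the range pulls the local fit through
    itself and hides from the residual. A Theil-Sen line (median of
    pairwise slopes, immune to a minority of outliers in x or y) serves
    as the first pass; genes far above it are excluded from the lowess
    fit that defines the final trend.
    """
    if len(lx) > 4:
        slope, intercept, *_ = theilslopes(ly, lx)
        res1 = ly - (intercept + slope * lx)
    else:
        res1 = ly - ly.mean()
    med = np.median(res1)
    sigma = 1.4826 * np.median(np.abs(res1 - med))
    keep = res1 - med <= 3.0 * sigma if sigma > 0 else np.ones_like(res1, bool)
    if keep.sum() < max(5, int(0.5 * len(lx))) or np.unique(lx[keep]).size < 2:
        fit = lowess(ly, lx, frac=2.0 / 3.0, return_sorted=False)
        return ly - fit
    curve = lowess(ly[keep], lx[keep], frac=2.0 / 3.0, return_sorted=True)
    xs, first = np.unique(curve[:, 0], return_index=True)
    return ly - np.interp(lx, xs, curve[first, 1])


def select_variable_genes(
    expr: pd.DataFrame | np.ndarray,
    n_top: int,
    genes: list[str] | None = None,
) -> list[str]:
    """Rank genes by variance in excess of the mean-variance trend.

    Fits a lowess of log10(variance) on log10(mean) across expressed
    genes and ranks by the residual (standardized variance), descending;
    ties break lexicographically. The trend is fit twice: genes more than
    3 robust sigmas above the first fit are excluded from the second, so
    a hypervariable gene cannot drag the trend through itself even when
    its mean sits at the edge of the range (a leverage point for local
    regression). Genes with zero variance are never selected while a
    variable gene remains. An approximation of the variance-stabilizing
    selection used by the major single-cell toolkits.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if isinstance(expr, pd.DataFrame):
        genes = list(expr.columns)
        mat = expr.to_numpy(dtype=float)
    else:
        mat = np.asarray(expr, dtype=float)
        if genes is None:
            genes = [f"g{j}" for j in range(mat.shape[1])]
    if n_top > len(genes):
        raise ValueError(f"n_top={n_top} exceeds gene count {len(genes)}")
    mean = mat.mean(axis=0)
    var = mat.var(axis=0)
    residual = np.full(len(genes), -np.inf)
    ok = (mean > 0) & (var > 0)
    if ok.sum() >= 2:
        lx, ly = np.log10(mean[ok]), np.log10(var[ok])
        if np.unique(lx).size >= 2:
            residual[ok] = _trend_residuals(lx, ly)
        else:  # identical means: trend is flat, rank by raw variance
            residual[ok] = ly - ly.mean()
    elif ok.sum() == 1:
        residual[ok] = 0.0
    order = sorted(range(len(genes)), key=lambda j: (-residual[j], genes[j]))
    return [genes[j] for j in order[:n_top]]


def row_scale_joint(blocks: list[pd.DataFrame]) -> list[pd.DataFrame]:
    """Z-score each gene row jointly across the columns of all blocks.

    All blocks must share an identical gene index. Per gene the mean and
    population standard deviation (divide by n) are computed over the
    concatenation of every block's columns; zero-variance rows map to
    all-zeros. Used to color heatmap panels on one shared scale.
    """
    if not blocks:
        return []
    index = blocks[0].index
    for b in blocks[1:]:
        if not b.index.equals(index):
            raise ValueError("blocks must share identical gene rows")
    concat = np.concatenate([b.to_numpy(dtype=float) for b in blocks], axis=1)
    mean = concat.mean(axis=1, keepdims=True)
    sd = concat.std(axis=1, keepdims=True)  # population convention
    safe = np.where(sd > 0, sd, 1.0)
    out = []
    for b in blocks:
        z = (b.to_numpy(dtype=float) - mean) / safe
        z[(sd == 0).ravel(), :] = 0.0
        out.append(pd.DataFrame(z, index=index, columns=b.columns))
    return out
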