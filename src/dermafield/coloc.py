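"""Directional Gaussian-field colocalization between cell types.

Each cell of a *reference* type is modeled as an isotropic Gaussian kernel
centered at its centroid (bandwidth sd = 400 px by default). The
colocalization score of any point is the sum of kernel values over all
reference cells within a truncation radius (3 sd by default):

    score(p) = sum_{r : |p - r| <= R} exp(-|p - r|^2 / (2 sd^2))

The kernel is unnormalized (value 1 at distance 0) because the affine
rescaling below removes any absolute kernel scale; a pdf-normalized mode
is available. Averaging per-cell scores over every cell of a *query* type
gives the type x type colocalization matrix. The metric is directional:
the field of a dense reference type weights a sparse query type very
differently from the reverse.

Per reference column the per-cell scores are affinely rescaled so that the
mean over all cells in the sample is 0 and the aggregate of the reference
type within its own field is 100:

    s' = 100 * (s - mean_all) / (mean_self - mean_all)

Fields can be evaluated exactly (direct summation over a spatial index —
the default, and the oracle) or on a bilinear grid with spacing at most
sd / 4, which matches the exact sum within 1% of the section maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from .io import SpatialDataset

__all__ = [
    "KernelParams",
    "ColocField",
    "ColocMatrix",
    "coloc_score_exact",
    "create_field",
    "evaluate_field",
    "colocalization_matrix",
    "normalize_coloc_matrix",
    "order_matrix_hclust",
]


@dataclass(frozen=True)
class KernelParams:
    """Gaussian kernel: bandwidth, hard truncation radius, normalization."""

    sd: float = 400.0
    truncation_radius: float | None = None  # default 3 * sd
    normalized_pdf: bool = False

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.truncation_radius is not None and self.truncation_radius < self.sd:
            raise ValueError("truncation_radius must be at least sd")

    @property
    def radius(self) -> float:
        return 3.0 * self.sd if self.truncation_radius is None else self.truncation_radius

    @property
    def amplitude(self) -> float:
        return 1.0 / (2.0 * np.pi * self.sd**2) if self.normalized_pdf else 1.0


def coloc_score_exact(
    query_points: np.ndarray,
    reference_cells: np.ndarray,
    params: KernelParams = KernelParams(),
) -> np.ndarray:
    """Brute-force field evaluation: truncated Gaussian sum per query point.

    ``query_points`` is (m, 2) (a single (2,) point is accepted);
    ``reference_cells`` is (n, 2). An empty reference set scores 0
    everywhere. This direct summation is the oracle that grid evaluation
    must match.
    """
    q = np.atleast_2d(np.asarray(query_points, dtype=float))
    ref = np.asarray(reference_cells, dtype=float).reshape(-1, 2)
    scores = np.zeros(len(q))
    if len(ref):
        tree = cKDTree(ref)
        inv2s2 = 1.0 / (2.0 * params.sd**2)
        for i, neighbors in enumerate(tree.query_ball_point(q, params.radius)):
            if neighbors:
                d2 = np.square(ref[neighbors] - q[i]).sum(axis=1)
                scores[i] = np.exp(-d2 * inv2s2).sum()
        scores *= params.amplitude
    if np.asarray(query_points).ndim == 1:
        return scores  # still a length-1 array for API uniformity
    return scores


@dataclass
class ColocField:
    """A reference type's Gaussian density surface, gridded or exact."""

    reference_type: str
    params: KernelParams
    exact: bool = False
    reference_points: np.ndarray | None = None
    origin: tuple[float, float] | None = None  # grid (x0, y0)
    spacing: float | None = None
    values: np.ndarray | None = None  # shape (ny, nx)
    _interp: RegularGridInterpolator | None = field(default=None, repr=False)


def create_field(
    reference_cells: np.ndarray,
    params: KernelParams = KernelParams(),
    grid_spacing: float | None = None,
    bbox: tuple[float, float, float, float] | None = None,
    exact: bool = False,
    reference_type: str = "reference",
) -> ColocField:
    """Build a colocalization field from one reference point set.

    Grid mode (default) evaluates the exact score on a lattice covering
    the bounding box padded by the truncation radius; ``grid_spacing``
    must not exceed ``sd / 4`` (accuracy contract, default ``sd / 4``).
    The internal lattice is built at half the requested spacing: node
    values are still exact scores and evaluation is still bilinear, but
    the finer stencil keeps the interpolation error — including the step
    at the hard truncation radius, worth exp(-4.5) of a kernel — well
    below 1% of the section maximum even for isolated reference cells.
    ``exact=True`` keeps the points and defers to direct summation.
    """
    ref = np.asarray(reference_cells, dtype=float).reshape(-1, 2)
    if exact:
        return ColocField(reference_type, params, exact=True, reference_points=ref)
    if grid_spacing is None:
        grid_spacing = params.sd / 4.0
    if grid_spacing > params.sd / 4.0 + 1e-12:
        raise ValueError(
            f"grid_spacing {grid_spacing} exceeds sd/4 = {params.sd / 4.0}; "
            "coarser grids break the 1% interpolation accuracy contract"
        )
    grid_spacing = grid_spacing / 2.0  # internal refinement (see docstring)
    if bbox is None:
        if len(ref) == 0:
            bbox = (0.0, 0.0, 1.0, 1.0)
        else:
            bbox = (ref[:, 0].min(), ref[:, 1].min(), ref[:, 0].max(), ref[:, 1].max())
    pad = params.radius
    x0, y0 = bbox[0] - pad, bbox[1] - pad
    x1, y1 = bbox[2] + pad, bbox[3] + pad
    xs = np.arange(x0, x1 + grid_spacing, grid_spacing)
    ys = np.arange(y0, y1 + grid_spacing, grid_spacing)
    gx, gy = np.meshgrid(xs, ys)
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    values = coloc_score_exact(nodes, ref, params).reshape(len(ys), len(xs))
    interp = RegularGridInterpolator(
        (ys, xs), values, method="linear", bounds_error=False, fill_value=0.0
    )
    return ColocField(
        reference_type,
        params,
        exact=False,
        reference_points=ref,
        origin=(float(x0), float(y0)),
        spacing=float(grid_spacing),
        values=values,
        _interp=interp,
    )


def evaluate_field(fld: ColocField, points: np.ndarray) -> np.ndarray:
    """Score points in a field: bilinear interpolation in grid mode,
    direct summation in exact mode; points outside the padded box are 0."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if fld.exact:
        return coloc_score_exact(pts, fld.reference_points, fld.params)
    return fld._interp(pts[:, ::-1])  # interpolator is (y, x)-ordered


# ---------------------------------------------------------------------------
# type x type matrices
# ---------------------------------------------------------------------------

@dataclass
class ColocMatrix:
    """Raw and normalized colocalization scores, per sample and pooled.

    ``per_cell_raw[sample]`` holds per-cell raw scores (cells x reference
    types); ``raw`` is the query x reference aggregate averaged across
    samples. After :func:`normalize_coloc_matrix`, ``normalized`` carries
    the mean-0 / self-100 twin and ``constants`` the per-(sample,
    reference) affine constants.
    """

    params: KernelParams
    samples: list[str]
    per_cell_raw: dict[str, pd.DataFrame]
    cell_types: dict[str, pd.Series]
    raw_per_sample: dict[str, pd.DataFrame]
    raw: pd.DataFrame
    per_cell_norm: dict[str, pd.DataFrame] | None = None
    normalized_per_sample: dict[str, pd.DataFrame] | None = None
    normalized: pd.DataFrame | None = None
    constants: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    degenerate: list[tuple[str, str]] = field(default_factory=list)


def _aggregate(per_cell: pd.DataFrame, types: pd.Series) -> pd.DataFrame:
    agg = per_cell.groupby(types, sort=True).mean()
    agg.index.name = "query_type"
    agg.columns.name = "reference_type"
    return agg


def colocalization_matrix(
    dataset: SpatialDataset,
    params: KernelParams = KernelParams(),
    mode: str = "auto",
    grid_spacing: float | None = None,
    exact_max_cells: int = 50_000,
    reference_types: list[str] | None = None,
) -> ColocMatrix:
    """Score every cell in every reference type's field, per sample.

    For each sample and each reference type R present there, a field is
    built from the R cells and evaluated at every cell of the sample; the
    aggregate entry (Q, R) is the mean score over cells of type Q. ``mode``
    is ``"exact"``, ``"grid"`` or ``"auto"`` (exact below
    ``exact_max_cells`` cells per section). Types with no cells in a
    sample are dropped from its columns with a warning.
    ``reference_types`` restricts the columns (fields built); every cell
    is still scored as a query.
    """
    if "cell_type" not in dataset.cells.columns:
        raise ValueError("dataset cells must carry cell_type labels")
    all_types = sorted(
        dataset.cells["cell_type"].unique()
        if reference_types is None
        else reference_types
    )
    per_cell_raw: dict[str, pd.DataFrame] = {}
    cell_types: dict[str, pd.Series] = {}
    raw_per_sample: dict[str, pd.DataFrame] = {}
    samples = sorted(dataset.cells["sample_id"].unique())
    for sample in samples:
        sub = dataset.cells[dataset.cells["sample_id"] == sample]
        pts = sub[["x_px", "y_px"]].to_numpy(dtype=float)
        types = pd.Series(sub["cell_type"].to_numpy(), index=sub["cell_id"].to_numpy())
        use_exact = mode == "exact" or (mode == "auto" and len(sub) < exact_max_cells)
        if mode not in ("exact", "grid", "auto"):
            raise ValueError(f"unknown mode {mode!r}")
        missing = [t for t in all_types if (types == t).sum() == 0]
        if missing:
            warnings.warn(
                f"sample {sample!r}: no cells of type(s) {missing}; columns dropped"
            )
        cols = {}
        bbox = (
            pts[:, 0].min(), pts[:, 1].min(), pts[:, 0].max(), pts[:, 1].max()
        ) if len(sub) else None
        for ref_type in all_types:
            ref_pts = pts[(types == ref_type).to_numpy()]
            if len(ref_pts) == 0:
                continue
            if use_exact:
                cols[ref_type] = coloc_score_exact(pts, ref_pts, params)
            else:
                fld = create_field(ref_pts, params, grid_spacing, bbox=bbox)
                cols[ref_type] = evaluate_field(fld, pts)
        per_cell = pd.DataFrame(cols, index=types.index)
        per_cell.index.name = "cell_id"
        per_cell_raw[sample] = per_cell
        cell_types[sample] = types
        raw_per_sample[sample] = _aggregate(per_cell, types)
    raw = (
        pd.concat(raw_per_sample.values()).groupby(level=0, sort=True).mean()
        if raw_per_sample
        else pd.DataFrame()
    )
    return ColocMatrix(
        params=params,
        samples=samples,
        per_cell_raw=per_cell_raw,
        cell_types=cell_types,
        raw_per_sample=raw_per_sample,
        raw=raw,
    )


def normalize_coloc_matrix(matrix: ColocMatrix) -> ColocMatrix:
    """Affine rescaling per (sample, reference type): all-cell mean 0,
    self-aggregate 100.

    ``s' = 100 * (s - mean_all) / (mean_self - mean_all)`` where
    ``mean_all`` is the mean raw score over every cell of the sample
    (reference-type cells included) and ``mean_self`` the mean over cells
    of the reference type scored in their own field. Degenerate columns
    (``mean_self == mean_all``) are flagged and left unnormalized with a
    warning. Samples are normalized independently; the pooled normalized
    aggregate is their across-sample average.
    """
    per_cell_norm: dict[str, pd.DataFrame] = {}
    normalized_per_sample: dict[str, pd.DataFrame] = {}
    constants: dict[str, dict[str, dict[str, float]]] = {}
    degenerate: list[tuple[str, str]] = []
    for sample in matrix.samples:
        per_cell = matrix.per_cell_raw[sample]
        types = matrix.cell_types[sample]
        normed = {}
        constants[sample] = {}
        for ref in per_cell.columns:
            s = per_cell[ref].to_numpy(dtype=float)
            mean_all = s.mean()
            self_mask = (types == ref).to_numpy()
            mean_self = s[self_mask].mean()
            constants[sample][ref] = {
                "mean_all": float(mean_all), "mean_self": float(mean_self)
            }
            if abs(mean_self - mean_all) <= 1e-12 * max(1.0, abs(mean_all)):
                degenerate.append((sample, ref))
                warnings.warn(
                    f"sample {sample!r}, reference {ref!r}: mean_self == "
                    "mean_all; column left unnormalized"
                )
                continue
            normed[ref] = 100.0 * (s - mean_all) / (mean_self - mean_all)
        pcn = pd.DataFrame(normed, index=per_cell.index)
        per_cell_norm[sample] = pcn
        normalized_per_sample[sample] = _aggregate(pcn, types)
    normalized = (
        pd.concat(normalized_per_sample.values()).groupby(level=0, sort=True).mean()
        if normalized_per_sample
        else None
    )
    return replace(
        matrix,
        per_cell_norm=per_cell_norm,
        normalized_per_sample=normalized_per_sample,
        normalized=normalized,
        constants=constants,
        degenerate=degenerate,
    )


def order_matrix_hclust(
    matrix: pd.DataFrame,
) -> dict:
    """Agglomerative ordering of a heatmap matrix (average linkage,
    Euclidean), deterministic with label tie-breaks.

    Returns row/column label orders plus the scipy linkage matrices.
    Single-row or single-column matrices get the trivial ordering.
    """
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing entries")

    def _order(df: pd.DataFrame):
        labels = list(df.index)
        pos = sorted(range(len(labels)), key=lambda i: str(labels[i]))
        labels = [labels[i] for i in pos]
        if len(labels) < 2:
            return labels, None
        lk = linkage(
            df.iloc[pos].to_numpy(dtype=float), method="average", metric="euclidean"
        )
        return [labels[i] for i in leaves_list(lk)], lk

    row_order, row_linkage = _order(matrix)
    col_order, col_linkage = _order(matrix.T)
    return {
        "row_order": row_order,
        "col_order": col_order,
        "row_linkage": row_linkage,
        "col_linkage": col_linkage,
    }
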