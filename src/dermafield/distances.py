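"""Distance-to-structure metrics and depth profiles.

Other cell types serve as landmarks for tissue structures: the minimum
distance from a CD14+ cell to the closest basal keratinocyte stands in
for its distance to the epidermis, and the minimum distance to a CD4/CD8
T cell for its distance to lymphocyte-infiltrated aggregates. Unlike the
colocalization field, landmark density is deliberately not factored in —
only the nearest cell matters. Distances are between centroids, in
pixels, converted to microns at reporting time.

Depth profiles are per-type 1-D Gaussian kernel densities over y (depth),
evaluated on a shared grid, with quartile summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import PixelScale, PIXEL_SCALE_DEFAULT, SpatialDataset
from .spatial_expr import rolling_mean_by_score
from .transition import TransitionOrdering

__all__ = [
    "min_distance_to_type",
    "depth_profile",
    "transition_distance_table",
]


def min_distance_to_type(
    dataset: SpatialDataset,
    focal_type: str,
    target_types: str | set[str],
    scale: PixelScale = PIXEL_SCALE_DEFAULT,
) -> pd.DataFrame:
    """Per focal cell, the Euclidean minimum distance to any cell of the
    target type(s) (union over types), via a k-d tree.

    Returns columns ``cell_id, dist_px, dist_um, depth_px``. Empty focal
    or target sets are errors naming the missing type.
    """
    targets = {target_types} if isinstance(target_types, str) else set(target_types)
    focal = dataset.cells[dataset.cells["cell_type"] == focal_type]
    if focal.empty:
        raise ValueError(f"no cells of focal type {focal_type!r}")
    tcells = dataset.cells[dataset.cells["cell_type"].isin(targets)]
    if tcells.empty:
        raise ValueError(f"no cells of target type(s) {sorted(targets)}")
    tree = cKDTree(tcells[["x_px", "y_px"]].to_numpy(dtype=float))
    d, _ = tree.query(focal[["x_px", "y_px"]].to_numpy(dtype=float), k=1)
    return pd.DataFrame(
        {
            "cell_id": focal["cell_id"].to_numpy(),
            "dist_px": d,
            "dist_um": d * scale.um_per_px,
            "depth_px": focal["y_px"].to_numpy(),
        }
    )


@dataclass
class DepthProfile:
    grid: np.ndarray
    densities: dict[str, np.ndarray]  # type -> density on grid (or None)
    quantiles: pd.DataFrame  # types x (q25, q50, q75)


def depth_profile(
    dataset: SpatialDataset,
    types: set[str] | list[str],
    bandwidth: float = 100.0,
) -> DepthProfile:
    """Smoothed depth (y) densities per cell type on a shared grid.

    Each type's density is the mean of Gaussian bumps of sd ``bandwidth``
    at its cells' depths; it integrates to ~1 on the grid (padded by 5
    bandwidths). Types with fewer than 2 cells report quantiles only.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    types = sorted(types)
    depths = {
        t: dataset.cells.loc[dataset.cells["cell_type"] == t, "y_px"].to_numpy(dtype=float)
        for t in types
    }
    all_y = np.concatenate([d for d in depths.values() if d.size]) if any(
        d.size for d in depths.values()
    ) else np.array([0.0])
    pad = 5.0 * bandwidth
    grid = np.linspace(all_y.min() - pad, all_y.max() + pad, 512)
    densities: dict[str, np.ndarray | None] = {}
    rows = []
    for t in types:
        y = depths[t]
        if y.size >= 2:
            diff = (grid[:, None] - y[None, :]) / bandwidth
            dens = np.exp(-0.5 * diff**2).sum(axis=1)
            dens /= y.size * bandwidth * np.sqrt(2.0 * np.pi)
            densities[t] = dens
        else:
            densities[t] = None
        if y.size:
            q25, q50, q75 = np.quantile(y, [0.25, 0.5, 0.75])
        else:
            q25 = q50 = q75 = np.nan
        rows.append({"cell_type": t, "q25": q25, "q50": q50, "q75": q75})
    return DepthProfile(
        grid=grid,
        densities=densities,
        quantiles=pd.DataFrame(rows).set_index("cell_type"),
    )


def transition_distance_table(
    ordering: TransitionOrdering,
    distances: pd.DataFrame,
    window_prop: float = 0.1,
    score_column: str = "rank_norm",
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Join a transition ordering with a distance table and smooth the
    transition score along each distance axis.

    Inner join on ``cell_id`` (a warning reports any cells lost);
    marginals are centered rolling means of the transition score ordered
    by ``dist_px`` (and by ``depth_px``), the numeric summaries behind
    scatter-plus-marginal distance figures.
    """
    left = ordering.to_frame()
    joined = left.merge(distances, on="cell_id", how="inner")
    lost = max(len(left), len(distances)) - len(joined)
    if lost > 0:
        warnings.warn(f"join dropped {lost} cells absent from one input")
    marginals: dict[str, pd.DataFrame] = {}
    if len(joined):
        for axis in ("dist_px", "depth_px"):
            if axis in joined.columns:
                marginals[axis] = rolling_mean_by_score(
                    joined[score_column].to_numpy(),
                    joined[axis].to_numpy(),
                    window_prop=window_prop,
                )
    return joined, marginals
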