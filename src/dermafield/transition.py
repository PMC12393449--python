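"""Diffusion-map ordering of a cell-state transition.

The CD14+ myeloid continuum from tissue-resident (LYVE1+) to inflammatory
(MMP9+) states is recovered by embedding the labeled subset with PCA on
variable genes, building a k-nearest-neighbor diffusion map (k = 200 by
default), and reading cells' positions along the first nontrivial
diffusion component (DC1).

Diffusion-map construction: a symmetric kNN graph (union of
neighborhoods) carries a Gaussian kernel with per-cell local bandwidths —
``w_ij = exp(-d_ij^2 / (s_i^2 + s_j^2))`` where ``s_i`` is cell i's
distance to its ceil(k/3)-th neighbor — density-normalized with
``alpha = 1`` (kernel divided by the product of vertex degrees) before
forming the Markov operator. DC_i is the i-th nontrivial right
eigenvector scaled by its eigenvalue. The construction is deterministic:
no random initialization, fixed sign conventions.

DC1's sign is arbitrary, so the ordering is *oriented* by anchor genes:
the sign is chosen so the up-anchor (MMP9) is higher in the top DC1
quartile than in the bottom. Cells are then ranked 1..n along oriented
DC1 and can be cut into equal-size contiguous bins for heatmaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "TransitionOrdering",
    "pca_embed",
    "diffusion_map",
    "orient_and_rank",
    "bin_aggregate",
    "order_transition",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_embed(
    expr: pd.DataFrame | np.ndarray, n_components: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centered PCA via SVD: ``(scores, loadings, explained_variance)``.

    Components are ordered by decreasing variance; each component's sign
    is fixed so its largest-magnitude loading is positive.
    """
    X = expr.to_numpy(dtype=float) if isinstance(expr, pd.DataFrame) else np.asarray(expr, dtype=float)
    n, p = X.shape
    max_rank = min(n - 1, p)
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds max rank {max_rank} "
            f"for {n} cells x {p} genes"
        )
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(n_components):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U * S
    explained = (S**2) / (n - 1)
    return scores, Vt.T, explained


# ---------------------------------------------------------------------------
# diffusion map
# ---------------------------------------------------------------------------

def diffusion_map(
    embedding: np.ndarray,
    k: int = 200,
    n_components: int = 2,
    local_bandwidth: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Diffusion components of a point cloud: ``(eigenvalues, DCs)``.

    ``embedding`` is (n, p) component scores. Returns the top
    ``n_components`` nontrivial eigenvalues and an (n, n_components)
    array of diffusion components, each eigenvector scaled by its
    eigenvalue, sign fixed (largest-|entry| positive). ``k`` is capped at
    n - 1 with a warning; a disconnected kNN graph is an error advising a
    larger k.

    The kernel scale derives from the per-cell distance to the
    ceil(k/3)-th neighbor. By default their median is used as one global
    bandwidth — per-cell bandwidths (``local_bandwidth=True``) inflate
    the scale of boundary cells, which visibly kinks DC1 at the ends of
    an ordering (density normalization alone corrects density, not
    scale, at the boundary).
    """
    X = np.asarray(embedding, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 3:
        raise ValueError("diffusion map needs at least 3 cells")
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n - 1:
        warnings.warn(f"k={k} exceeds n-1={n - 1}; capped")
        k = n - 1

    tree = cKDTree(X)
    dist, idx = tree.query(X, k=k + 1)  # self included at column 0
    dist, idx = dist[:, 1:], idx[:, 1:]
    k_local = int(np.ceil(k / 3))
    bandwidth = dist[:, k_local - 1]
    if not local_bandwidth:
        bandwidth = np.full(n, np.median(bandwidth))
    bandwidth = np.where(bandwidth > 0, bandwidth, np.finfo(float).tiny ** 0.25)

    rows = np.repeat(np.arange(n), k)
    cols = idx.ravel()
    d2 = np.square(dist.ravel())
    denom = np.square(bandwidth)[rows] + np.square(bandwidth)[cols]
    w = np.exp(-d2 / denom)
    W = sp.coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    W = W.maximum(W.T)  # union of neighborhoods, symmetric
    W = W + sp.eye(n, format="csr")  # self-affinity 1

    n_comp, _ = connected_components(W, directed=False)
    if n_comp > 1:
        raise ValueError(
            f"kNN graph is disconnected ({n_comp} components); increase k"
        )

    # alpha = 1 density normalization, then symmetric Markov eigenproblem
    q = np.asarray(W.sum(axis=1)).ravel()
    Dq = sp.diags(1.0 / q)
    K = Dq @ W @ Dq
    d = np.asarray(K.sum(axis=1)).ravel()
    Ds = sp.diags(1.0 / np.sqrt(d))
    S = Ds @ K @ Ds

    m = n_components + 1
    if n <= 2000:
        evals, evecs = np.linalg.eigh(S.toarray())
        evals, evecs = evals[::-1][:m], evecs[:, ::-1][:, :m]
    else:
        v0 = np.full(n, 1.0 / np.sqrt(n))
        evals, evecs = sp.linalg.eigsh(S, k=m, which="LA", v0=v0)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]

    # right eigenvectors of the Markov operator; drop the trivial first
    psi = evecs / np.sqrt(d)[:, None]
    psi = psi / np.linalg.norm(psi, axis=0)
    eigenvalues = evals[1:]
    dcs = psi[:, 1:] * eigenvalues[None, :]
    for j in range(dcs.shape[1]):
        i = int(np.argmax(np.abs(dcs[:, j])))
        if dcs[i, j] < 0:
            dcs[:, j] *= -1.0
    return eigenvalues, dcs


# ---------------------------------------------------------------------------
# orientation, ranking, binning
# ---------------------------------------------------------------------------

@dataclass
class TransitionOrdering:
    """An oriented ordering of a cell subset along DC1.

    ``rank`` is a permutation of 1..n along oriented DC1 (rank n = the
    up-anchor end); ``rank_norm`` rescales it to [0, 1]. ``bins(m)``
    cuts ranked cells into m contiguous near-equal blocks (sizes differ
    by at most one, larger bins first).
    """

    cell_ids: np.ndarray
    dc1: np.ndarray  # oriented
    sign: int
    rank: np.ndarray
    eigenvalues: np.ndarray | None = None
    components: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.cell_ids)

    @property
    def rank_norm(self) -> np.ndarray:
        if self.n == 1:
            return np.zeros(1)
        return (self.rank - 1) / (self.n - 1)

    def bins(self, n_bins: int) -> np.ndarray:
        """0-based bin index per cell; contiguous rank blocks, sizes
        floor(n/m) or ceil(n/m) with the larger bins first."""
        return bin_assign(self.rank, n_bins)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.cell_ids, "dc1": self.dc1, "rank": self.rank,
             "rank_norm": self.rank_norm}
        )


def bin_assign(rank: np.ndarray, n_bins: int) -> np.ndarray:
    n = len(rank)
    if not (1 <= n_bins <= n):
        raise ValueError(f"n_bins must be in [1, {n}], got {n_bins}")
    q, r = divmod(n, n_bins)
    sizes = np.array([q + 1] * r + [q] * (n_bins - r))
    edges = np.concatenate([[0], np.cumsum(sizes)])  # rank boundaries
    # rank r belongs to bin b iff edges[b] < r <= edges[b+1]
    return (np.searchsorted(edges, rank, side="left") - 1).astype(np.int64)


def orient_and_rank(
    dc1: np.ndarray,
    expr: pd.DataFrame,
    cell_ids: np.ndarray | list[str],
    anchor_up: str = "MMP9",
    anchor_down: str = "LYVE1",
    eigenvalues: np.ndarray | None = None,
    components: np.ndarray | None = None,
) -> TransitionOrdering:
    """Orient DC1 by anchor genes and rank cells along it.

    The sign is chosen so that moving up the oriented axis increases the
    up-anchor relative to the down-anchor (top vs bottom DC1 quartile
    means); ranks 1..n follow oriented DC1 with ties broken by cell id.
    """
    dc1 = np.asarray(dc1, dtype=float)
    ids = np.asarray([str(i) for i in cell_ids])
    if dc1.shape[0] != ids.shape[0]:
        raise ValueError("dc1 and cell_ids must align")
    for g in (anchor_up, anchor_down):
        if g not in expr.columns:
            raise KeyError(f"anchor gene {g!r} absent from expression")
    n = dc1.size
    if n == 0:
        raise ValueError("empty cell subset")
    up = expr[anchor_up].reindex(ids).to_numpy(dtype=float)
    down = expr[anchor_down].reindex(ids).to_numpy(dtype=float)
    lo, hi = np.quantile(dc1, [0.25, 0.75])
    top, bottom = dc1 >= hi, dc1 <= lo
    contrast = (up[top].mean() - up[bottom].mean()) - (
        down[top].mean() - down[bottom].mean()
    )
    if contrast > 0:
        sign = 1
    elif contrast < 0:
        sign = -1
    else:
        raise ValueError(
            "orientation undecidable: anchor contrast is zero; pass an "
            "explicit sign by negating dc1"
        )
    oriented = sign * dc1
    order = np.lexsort((ids, oriented))
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(1, n + 1)
    return TransitionOrdering(
        cell_ids=ids, dc1=oriented, sign=sign, rank=rank,
        eigenvalues=eigenvalues, components=components,
    )


def bin_aggregate(
    ordering: TransitionOrdering,
    expr: pd.DataFrame,
    n_bins: int,
    genes: list[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Mean expression per gene in each of ``n_bins`` contiguous rank
    blocks: ``(genes x bins DataFrame, bin sizes)``."""
    genes = list(expr.columns) if genes is None else list(genes)
    missing = [g for g in genes if g not in expr.columns]
    if missing:
        raise KeyError(f"genes absent from expression: {missing[:5]}")
    bins = ordering.bins(n_bins)
    sub = expr[genes].reindex(ordering.cell_ids).to_numpy(dtype=float)
    mat = np.zeros((len(genes), n_bins))
    sizes = np.zeros(n_bins, dtype=np.int64)
    for b in range(n_bins):
        mask = bins == b
        sizes[b] = int(mask.sum())
        mat[:, b] = sub[mask].mean(axis=0)
    out = pd.DataFrame(
        mat, index=pd.Index(genes, name="gene"),
        columns=pd.RangeIndex(n_bins, name="bin"),
    )
    return out, sizes


def order_transition(
    dataset,
    expr: pd.DataFrame,
    cell_type: str = "CD14_myeloid",
    n_var_genes: int = 100,
    n_pcs: int = 5,
    k: int = 200,
    anchor_up: str = "MMP9",
    anchor_down: str = "LYVE1",
) -> TransitionOrdering:
    """Full ordering chain for one labeled subset: variable genes -> PCA
    -> diffusion map -> anchor-oriented ranks.

    ``n_var_genes`` and ``k`` are capped at what the subset supports.
    """
    from .qc import select_variable_genes

    mask = (dataset.cells["cell_type"] == cell_type).to_numpy()
    ids = dataset.cells["cell_id"].to_numpy()[mask]
    if ids.size < 3:
        raise ValueError(f"need at least 3 cells of type {cell_type!r}")
    sub = expr.reindex(ids)
    genes = select_variable_genes(sub, min(n_var_genes, sub.shape[1]))
    n_pcs = min(n_pcs, len(ids) - 1, len(genes))
    scores, _, _ = pca_embed(sub[genes], n_pcs)
    evals, dcs = diffusion_map(scores, k=min(k, len(ids) - 1))
    return orient_and_rank(
        dcs[:, 0], sub, ids, anchor_up=anchor_up, anchor_down=anchor_down,
        eigenvalues=evals, components=dcs,
    )
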