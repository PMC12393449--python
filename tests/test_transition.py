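"""PCA, diffusion-map construction, anchor orientation, equal-size binning."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import dermafield as df
from dermafield.transition import bin_assign


# -- PCA --------------------------------------------------------------------

def test_rank_one_data_explained_by_pc1():
    rng = np.random.default_rng(0)
    direction = np.array([1.0, 2.0, -0.5, 3.0])
    X = np.outer(rng.normal(size=80), direction)
    scores, loadings, explained = df.pca_embed(X, 2)
    assert explained[0] / explained.sum() >= 0.999


def test_pca_scores_orthogonal():
    rng = np.random.default_rng(1)
    scores, _, _ = df.pca_embed(rng.normal(size=(60, 8)), 4)
    gram = scores.T @ scores
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8


def test_pca_matches_covariance_eigendecomposition():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(50, 10))
    _, _, explained = df.pca_embed(X, 5)
    cov = np.cov(X, rowvar=False)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1][:5]
    np.testing.assert_allclose(explained, eig, rtol=1e-10)


def test_pca_component_limit():
    with pytest.raises(ValueError, match="rank"):
        df.pca_embed(np.random.default_rng(3).normal(size=(5, 10)), 5)


def test_pca_deterministic_sign():
    X = np.random.default_rng(4).normal(size=(30, 6))
    _, load1, _ = df.pca_embed(X, 3)
    _, load2, _ = df.pca_embed(X.copy(), 3)
    np.testing.assert_array_equal(load1, load2)
    for j in range(3):
        assert load1[np.argmax(np.abs(load1[:, j])), j] > 0


# -- diffusion map ----------------------------------------------------------

def test_line_ordering_is_exact():
    """Equally spaced points on a line: DC1 recovers the ordering exactly."""
    x = np.linspace(0, 1, 50)[:, None]
    _, dcs = df.diffusion_map(x, k=10)
    rho = abs(spearmanr(dcs[:, 0], x.ravel()).statistic)
    assert rho == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_noisy_manifold_ordering(seed):
    """Line plus 5%-of-length Gaussian noise, n=1,000: |rho| >= 0.9."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, 100, 1000)
    pts = np.column_stack([pos, np.zeros(1000)]) + rng.normal(0, 5, (1000, 2))
    _, dcs = df.diffusion_map(pts, k=200)
    assert abs(spearmanr(dcs[:, 0], pos).statistic) >= 0.9


def test_dc1_is_not_constant():
    rng = np.random.default_rng(6)
    _, dcs = df.diffusion_map(rng.normal(size=(40, 3)), k=10)
    assert np.std(dcs[:, 0]) > 1e-8


def test_disconnected_graph_is_error():
    a = np.random.default_rng(7).normal(size=(20, 2))
    b = a + 1e6
    with pytest.raises(ValueError, match="disconnected"):
        df.diffusion_map(np.vstack([a, b]), k=3)


def test_k_capped_with_warning():
    x = np.linspace(0, 1, 10)[:, None]
    with pytest.warns(UserWarning, match="capped"):
        df.diffusion_map(x, k=50)


# -- orientation & ranks ----------------------------------------------------

def _anchor_expr(ids, up, down):
    return pd.DataFrame(
        {"MMP9": up, "LYVE1": down}, index=pd.Index(ids, name="cell_id")
    )


def test_orientation_flip_preserves_ranks():
    rng = np.random.default_rng(8)
    n = 60
    dc1 = rng.normal(size=n)
    ids = [f"c{i}" for i in range(n)]
    expr = _anchor_expr(ids, up=dc1 + rng.normal(0, 0.1, n), down=-dc1)
    o1 = df.orient_and_rank(dc1, expr, ids)
    o2 = df.orient_and_rank(-dc1, expr, ids)
    assert o1.sign == -o2.sign
    np.testing.assert_array_equal(o1.rank, o2.rank)


def test_ranks_are_exact_permutation():
    rng = np.random.default_rng(9)
    n = 35
    dc1 = rng.normal(size=n)
    ids = [f"c{i}" for i in range(n)]
    o = df.orient_and_rank(dc1, _anchor_expr(ids, dc1, -dc1), ids)
    assert sorted(o.rank) == list(range(1, n + 1))


def test_negating_anchor_expression_reverses_ranks():
    rng = np.random.default_rng(10)
    n = 40
    dc1 = rng.normal(size=n)
    ids = [f"c{i}" for i in range(n)]
    o1 = df.orient_and_rank(dc1, _anchor_expr(ids, dc1, -dc1), ids)
    o2 = df.orient_and_rank(dc1, _anchor_expr(ids, -dc1, dc1), ids)
    assert o2.sign == -o1.sign
    np.testing.assert_array_equal(o2.rank, o1.n + 1 - o1.rank)


def test_undecidable_orientation_is_error():
    ids = ["a", "b", "c", "d"]
    dc1 = np.array([0.0, 1.0, 2.0, 3.0])
    flat = _anchor_expr(ids, np.ones(4), np.ones(4))
    with pytest.raises(ValueError, match="undecidable"):
        df.orient_and_rank(dc1, flat, ids)


# -- binning ----------------------------------------------------------------

def test_equal_bins_7200_cells_50_bins():
    """7,200 ranked cells cut into 50 bins give exactly 144 cells each."""
    rank = np.arange(1, 7201)
    bins = bin_assign(rank, 50)
    sizes = np.bincount(bins)
    assert (sizes == 144).all() and len(sizes) == 50


def test_bins_of_size_one_reproduce_cells():
    rng = np.random.default_rng(11)
    n = 10
    dc1 = rng.normal(size=n)
    ids = [f"c{i}" for i in range(n)]
    o = df.orient_and_rank(dc1, _anchor_expr(ids, dc1, -dc1), ids)
    expr = pd.DataFrame({"G": rng.normal(size=n)}, index=pd.Index(ids))
    binned, sizes = df.bin_aggregate(o, expr, 10, ["G"])
    assert (sizes == 1).all()
    by_rank = expr["G"].to_numpy()[np.argsort(o.rank)]
    np.testing.assert_allclose(binned.loc["G"].to_numpy(), by_rank)


def test_remainder_bins_larger_first():
    bins = bin_assign(np.arange(1, 101), 30)
    sizes = np.bincount(bins)
    assert sizes[:10].tolist() == [4] * 10 and sizes[10:].tolist() == [3] * 20


def test_bins_partition_contiguously():
    rng = np.random.default_rng(12)
    n, m = 137, 12
    rank = rng.permutation(n) + 1
    bins = bin_assign(rank, m)
    sizes = np.bincount(bins)
    assert sizes.max() - sizes.min() <= 1
    order = np.argsort(rank)
    assert (np.diff(bins[order]) >= 0).all()  # ranks sorted -> bins sorted


def test_n_bins_exceeding_n_is_error():
    with pytest.raises(ValueError):
        bin_assign(np.arange(1, 6), 6)


# -- end-to-end recovery ----------------------------------------------------

def test_transition_recovery_single_seed(qc_tissue):
    """Full chain on the default section recovers the latent state."""
    ds, expr, truth = qc_tissue
    ordering = df.order_transition(ds, expr)
    t = truth.cells.set_index("cell_id")["t"].reindex(ordering.cell_ids).to_numpy()
    assert spearmanr(ordering.rank, t).statistic >= 0.8
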