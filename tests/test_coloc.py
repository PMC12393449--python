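"""Gaussian-field colocalization: kernel values, grid/exact agreement,
direction dependence, affine normalization, heatmap ordering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import dermafield as df
from dermafield.coloc import KernelParams

from conftest import make_dataset

SD = 400.0


# -- exact kernel sums ------------------------------------------------------

@pytest.mark.parametrize(
    "refs, expected",
    [
        ([(0.0, 0.0)], 1.0),  # kernel maximum at distance 0
        ([(SD, 0.0)], np.exp(-0.5)),  # closed-form value at d = sd
        ([(3.5 * SD, 0.0)], 0.0),  # beyond 3 sd truncation
        ([(0.0, 0.0), (0.0, 0.0)], 2.0),  # additivity of coincident kernels
    ],
)
def test_exact_kernel_values(refs, expected):
    score = df.coloc_score_exact(np.array([[0.0, 0.0]]), np.array(refs))
    assert score[0] == pytest.approx(expected, abs=1e-12)


def test_empty_reference_scores_zero():
    score = df.coloc_score_exact(np.array([[1.0, 2.0]]), np.empty((0, 2)))
    assert score[0] == 0.0


def test_pdf_normalized_kernel_amplitude():
    params = KernelParams(sd=SD, normalized_pdf=True)
    score = df.coloc_score_exact(np.zeros((1, 2)), np.zeros((1, 2)), params)
    assert score[0] == pytest.approx(1.0 / (2 * np.pi * SD**2))


def test_single_reference_monotone_decreasing_to_truncation():
    d = np.linspace(0, 2.99 * SD, 200)
    pts = np.column_stack([d, np.zeros_like(d)])
    s = df.coloc_score_exact(pts, np.zeros((1, 2)))
    assert (np.diff(s) < 0).all()
    beyond = df.coloc_score_exact(np.array([[3.01 * SD, 0.0]]), np.zeros((1, 2)))
    assert beyond[0] == 0.0


def test_additivity_over_reference_union():
    rng = np.random.default_rng(0)
    a, b = rng.uniform(0, 1000, (30, 2)), rng.uniform(0, 1000, (20, 2))
    q = rng.uniform(0, 1000, (50, 2))
    params = KernelParams(sd=200.0)
    s_union = df.coloc_score_exact(q, np.vstack([a, b]), params)
    s_sum = df.coloc_score_exact(q, a, params) + df.coloc_score_exact(q, b, params)
    np.testing.assert_allclose(s_union, s_sum, rtol=1e-12)


# -- fields -----------------------------------------------------------------

def test_empty_field_is_all_zero():
    fld = df.create_field(np.empty((0, 2)), KernelParams(sd=100.0))
    assert (fld.values == 0).all()


def test_single_reference_peaks_at_nearest_node():
    fld = df.create_field(np.array([[500.0, 400.0]]), KernelParams(sd=100.0))
    iy, ix = np.unravel_index(np.argmax(fld.values), fld.values.shape)
    x0, y0 = fld.origin
    node = (x0 + ix * fld.spacing, y0 + iy * fld.spacing)
    assert abs(node[0] - 500.0) <= fld.spacing and abs(node[1] - 400.0) <= fld.spacing


def test_spacing_above_quarter_sd_rejected():
    with pytest.raises(ValueError, match="sd/4"):
        df.create_field(np.zeros((1, 2)), KernelParams(sd=100.0), grid_spacing=30.0)


def test_point_on_grid_node_is_exact():
    params = KernelParams(sd=100.0)
    ref = np.random.default_rng(1).uniform(0, 500, (20, 2))
    fld = df.create_field(ref, params)
    x0, y0 = fld.origin
    node = np.array([[x0 + 5 * fld.spacing, y0 + 7 * fld.spacing]])
    np.testing.assert_allclose(
        df.evaluate_field(fld, node)[0], fld.values[7, 5], rtol=1e-12
    )
    np.testing.assert_allclose(
        fld.values[7, 5], df.coloc_score_exact(node, ref, params)[0], rtol=1e-12
    )


def test_outside_padded_box_scores_zero():
    fld = df.create_field(np.zeros((1, 2)), KernelParams(sd=100.0))
    far = np.array([[1e6, 1e6]])
    assert df.evaluate_field(fld, far)[0] == 0.0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_grid_matches_exact_oracle_property(seed):
    """Grid interpolation agrees with the brute-force sum within 1% of
    the section max at spacing sd/4."""
    rng = np.random.default_rng(seed)
    sd = rng.uniform(50, 400)
    params = KernelParams(sd=sd)
    ref = rng.uniform(0, 2000, (int(rng.integers(5, 150)), 2))
    fld = df.create_field(ref, params, grid_spacing=sd / 4)
    q = rng.uniform(-sd, 2000 + sd, (300, 2))
    exact = df.coloc_score_exact(q, ref, params)
    approx = df.evaluate_field(fld, q)
    assert np.abs(approx - exact).max() < 1e-2 * exact.max()


# -- type x type matrix -----------------------------------------------------

def test_coincident_pair_all_entries_one():
    ds = make_dataset([(0, 0), (0, 0)], ["A", "B"])
    mat = df.colocalization_matrix(ds, KernelParams(sd=SD), mode="exact")
    for q in "AB":
        for r in "AB":
            assert mat.raw.loc[q, r] == pytest.approx(1.0)


def test_direction_dependence_closed_form():
    """Three A cells at distance sd from one B cell: (A in B-field) =
    e^-0.5 while (B in A-field) = 3 e^-0.5 — asymmetric by construction."""
    ds = make_dataset(
        [(SD, 0), (-SD, 0), (0, SD), (0, 0)], ["A", "A", "A", "B"]
    )
    mat = df.colocalization_matrix(ds, KernelParams(sd=SD), mode="exact")
    a_in_b = mat.raw.loc["A", "B"]
    b_in_a = mat.raw.loc["B", "A"]
    assert a_in_b == pytest.approx(np.exp(-0.5), abs=1e-12)
    assert b_in_a == pytest.approx(3 * np.exp(-0.5), abs=1e-12)
    assert b_in_a / a_in_b == pytest.approx(3.0, abs=1e-12)


def test_matrix_invariant_to_cell_order(qc_tissue):
    ds, _, _ = qc_tissue
    sub = ds.subset(np.arange(400))
    perm = np.random.default_rng(5).permutation(400)
    mat1 = df.colocalization_matrix(sub, KernelParams(sd=SD), mode="exact")
    mat2 = df.colocalization_matrix(sub.subset(perm), KernelParams(sd=SD), mode="exact")
    pd.testing.assert_frame_equal(mat1.raw, mat2.raw)


def test_missing_type_column_dropped_with_warning():
    ds = make_dataset([(0, 0), (10, 10)], ["A", "A"])
    mat = df.colocalization_matrix(ds, KernelParams(sd=SD), reference_types=["A", "B"])
    assert list(mat.raw.columns) == ["A"]


# -- normalization ----------------------------------------------------------

def test_normalization_constants_and_affine_formula(qc_tissue):
    """self-aggregate 100, all-cell mean 0, and the affine map matches a
    hand computation from the stored constants."""
    ds, _, _ = qc_tissue
    mat = df.normalize_coloc_matrix(
        df.colocalization_matrix(ds, KernelParams(sd=SD), mode="exact")
    )
    sample = mat.samples[0]
    assert not mat.degenerate
    for ref in mat.normalized.columns:
        assert mat.normalized.loc[ref, ref] == pytest.approx(100.0, abs=1e-9)
        assert abs(mat.per_cell_norm[sample][ref].mean()) < 1e-9
    ref = mat.normalized.columns[0]
    c = mat.constants[sample][ref]
    raw = mat.per_cell_raw[sample][ref].iloc[17]
    expected = 100.0 * (raw - c["mean_all"]) / (c["mean_self"] - c["mean_all"])
    assert mat.per_cell_norm[sample][ref].iloc[17] == pytest.approx(expected)


def test_affine_midpoint_example():
    """mean_all=2, mean_self=4: a raw score of 3 normalizes to 50."""
    assert 100.0 * (3 - 2) / (4 - 2) == pytest.approx(50.0)
    # through the API: B at the A centroid, A alone far away
    ds = make_dataset([(0, 0), (0, 0), (10_000, 10_000)], ["A", "B", "B"])
    mat = df.normalize_coloc_matrix(
        df.colocalization_matrix(ds, KernelParams(sd=SD), mode="exact")
    )
    s = mat.per_cell_norm["s1"]["A"]
    c = mat.constants["s1"]["A"]
    raw = mat.per_cell_raw["s1"]["A"]
    np.testing.assert_allclose(
        s, 100.0 * (raw - c["mean_all"]) / (c["mean_self"] - c["mean_all"])
    )


def test_degenerate_column_flagged():
    ds = make_dataset([(0, 0), (1, 1)], ["A", "A"])
    with pytest.warns(UserWarning, match="unnormalized"):
        mat = df.normalize_coloc_matrix(
            df.colocalization_matrix(ds, KernelParams(sd=SD), mode="exact")
        )
    assert ("s1", "A") in mat.degenerate


# -- heatmap ordering -------------------------------------------------------

def test_hclust_groups_block_diagonal():
    m = pd.DataFrame(
        [[10, 10, 0, 0], [10, 11, 0, 0], [0, 0, 8, 8], [0, 0, 8, 9]],
        index=list("abcd"), columns=list("wxyz"), dtype=float,
    )
    res = df.order_matrix_hclust(m)
    order = res["row_order"]
    assert {order.index("a"), order.index("b")} in ({0, 1}, {2, 3})
    assert {order.index("c"), order.index("d")} in ({0, 1}, {2, 3})


def test_identical_rows_merge_at_zero():
    m = pd.DataFrame(
        [[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]], index=list("abc"), columns=["u", "v"]
    )
    res = df.order_matrix_hclust(m)
    assert res["row_linkage"][0, 2] == 0.0  # first merge at distance 0


def test_hclust_partition_invariant_to_row_permutation():
    rng = np.random.default_rng(7)
    m = pd.DataFrame(rng.normal(size=(6, 4)), index=list("abcdef"))
    res1 = df.order_matrix_hclust(m)
    res2 = df.order_matrix_hclust(m.sample(frac=1, random_state=1))
    assert res1["row_order"] == res2["row_order"]


def test_hclust_single_row_trivial():
    m = pd.DataFrame([[1.0, 2.0]], index=["only"])
    res = df.order_matrix_hclust(m)
    assert res["row_order"] == ["only"] and res["row_linkage"] is None
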