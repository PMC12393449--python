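"""Neighborhood expression, smoothed surfaces, contour levels, rolling means."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import dermafield as df
from dermafield.spatial_expr import SmoothedMap

from conftest import make_dataset


def _expr(ds, values, gene="G"):
    return pd.DataFrame(
        {gene: np.asarray(values, dtype=float)},
        index=pd.Index(ds.cells["cell_id"], name="cell_id"),
    )


# -- local expression -------------------------------------------------------

def test_isolated_focal_cell_has_no_value():
    ds = make_dataset([(0, 0), (5000, 5000)], ["F", "N"])
    res = df.local_expression(ds, _expr(ds, [1.0, 2.0]), "G", ["c0"], radius=400)
    row = res.table.iloc[0]
    assert row["n_neighbors"] == 0 and np.isnan(row["value"])


def test_single_neighbor_value_passthrough():
    ds = make_dataset([(0, 0), (100, 0)], ["F", "N"])
    res = df.local_expression(ds, _expr(ds, [9.0, 4.0]), "G", ["c0"], radius=400)
    assert res.table["value"].iloc[0] == pytest.approx(4.0)
    assert res.table["n_neighbors"].iloc[0] == 1


def test_neighbor_mean_excludes_focal():
    ds = make_dataset([(0, 0), (100, 0), (0, 100)], ["F", "N", "N"])
    res = df.local_expression(ds, _expr(ds, [99.0, 2.0, 6.0]), "G", ["c0"], radius=400)
    assert res.table["value"].iloc[0] == pytest.approx(4.0)  # (2+6)/2, focal's 99 out


def test_include_focal_switch():
    ds = make_dataset([(0, 0), (100, 0)], ["F", "N"])
    res = df.local_expression(
        ds, _expr(ds, [8.0, 4.0]), "G", ["c0"], radius=400, include_focal=True
    )
    assert res.table["value"].iloc[0] == pytest.approx(6.0)


def test_neighbor_type_filter():
    ds = make_dataset([(0, 0), (50, 0), (0, 50)], ["F", "N", "M"])
    res = df.local_expression(
        ds, _expr(ds, [0.0, 3.0, 7.0]), "G", ["c0"], radius=400,
        neighbor_types={"M"},
    )
    assert res.table["value"].iloc[0] == pytest.approx(7.0)


def test_unknown_gene_and_empty_focal():
    ds = make_dataset([(0, 0)], ["F"])
    with pytest.raises(KeyError, match="NOPE"):
        df.local_expression(ds, _expr(ds, [1.0]), "NOPE", ["c0"])
    res = df.local_expression(ds, _expr(ds, [1.0]), "G", [])
    assert res.table.empty


def test_local_expression_translation_invariant():
    rng = np.random.default_rng(0)
    coords = rng.uniform(0, 1000, (40, 2))
    vals = rng.normal(size=40)
    ds1 = make_dataset(coords, ["N"] * 40)
    ds2 = make_dataset(coords + [1e4, -2e3], ["N"] * 40)
    r1 = df.local_expression(ds1, _expr(ds1, vals), "G", ["c3", "c7"], radius=300)
    r2 = df.local_expression(ds2, _expr(ds2, vals), "G", ["c3", "c7"], radius=300)
    pd.testing.assert_frame_equal(r1.table, r2.table)


# -- smoothed maps ----------------------------------------------------------

def test_single_cell_surface_equals_its_value():
    ds = make_dataset([(100, 100)], ["A"])
    smap = df.smooth_expression_map(ds, _expr(ds, [3.5]), "G", sigma=50)
    assert smap.values[0, 0] == pytest.approx(3.5)


def test_midpoint_of_two_equidistant_cells():
    ds = make_dataset([(0, 0), (100, 0)], ["A", "A"])
    smap = df.smooth_expression_map(
        ds, _expr(ds, [2.0, 6.0]), "G", sigma=100, grid_spacing=25
    )
    j = int(np.argmin(np.abs(smap.xs - 50.0)))
    assert smap.xs[j] == pytest.approx(50.0)
    assert smap.values[0, j] == pytest.approx(4.0)


def test_constant_expression_gives_constant_surface():
    rng = np.random.default_rng(1)
    ds = make_dataset(rng.uniform(0, 500, (30, 2)), ["A"] * 30)
    smap = df.smooth_expression_map(ds, _expr(ds, np.full(30, 2.5)), "G", sigma=100)
    np.testing.assert_allclose(smap.unmasked, 2.5)


def test_surface_bounded_by_expression_range():
    rng = np.random.default_rng(2)
    ds = make_dataset(rng.uniform(0, 800, (60, 2)), ["A"] * 60)
    vals = rng.normal(size=60)
    smap = df.smooth_expression_map(ds, _expr(ds, vals), "G", sigma=150)
    assert smap.unmasked.min() >= vals.min() - 1e-12
    assert smap.unmasked.max() <= vals.max() + 1e-12


# -- contour levels ---------------------------------------------------------

def test_default_contour_count_is_six():
    smap = SmoothedMap("G", 400.0, np.arange(4), np.arange(4),
                       np.arange(16, dtype=float).reshape(4, 4))
    assert len(df.contour_levels(smap)) == 6


def test_contour_levels_match_quantile_linspace_oracle():
    vals = np.arange(100, dtype=float)
    smap = SmoothedMap("G", 400.0, np.arange(10), np.arange(10), vals.reshape(10, 10))
    levels = df.contour_levels(smap, threshold=0.9, n_levels=6)
    q = np.quantile(vals, 0.9)  # linear-interpolation convention
    np.testing.assert_allclose(levels, np.linspace(q, 99.0, 6))


def test_constant_surface_levels_collapse():
    smap = SmoothedMap("G", 400.0, np.arange(3), np.arange(3), np.full((3, 3), 7.0))
    np.testing.assert_allclose(df.contour_levels(smap), 7.0)


def test_all_masked_surface_is_error():
    smap = SmoothedMap("G", 400.0, np.arange(2), np.arange(2), np.full((2, 2), np.nan))
    with pytest.raises(ValueError, match="masked"):
        df.contour_levels(smap)


# -- rolling means ----------------------------------------------------------

def test_rolling_hand_computed_example():
    out = df.rolling_mean_by_score(
        np.array([1.0, 2, 3, 4, 5]), np.array([1.0, 2, 3, 4, 5]), window_prop=0.6
    )
    np.testing.assert_allclose(out["mean"], [1.5, 2.0, 3.0, 4.0, 4.5])


def test_rolling_constant_values():
    out = df.rolling_mean_by_score(np.full(50, 3.0), np.arange(50), 0.1)
    np.testing.assert_allclose(out["mean"], 3.0)


def test_full_window_centers_on_global_mean():
    rng = np.random.default_rng(3)
    vals = rng.normal(size=101)
    out = df.rolling_mean_by_score(vals, np.arange(101), window_prop=1.0)
    assert out["mean"].iloc[50] == pytest.approx(vals.mean())


def test_rolling_empty_input():
    out = df.rolling_mean_by_score(np.array([]), np.array([]))
    assert out.empty


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(1, 200),
       prop=st.floats(0.05, 1.0))
def test_rolling_length_and_monotonicity_property(seed, n, prop):
    """Output length equals input length; monotone values stay monotone."""
    rng = np.random.default_rng(seed)
    score = rng.normal(size=n)
    vals = np.sort(rng.normal(size=n))[np.argsort(np.argsort(score))]
    # vals are monotone in score by construction
    out = df.rolling_mean_by_score(vals, score, window_prop=prop)
    assert len(out) == n
    assert (np.diff(out["mean"]) >= -1e-12).all()
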