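"""Shared fixtures: one default synthetic section generated once per
session, plus its QC'd/normalized derivatives and small hand-built
datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import dermafield as df


@pytest.fixture(scope="session")
def default_cfg():
    return df.default_skin_config()


@pytest.fixture(scope="session")
def tissue(default_cfg):
    """(dataset, ground_truth) for the default config, seed 0."""
    return df.generate_tissue(default_cfg, 0)


@pytest.fixture(scope="session")
def qc_tissue(tissue):
    """(filtered dataset, normalized expression, ground_truth)."""
    dataset, truth = tissue
    filtered, _ = df.qc_filter(dataset)
    expr = df.log_normalize(filtered)
    return filtered, expr, truth


def make_dataset(
    coords: np.ndarray,
    cell_types: list[str],
    counts: np.ndarray | None = None,
    genes: list[str] | None = None,
    surface: list[bool] | None = None,
    sample_id: str = "s1",
) -> df.SpatialDataset:
    """Small hand-built dataset helper used across test modules."""
    n = len(coords)
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "x_px": np.asarray(coords, dtype=float)[:, 0],
            "y_px": np.asarray(coords, dtype=float)[:, 1],
            "sample_id": sample_id,
            "section_id": "sec1",
            "cell_type": cell_types,
            "surface_flag": surface if surface is not None else [False] * n,
        }
    )
    mat = sp.csr_matrix(counts) if counts is not None else None
    return df.SpatialDataset(cells, mat, genes)
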