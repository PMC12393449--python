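"""Seeded generator of skin-like seqFISH sections with known ground truth.

The generator emulates the statistical structure of an inflamed-skin
section as the downstream analysis assumes it:

* layered geometry — an epidermis band on top (basal + suprabasal
  keratinocytes, with a keratinized surface sub-band of low-yield cells),
  a papillary and a reticular dermis below, each populated by homogeneous
  Poisson point processes per cell type;
* immune aggregates — isotropic Gaussian clumps of CD4/CD8 T cells,
  CD14+ myeloid cells and fibroblasts seeded just beneath the
  dermal-epidermal junction;
* a CD14+ myeloid state transition — each CD14 cell carries a latent
  state ``t in [0, 1]`` tied to depth, ``t = clip(a - b * depth/height + eps)``,
  with marker genes responding monotonically (an M1-like panel, MMP9
  foremost, increases with t; an M2-like panel, LYVE1 foremost, decreases);
* fibroblast chemokine gradients — CCL2/CCL8 means decay as a Gaussian of
  the distance to the nearest aggregate center;
* negative-binomial transcript counts per gene, overdispersed as imaging
  counts are, with reduced library size in surface keratinocytes so the
  lenient QC path is exercised.

Everything is driven by a :class:`TissueConfig` plus a seed; the same pair
reproduces byte-identical output, and the latent truth (per-cell type,
transition state, nearest aggregate) is returned alongside for recovery
tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import SpatialDataset

__all__ = [
    "AggregateSpec",
    "TransitionModel",
    "ExpressionModel",
    "TissueConfig",
    "GroundTruth",
    "default_skin_config",
    "expected_cell_count",
    "generate_tissue",
    "generate_counts",
]

KERATINOCYTE_TYPES = ("Krt_basal", "Krt_suprabasal")


@dataclass
class AggregateSpec:
    """One immune aggregate: Gaussian position model + expected composition."""

    center: tuple[float, float]
    sd_px: float
    counts: dict[str, float]  # cell type -> expected number of cells

    def validate(self) -> None:
        if self.sd_px <= 0:
            raise ValueError("aggregate sd_px must be positive")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("aggregate expected counts must be nonnegative")


@dataclass
class TransitionModel:
    """Latent CD14 state: t = clip(a - b * depth_norm + eps), eps ~ N(0, sigma_t^2)."""

    a: float = 1.15
    b: float = 1.2
    sigma_t: float = 0.05


@dataclass
class ExpressionModel:
    """Per-type negative-binomial expression model.

    ``means[type][gene]`` is the NB mean; genes absent from a type's map
    have mean 0. ``dispersions[type]`` is the NB size parameter theta
    (variance = mu + mu^2/theta); ``math.inf`` selects the Poisson limit.
    Transition-responsive genes (CD14 cells only) follow
    ``mu_up * t + baseline`` / ``mu_down * (1 - t) + baseline``; fibroblast
    chemokines follow ``base + amp * exp(-d_agg^2 / (2 * lambda^2))`` with
    ``d_agg`` the distance to the nearest aggregate center.
    """

    means: dict[str, dict[str, float]]
    dispersions: dict[str, float]
    transition_up: dict[str, tuple[float, float]] = field(default_factory=dict)
    transition_down: dict[str, tuple[float, float]] = field(default_factory=dict)
    chemokine_genes: dict[str, tuple[float, float]] = field(default_factory=dict)
    chemokine_lambda_px: float = 300.0
    chemokine_types: tuple[str, ...] = ("Fibroblast_proInf", "Fibroblast")
    surface_library_factor: float = 0.25

    def validate(self, genes: list[str]) -> None:
        gene_set = set(genes)
        for ctype, gmap in self.means.items():
            for g, m in gmap.items():
                if g not in gene_set:
                    raise ValueError(f"model gene {g!r} (type {ctype!r}) not in gene list")
                if m < 0:
                    raise ValueError(f"negative mean for {ctype}/{g}")
        for ctype, th in self.dispersions.items():
            if th <= 0:
                raise ValueError(f"dispersion for {ctype!r} must be positive")


@dataclass
class TissueConfig:
    """Generative parameters for one synthetic skin section."""

    width_px: float
    height_px: float
    #: ordered (name, (y_lo, y_hi)) intervals partitioning [0, height]
    layers: list[tuple[str, tuple[float, float]]]
    #: layer name -> cell type -> intensity (expected cells per px^2)
    intensities: dict[str, dict[str, float]]
    aggregates: list[AggregateSpec]
    genes: list[str]
    expression: ExpressionModel
    transition: TransitionModel = field(default_factory=TransitionModel)
    transition_type: str = "CD14_myeloid"
    surface_band_px: float = 0.0
    sample_id: str = "synthetic"
    section_id: str = "sec1"

    def validate(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("section dimensions must be positive")
        y = 0.0
        for name, (lo, hi) in self.layers:
            if not math.isclose(lo, y, abs_tol=1e-9):
                raise ValueError(f"layer {name!r} starts at {lo}, expected {y}")
            if hi < lo:
                raise ValueError(f"layer {name!r} has negative height")
            y = hi
        if not math.isclose(y, self.height_px, abs_tol=1e-9):
            raise ValueError("layers must partition [0, height]")
        layer_names = {name for name, _ in self.layers}
        for lname, imap in self.intensities.items():
            if lname not in layer_names:
                raise ValueError(f"intensity map names unknown layer {lname!r}")
            for ctype, lam in imap.items():
                if lam < 0:
                    raise ValueError(f"negative intensity for {lname}/{ctype}")
        for agg in self.aggregates:
            agg.validate()
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene list has duplicates")
        self.expression.validate(self.genes)
        if not (0 <= self.transition.sigma_t):
            raise ValueError("sigma_t must be nonnegative")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["layers"] = [[n, list(iv)] for n, iv in self.layers]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TissueConfig":
        d = dict(d)
        d["layers"] = [(n, (float(iv[0]), float(iv[1]))) for n, iv in d["layers"]]
        d["aggregates"] = [
            AggregateSpec(tuple(a["center"]), a["sd_px"], dict(a["counts"]))
            for a in d["aggregates"]
        ]
        em = dict(d["expression"])
        em["transition_up"] = {g: tuple(v) for g, v in em.get("transition_up", {}).items()}
        em["transition_down"] = {g: tuple(v) for g, v in em.get("transition_down", {}).items()}
        em["chemokine_genes"] = {g: tuple(v) for g, v in em.get("chemokine_genes", {}).items()}
        em["chemokine_types"] = tuple(em.get("chemokine_types", ()))
        d["expression"] = ExpressionModel(**em)
        d["transition"] = TransitionModel(**d["transition"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TissueConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


@dataclass
class GroundTruth:
    """Latent truth for one generated section (one record per cell)."""

    cells: pd.DataFrame  # cell_id, cell_type, depth_px, t, nearest_aggregate
    gene_means: dict[str, dict[str, float]]  # type -> gene -> generating baseline mean


# ---------------------------------------------------------------------------
# default configuration
# ---------------------------------------------------------------------------

HOUSEKEEPING = ("ACTB", "GAPDH", "B2M", "UBC", "RPL13A", "TUBB")

M1_PANEL = {  # gene -> (mu_up, baseline); mean = mu_up * t + baseline
    "MMP9": (16.0, 0.3),
    "IL1B": (10.0, 0.3),
    "TNF": (8.0, 0.3),
    "CXCL9": (7.0, 0.2),
    "CCR1": (5.0, 0.3),
    "CCR5": (5.0, 0.3),
}
M2_PANEL = {  # gene -> (mu_down, baseline); mean = mu_down * (1 - t) + baseline
    "LYVE1": (16.0, 0.3),
    "MRC1": (10.0, 0.3),
    "CD163": (8.0, 0.3),
    "SELENOP": (7.0, 0.3),
    "F13A1": (6.0, 0.2),
    "DAB2": (5.0, 0.3),
}

_TYPE_MARKERS = {
    "Krt_basal": {"KRT14": 22.0, "KRT5": 18.0, "COL17A1": 8.0},
    "Krt_suprabasal": {"KRT10": 22.0, "KRT1": 18.0, "IVL": 8.0},
    "Fibroblast": {"COL1A1": 22.0, "PDGFRA": 10.0, "DCN": 12.0, "CXCL12": 6.0},
    "Fibroblast_proInf": {"COL1A1": 18.0, "PDGFRA": 9.0, "CCL19": 8.0, "CXCL12": 7.0},
    "CD4_T": {"CD3D": 16.0, "CD4": 12.0, "IL7R": 8.0, "IFNG": 3.0},
    "CD8_T": {"CD3D": 16.0, "CD8A": 14.0, "GZMK": 8.0, "IFNG": 4.0},
    "CD14_myeloid": {"CD14": 16.0, "LYZ": 14.0, "AIF1": 8.0},
    "Endothelial": {"PECAM1": 18.0, "VWF": 14.0, "CLDN5": 8.0},
}


def default_skin_config() -> TissueConfig:
    """Default ~3,800-cell section: epidermis band, two dermis layers,
    three sub-junctional immune aggregates, 45 genes."""
    width, height = 6000.0, 4000.0
    layers = [
        ("epidermis", (0.0, 400.0)),
        ("papillary_dermis", (400.0, 1200.0)),
        ("reticular_dermis", (1200.0, height)),
    ]

    def per_layer(layer: str, expected: dict[str, float]) -> dict[str, float]:
        lo, hi = dict(layers)[layer]
        area = width * (hi - lo)
        return {t: n / area for t, n in expected.items()}

    intensities = {
        "epidermis": per_layer("epidermis", {"Krt_basal": 600, "Krt_suprabasal": 700}),
        "papillary_dermis": per_layer(
            "papillary_dermis",
            {
                "Fibroblast_proInf": 350,
                "Fibroblast": 150,
                "Endothelial": 100,
                "CD14_myeloid": 150,
                "CD4_T": 80,
                "CD8_T": 50,
            },
        ),
        "reticular_dermis": per_layer(
            "reticular_dermis",
            {
                "Fibroblast": 800,
                "Endothelial": 150,
                "CD14_myeloid": 250,
                "CD4_T": 60,
                "CD8_T": 40,
            },
        ),
    }
    agg_counts = {"CD4_T": 50.0, "CD8_T": 30.0, "CD14_myeloid": 25.0, "Fibroblast_proInf": 10.0}
    aggregates = [
        AggregateSpec((1200.0, 650.0), 120.0, dict(agg_counts)),
        AggregateSpec((3000.0, 700.0), 120.0, dict(agg_counts)),
        AggregateSpec((4800.0, 620.0), 120.0, dict(agg_counts)),
    ]

    genes: list[str] = list(HOUSEKEEPING)
    for markers in _TYPE_MARKERS.values():
        genes.extend(g for g in markers if g not in genes)
    for g in (*M1_PANEL, *M2_PANEL, "CCL2", "CCL8", "CCR2"):
        if g not in genes:
            genes.append(g)

    means: dict[str, dict[str, float]] = {}
    for ctype, markers in _TYPE_MARKERS.items():
        m = {g: 8.0 for g in HOUSEKEEPING}
        m.update(markers)
        means[ctype] = m
    # low-level chemokine receptor tone outside the transition response
    means["CD14_myeloid"]["CCR2"] = 4.0

    expression = ExpressionModel(
        means=means,
        dispersions={t: 2.0 for t in _TYPE_MARKERS},
        transition_up=dict(M1_PANEL),
        transition_down=dict(M2_PANEL),
        chemokine_genes={"CCL2": (0.5, 12.0), "CCL8": (0.5, 10.0)},
        chemokine_lambda_px=300.0,
        chemokine_types=("Fibroblast_proInf", "Fibroblast"),
        surface_library_factor=0.25,
    )
    cfg = TissueConfig(
        width_px=width,
        height_px=height,
        layers=layers,
        intensities=intensities,
        aggregates=aggregates,
        genes=genes,
        expression=expression,
        transition=TransitionModel(a=1.15, b=1.2, sigma_t=0.05),
        surface_band_px=120.0,
    )
    cfg.validate()
    return cfg


def expected_cell_count(config: TissueConfig) -> float:
    """Expected total number of cells (Poisson means summed)."""
    total = 0.0
    intervals = dict(config.layers)
    for lname, imap in config.intensities.items():
        lo, hi = intervals[lname]
        area = config.width_px * (hi - lo)
        total += area * sum(imap.values())
    total += sum(sum(a.counts.values()) for a in config.aggregates)
    return total


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Negative-binomial draws with mean `mean`, size theta; Poisson when
    theta is infinite."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if not np.any(pos):
        return out
    if math.isinf(theta):
        out[pos] = rng.poisson(mean[pos])
    else:
        p = theta / (theta + mean[pos])
        out[pos] = rng.negative_binomial(theta, p)
    return out


def generate_counts(
    cells: pd.DataFrame,
    model: ExpressionModel,
    genes: list[str],
    seed: int,
    transition_type: str = "CD14_myeloid",
) -> sp.csr_matrix:
    """Draw a cells x genes NB count matrix from the expression model.

    ``cells`` must carry ``cell_type`` and, for transition/chemokine
    responses, ``t`` and ``agg_dist_px`` columns (NaN/inf tolerated where
    the response does not apply).
    """
    known = set(model.means)
    unknown = sorted(set(cells["cell_type"]) - known)
    if unknown:
        raise ValueError(f"cell types missing from expression model: {unknown}")
    n, g = len(cells), len(genes)
    gene_idx = {gene: j for j, gene in enumerate(genes)}
    mu = np.zeros((n, g), dtype=float)
    ctype_arr = cells["cell_type"].to_numpy()
    for ctype in sorted(known):
        rows = np.flatnonzero(ctype_arr == ctype)
        if rows.size == 0:
            continue
        for gene, m in model.means[ctype].items():
            mu[rows, gene_idx[gene]] = m
    # transition response (CD14 cells)
    if "t" in cells.columns:
        rows = np.flatnonzero((ctype_arr == transition_type))
        if rows.size:
            t = cells["t"].to_numpy(dtype=float)[rows]
            for gene, (slope, base) in model.transition_up.items():
                if gene in gene_idx:
                    mu[rows, gene_idx[gene]] = slope * t + base
            for gene, (slope, base) in model.transition_down.items():
                if gene in gene_idx:
                    mu[rows, gene_idx[gene]] = slope * (1.0 - t) + base
    # chemokine gradient (fibroblasts near aggregates)
    if "agg_dist_px" in cells.columns and model.chemokine_genes:
        rows = np.flatnonzero(np.isin(ctype_arr, list(model.chemokine_types)))
        if rows.size:
            d = cells["agg_dist_px"].to_numpy(dtype=float)[rows]
            lam = model.chemokine_lambda_px
            with np.errstate(over="ignore"):
                decay = np.exp(-np.square(d) / (2.0 * lam * lam))
            decay[~np.isfinite(d)] = 0.0
            for gene, (base, amp) in model.chemokine_genes.items():
                if gene in gene_idx:
                    mu[rows, gene_idx[gene]] = base + amp * decay
    # surface keratinocytes: shrunken library
    if "surface_flag" in cells.columns:
        surf = cells["surface_flag"].to_numpy(dtype=bool)
        mu[surf] *= model.surface_library_factor

    rng = np.random.default_rng(seed)
    counts = np.zeros((n, g), dtype=np.int64)
    for ctype in sorted(known):
        rows = np.flatnonzero(ctype_arr == ctype)
        if rows.size == 0:
            continue
        theta = model.dispersions.get(ctype, math.inf)
        counts[rows] = _nb_draw(rng, mu[rows], theta)
    return sp.csr_matrix(counts)


def generate_tissue(
    config: TissueConfig, seed: int
) -> tuple[SpatialDataset, GroundTruth]:
    """Generate one section: positions, types, latent states, counts.

    Identical ``(config, seed)`` pairs produce byte-identical output.
    """
    config.validate()
    intervals = dict(config.layers)
    for lname, imap in config.intensities.items():
        lo, hi = intervals[lname]
        if hi - lo <= 0 and any(v > 0 for v in imap.values()):
            raise ValueError(
                f"layer {lname!r} has zero height but positive intensity"
            )
    rng = np.random.default_rng(seed)

    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    types: list[str] = []
    agg_ids: list[np.ndarray] = []

    # layered homogeneous Poisson processes
    for lname, (lo, hi) in config.layers:
        imap = config.intensities.get(lname, {})
        area = config.width_px * (hi - lo)
        for ctype in sorted(imap):
            n = rng.poisson(imap[ctype] * area)
            if n == 0:
                continue
            xs.append(rng.uniform(0.0, config.width_px, n))
            ys.append(rng.uniform(lo, hi, n))
            types.extend([ctype] * n)
            agg_ids.append(np.full(n, -1, dtype=np.int64))

    # Gaussian aggregates
    for aid, agg in enumerate(config.aggregates):
        for ctype in sorted(agg.counts):
            n = rng.poisson(agg.counts[ctype])
            if n == 0:
                continue
            pts = rng.normal(loc=agg.center, scale=agg.sd_px, size=(n, 2))
            xs.append(np.clip(pts[:, 0], 0.0, config.width_px))
            ys.append(np.clip(pts[:, 1], 0.0, config.height_px))
            types.extend([ctype] * n)
            agg_ids.append(np.full(n, aid, dtype=np.int64))

    if xs:
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        member = np.concatenate(agg_ids)
    else:
        x = np.empty(0)
        y = np.empty(0)
        member = np.empty(0, dtype=np.int64)
    n_cells = x.size
    width = max(1, len(str(max(n_cells, 1))))
    cell_ids = np.array([f"c{i:0{width}d}" for i in range(n_cells)])
    ctype_arr = np.array(types, dtype=object)

    surface = np.zeros(n_cells, dtype=bool)
    if config.surface_band_px > 0:
        surface = (y < config.surface_band_px) & np.isin(
            ctype_arr, list(KERATINOCYTE_TYPES)
        )

    # latent transition state for the CD14 population
    depth_norm = y / config.height_px if n_cells else y
    t = np.full(n_cells, np.nan)
    is_cd14 = ctype_arr == config.transition_type
    if is_cd14.any():
        tm = config.transition
        eps = rng.normal(0.0, tm.sigma_t, int(is_cd14.sum()))
        t[is_cd14] = np.clip(tm.a - tm.b * depth_norm[is_cd14] + eps, 0.0, 1.0)

    # distance to nearest aggregate center (all cells; drives chemokines)
    if config.aggregates and n_cells:
        centers = np.array([a.center for a in config.aggregates])
        diff = np.column_stack([x, y])[:, None, :] - centers[None, :, :]
        d_all = np.sqrt(np.square(diff).sum(axis=2))
        agg_dist = d_all.min(axis=1)
        nearest = d_all.argmin(axis=1)
    else:
        agg_dist = np.full(n_cells, np.inf)
        nearest = np.full(n_cells, -1, dtype=np.int64)

    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "x_px": x,
            "y_px": y,
            "sample_id": config.sample_id,
            "section_id": config.section_id,
            "cell_type": ctype_arr.astype(str),
            "surface_flag": surface,
            "t": t,
            "agg_dist_px": agg_dist,
        }
    )
    counts = generate_counts(
        cells, config.expression, config.genes,
        seed=int(rng.integers(0, 2**31 - 1)),
        transition_type=config.transition_type,
    ) if n_cells else sp.csr_matrix((0, len(config.genes)), dtype=np.int64)

    dataset = SpatialDataset(
        cells.drop(columns=["t", "agg_dist_px"]),
        counts,
        list(config.genes),
        params={"generator": "dermafield.synthetic", "seed": int(seed)},
    )
    truth = GroundTruth(
        cells=pd.DataFrame(
            {
                "cell_id": cell_ids,
                "cell_type": ctype_arr.astype(str),
                "depth_px": y,
                "t": t,
                "nearest_aggregate": np.where(member >= 0, member, nearest),
                "in_aggregate": member >= 0,
                "agg_dist_px": agg_dist,
            }
        ),
        gene_means={ct: dict(gm) for ct, gm in config.expression.means.items()},
    )
    return dataset, truth
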