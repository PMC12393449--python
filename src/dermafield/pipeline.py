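"""End-to-end pipeline: (synthetic or on-disk) section -> QC ->
normalization -> colocalization -> transition ordering -> spatial
expression -> distances -> machine-readable report.

The run is a pure function of (config, seed): identical inputs reproduce
identical outputs. Each stage logs its parameters and row counts to
stderr and to ``run.log`` in the output directory; any stage failure
aborts the run with the stage name and removes partial outputs.
"""

from __future__ import annotations

import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coloc, distances, qc, spatial_expr, synthetic, transition
from .io import SpatialDataset, read_dataset, write_dataset

__all__ = ["RunConfig", "run_pipeline"]

REPORT_SCHEMA_VERSION = 1

logger = logging.getLogger("dermafield")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_dir`` (a directory written by
    :func:`dermafield.io.write_dataset`) or ``tissue`` (a synthetic
    :class:`~dermafield.synthetic.TissueConfig`) supplies the data.
    """

    input_dir: str | None = None
    tissue: synthetic.TissueConfig | None = None
    seed: int = 0
    min_transcripts: int = 50
    surface_min: int = 10
    scale_total: float = 1e4
    kernel: coloc.KernelParams = field(default_factory=coloc.KernelParams)
    coloc_mode: str = "auto"
    transition_type: str = "CD14_myeloid"
    anchor_up: str = "MMP9"
    anchor_down: str = "LYVE1"
    n_var_genes: int = 100
    n_pcs: int = 5
    diffusion_k: int = 200
    n_bins: int = 30
    local_radius: float = 400.0
    local_genes: tuple[str, ...] = ("TNF", "IFNG")
    smooth_sigma: float = 400.0
    epidermis_type: str = "Krt_basal"
    lymphocyte_types: tuple[str, ...] = ("CD4_T", "CD8_T")
    window_prop: float = 0.1

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.tissue is None):
            raise ValueError("exactly one of input_dir / tissue must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "tissue" in raw and raw["tissue"] is not None:
            if raw["tissue"] == "default":
                raw["tissue"] = synthetic.default_skin_config()
            else:
                raw["tissue"] = synthetic.TissueConfig.from_dict(raw["tissue"])
        if "kernel" in raw:
            raw["kernel"] = coloc.KernelParams(**raw["kernel"])
        for key in ("local_genes", "lymphocyte_types"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage(report: dict, name: str, t0: float, **info) -> None:
    entry = {"stage": name, "seconds": round(time.time() - t0, 3), **info}
    report["stages"].append(entry)
    logger.info("stage %s: %s", name, json.dumps(info, default=str))


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline, write outputs under ``out_dir``, return
    (and save as ``report.json``) the run report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "seed": config.seed,
                    "stages": [], "outputs": {}}
    stage_name = "setup"
    try:
        # ---- load / generate -------------------------------------------
        t0 = time.time()
        stage_name = "data"
        if config.tissue is not None:
            dataset, truth = synthetic.generate_tissue(config.tissue, config.seed)
            truth.cells.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        else:
            dataset = read_dataset(config.input_dir)
            truth = None
        _stage(report, "data", t0, n_cells=dataset.n_cells,
               n_genes=len(dataset.genes or []))

        # ---- QC + normalization ----------------------------------------
        t0 = time.time()
        stage_name = "qc"
        dataset, qc_report = qc.qc_filter(
            dataset, config.min_transcripts, config.surface_min
        )
        report["qc"] = qc_report.to_dict()
        _stage(report, "qc", t0, **qc_report.to_dict())

        t0 = time.time()
        stage_name = "normalize"
        expr = qc.log_normalize(dataset, scale_total=config.scale_total)
        _stage(report, "normalize", t0, scale_total=config.scale_total)

        # ---- colocalization --------------------------------------------
        t0 = time.time()
        stage_name = "colocalization"
        cmat = coloc.colocalization_matrix(dataset, config.kernel, mode=config.coloc_mode)
        cmat = coloc.normalize_coloc_matrix(cmat)
        cmat.raw.to_csv(out / "coloc_raw.tsv", sep="\t")
        if cmat.normalized is not None:
            cmat.normalized.to_csv(out / "coloc_normalized.tsv", sep="\t")
            ordering_hc = coloc.order_matrix_hclust(cmat.normalized)
            report["coloc_row_order"] = ordering_hc["row_order"]
            report["coloc_col_order"] = ordering_hc["col_order"]
        (out / "coloc_constants.json").write_text(
            json.dumps(cmat.constants, indent=2, sort_keys=True)
        )
        _stage(report, "colocalization", t0, sd=config.kernel.sd,
               n_types=cmat.raw.shape[0])

        # ---- transition ordering ---------------------------------------
        t0 = time.time()
        stage_name = "transition"
        n_sub = int((dataset.cells["cell_type"] == config.transition_type).sum())
        if n_sub >= 10:
            ordering = transition.order_transition(
                dataset, expr,
                cell_type=config.transition_type,
                n_var_genes=config.n_var_genes,
                n_pcs=config.n_pcs,
                k=config.diffusion_k,
                anchor_up=config.anchor_up,
                anchor_down=config.anchor_down,
            )
            ordering_df = ordering.to_frame()
            ordering_df["bin"] = ordering.bins(min(config.n_bins, ordering.n))
            ordering_df.to_csv(out / "transition_ordering.tsv", sep="\t", index=False)
            binned, sizes = transition.bin_aggregate(
                ordering, expr.reindex(ordering.cell_ids),
                min(config.n_bins, ordering.n),
            )
            scaled = qc.row_scale_joint([binned])[0]
            scaled.to_csv(out / "transition_binned.tsv", sep="\t")
            _stage(report, "transition", t0, n_cells=ordering.n,
                   n_bins=int(len(sizes)), sign=ordering.sign)
        else:
            ordering = None
            _stage(report, "transition", t0, skipped=True,
                   reason=f"only {n_sub} cells of type {config.transition_type!r}")

        # ---- spatial expression ----------------------------------------
        t0 = time.time()
        stage_name = "spatial_expression"
        focal_ids = dataset.cells.loc[
            dataset.cells["cell_type"] == config.transition_type, "cell_id"
        ].tolist()
        genes_present = [g for g in config.local_genes if g in expr.columns]
        for gene in genes_present:
            if focal_ids:
                res = spatial_expr.local_expression(
                    dataset, expr, gene, focal_ids, radius=config.local_radius
                )
                res.table.to_csv(out / f"local_expression_{gene}.tsv", sep="\t",
                                 index=False)
            smap = spatial_expr.smooth_expression_map(
                dataset, expr, gene, sigma=config.smooth_sigma
            )
            levels = spatial_expr.contour_levels(smap)
            gx, gy = np.meshgrid(smap.xs, smap.ys)
            pd.DataFrame(
                {"x": gx.ravel(), "y": gy.ravel(), "value": smap.values.ravel()}
            ).to_csv(out / f"smoothed_{gene}.tsv", sep="\t", index=False)
            report.setdefault("contour_levels", {})[gene] = [float(v) for v in levels]
        _stage(report, "spatial_expression", t0, genes=genes_present)

        # ---- distances --------------------------------------------------
        t0 = time.time()
        stage_name = "distances"
        types_present = set(dataset.cells["cell_type"])
        if config.transition_type in types_present and ordering is not None:
            if config.epidermis_type in types_present:
                d_epi = distances.min_distance_to_type(
                    dataset, config.transition_type, config.epidermis_type
                )
                joined, marginals = distances.transition_distance_table(
                    ordering, d_epi, window_prop=config.window_prop
                )
                joined.to_csv(out / "transition_vs_epidermis.tsv", sep="\t",
                              index=False)
            lymph = set(config.lymphocyte_types) & types_present
            if lymph:
                d_agg = distances.min_distance_to_type(
                    dataset, config.transition_type, lymph
                )
                joined, _ = distances.transition_distance_table(
                    ordering, d_agg, window_prop=config.window_prop
                )
                joined.to_csv(out / "transition_vs_lymphocytes.tsv", sep="\t",
                              index=False)
        profile = distances.depth_profile(dataset, sorted(types_present))
        profile.quantiles.to_csv(out / "depth_quantiles.tsv", sep="\t")
        _stage(report, "distances", t0, n_types=len(types_present))

        # ---- finalize ----------------------------------------------------
        stage_name = "write"
        manifest = write_dataset(dataset, out / "dataset")
        report["outputs"]["dataset_manifest"] = manifest
        report["outputs"]["files"] = sorted(
            p.name for p in out.iterdir() if p.is_file()
        )
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        return report
    except Exception as exc:
        logger.error("pipeline failed at stage %s: %s", stage_name, exc)
        for p in out.iterdir():
            if p.is_file():
                p.unlink()
            elif p.is_dir():
                shutil.rmtree(p)
        raise RuntimeError(f"pipeline failed at stage {stage_name!r}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
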