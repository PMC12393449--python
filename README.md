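# dermafield

Spatial analysis of seqFISH skin sections: a directional Gaussian-field
colocalization metric between cell types, diffusion-map ordering of the
CD14⁺ myeloid LYVE1→MMP9 state transition, neighborhood expression
scoring, distance-to-structure profiling — and a seeded synthetic
skin-tissue generator with known ground truth, so the whole pipeline can
be exercised and validated without any data download.

It is written for researchers analyzing imaging-based spatial
transcriptomics of inflamed skin (interface dermatitis, cutaneous lupus,
dermatomyositis, psoriasis), where the questions are *which cell types sit
together*, *how a myeloid population changes state across the tissue*, and
*how both relate to structures such as the epidermis and immune
aggregates*.

## The statistics at the core

**Colocalization strength.** Every cell of a *reference* type R is modeled
as a Gaussian kernel at its centroid (σ = 400 px ≈ 41 µm by default). The
score of a cell at position *p* is the truncated kernel sum

```
s(p) = Σ_{r ∈ R, |p−r| ≤ 3σ}  exp(−|p−r|² / 2σ²)
```

and the (query Q, reference R) entry of the colocalization matrix is the
mean of `s` over cells of type Q. The metric blends density and proximity
of R around Q, and it is *directional*: three A cells around one B cell
give (B within A) = 3·(A within B). Per reference column, scores are
affinely rescaled so the mean over all cells in the sample is 0 and the
reference type's own aggregate is 100 — which makes columns comparable
across samples and kernel scales. Fields can be evaluated exactly
(k-d-tree summation, the default) or on a bilinear grid.

**Transition ordering.** For a labeled subset (CD14⁺ myeloid cells), the
pipeline selects variable genes, embeds them with PCA (5 components), and
builds a k-nearest-neighbor diffusion map (k = 200). The first nontrivial
diffusion component DC1 orders cells along their dominant continuum; the
sign is anchored so MMP9 rises and LYVE1 falls along it, cells are ranked
1..n, and ranks are cut into equal-size bins (30 or 50) for expression
heatmaps.

**Distances and neighborhoods.** Minimum centroid distance to landmark
types (basal keratinocytes ≙ epidermis; CD4/CD8 T cells ≙ immune
aggregates), per-type depth densities, mean expression of a gene among
the neighbors within 400 px of each focal cell, and Nadaraya–Watson
smoothed expression surfaces with quantile-anchored contour levels.

**Synthetic tissue.** A layered skin section (epidermis band, papillary
and reticular dermis) populated by Poisson point processes per cell type,
Gaussian immune aggregates beneath the dermal–epidermal junction, a
latent CD14 transition state `t = clip(a − b·depth + ε)` driving monotone
M1/M2 marker responses, fibroblast chemokine gradients decaying with
distance to the nearest aggregate, and overdispersed negative-binomial
counts. The generator returns the latent truth, so recovery of `t` and of
the aggregate colocalization contrast is testable.

## Worked example

```python
import dermafield as df
from scipy.stats import spearmanr

cfg = df.default_skin_config()
dataset, truth = df.generate_tissue(cfg, seed=1)     # 3,769 cells, 44 genes
dataset, report = df.qc_filter(dataset)              # keeps 3,693 (≥50, surface ≥10)
expr = df.log_normalize(dataset)

mat = df.normalize_coloc_matrix(
    df.colocalization_matrix(dataset, df.KernelParams(sd=400.0))
)
mat.normalized.loc["CD14_myeloid", "CD4_T"]          # -1.6
mat.normalized.loc["CD4_T", "CD14_myeloid"]          # 329.5

ordering = df.order_transition(dataset, expr)        # 476 CD14 cells
t = truth.cells.set_index("cell_id")["t"].reindex(ordering.cell_ids)
spearmanr(ordering.rank, t).statistic                # 0.926

dist = df.min_distance_to_type(dataset, "CD14_myeloid", {"Krt_basal"})
joined, marginals = df.transition_distance_table(ordering, dist)
spearmanr(joined["rank_norm"], joined["dist_px"]).statistic   # -0.901
```

Reading the numbers: the *whole* CD14 population is not enriched around
T cells (−1.6 on a scale where 0 is the sample average and 100 the T
cells' own self-colocalization) — but T cells score 329.5 inside the CD14
field, because the aggregates that contain them are dense in myeloid
cells: the metric is directional by design. The diffusion-map ranking
recovers the generator's latent transition state at ρ = 0.93, and the
transition score falls with distance from the epidermis (ρ = −0.90), the
spatial stratification the tissue model encodes.

The same run, end to end with all outputs on disk:

```bash
dermafield demo --seed 1 --out demo_out
```

## Layout

- `src/dermafield/io.py` — data model (cell table + aligned counts), TSV/Matrix-Market round-trips, pixel↔micron scales
- `src/dermafield/synthetic.py` — tissue config, generator, ground truth
- `src/dermafield/qc.py` — transcript-count filters, log-normalization, variable genes, joint row z-scaling
- `src/dermafield/coloc.py` — Gaussian fields, colocalization matrices, affine normalization, heatmap ordering
- `src/dermafield/spatial_expr.py` — local expression, smoothed maps, contour levels, rolling means
- `src/dermafield/transition.py` — PCA, diffusion map, anchor orientation, equal-size binning
- `src/dermafield/distances.py` — minimum distance to landmark types, depth profiles, joined tables
- `src/dermafield/pipeline.py`, `cli.py` — config-driven orchestration and the `dermafield` command

See `docs/methods.md` for the models, parameter choices, and limitations.
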