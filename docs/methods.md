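# Methods

This note documents the models and procedures dermafield implements, the
parameter choices that matter, what the synthetic tissue does and does
not emulate, and the numerical conventions a user should know before
trusting or comparing results.

## Coordinate and unit conventions

All geometry is computed in pixels. The origin is the top-left corner of
the section image and y increases downward — from the keratinized surface
into the dermis — so `y_px` doubles as a depth proxy. Imaging platforms do
not standardize this; if your sections are oriented differently, flip y
before loading. Micron conversion happens only at reporting time through
a `PixelScale`. Two presets exist because the two printed conversions in
common use disagree slightly: 0.1 µm/px (from a 15 px ≈ 1.5 µm
segmentation expansion; the default) and 0.103 µm/px (from a 400 px ≈
41.2 µm neighborhood radius). Choose per dataset.

## QC and normalization

Cells with fewer than 50 detected transcripts are removed; cells flagged
as surface cells pass at 10. Both thresholds are inclusive minima
(≥50 / ≥10 kept). The lenient path exists because transcription falls as
keratinocytes differentiate toward the surface, and it is keyed on an
explicit `surface_flag` rather than a y-band: position-based flagging is
easy to add upstream, while a flag is unambiguous. The filter is
idempotent and order-independent.

Expression is normalized as `log1p(count · 10⁴ / cell_total)` — the
ecosystem-standard library-size normalization. Zero counts map exactly to
zero and each cell's profile is invariant to rescaling its library.

Variable genes are ranked by variance in excess of a mean–variance
trend: lowess of log₁₀(variance) on log₁₀(mean), residual = standardized
variance. The trend is made leverage-robust: a Theil–Sen line first
identifies genes far above the bulk trend, and the lowess defining the
final trend excludes them. Without this, a hypervariable gene whose mean
sits at the edge of the range drags the local fit through itself and
escapes selection. This selector approximates, but is not identical to,
the variance-stabilizing selection in the large single-cell toolkits.

Joint row scaling (for heatmap panels that must share a color scale)
z-scores each gene across the concatenation of all panels' columns,
using the population standard deviation (divide by n); zero-variance rows
map to zeros.

## Colocalization

Reference cells are Gaussian kernels `exp(−d²/2σ²)`, σ = 400 px by
default, hard-truncated at 3σ. The kernel is unnormalized (maximum 1):
the affine rescaling below cancels any global kernel scale, so a pdf
factor would only obscure the closed-form values; a `normalized_pdf`
mode exists for density semantics. A cell's score is the kernel sum over
reference cells within the truncation radius; the (query, reference)
matrix entry is the **mean** over the query type's cells. Summing
instead of averaging is an equally coherent convention (and some
implementations in the field do sum); dermafield averages, because the
mean makes the aggregate independent of the query type's abundance, and
the affine normalization below pins the self and total values
identically either way.

Normalization, per sample and per reference column:
`s′ = 100·(s − mean_all)/(mean_self − mean_all)`, with `mean_all` the mean
raw score over *all* cells in the sample (reference cells included) and
`mean_self` the mean over the reference type's own cells in their own
field, with each cell's own kernel included (no leave-one-out — a
leave-one-out switch exists, off by default). Columns with
`mean_self = mean_all` (e.g., a single-type sample) are flagged and left
raw. Multi-sample data are normalized within each sample first, then
normalized aggregates are averaged across samples; per-sample matrices
are always retained.

Evaluation is exact by default (k-d-tree truncated summation) up to 50k
cells per section. Grid mode evaluates exact scores on a lattice and
interpolates bilinearly; the public contract caps requested spacing at
σ/4, and the lattice is built internally at half the requested spacing.
The refinement exists because two error sources otherwise approach 1% of
the section maximum in sparse-kernel regimes: bilinear curvature error
(~h²/8·|f″|) and the step of height `exp(−4.5)` ≈ 1.1% of one kernel at
the hard truncation radius. At σ/8 internal spacing the measured
worst-case disagreement with the exact oracle is ~0.6% of the section
maximum over adversarial random configurations.

Heatmap ordering uses agglomerative hierarchical clustering (Euclidean
distance, average linkage) with rows pre-sorted by label so ties and
leaf order are deterministic.

## Transition ordering

The chain for a labeled subset is: variable genes (100 by default, capped
at the panel size) → centered PCA via SVD (5 components; signs fixed so
each component's largest-magnitude loading is positive) → diffusion map →
anchor orientation → ranks → equal-size bins.

The diffusion map builds a symmetric kNN graph (k = 200, capped at n−1;
union of neighborhoods; self-affinity 1), applies a Gaussian kernel
`exp(−d²/(s_i² + s_j²))`, density-normalizes with α = 1 (kernel divided
by the product of vertex degrees), and takes right eigenvectors of the
resulting Markov operator; DC_i is the i-th nontrivial eigenvector scaled
by its eigenvalue. Everything is deterministic: dense symmetric
eigendecomposition up to n = 2000, Lanczos with a fixed start vector
above.

The kernel scales s_i derive from each cell's distance to its ⌈k/3⌉-th
neighbor. By default their **median** is used as a single global
bandwidth. The per-cell variant (`local_bandwidth=True`) adapts to
density gradients but inflates the scale of cells at the boundary of the
state space, which visibly kinks DC1 at the ends of an ordering — on
equally spaced points on a line it breaks the exact monotonicity of DC1
(ρ = 0.9992 instead of 1.0). Density normalization corrects for sampling
density but not for this boundary scale inflation, so the global
bandwidth is the default.

DC1's sign is arbitrary, so the ordering is oriented by anchor genes
(MMP9 up, LYVE1 down by default): the sign is chosen to make the
up-anchor minus down-anchor contrast between the top and bottom DC1
quartiles positive; an exactly zero contrast is an error asking for an
explicit sign. Ranks 1..n follow oriented DC1 with ties broken by cell
id; a [0,1]-rescaled rank is also emitted. Binning cuts ranked cells into
contiguous blocks of size ⌊n/m⌋ or ⌈n/m⌉ with the larger blocks first —
any fixed remainder rule works; this one is documented and tested
(7,200 cells into 50 bins gives exactly 144 per bin). When several
conditions are pooled, one joint ordering is computed and then binned;
per-condition binning is available downstream by subsetting.

Note that batch integration (which the original workflows interleave
with PCA before the diffusion map) is deliberately out of scope; the
synthetic data are single-batch, and real multi-batch data should be
integrated upstream.

## Local expression, smoothed maps, rolling means

Local expression of a gene at a focal cell is the **mean** normalized
expression over neighbor cells within the radius (400 px default),
excluding the focal cell itself — the statistic asks what the
neighborhood produces, not the cell; an `include_focal` switch exists.
The mean (rather than the sum) makes the value independent of local cell
density; users comparing against sum-based implementations should expect
a density factor of difference. An optional neighbor-type filter
restricts who counts as a producer.

Smoothed maps are Nadaraya–Watson surfaces: kernel-weighted mean
expression at each grid node (σ = 400 px, truncation 3σ), masked where no
cell contributes weight. Values are convex combinations of cell values,
hence bounded by the expression range. Contour levels are `n_levels = 6`
values evenly spaced between the 0.9 empirical quantile (linear
interpolation / type-7 convention) of the unmasked surface and its
maximum.

Rolling means along a continuous ordering sort cells by the ordering
score and apply a centered moving average whose window is
`max(1, round(window_prop · n))` cells, shrinking at the edges
(pandas `rolling(center=True, min_periods=1)` semantics). The package
default is `window_prop = 0.1`. A value of 1.0 — a window spanning *all*
cells — is accepted and honored, but it nearly flattens the curve;
helpers in other toolchains that take a nominally identical parameter
may interpret its units differently, so curves should be compared at
matched absolute window sizes.

## Distances and depth

Minimum distances are centroid-to-centroid Euclidean minima over the
union of the target types, via a k-d tree, exact (verified against the
brute-force pairwise minimum). Landmark density deliberately does not
enter: unlike colocalization, distance-to-structure should not reward
dense landmarks. Depth profiles are 1-D Gaussian KDEs of y per type on a
shared grid padded by 5 bandwidths (so the density integrates to 1 within
10⁻³ on the grid), with quartile summaries. The transition–distance
table inner-joins an ordering with a distance table on cell id (warning
when cells are lost) and smooths the transition score along each distance
axis with the rolling mean above.

## Synthetic tissue: what it emulates, what it does not

The generator reproduces the statistical structure the analysis consumes:

- **Geometry.** A 6000×4000 px section; epidermis band (0–400 px) with
  basal and suprabasal keratinocytes, papillary dermis (400–1200 px),
  reticular dermis (1200–4000 px); each layer a homogeneous Poisson point
  process per cell type. Default expected total ≈ 3,800 cells — large
  enough for stable colocalization and diffusion maps, small enough that
  the full test suite and 100-seed recovery checks run in minutes on one
  core. Keratinocytes above y = 120 px are flagged as surface cells and
  draw a 4× reduced library, exercising the lenient QC path.
- **Aggregates.** Three isotropic Gaussian clumps (sd 120 px) just below
  the dermal–epidermal junction, each expecting ~50 CD4 T, 30 CD8 T,
  25 CD14 and 10 fibroblast cells — the scale of lymphocyte aggregates in
  interface dermatitis, and the source of the directional
  colocalization contrast the tests recover.
- **Transition.** Each CD14 cell carries
  `t = clip(1.15 − 1.2·(y/height) + ε)`, ε ~ N(0, 0.05²): t ≈ 1 at the
  junction, ≈ 0 deep in the reticular dermis. Six M1-like genes (MMP9,
  IL1B, TNF, CXCL9, CCR1, CCR5) have NB means linear in t; six M2-like
  genes (LYVE1, MRC1, CD163, SELENOP, F13A1, DAB2) linear in 1−t. Two
  anchor genes alone cannot anchor a diffusion map against
  negative-binomial noise; a panel-scale response is what makes the
  latent state recoverable, and is also what real M1/M2 continua look
  like. Slopes (5–16 counts full-scale) sit in the regime where recovery
  is good (ρ ≈ 0.93) but far from trivial.
- **Chemokines.** Fibroblast CCL2/CCL8 means are
  `base + amp·exp(−d²/2λ²)` with λ = 300 px and d the distance to the
  nearest aggregate center.
- **Counts.** Negative binomial per gene with per-type dispersion
  θ = 2 (variance = µ + µ²/2, strongly overdispersed, as imaging counts
  are); θ = ∞ selects the Poisson limit. Typical libraries are ~100–250
  transcripts over a 44-gene panel.

Not emulated: optical noise, segmentation errors, transcript-decoding
false discoveries, doublets, batch effects, cell shape (cells are
points), anisotropic or curved tissue layers, and within-type expression
correlation structure beyond the shared latent t. Passing recovery tests
therefore demonstrates that the *algorithms* behave as specified on data
matching their generative assumptions — not that those assumptions hold
in any particular real section.

Determinism: one `numpy` generator seeded per call drives all draws in a
fixed order; the same (config, seed) pair is byte-identical across runs
and platforms, and the pipeline as a whole is a pure function of
(config, seed).

## Numerical conventions and degenerate inputs

- Quantiles everywhere use linear interpolation (numpy default, type-7).
- Z-scores use the population standard deviation.
- Hierarchical clustering and diffusion maps break ties by label / fixed
  sign conventions; no randomized algorithm is used anywhere outside the
  generator.
- Degenerate cases are contracts, not crashes: empty reference sets score
  0; a cell type absent from a sample drops its column with a warning; a
  degenerate normalization column is flagged and left raw; an empty
  dataset round-trips; a disconnected kNN graph and an undecidable
  orientation are errors with actionable messages.

## Known limitations

- The colocalization metric has no significance model; scores are
  descriptive (permutation nulls would be a natural extension).
- `mean_all` includes the reference type's own cells — the literal
  reading of "all cells in the sample"; excluding them would shift
  normalized scores by a type-abundance-dependent factor.
- Grid-mode fields trade ~0.6% worst-case error for memory/speed; exact
  mode is the default below 50k cells per section.
- The vst-style gene selector is an approximation (documented above).
- Distances are 2-D centroid distances within a section; boundaries and
  z-planes are out of scope.
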