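# Methods

## Scope and data model

`nichemap` analyzes segmented multiplexed tissue images and their derived
tables. The interchange object is the **cell table**: one row per cell
with `cell_id`, `region_id`, centroid coordinates in pixels and microns,
per-marker intensities, and (after typing) a `cell_type` and optionally a
`cn`/`niche` label. Images enter as an integer **label mask** (one
connected nucleus per positive id, 0 = background) and an aligned
multi-channel **intensity stack**. Nucleus segmentation itself is out of
scope; the pipeline starts at the mask.

Coordinates are pixel-based internally; physical distances use an
explicit `microns_per_pixel` factor (default 0.5 µm/px). The factor is
always required rather than guessed, because imaging setups differ and a
silent default on real data would corrupt every distance.

## Quantification

A cell is defined as the nucleus together with the surrounding rim within
3 px Euclidean distance of the nucleus boundary. `expand_labels` assigns
each background pixel within the radius to its *nearest* nucleus; exact
ties go to the lower label id so outputs are deterministic. The metric is
Euclidean (the common choice in segmentation-expansion pipelines;
Chebyshev would grow squares rather than discs). The per-cell marker
statistic is the **mean** intensity over the expanded area — mean rather
than sum so that the value is invariant to cell area; sum and median are
available via the `aggregator` option. The nucleus interior is included
in the averaged area (the cell *is* nucleus ∪ rim). Centroids use nucleus
pixels only, since the nucleus is the detected object and rim shape
depends on crowding.

## Typing

Marker columns are z-scored with the population standard deviation over
the whole table by default (per-region normalization is a flag; whole-
table is the default because staining batches usually span regions on one
slide). Zero-variance columns become zeros with a warning.

Clustering is Leiden community detection (RB-configuration partition,
fixed seed, two iterations) on a symmetrized k-NN graph (k = 30,
Euclidean) of the z-scored marker vectors. Cluster annotation — in many
published imaging studies a manual, visual step — is an explicit ordered
**gating scheme**: each rule names a cell type, required-positive and
required-negative markers, and a z threshold (default 0.5). A cluster (or
a cell, in the clustering-free `gate_cells` path) takes the first rule
whose positive markers are ≥ threshold and negative markers < threshold
on the mean z-profile; otherwise it is "Unassigned", which is counted,
never dropped. First-match ordering mirrors hierarchical gating practice
and resolves ties deterministically.

On simulated balanced four-type tissue, cluster-then-annotate reaches
the high-90s percent accuracy at a 2-sd marker separation; accuracy is
monotone in separation (tested at 1, 2, 4 sd). Cluster-level annotation
beats per-cell gating at moderate separation because the cluster mean
averages out per-cell noise. Gating against a marker with no genuinely
positive population in the data misfires (the z-scores of pure noise
still have a positive tail) — schemes should only name markers whose
positive population exists in the sample.

## Distances and their statistics

`nearest_target_distance` computes, for each query cell, the Euclidean
centroid distance (µm) to the closest target cell **within the same
region**; cross-region pairs are never formed, matching how tissue cores
are physically independent. Regions without target cells have their
queries flagged and excluded from testing, with a logged count —
exclusion-with-logging rather than imputation. Distances are analyzed on
the raw µm scale (a `log1p` option exists for skew-robustness).

Within one region, two groups are compared with a two-sided Wilcoxon
rank-sum test: exact enumeration when both samples are ≤ 20 without ties,
otherwise the tie-corrected normal approximation. Passing multi-region
data to the Wilcoxon path is an error directing the user to the mixed
model, because pooling regions pseudo-replicates.

Across regions the model is a random-intercept LMM,
`distance ~ group + (1 | region)`, fit by REML (statsmodels `MixedLM`).
All pairwise group contrasts are t-ratios on the fixed-effect
differences. Degrees of freedom use the residual approximation
`n − p − (r − 1)` (p fixed effects, r regions), switching to the normal
reference above 200 residual df; statsmodels does not provide
Satterthwaite df for MixedLM, and at the cell counts this pipeline
targets (hundreds per region) the two references are indistinguishable.
Simulation confirms the operating characteristics at the study scale:
family-wise type-I error ≈ 0.02–0.05 at nominal 0.05 over 200 null
datasets (8 regions × 40 cells, region sd 10 µm, residual sd 15 µm), and
power ≈ 1.0 for a 30 µm shift at 10 regions × 50 cells. Contrast families
are Holm–Bonferroni adjusted.

## Cellular neighborhoods

The window of cell *i* is *i* itself plus its k = 10 nearest intra-region
neighbors (self-inclusion matches the established CN methodology and is a
flag). Neighbor ties are broken by ascending cell id for
bit-reproducibility; regions with ≤ k cells use all their cells. Window
rows are cell-type **fractions** (not counts) so that windows of unequal
size are comparable. Regions up to 2,000 cells use an exact full-sort
path; larger regions use a KD-tree with a padded candidate set before the
same lexicographic tie-break.

Windows are clustered with k-means (k-means++ init, best of 10 restarts,
fixed seed; mini-batch k-means above 2×10⁵ windows). The CN count is
config, not a constant — published analyses have used ~30 CNs grouped
into a handful of niches, and the grouping step (`group_niches`) is an
explicit user-supplied CN→niche table, since that grouping is a judgment
informed by the enrichment matrix and tissue location. Enrichment is the
CN × type fraction matrix z-scored within each type column across CNs
(population sd; zero-variance columns → 0). Niche summaries report
per-location niche frequencies (columns sum to 1), per-niche target-cell
fraction, and distance-to-tumor distributions joined from the distance
module.

## Cohort statistics

Per-sample cluster frequencies apply a strict `total > 35` cell filter
(a 35-cell sample is excluded, a 36-cell sample retained); excluded
samples are logged. Group comparisons of mean frequencies use
log2(mean_A/mean_B) per cluster, with zero means reported as signed
infinities and flagged rather than dropped.

The chi-squared path is the Pearson test without continuity correction,
with post-hoc per-cell margin-corrected standardized residuals
r = (O−E)/√(E(1−row/N)(1−col/N)), two-sided normal p, Bonferroni factor =
number of table cells.

Survival: the signature score of a sample is the mean of the per-gene
z-scores (each gene z-scored across the samples of its dataset); the
score enters a univariable Cox proportional-hazards model as a
**continuous** covariate (no dichotomization), giving a Wald z per
dataset. Datasets are integrated with the √n-weighted Stouffer/Liptak
combination `z_meta = Σ√n_d z_d / √Σn_d` (unweighted Stouffer via flag),
converted to a two-sided p and reported as signed −log10 p carrying the
meta-z sign. Null calibration over 500 simulations puts both the
per-dataset Cox z and the 4-dataset meta-z at mean ≈ 0, variance ≈ 1.

## The synthetic-tissue generator

`simulate_tissue` emulates tissue-microarray cores: each region is an
image (default 600×600 px at 0.5 µm/px ≈ a 300 µm field) with circular
tumor nests. Cell populations are placed per region by one of three
rules: uniform inside a nest (`in_nest`), uniform over the region
(`uniform`), or at a Gaussian-distributed distance from the closest tumor
cell (`ring(d_mean, d_sd)` in µm). Ring placement proposes a point on a
nest boundary offset radially, then corrects it iteratively against a
KD-tree of the placed tumor cells so that the *nearest-tumor-cell*
distance — the quantity the analysis measures — is the planted one;
empirical means land within a few percent of `d_mean`. Nuclei are hard
discs (radius 4 px) placed by rejection sampling with a bounded retry
budget (default 1,000/cell); overlap is forbidden so label masks are
unambiguous, and exhaustion raises an error naming the crowded type.

Marker intensity is per-pixel Gaussian background (mean 5, sd 2, clipped
at 0) plus a per-cell log-normal signal painted over the nucleus disc.
The marker model is a (type, marker) table of log-intensity mean and sd;
the helper `make_marker_model` places a type's positive markers at
`base + s·σ` and negatives at `base − s·σ` in log space (σ = 0.25,
base = 3.9 ≈ intensity 50), so the separation parameter `s` is the
half-gap between positive and negative populations in units of the
within-population log-sd. Ground truth records each cell's type and a
geometric niche id: inside a nest, within a 60 µm peri-nest band, or
distal — three spatial niches with distinct composition that the CN
pipeline should recover (observed ARI ≈ 0.9 at default conditions).

Default study conditions: 3 regions × 1,000 cells (42% tumor, three
macrophage populations at planted distances 36–38 µm near / 100 µm
distal, the remainder uniform stroma). The balanced
`typing_tissue_config` (4 × 250 cells/region) is used for typing
benchmarks, because population-wide z-normalization compresses the axis
of a dominant type and typing accuracy is then a property of the type
mix, not of the classifier.

What the generator does **not** emulate: nucleus morphology beyond discs,
optical PSF/autofluorescence, staining batch effects, irregular nest
shapes, or spatial correlation of marker noise. Passing tests therefore
demonstrate correctness of the computations and calibration of the
statistics under the stated model — not robustness to the full messiness
of real stains.

Cohort generators: per-sample cluster counts are Dirichlet-multinomial
(concentration 80) with group means shifted so a planted log2 ratio is
exact in expectation for the shifted clusters (the unshifted clusters
absorb a common renormalization; planted clusters should be minor
fractions for the ratio to be cleanly interpretable). Survival cohorts
draw a latent score u ~ N(0,1) per sample; signature genes load on u with
residual sd 0.5, noise genes are independent; event times are exponential
with hazard ∝ exp(β·u) and censoring is an independent exponential
calibrated to the requested null censoring fraction.

## Determinism and numerics

All randomness flows from a single integer seed per generator call
(NumPy `default_rng`); Leiden and k-means take explicit seeds; k-NN ties
are id-broken. Two runs of the full pipeline with the same seed produce
bit-identical masks, tables, labels and statistics (verified by hashing
every intermediate). Z-scores use population sd throughout; zero-variance
columns normalize to zeros with a warning rather than NaN. Wilcoxon
switches exact↔asymptotic at n = 20 per the usual enumeration-cost
boundary. Mixed-model fits on strongly separated groups can report
boundary/singular random-effect warnings from the optimizer; estimates
and contrasts remain valid and are exercised in the calibration suite.

## Validation experiment sizes

The reproduction script (`scripts/acceptance.py`) uses: typing accuracy
on 3,000 balanced cells; CN recovery over 5 seeded tissues; distance
ordering over 50 two-region replicates; frequency-ratio recovery at 50
samples/group; 200 null and 100 shifted LMM datasets; 500 null Cox and
500 null meta-z simulations; and two full pipeline runs for the
reproducibility digest. These sizes give Monte-Carlo error comfortably
inside the bands being checked while keeping the full run at roughly two
minutes on one CPU.
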