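# Methods

This note documents the models, estimators, and numerical choices
behind `oncosyn`, and what the synthetic-data tests do and do not show
about real data.

## Study design and data model

The pipeline targets a 2×2 genetic design observed longitudinally:
wild type (`WT`), two single lesions (`A`: constitutive signaling
activation; `B`: loss of a repressive chromatin regulator), and the
double mutant (`AB`), each profiled by droplet scRNA-seq of
stem/progenitor-enriched bone marrow at three disease stages
(`T1`–`T3`). All per-cell measurements are UMI counts; expression is
analyzed as `log(1 + 10^4 · count/total)` (natural log,
counts-per-10k). This is the UMI analogue of log-transformed TPM:
3′-tag data has no length component, so depth normalization is the
only sensible within-cell scaling.

## Synthetic data generator

`oncosyn.simdata` draws counts from a gamma–Poisson (negative
binomial) model over a rooted tree of cell states (default: an
11-state hematopoietic hierarchy rooted at HSC/MPP with
erythro-megakaryocytic, granulo-monocytic, and lymphoid branches).

* **State programs.** Each gene has a log-normal baseline mean
  (median ≈ 0.5 counts/cell); each state boosts its 25 marker genes
  8-fold and damps other states' markers 8-fold, giving cleanly
  separated programs like real lineage markers (which commonly span
  1–2 orders of magnitude between on- and off-states).
* **Continuum of intermediates.** Each cell carries a position `u ∈
  [0,1]` drawn from Beta(2,1). A state occupies a *star* in program
  space: the committed half of the edge from its parent (log-linear
  interpolation weight `w = 0.5 + 0.5u` toward its own program) plus,
  for half of its cells, the first half of an outgoing edge toward a
  child (`w_out = 0.5(1−u)`). Every cell is therefore closest to its
  own state's program — so state labels are well defined — while
  adjacent states are bridged by intermediates with no density gap.
  An earlier design that interpolated the full parent→child edge made
  low-`u` cells expression-identical to the parent, which caps
  nearest-neighbor label transfer near 85% for reasons of label
  semantics, not method quality.
* **Genotype effects.** Composition: per-sample state-frequency
  simplex vectors; defaults tilt the myeloid branch up under `A`,
  HSC/MPP up under `B`, and additionally MEP/Meg up — progressively
  with time — under `AB`. Expression: per-gene additive log-effects
  for `A` and `B` and an interaction log-effect applied only in `AB`,
  optionally ramped over time. The default design plants ten
  HSC/MPP-marker genes with interaction effect +1.0 (well-expressed,
  baseline 2 counts/cell before the marker boost) plus 60 additive
  background effects of ±0.5.
* **Noise.** NB dispersion (size) 10 — a typical UMI value, variance
  ≈ μ + μ²/10; log-normal library factors (σ = 0.35); 5% doublets
  formed by summing two independently drawn same-sample cells; 2%
  mitochondrial outliers with the ten `mt-` genes inflated to a
  12–30% transcript share (inlier share 4%).
* **Reproducibility.** One seed fans out to per-sample substreams via
  `numpy.random.SeedSequence`; identical configs are bit-identical.

Not emulated: ambient RNA, batch effects, cell-cycle structure, and
gene–gene correlation beyond state programs. Passing tests therefore
demonstrate correct recovery under a clean hierarchical NB world —
they bound implementation error, not robustness to real-data artifacts.

## QC

Cells with a mitochondrial transcript share strictly above 0.10 are
removed (a cell at exactly the threshold is retained); zero-count
cells are removed and reported separately. Doublet scoring is a
simplified simulated-doublet method: synthesize `⌈n_sim_frac·n⌉`
artificial doublets by summing random cell pairs, co-embed (log1p
CP10k, PCA fitted on observed cells, 30 PCs), and score each cell by
the simulated-doublet odds among its 30 nearest neighbors, rescaled by
the simulation ratio and mapped to `ρ/(1+ρ) ∈ [0,1]`. The flagging
threshold sits at the minimum-density valley of the simulated-score
histogram, falling back to 0.25 when no valley exists. Same-state
("embedded") doublets are not detectable by construction — the
benchmark therefore plants cross-state doublets, which is what the
method can and should catch.

## Reference atlas and projection

The reference is fit on wild-type cells pooled across time points:
HVG selection by dispersion (variance/mean of log-normalized
expression) z-scored within 20 equal-count mean bins; per-gene
z-scoring whose means/SDs are frozen into the model; PCA to 50
components (full SVD, deterministic); a k=15 kNN graph; Louvain
communities at resolution 1.0 (igraph, seeded). Cluster merging uses
average-linkage agglomeration on 1 − Pearson correlation of cluster
mean profiles, restricted to adjacent cluster pairs (≥1% of the
smaller cluster's kNN slots crossing between them), stopping below a
0.6 correlation. Correlations are computed on *gene-standardized*
profiles: raw log-mean profiles of unrelated branches correlate above
0.75 because ubiquitously expressed genes dominate, which would merge
everything; standardizing each gene across clusters puts unrelated
branches near zero and sub-clusters of one state near one.
Populations are annotated by the argmax over marker sets of mean
z-scored marker expression; duplicated winning labels get
"-early"/"-late" suffixes ordered by distance from the root-most
population.

Mutant cells are log-normalized, restricted to the reference HVGs
(missing genes imputed as zero before standardization), z-scored with
the *reference* scaler, rotated by the reference loadings, and labeled
by their single closest reference cell (Euclidean; ties to the lowest
reference index). Re-fitting the scaler per mutant sample would break
the shared space, so the reference parameters are used throughout.

## Differential expression

Two-sided Mann–Whitney U per gene on log-normalized expression (exact
null when both groups ≤ 8 and untied, else normal approximation with
tie and continuity correction), BH correction per comparison,
significance at adjusted p < 0.01, restricted to genes detected in
more than 3 cells of the two groups pooled. Groups below 20 cells are
skipped and reported. Within-state comparisons test wild type against
each mutant genotype per state at matched time points; between-state
comparisons test all unordered state pairs within a genotype (a
one-vs-rest mode exists). The scientific logic: a genuinely new
mutant cell state would make within-state counts approach
between-state counts.

## Trajectory analysis

Diffusion pseudotime on the pooled (reference + projected) embedding:
symmetric kNN graph (k=15), Gaussian kernel with adaptive bandwidth
(distance to the ⌈k/2⌉-th neighbor, making pseudotime invariant to
uniform rescaling of the embedding), **anisotropic density
normalization (α = 1)** — without it a low-density bottleneck
dominates the relaxation spectrum and the scaled diffusion distance
degenerates to a step function — then row normalization,
eigendecomposition of the symmetric conjugate (deterministic start
vector), and pseudotime as the Euclidean distance from the root cell
in the space of the first 10 non-stationary components scaled by
λ/(1−λ). The root cell is the root-state cell closest to its state
centroid — deterministic and logged. Cells in graph components not
containing the root get τ = ∞ and are excluded from ranking. Ranks
are percentiles (0–100) within the lineage-restricted all-genotype
pool; density comparisons use a reflected Gaussian KDE (bandwidth 3
rank units; reflection at 0 and 100 keeps each density's mass on the
interval to <10⁻³), enrichment where a mutant's density exceeds
(1+δ)×WT with δ = 0.2, and the composition of mutant cells inside
enriched intervals.

## Interaction score

For each gene, `I = d_obs − d_exp` with `d_exp = dA + dB`, all deltas
being differences of mean log-normalized expression against the same
wild-type sample at that time point. Significance uses a permutation
null pooled over permutations with three schemes:

* **swap (default)** — per gene, randomly exchange which value is
  "observed" and which "expected"; the null scores are sign flips of
  the per-gene scores. Observed and null scores are exchangeable under
  the global null, so the two-sided 5% cut calls exactly 10% of genes
  on null data — this is the only scheme whose calibration is a
  construction-level property.
* **independent / paired** — shuffle the gene order of the two change
  vectors (independently, or only the observed one). These break the
  within-gene covariance induced by the shared WT and single-mutant
  means: `Var(d_obs_i − d_exp_j) = 8σ²/n` across random pairs versus
  `Var(I) = 4σ²/n` for the observed score, so the null is wider and a
  pure-noise simulation yields ~2% called instead of 10%. They are
  retained for sensitivity analyses, and the pooled independent null
  for small gene sets is exactly enumerable (all pairwise differences),
  which the tests exploit as an oracle.

Effect-recovery benchmarks plant ±1.0 log effects on well-detected
genes (baseline 12 counts/cell up, 12e down) with up/down baselines
balanced so the double mutant's expected library size matches wild
type. Two systematic biases otherwise contaminate recovery under
relative (counts-per-10k) normalization: a compositional shift
(~log of the library inflation, ≈0.2 for 50 unbalanced strong genes)
and log1p concavity (≈0.3/λ for baseline λ). With the balanced design
the measured bias is ≈0.01 at 5000 cells/genotype.

The change decomposition for a gene set,
`total = Σ_s f_s^m μ_{g,s}^m − Σ_s f_s^WT μ_{g,s}^WT`,
`composition = Σ_s (f_s^m − f_s^WT) μ_{g,s}^WT`,
`expression = Σ_s f_s^m (μ_{g,s}^m − μ_{g,s}^WT)`,
is an exact algebraic identity (verified to 10⁻¹²); states present in
only one genotype contribute with the missing side's mean set to zero
and are flagged.

## Co-expression

A cell co-expresses a pair iff both genes exceed the expression
threshold (default: UMI count > 0). Groups are downsampled without
replacement to 1000 cells for 10 iterations; the iteration mean is an
unbiased estimate of the finite-population fraction. The
cross-iteration t-test mirrors the conventional figure statistic but
is anti-conservative (iterations overlap); a label-permutation test on
the full-sample fractions is provided and preferred.

## Random-forest screen

Stage 1 fits a 500-tree forest on all expressed genes and ranks genes
by mean impurity decrease; stage 2 refits on the top 1000 with
stratified 5-fold CV. Class imbalance is handled by stratification
only. Feature selection happens outside the CV loop (as is
conventional for this screen), which leaks a little optimism into the
CV estimate at small sample sizes; the shuffled-label chance baseline
is therefore computed on a class-balanced subsample, where chance is
1/n_states. Candidate nomination requires all three of: Pearson
correlation ≥ 0.3 between a gene's expression and the HSC/MPP class
probability across double-mutant cells, a synergistic interaction call
in the HSC/MPP subset, and a positive AB-vs-WT fold change there;
candidates are ranked by correlation × interaction score.

## Problem sizes and determinism

Validation scenarios use 2000 genes with 2000 cells/genotype for
interaction recovery and calibration (5000 for the bias check), 6000
wild-type cells for projection, 600 cells/sample for the DEG and
screen benchmarks, and a 2000-cell 5-state chain for pseudotime —
sizes at which the measured quantities are stable across seeds while a
full validation sweep stays inexpensive. All randomness flows from
explicit seeds; the pipeline writes a manifest of config hash,
per-stage seeds, and output checksums, and an unchanged rerun
reproduces identical checksums for every stage.

## Known limitations

* The doublet caller omits the collision-rate calibration of the full
  published strategy; it is a pre-filter, not an estimator of doublet
  rates.
* Label transfer detects no states absent from the reference; the
  within/between DEG analysis is the designed fallback for that case.
* The interaction score is a difference of means: genes expressed in
  few cells have noisy scores, mitigated only by the detection filter.
* Trajectory analysis assumes the lineage of interest is connected in
  the kNN graph; disconnected cells are reported, not imputed.
* Pseudotime quality degrades gracefully but measurably below ~1000
  cells per lineage; the chain benchmark's ρ ≥ 0.9 holds at 2000 cells.
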