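# Methods

`germnet` reconstructs two layers of a germ-layer differentiation experiment
from gene-level read counts: the trajectory map (how expression profiles of
ectoderm-, mesoderm- and endoderm-directed time courses relate to each other
and to external datasets) and the regulatory network implied by promoter
motif content and motif-activity time courses.  This note records the models,
the tunable parameters, the synthetic data the tests run on, and the design
choices made where the procedure was genuinely open.

## Normalization

Counts are never corrected for transcript length — only relative changes
across samples matter.  Two stages:

1. **Gross**: reads per million aligned reads (rpm), using per-sample total
   aligned read counts (which may exceed the matrix's column sums).
2. **Fine**: residual per-sample factors.  For genes highly expressed on the
   reference profile, per-gene log2 ratios (sample − reference) are ordered by
   reference expression, smoothed with a running median, and the sample is
   rescaled by 2^(−median of the smoothed ratios) so the ratios match the
   identity line.

Parameters (all config keys): pseudocount 1 rpm for every log transform and
fold ratio (bounded behavior at zero counts); high-expression floor 32 rpm;
running-median window 101 genes; reference profile = per-gene geometric mean
of rpm across samples.

Two deliberate choices make fine normalization exactly idempotent: the
high-expression mask is evaluated on the *reference* profile (geometric-mean
rpm > floor) rather than per sample, and the factors are renormalized to
geometric mean 1.  Together these leave the reference profile — and hence the
gene mask and gene ordering — fixed under re-normalization, so a second pass
returns factors of exactly 1.  A per-sample mask ("above the floor in every
sample") can flip membership of borderline genes after rescaling and is
therefore not used.

A consequence worth knowing: any global per-sample expression shift is
unobservable in count data (sequencing measures relative abundance), and
median matching anchors each sample to its typical stable gene.  The
procedure presumes most highly expressed genes are not differential, which
holds in the data it is designed for and in the synthetic generator (see
below).

## Differential sets and trajectory map

A gene is differential over a sample subset if its maximal rpm exceeds 3 and
its pseudocounted max/min ratio reaches 4 (inclusive boundary — deterministic
and documented).  Per-condition sets use the condition's full time course
plus the shared day-0 baseline; three conditions yield seven Venn regions.
Extremes are taken over all samples of the subset, replicates included;
replicates stay separate through normalization.

Clustering is average linkage over samples; the distance is 1 − Pearson on
log2 expression of the filtered genes (Euclidean available).  PCA treats
samples as observations of gene-centered log2 expression, decomposed by SVD;
variance fractions come from the squared singular values.  External profiles
are projected by centering with the *training* means and multiplying onto the
loadings restricted to shared genes (≥ 50 % overlap required, configurable;
no re-orthonormalization) — this preserves the coordinate frame so external
samples land where comparable training samples sit.  Cross-platform inputs
are first harmonized: microarray intensities are quantile-matched to the
sequencing distribution (each value replaced by the reference quantile of its
within-sample average rank); spatial-transcriptome sections are per-gene mean
centered.  Probe sets collapse to genes by highest mean intensity.  Named
variation-filter presets: `episc` (16-fold within any in-vitro lineage) and
`geoseq` (the 16-fold clause AND 8-fold across embryo sections).

## Promoter scanning

Motifs are JASPAR position frequency matrices.  Log-odds against a uniform
background use a pseudocount of 0.8 distributed by background probabilities
(finite scores, standard magnitude).  Both strands of the 1 kb upstream
region are scanned; a window is a site when its score reaches 0.80 of the
motif's maximum achievable score — a widely used relative-score convention,
exposed as `--rel-score`, since no absolute threshold is canonical.
Overlapping hits all count (no greedy masking); windows containing N are
skipped; longer input is trimmed to the proximal 1 kb.  N holds counts by
default with a `--binarize` switch; edge inference only ever uses presence.

## Motif activities and significance

Per sample `s`, ordinary least squares of log2(rpm+1) on the site-count
columns plus an intercept:

    log2_expr[g, s] = c[s] + Σ_m N[g, m]·A[m, s] + ε[g, s].

`A[m, s]` is the motif activity (log2-expression units per site); `c[s]`
absorbs per-sample shifts, so activities are invariant to adding a constant
to any sample.  Fits are independent across samples with a shared design.

Transcription factors enter as candidates only if expressed above 6 rpm
maximal; a dimer motif (Fos::Jun) requires *every* constituent gene to pass —
the conservative reading.

Significance is the package's central interpretive decision and is isolated
in one function for replaceability: per-sample forward selection in residual
space.  At each step the candidate with the greatest residual-variance
reduction is scored by the F-test of its coefficient (1 numerator df);
it is admitted if its p-value, Bonferroni-corrected for the number of
remaining candidates, is below alpha (default 0.01), otherwise selection
stops.  A motif's overall p-value is its best corrected p over samples;
the selected set is the union of per-sample admissions; alpha ≥ 1 is the
degenerate no-filter case and selects everything.  After selection,
activities of all selected motifs are refit jointly in every sample so each
node carries a complete activity trajectory (the alternative — activities
defined only where admitted — would leave gaps in the time courses the
network step correlates against).

Calibration (checked by simulation in the test suite): under pure noise the
per-candidate false-selection rate stays well below alpha-level bounds
(measured ≈ 0.002–0.005 per motif at alpha 0.01 over 200 simulations of
400 genes × 20 candidates × 6 samples); a planted motif with activity
amplitude 4× the residual noise is selected essentially always.  The
per-simulation family-wise rate across many samples is *not* bounded by
alpha — each sample runs its own Bonferroni — which is why calibration is
stated per candidate motif.

## Network inference and census

Nodes are the selected motifs.  A directed edge regulator → target requires
(i) ≥ 1 predicted site of the regulator motif in the target gene's promoter
and (ii) |Pearson r| between the regulator's activity trajectory and the
target gene's log2 expression strictly greater than 0.8 (an epsilon guard
makes the strict boundary deterministic under floating point).  Positive r
is inductive, negative inhibitory; the correlation is the edge weight.
Self-edges are excluded by default (`--allow-self` exists).  A dimer target
qualifies through any constituent gene carrying a site; the
strongest-correlated qualifying constituent defines the edge.  Correlations
run over the same samples used for activity fitting.

Feed-forward loops are all ordered triples a→b, b→c, a→c of distinct nodes,
with per-edge signs available for coherence classification.  Dense
overlapping regulons are maximal groups of ≥ 2 regulators sharing ≥ 3 common
targets (no strict superset still qualifies); both minima are configurable
because no formal DOR criterion is canonical — the defaults identify the
planted DOR of the synthetic fixtures uniquely.  Exports: SIF and GraphML
with deterministic ordering (nodes lexicographic, edges by regulator then
target), plus a TSV edge table.

## Enrichment

The overlap of a gene set with a hit list is compared against resampled
same-size subsets of the gene pool drawn without replacement;
p = (1 + #{null ≥ observed}) / (resamples + 1), never zero.  The default
pool is all genes passing the expression filter.  Across sets, p-values are
BH-adjusted.  At 10⁵ resamples the empirical p agrees with the
hypergeometric tail within Monte-Carlo error (tested).

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

- **Promoters**: 1 kb i.i.d. uniform ACGT; for a regulated fraction of genes
  (default 0.5), Poisson(0.5)-many occurrences per motif sampled from the
  PFM's column probabilities, placed non-overlapping on a random strand.
  Unregulated genes model the stably expressed majority that median-matching
  normalization relies on.
- **Activities**: logistic (or piecewise-linear) trajectories per motif and
  condition, anchored so all conditions share each motif's day-0 value (one
  undifferentiated starting population), with a per-motif baseline.  Default
  assignment alternates common-program motifs (same shape in all conditions)
  with lineage-specific ones — the structure that puts the shared program on
  PC1 and lineage divergence on PC2/PC3.
- **Expression**: log2 L = c_s + Σ N·A + per-gene baseline offset
  (sd 1.0 log2, a constant gene effect widening the dynamic range) +
  Gaussian noise (sd 0.5); counts are Poisson (optional gamma
  overdispersion) with means proportional to 2^L at ~2 × 10⁶ reads/sample.
  Three conditions × 8 days × 2 replicates by default.
- **Cross-platform**: a monotone power-law intensity transform with additive
  noise stands in for microarray data.

The documented five-edge recovery scenario plants three inductive and two
inhibitory TF→TF couplings among ten motifs over 16 samples.  Inhibitory
couplings are generated by writing target expression directly as
intercept + w·A_regulator with w < 0 (the nonnegative N·A model cannot
produce anticorrelation); sites are planted independently, which is exactly
how anticorrelated regulator/target pairs arise in real data.  Background
motif amplitudes cancel pairwise so the median gene carries no net trend,
and the baseline intercept is constant across samples — a global per-sample
intercept is unobservable in depth-normalized counts and would only inject
an artificial common mode into every gene profile.

What passing tests therefore show: the pipeline recovers activities, edges,
signs, factors and trajectory structure when its model assumptions hold and
most genes are stable.  What they do not show: robustness to
transcript-isoform effects, GC/length biases, batch structure beyond a
per-sample scale, chance promoter matches being biologically inert, or motif
databases whose PFMs differ from the sites actually bound — real-data
caveats outside the generative model.

## Numerical choices and scale

Degenerate inputs raise typed errors early: duplicate gene ids, non-positive
aligned totals, constant vectors under correlation, rank-deficient site
designs (collinear motif groups are listed), too few high-expression genes.
Forward selection skips candidates whose orthogonalized norm is numerically
zero.  All randomness flows through seeded `numpy` generators; identical
seeds give byte-identical serialized outputs.

Problem sizes used by the test suite and `scripts/acceptance.py` — 2,000
genes × 20 motifs × 16–48 samples for recovery, 200 null and 100 power
simulations at 400 genes × 20 candidates × 6 samples, 10⁵ enrichment
resamples, and 100 random scanner pairs — are the package's chosen
desk-scale study conditions; they complete in well under a minute each on a
single core.
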