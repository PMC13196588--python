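# Methods

This note documents the models, estimators, default parameters and
numerical choices behind `phage_evo`, and what the synthetic-data
generators do and do not emulate.

## Resistance scoring and threshold calibration

The relative-bacterial-growth score of a strain × phage interaction is
the ratio of endpoint OD600 gains with and without phage over a fixed
assay window (8 h by default, 16 h for slow growers). A negative
phage-well gain (lysis below the inoculum density) is clamped to 0 and
flagged: growth below the starting density is complete sensitivity by
the score's semantics. Values above 1 (phage-stimulated growth or
control underperformance) are preserved. A non-positive control gain
leaves the score undefined and raises.

Class boundaries are calibrated from the empirical distribution of
per-cell mean RBG rather than fixed a priori, because the distribution
is strongly bimodal — most interactions are nearly fully sensitive or
nearly fully resistant. The procedure:

1. Gaussian KDE with Silverman's rule-of-thumb bandwidth (exposed as a
   parameter), evaluated on a 512-point grid. The grid extends three
   bandwidths beyond the data range, matching the evaluation window of
   R's `density()`; without this padding a mode close to the data
   extreme sits at the grid edge and cannot be detected as a local
   maximum.
2. Local maxima with prominence ≥ 1% of the peak density are candidate
   modes; the two highest are taken. Fewer than two modes raises a
   unimodality error — no thresholds are issued for unimodal data.
3. The valley is the density argmin strictly between the two modes; on
   an exactly flat plateau the midpoint of the argmin set is used.
4. The valley is bootstrapped (resampling the values with replacement,
   1000 iterations by default; resamples whose density turns out
   unimodal are dropped) and the percentile 95% CI, rounded outward to
   two decimals, gives the sensitive/resistant class bounds. Scores at
   or below the lower bound are sensitive, at or above the upper bound
   resistant, and intermediate between them (outer boundaries
   inclusive).

Cross-resistance is summarised at the receptor-group level. The
denominator for a source group counts strains that were selected by a
phage of that group and are resistant to that selecting phage; the
numerator counts those also resistant to the target group's phages —
under the default `all` rule, to every phage of the group (`any` is
available; intermediate calls never count as resistant). An empty
denominator is reported as undefined, not 0%. Strain profiles are
ordered by agglomerative clustering (Euclidean distance, average
linkage, scipy); missing cells are imputed with per-phage means and
flagged. The ordering is deterministic given the input row order.

## Growth kinetics

μ_max is estimated as the maximum over sliding windows (default 5
points) of the least-squares slope of ln(OD − blank) against time, with
the blank-corrected OD floored at 1e-6 before the log. This estimator is
deliberately transparent — it is checked exactly against a brute-force
fit of every window — rather than a parametric logistic or Baranyi fit.
AUC is the trapezoidal integral of blank-corrected OD (negatives clamped
to 0) on the raw sampling grid; the endpoint OD change is computed on
the uncorrected series over a configurable window (0–8 h by default).
Blank correction is off by default (blank = 0), configurable.

Two optional robustness settings, both off by default, address a known
failure mode of max-window log-slopes on noisy data: additive OD noise
near the detection floor makes the log-slope of early windows an
extreme-value statistic that can dominate the maximum. `smooth_points`
applies a centered moving average before the log, and `min_od` restricts
the window search to windows whose blank-corrected OD stays at or above
a floor. The recommended protocol for noisy plate-reader data is
`smooth_points=5, min_od=0.05` (about ten times a typical 0.005-OD read
noise); these trade a small saturation bias (the eligible windows sit
slightly into the logistic shoulder) for a large variance reduction.
Relative fitness (mutant μ_max / wild-type μ_max) should additionally be
averaged over replicate wells and, as in phenotype-level designs, over
strains sharing a phenotype; the recovery tests use a 25-strain panel
with triplicate wells, which bounds the error of a true ratio of 0.9 to
about ±0.015.

Group comparisons of AUC use pairwise two-sided Welch t-tests with raw
p-values (optional Benjamini–Hochberg). Zero-variance degenerate groups
map to p = 1 for equal means and p = 0 otherwise, so identical groups
compare as expected instead of returning NaN.

## Fitness metrics

Competition fitness W is the ratio of the log fold-changes of the two
competitors. The resistant proportion at 24 h comes from a 20-colony
phenotype sample; 0/20 and 20/20 splits receive a Haldane–Anscombe
+0.5/+0.5 continuity correction by default (disable to raise instead).
Initial densities are taken from separate plating of each strain, not an
assumed 50:50 mix. A wild-type fold-change ≤ 1 leaves W undefined
(flagged) since the denominator's sign would flip the interpretation.
EOP reports 0 with a below-detection flag and the detection-limit upper
bound when no plaques form; adsorption rates are clamped to [0, 1] with
a warning when titration noise puts the free titer above the input.

## Mutation analysis

The loss-of-function filter retains nonsense, missense, frameshift and
large-indel calls at or above a 5% population frequency, following the
screen's convention of treating missense receptor mutations as
function-disrupting (broader than a strict LOF definition). "Large"
indels default to ≥ 30 bp — observed resistance deletions are either
1–2 bp frameshifts or ≥ 78 bp — and records carrying an explicit indel
length are re-classified against the threshold at filter time.
Background subtraction removes calls matching an ancestral record on
(gene, nucleotide change); coordinates are not required so flat TSV
inputs without positions still subtract correctly.

The genome-diff reader maps breseq mutation lines onto the closed type
vocabulary: SNP classes follow the annotated `snp_type`; DEL/INS below
the large-indel threshold become frameshifts when in a coding region
with length not a multiple of 3, otherwise `other`; mobile-element
insertions count as large indels. Evidence lines (RA/MC/JC/UN) are
skipped; unmappable mutation lines are kept as `other` with a warning.

The built-in receptor-class map is phenotype-based: rfb-cluster and rfc
lesions remove the O-antigen only; deep rfa-cluster lesions (rfaF, rfaG,
rfaI, rfaJ) and the regulator rfaH truncate the core and with it the
O-antigen ("both-LPS"); rfaP, rfaK, and the sugar-precursor genes pgm
and galE alter the core only (hldE is mapped core-only by pathway
analogy and marked inferred); btuB is its own class. rfaJ is
allele-dependent: the missense alleles A198V, L229P, A275E and D216E
modify the core without losing the O-antigen and override to core-only.

Trajectories aggregate population records per replicate, timepoint and
gene (or class), combining multiple alleles of one gene by `max`
(alternative sweeps) or `sum-capped` (co-occurring lesions, capped at
1); absent timepoints are frequency 0. Sequential acquisition takes the
per-timepoint median across replicates and reports, per class, the first
timepoint at or above the dominance threshold (default 0.5), ordering
classes by crossing time and flagging ties.

## Tn-seq enrichment

Counts are normalised per million of each library; enrichment is
log2(mean CPM infected + pseudocount) − log2(mean CPM control +
pseudocount) with a default pseudocount of 1 CPM. Significance uses a
two-sided two-proportion z-test on replicate-pooled counts versus pooled
library sizes, with Benjamini–Hochberg q-values across genes; degenerate
genes (zero in both conditions, or identical proportions) get p = 1.
This is a deliberately transparent substitute for full insertion-
sequencing pipelines, sufficient for planted-signal designs; because
enrichment reweights a closed library, log2FC values saturate once the
planted genes dominate the infected library, so rank order and
significance — not the fold-change magnitudes of any particular external
pipeline — are the meaningful readout.

## Synthetic data

All generators are pure functions of a `SimulationConfig`; the single
seed fixes every output bit-for-bit via per-generator substreams.
Defaults encode the assay designs the analyses assume:

- **Growth**: logistic curves (r = 0.8 h⁻¹, K = 1.0 OD, N0 = 0.01 OD)
  read every 30 min for 24 h in triplicate, with additive Gaussian read
  noise (sd 0.005 OD, clipped at 0). Under phage, sensitive strains stay
  flat at the inoculum (optionally declining), resistant strains grow as
  the control. Lag phases can be emulated via N0; no mechanistic
  phage–host dynamics (adsorption, bursts) are modelled.
- **RBG screen**: 180 strains × 8 phages × 3 replicates with Beta-
  distributed scores around modes 0.034 and 0.977 (concentration 200),
  converted to endpoint absorbances. `gen_interaction_rbg` draws each
  cell independently resistant with probability 0.39 (the approximate
  resistant-cell fraction of the screen); `gen_study_rbg_table` is a
  synthetic stand-in for the full screen that plants its marginal
  structure exactly — 80/40/60 strains selected per receptor group,
  76/37/53 focal-resistant (166/180), complete same-receptor
  cross-resistance, 34/76 core→O-antigen and 8/37 O-antigen→core
  cross-resistance, none to or from BtuB.
- **Sweeps**: logistic allele-frequency trajectories
  f(t) = f0·e^{s(t−onset)} / (1 + f0·(e^{s(t−onset)} − 1)) with s = 7
  day⁻¹ and f0 = 0.01, LPS onset day 0 and btuB onset day 3, observed as
  binomial draws at depth 100 at 12 h and days 1, 3, 5, 7 in triplicate
  — reproducing the observed kinetics (LPS alleles near 90% by day 1,
  btuB fixing between days 5 and 7).
- **Competition**: wild type grows 10⁴-fold in 24 h, the resistant
  strain 10^(4·W)-fold with true W = 0.93; 20-colony binomial
  phenotyping.
- **Tn-seq**: 500 genes with gamma-distributed library weights, 10
  planted enriched genes reweighted ×2¹², multinomial libraries of 10⁶
  reads, 3 replicates per condition.

Passing tests on these data demonstrate that the estimators recover
their generating parameters under the assays' sampling designs and
noise scales; they do not validate biological assumptions the
generators idealise (no plate effects, no well-to-well contamination,
no evaporation drift, binomial rather than overdispersed read
sampling, independence between cells of the interaction matrix).

## Workflow

A single YAML config drives the stage chain simulate → kinetics → rbg →
fitness → mutations → tnseq. Validation reports all schema violations at
once and runs before any stage; a stage failure aborts the stages after
it while preserving completed outputs; a manifest (config snapshot,
SHA-256 input digests, seed, version, per-stage output paths, collected
warnings) is written last. Re-running an unchanged config over unchanged
inputs reproduces every output digest because all randomness derives
from the config seed.

## Problem sizes in the test suite

The suite runs the full 180 × 8 × 3 screen, 1000-iteration bootstraps
where calibration outputs are asserted, 500-assay competition
round-trips, 20-seed sweeps for ordering/valley invariants, and
500-gene × 6-library Tn-seq tables; the whole suite completes in well
under a minute on one CPU.
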