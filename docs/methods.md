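# Methods

## The featurization chain

The pipeline treats pathways as a shared vocabulary between drugs and
cell lines. A drug "acts" on a pathway when its target-gene set
intersects the pathway's gene set — a deliberately permissive definition,
since curated drug→pathway effects are scarce. The indicator matrix D is
refined by the pathway–pathway Jaccard matrix P through D̃ = DP, so a
drug that directly hits pathway k also receives credit on pathways that
share genes with k, proportional to the overlap. The pair score
a_ijk = (d_ik·d̃_jk + d_jk·d̃_ik)/2 is symmetric by construction and zero
on any pathway neither drug hits directly (d_ik = d_jk = 0 forces both
terms to zero). Because p_kk = 1 and all entries are non-negative,
D̃ ≥ D elementwise; both facts are enforced by tests against brute-force
triple-loop evaluation.

Coverage filters precede the algebra: drugs need ≥ 10 target genes,
pathways ≥ 10 genes, and a pathway is kept only when at least half of the
*retained* drugs act on it. The half-of-drugs denominator is the drug set
remaining after the target-count filter, and the screening is a single
pass, not a fixpoint iteration — iterating could cascade removals that
the one-shot screening (which reproduces the reference counts) does not.
With an odd retained-drug count the fraction boundary is genuinely
fractional: with 87 drugs, 43 acting drugs drop a pathway and 44 keep it.

## Drug-level features

MACCS fingerprints use the standard 166-key definition; the padding bit 0
of 167-length toolkit output is discarded so column `MACCS_001` is key 1.
The ethanol fingerprint is cross-checked in the test suite against Open
Babel, an independent cheminformatics implementation. Descriptor columns
must be set in ≥ 10 drugs (inclusive), counted on the drug set actually
supplied to the filter — i.e. the post-screening set, since that is the
matrix the model sees; toxicity terms need ≥ 1 carrier drug. Drugs with
no recorded toxicity keep an all-zero vector rather than being dropped:
absence of side-effect annotation is informative missingness we do not
attempt to fill. Pair encodings are elementwise sums, hence values in
{0, 1, 2} and order invariance.

## Cell-line pathway scores

GSVA is implemented from first principles with the following fixed
conventions, chosen to match the published algorithm's defaults for
continuous data and verified against gseapy's implementation to < 1e-6 on
random fixtures:

- per-gene Gaussian-kernel CDF estimate across cell lines with bandwidth
  sd/4 (sample sd, ddof 1);
- the bandwidth is floored at 1e-8 × the matrix value range so constant
  gene rows degrade gracefully instead of erroring;
- per-sample increasing ranks of the CDF scores (highest density → rank
  p), symmetric rank statistic |rank − p/2| with exponent τ = 1;
- a KS-like random walk over genes in decreasing-density order, scored by
  the maximum deviation from zero (signed); no magnitude-difference
  variant.

Scores therefore lie in [−1, 1], are deterministic, and are invariant to
gene-row order. Pathways sharing no genes with the matrix score 0 with a
warning rather than erroring, so a mismatched annotation cannot silently
abort a run. Mutation profiles are scored as plain Jaccard overlap with
each pathway; an empty mutated set scores 0 on every pathway (empty
intersection over a non-empty union).

Methylation and RNAi preprocessing drops rows whose NA fraction strictly
exceeds 0.7, then imputes with k = 5 nearest gene rows (Euclidean
distance over jointly observed cells, rescaled by the observed-cell
count — the `nan_euclidean` convention), then collapses probes to genes
by per-cell-line averaging. k = 5 is a conventional default; the
imputation only has to be sane, not optimal, because downstream GSVA uses
ranks. Observed entries are never modified by imputation.

## Labeling

The combination score is the mean of (expected − observed) growth over a
group's dose points; concentration identity is ignored, every dose point
weighs equally. The sign convention makes synergy positive (observed
growth below expectation). Labeling is strict: a score exactly at the
threshold is non-synergistic. The duplicate-identity case in the
reference screen (one compound under two ids) is handled by a
configurable exclusion list rather than hard-coded chemistry.

## Modeling choices

- **Split and scaling.** 80:20 stratified split; per-column
  standardization fitted on the training partition only. Stratification
  is needed at desk scale to guarantee both classes in every partition.
- **Imbalance.** Target negative:positive ratio 2:1. Class weights are
  inverse-frequency (positive weight = negative/positive count ratio).
  Undersampling removes *negative* (majority) instances — the minority
  class is never shrunk. SMOTE synthesizes minority points by uniform
  interpolation toward one of the k = 5 nearest minority neighbors;
  synthetic rows carry a `__smote__` index marker recording their two
  parent rows, which makes leakage assertable.
- **Cross-validation.** Leak-free mode (default) resamples inside each
  training fold. The resample-then-fold mode is retained behind a flag
  because it is a common field practice whose optimism is worth
  measuring: on oversampled synthetic data it inflates mean CV AUPR
  dramatically (0.94 vs 0.35 leak-free in the shipped check), since
  near-duplicates of training points appear in validation folds. Reported
  numbers from that mode should be read as upper bounds.
- **Hyperparameters.** Exhaustive grid search scored by mean
  cross-validated AUPR — the primary metric under imbalance, where
  ranking positives correctly matters more than calibrated accuracy.
  Ties keep the first grid point. The production default parameters are
  learning rate 0.1, depth 7, 700 trees.
- **Metrics.** Implemented directly (Mann–Whitney AUC with midranks;
  step-integrated precision-recall area identical to average precision;
  threshold 0.5 for the hard-call metrics; precision defined as 0 with no
  positive calls) and tested to 1e-9 against scikit-learn on random
  vectors.
- **Feature-set search.** All 2^8 − 1 = 255 block subsets under one model
  config and one shared split; subsets ranked by the average rank of
  recall, F1 and AUPR, ties broken by AUPR then bitmask. Importance
  analysis sums tree-gain importances per block and normalizes to
  proportions; top-k refits keep the k most important features per block.

## The synthetic-data generator

Defaults: 500 genes, 20 drugs, 30 pathways, 12 cell lines, pathway sizes
10–50, 15–40 targets per drug, 9 dose points per (pair, cell line)
(emulating a 3×3 concentration grid), signal strength α = 1, pair-level
noise σ = 0.5, dose-level noise σ_d = 2. This yields 190 pairs × 12 cell
lines = 2,280 instances and runs the full pipeline in seconds. Targets
per drug default to 15–40 so that, over a 500-gene universe, the coverage
filters retain all drugs and ≥ 80 % of pathways — the scaled-down
equivalent of a real screen where most library drugs are annotation-rich.

The planted signal is pathway-mediated by construction: each drug's
targets are biased toward 1–3 home pathways; three driver pathways (the
largest, so they survive screening) carry a per-cell-line activity γ_c;
the true synergy of (pair, cell) is α·⟨a_pair, w_cell⟩ + ε with w_cell
supported on the drivers, and driver-gene expression is shifted by the
same γ_c so the cell-line EXP block also carries signal. Dose records are
emitted as expected growth E ~ U(60, 100) and observed growth E − s − η,
so the combination score recovers s exactly at zero noise and with slope
1 under noise. The label threshold is calibrated to the (1 − prevalence)
quantile of the planted scores, prevalence 10 % by default, mirroring the
imbalance of real screens.

What the generator does *not* emulate: real chemistry (fingerprint bits
are Bernoulli draws; a small fixed SMILES list exercises the RDKit path
separately), marginal distributions of real screens, dose-response curve
shapes (the expected-growth column is taken as given, as in the source
data), correlated omics structure beyond the driver shift, or batch
effects. Passing the recovery tests therefore demonstrates that the
machinery is correct and leak-free, not that real-data performance will
match.

One desk-scale caveat observed with the default generator: per-block
importance proportions are sensitive to block width (many noise columns
in a wide block can out-sum a narrow signal block), so block-level
importance readings should be interpreted per feature, not per block,
when block widths are very unequal.

## The validation statistic

From replicate viability fractions, Δvia = mean(best mono) − mean(combo)
and HR = mean(combo)/mean(best mono); the score Δvia − Δvia·HR equals
Δvia²/mean(best mono) under this mean-ratio estimator, hence is
non-negative and zero exactly when the combination matches the best
monotherapy. The estimator choice from unpaired replicates is not unique;
alternative pairings of replicates yield slightly different point values,
which is why the decision rule (score > 0.004) rather than a point value
is the contract the package commits to. Viability values above control
level (> 1) are retained. The bundled T-47D table (bleomycin 200 nmol/L,
bortezomib 40 nmol/L, both combination orders, 8 replicates per arm)
scores 0.0157 and 0.0201 — both synergistic under the rule.

## Numerical and degenerate-input policy

Text formats round-trip floats via `%.17g` (bit-exact). Matrix algebra is
vectorized NumPy checked against naive loops at 1e-12. Degenerate inputs
fail loudly: empty gene sets, duplicate ids, NA in assays that forbid it,
single-class label vectors for ranking metrics, minority classes too
small for SMOTE, all-zero importance vectors. Silent conventions are
limited to the two documented zeros (empty mutated set; pathway with no
matched genes).

## Known limitations

- The GSVA variant is fixed (Gaussian kernel, τ = 1, max-deviation);
  Poisson-kernel scoring for raw counts is out of scope.
- Tree-gain importances are the only importance measure; no permutation
  or SHAP analysis.
- The desk-scale generator cannot reproduce headline metrics of
  full-scale screens; tests assert recovery and calibration properties
  instead of absolute benchmark values.
- No dose-response modeling: expected growth is consumed, never fitted.
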