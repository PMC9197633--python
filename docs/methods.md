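# Methods

## The problem

The MDS-UPDRS rates Parkinson's disease severity through 50 items (65
individual 0–4 ratings across four parts) and takes about half an hour,
which limits its use in routine clinics and over telemedicine. The
pipeline in this package finds the k-item subset (k = 8 by default)
whose unweighted rating sum best reconstructs the full-scale total,
optionally restricted to items that can be administered remotely, and
then characterises how well that abbreviated score stands in for the
total on an independent cohort.

## Scoring a subset

For a subset S, let x = Σ_{i∈S} (sum of item i's rating fields) and let
y be the 65-rating total. The candidate model is simple least squares
with intercept, ŷ = βx + α, and the selection criterion is the
explained variance score

EVS(S) = 1 − Var(y − ŷ)/Var(y),

which for intercept-including least squares equals R² and hence has the
closed form Cov(x, y)² / (Var(x)·Var(y)). Both Var(x) = Σ_{i,j∈S}
Cov(item_i, item_j) and Cov(x, y) = Σ_{i∈S} Cov(item_i, y) are linear
in precomputed item-level moments, so after one pass over the data any
subset is scored in O(k²) from the 50×50 item covariance matrix. The
test suite verifies this closed form against per-subset regression fits
to 1e-10 and checks the partition identities (total variance = 1ᵀC1,
item-total covariances = C1) that tie the sufficient statistics
together.

A multivariate mode (one coefficient per item, solved from the k×k
normal equations) is provided for comparison; its R² can never fall
below the sum mode's, but the published conversion uses the plain sum,
so `sum` is the default selection mode.

Aggregation convention: an item's score is the sum of its rating fields
(e.g. finger tapping = right + left), and the total is the sum of all
65 ratings — the instrument's standard total-score convention. This
also fixes what "the sum of the subset ratings" means for multi-rating
items.

## Exhaustive enumeration

All C(m, k) subsets of the candidate pool are enumerated in
lexicographic order over the canonically sorted pool (items ordered by
part, then item number), scored in vectorised blocks, and fed through a
bounded best-K accumulator, so memory is independent of the search
size. Ranks are assigned after full enumeration; EVS ties break by
canonical item order, making ranks reproducible bit-for-bit across
block sizes and resumptions. Periodic JSON checkpoints make long
searches interruptible; a resumed search provably (and testedly)
reproduces the uninterrupted output. Sum-mode throughput on one desk
CPU is on the order of 10⁶ subsets/s, so the remote-pool search
(C(42,8) = 118,030,185) is a couple of minutes and the unconstrained
search (C(50,8) = 536,878,650) an order of ten minutes. No pruning or
heuristics are used anywhere: exhaustiveness is the point, and the run
log reports the evaluated count for external checking against C(m, k).

Remote-practicality constraints are expressed as item flags in the
packaged instrument definition: two items need hands-on assessment
(rigidity 3.3, postural stability 3.12) and six need the lower limbs or
gait to be observed (3.7, 3.8, 3.10, 3.11, 3.13, 3.14), leaving a
42-item remote pool.

## Uncertainty, unbiasedness, agreement

Uncertainty intervals are seeded nonparametric case-resampling
bootstrap percentile intervals (default B = 10,000; smaller B where a
driver says so). The surrounding literature calls these "credible
intervals"; since no Bayesian machinery is involved they are labelled
bootstrap percentile intervals throughout. Degenerate resamples (zero
variance) are redrawn and counted. Supported statistics: EVS (with a
fixed model's predictions, or refit per resample, in which case EVS
equals the squared Pearson correlation), PCC, SRC, mean residual, and
the median.

Residuals are oriented actual − predicted everywhere, which makes the
Bland–Altman bias (limits of agreement = bias ± 1.96·SD of differences)
identical to the mean residual — an identity the tests pin. Skewness is
the adjusted Fisher–Pearson sample skewness. Conditional bias is
reported as mean residuals within bands of the actual total (default
width 25 over 0–260, so the clinically interesting "above 100" region
falls on band boundaries). The conditional distribution of the total
given each subset-sum value is summarised by the 2.5/25/50/75/97.5th
percentiles with linear interpolation between order statistics; groups
with n below 5 are flagged as display-suppressed but still counted.

Cohorts are compared with a two-sided Mann–Whitney U on total scores
(tie-corrected normal approximation with continuity correction). U is
oriented to the first sample: the count of pairs where its value
exceeds the second sample's, ties counting one half, so identical
samples give n²/2. The orientation is stated because published U values
can be checked only once an orientation is fixed.

## The synthetic cohorts

Real training/validation data for this instrument are access-restricted,
so the generator produces cohorts that reproduce the structural facts
the search relies on, with all parameters in `SimConfig`:

* latent severity s ~ Normal(mean 1.0, sd 0.8) truncated to [0, 4];
* a per-record, per-part factor ~ Normal(0, 0.3), giving within-part
  clustering;
* each rating field's latent value = loading·s + part factor +
  Normal(0, 0.6) noise, rounded to the nearest of {0,…,4} and clipped —
  i.e. equally spaced ordinal cut points;
* item loadings drawn once per item from Uniform(0.3, 0.9), so
  item-total correlations are heterogeneous (roughly 0.3–0.8 at the
  defaults, with a mean total near 50/260) — some items are far more
  informative than others, which is what makes subset selection
  non-trivial;
* an optional planted subset whose loadings are boosted (capped at 1),
  giving a known ground-truth optimum for recovery experiments;
* a paired validation cohort drawn from the identical item model with
  severity mean shifted by +0.5, emulating an external cohort with
  higher median severity. All randomness derives from one master seed
  via hashed (purpose, cohort) sub-streams, so the two cohorts share
  loadings but never share records.

Defaults produce a training cohort whose subset-sum/total correlations
sit near 0.9 for good 8-item subsets, the regime the method targets.

What the generator does **not** emulate: the real instrument's
item-wise marginal frequencies, rater effects, missingness mechanisms,
or longitudinal correlation between a subject's visits (all complete
assessments are treated as independent rows). Passing tests therefore
demonstrate the machinery is correct and well-calibrated under the
stated latent model, not that any particular subset is optimal for real
patients.

Two structural consequences of the generator are worth knowing:

1. Items scored from several rating fields average out field noise, so
   at equal loading a multi-rating item is mechanically more
   informative. The monotonicity check between loadings and item-total
   correlations is therefore run within single-rating items; across all
   50 items the rank correlation drops to ~0.84 purely through this
   multiplicity effect.
2. The 0–4 clipping makes E[total | subset sum] mildly convex, so a
   line fitted on the training cohort genuinely under-estimates on a
   more severe cohort: at a severity shift of +0.5 the validation mean
   residual is positive (a few points of 260) and its interval
   typically excludes zero, while at shift 0 (exchangeable cohorts) the
   interval crosses zero as unbiasedness predicts. The same
   right-skew/conditional-bias caveat applies to the real conversion at
   high totals. Tests pin both regimes.

## Problem sizes in the shipped drivers

The test suite runs searches up to C(20,4) = 4,845 (planted recovery,
20 seeds at n = 2,000), bootstrap calibration with 500 replicates of
n = 300 at B = 1,000 (95% PCC intervals empirically cover the
population value ~95% of the time), and oracle comparisons over all 120
3-subsets of a 10-item pool at n = 500. The acceptance script runs the
full remote-pool C(42,8) search at the study-sized n = 7,594. The
unconstrained C(50,8) search is available through
`analysis/02_search_subsets.py --pool any` (checkpointable) and is the
one job left to an explicit invocation rather than a default run.

## Known limitations

* The generator's ordinal thresholds are fixed and equally spaced; real
  items have idiosyncratic category frequencies.
* "Validation" here means an independent draw from a shifted version of
  the same latent model — a weaker claim than a second real instrument
  study.
* Multiple visits from one simulated subject are not modelled; with
  real longitudinal exports the rows are not independent and bootstrap
  intervals will be somewhat anti-conservative.
* The sum-mode EVS is not monotone in subset size (adding a noisy item
  can dilute the sum), so optimal k-subsets are not nested across k;
  each k requires its own search.
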