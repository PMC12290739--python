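# Methods

## Design model

The design generator reproduces a two-task conditioning layout: per task,
seven unpaired CS blocks interleaved with six CS–US paired blocks
(U P U P … U), three trials per block (two CS+ faces, one CS−), 39 trials
per task and 78 in total. Tasks are generated as separate runs and
concatenated appetitive-first; there is no cross-task temporal adjacency.
The CS order of unpaired blocks is the fixed canonical order (CS+1, CS+2,
CS−) in every unpaired block — by construction identical across blocks and
across seeds — so that learning-related changes in similarity cannot be
confounded with changes in temporal distance between trials. Paired-block
orders are drawn per block from the seed. The US occurs only on
paired-block CS+ trials: brush in the appetitive task, pressure in the
aversive task. Trial timing (fixation/ITI, US onset) is metadata only; the
pipeline consumes beta patterns, not time series, so no hemodynamics are
simulated.

## POI library

Ten POIs have a condition-level (6×6) form; three (Face Stimulus, Temporal
Adjacency, Violation of Expectation) exist only at trial level because
they depend on face identity, temporal order or block context. Valence
assignment: brush-paired CS+ and the aversive-task CS− are positive
events; pressure-paired CS+ and the appetitive-task CS− are negative
events (the CS− inherits the opposite of its task's US valence via
omission). Diagonals are stored as +1 but always masked before
vectorization (the self-correlation carries no model information), and
trial pairs of the same condition take +1 for every condition-level POI,
so expanding a condition POI to trials and averaging back by condition
pair reproduces the condition matrix exactly.

Two points were genuinely open and are configurable rather than silently
encoded:

- **Salience.** "High salience" plausibly covers touched trials and
  expectation-violating trials; at the condition level the default marks
  touch conditions high and CS− conditions low, with the −1 placed within
  low-salience pairs (the most literal reading); a variant places the −1
  between the classes, and a block-aware trial-level variant marks all
  paired-block trials high (touched or expecting touch). Block-aware
  matrices are flagged degenerate whenever all trials in a subset share
  one class (constant off-diagonal, collinear with the intercept).
- **Within-condition pairs.** Whether two presentations of the same
  stimulus should be modeled as +1 or excluded is unstated in the source
  design; the library models them as +1 (same condition = maximal model
  similarity), and callers can exclude them by subsetting the vectorized
  entries.

## Similarity

Similarity is the Pearson correlation across voxels of two beta patterns,
Fisher-z transformed. |r| ≥ 1 − 1e−7 is capped at atanh(1 − 1e−7) ≈ 8.4
and flagged, keeping the regression stage finite when patterns are
identical. Correlations are computed within one ROI only; ROIs are never
statistically compared (pattern analyses scale with ROI size). Two
granularities are provided: trial-wise (t×t over a trial subset, the full
cross-task matrix by default, as required by cross-task POIs) and
condition-wise (patterns averaged per condition before correlating). The
pipeline's default fit granularity is condition-wise, which matches the
condition-resolved similarity structure the POIs describe and avoids the
Fisher-capped within-condition entries that dominate trial-wise fits of
low-noise data. Masked/missing voxels are disallowed rather than
pairwise-deleted; callers must pre-filter, which keeps results
deterministic.

## Selection and reconstruction

BIC uses the Gaussian profile-likelihood form `n·ln(rss/n) + k·ln(n)` with
k = slopes + intercept + residual variance. The greedy best-first search
fits each candidate alone (level 1), keeps the lowest-BIC POI if it beats
the intercept-only model by ΔBIC ≥ 2, then repeatedly adds the best
remaining candidate while each addition lowers BIC by ≥ 2 (the threshold
is configurable; 2 is the conventional "positive evidence" cutoff). Ties
within 1e−9 break by registry order; aliased candidates are skipped; an
exact fit (rss = 0, BIC = −∞) stops the search. Final weights come from
one multiple regression of the selected set with an intercept (POI entries
are not centered). Selection runs on the subject-averaged similarity
vector by default, with weights re-estimated per subject (a per-subject
majority-consensus mode is available). The reconstructed US is the
β-weighted sum of the selected POI matrices at condition or trial level,
intercept applied uniformly off-diagonal, diagonal masked.

Small-sample caveat: with 15 condition-level observations and ΔBIC ≥ 2, a
chance candidate is admitted when its partial R² exceeds ~0.27, which
happens for ~7% of null candidates per fit — across eight remaining
candidates roughly four in ten single-dataset fits admit one spurious POI
alongside the true ones, independent of voxel count or noise scale
(partial R² is scale-free). Consumers needing stricter parsimony on single
datasets should raise `delta` or use the consensus mode; the default stays
at the conventional threshold.

## Reactivation statistics

Global reactivation: per subject and phase, the rUS matrix (restricted to
the phase's condition support) is correlated with the phase's CS-only
similarity matrix; the n_subjects × 3 correlations enter a one-way
within-subject ANOVA (standard subject × time decomposition;
η² = SS_time/(SS_time+SS_error)). Greenhouse–Geisser ε is Box's formula on
the double-centered timepoint covariance, clipped to [1/(k−1), 1]; the
default policy applies the correction when ε̂ < 0.95 (configurable
always/never/auto). The default phase split of the seven unpaired blocks
is early = {1, 2}, mid = {3, 4, 5}, late = {6, 7}; the early phase
deliberately contains the pre-association first block. Unpaired data
include CS+ and CS− trials by default (`cs_subset="csp_only"` restricts).

Component reactivation: Bayesian linear models of the group-mean rUS and
per-phase CS vectors with the US-identified POIs (by default the selected
set; configurable) as predictors. The prior is a conjugate
normal–inverse-gamma: β_j | σ² ~ N(0, σ²·(10/sd(x_j))²) — conditional
prior sd ≈ 10·sd(y)/sd(x_j) at σ ≈ sd(y), weak at the scale of the data —
with a diffuse intercept (scale 100) and σ² ~ IG(0.001, 0.001). The
posterior is sampled exactly (σ² from its marginal inverse gamma, then
β | σ² Gaussian), 1,000,000 draws by default, seeded; means and central
95% intervals are reported. Under this weak prior the posterior mean
agrees with OLS to well under 0.01 at n = 200, and 95% CrIs cover true
coefficients at their nominal rate — that calibration, not equivalence
with any particular packaged prior, is the test surface. Consistency
between datasets uses the closed-interval rule: X's point estimate inside
Y's CrI.

## Synthetic generator

`target_similarity` composes a condition correlation matrix from a POI
mixture (off-diagonal Σ wᵢ·POIᵢ scaled by a baseline variance, unit
diagonal), projecting to the nearest positive-semidefinite correlation
matrix by eigenvalue clipping at 0 and rescaling (tolerance 1e−8; any
entry moved by more than that raises a flag, e.g. when weights push
entries past the correlation bounds). `sample_beta_patterns` draws each
voxel's 6-vector of condition means from N(0, target) and adds independent
Gaussian trial noise — voxels act as samples of the condition structure,
so the empirical condition correlation converges to the target as voxels
grow. `simulate_cohort` draws segments (paired, early, mid, late)
independently so representational structure can change over learning.

Default study conditions used by the tests and the acceptance script:
12-subject cohorts, 200–300 voxels (2,000 where recovery at realistic
pattern size is probed), trial noise SD 0.5 against unit condition-mean
variance, generative mixture 0.4·Experimental Task + 0.3·Aversive
Pressure, and learning injected as the unpaired mixture scaling from 0
(early) through 0.5 (mid) to 1.0 (late) of the paired mixture. Simulation
counts (50–1,000 replicates depending on the quantity) were chosen to
bound Monte-Carlo error well below the asserted tolerances.

What the generator does *not* emulate: hemodynamic convolution and
temporal autocorrelation, motion/physiological noise, spatial smoothness
and voxel covariance, ROI-size effects, and between-subject variation in
the generating weights. Passing tests therefore demonstrate correctness of
the statistical machinery under its own assumptions — not that real fMRI
data satisfy those assumptions.

## Degenerate inputs and numerical choices

Zero-variance trial patterns are an error naming the trial; constant
(degenerate) model matrices are flagged and skipped by the search with an
empty-selection warning if nothing remains; asymmetric matrices beyond
1e−10 are rejected at vectorization; rank-deficient designs raise an
aliasing error naming the offending predictors (QR diagnostic, relative
tolerance 1e−10); RM-ANOVA with zero residual variability and phases with
fewer than two trials are errors. The reactivation pipeline records
recoverable stage failures (e.g. a subject set without unpaired data) and
continues with the stages that remain, so a paired-only dataset still
yields rUS component estimates.

## Known limitations

Real-data results of the study this design mirrors (per-ROI F statistics
and POI reactivation patterns) require the original fMRI dataset and its
preprocessing chain, which are out of scope; the package validates the
machinery on synthetic ground truth instead. The trial-level fit
granularity inherits strong dependence among trial pairs sharing a
condition pair (BIC treats them as independent observations and is
anticonservative there); the condition-level default avoids this. The
Bayesian prior is a pragmatic weak conjugate choice, not a reimplementation
of any specific package default.
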