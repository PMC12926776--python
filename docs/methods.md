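# Methods notes

This note documents the models, parameter choices, numerical conventions
and known limitations of `conflictdecode`, in the spirit of a methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Decoding model

All analyses use a two-class linear discriminant with the pooled
within-class covariance shrunk toward a scaled identity,
`S' = (1−λ)S + λ(tr S/p)I`, weights `S'⁻¹(μ₁−μ₀)` and the decision
threshold at the midpoint of the projected class means. The shrinkage
target (scaled identity) makes the rule well defined when features
outnumber trials; `λ = 0.01` by default, configurable everywhere, and the
exact λ used is recorded in every output's provenance header because
published work in this area rarely prints the regularization constant.
Decision-value ties go to class 0 — an arbitrary but documented
reproducibility convention. With balanced folds the chance level is 0.5.

Cross-validation balances classes by subsampling the majority class to
the minority count (without replacement, per balancing repeat), then
deals trials class-by-class into k = 10 folds; each fold's train and test
sets are therefore exactly balanced, and no trial appears twice within a
repeat. One partition is drawn per subject and reused across all
timepoints/cells of a map, so cells differ only in their features — this
avoids adding partition noise to cell-to-cell comparisons.

Within-task time-resolved decoding uses all channels' amplitudes at one
sample as features; the searchlights use a single (channel, time) or
(channel, frequency) feature per cell, computed by a vectorized
implementation that is verified in the tests to agree with the generic
path exactly. Frequency-domain decoding uses squared DFT magnitudes of
the 0–1000 ms post-stimulus window, retaining bins in 1–50 Hz
(channel-major feature order). The DFT window is a closed interval on the
sample grid, so the bin spacing is `fs / n_samples` (≈1 Hz for a 1 s
window); no taper by default (a Hann option exists). Power features are
z-scored per feature with train-fold statistics applied unchanged to the
test fold ("fold-wise", no leakage); a "global" variant exists for
comparison with published pipelines whose wording implies pre-CV
z-scoring. Zero-variance features are set to z = 0.

Cross-task generalization trains on *all* balanced trials of the training
task at each train-time and evaluates at every test-time of the other
task; no cross-validation is needed because no training-task trial is
ever scored. Both tasks are subsampled to a common per-condition count
(the minimum over both tasks and conditions, drawn once per subject
pair), so accuracies are comparable across task pairs. Directions A→B and
B→A are computed and reported separately — asymmetric transfer is
meaningful. Epoch grids are kept as-is (rectangular matrices); no
resampling to a common grid.

## Group inference

**TFCE + sign-flip max statistic.** Subject accuracy maps are centered at
chance, reduced to a one-sample t-map, and enhanced with
`e(p) = Σ_h extent(p,h)^E h^H dh` (E = 0.5, H = 2, dh = 0.1 in t-units,
thresholds from dh up to the map maximum — standard TFCE practice). The
null is built from whole-map sign flips; the corrected p of a cell is the
fraction of null iterations whose *maximum* enhanced value meets or
exceeds the observed one (one-tailed above-chance by default, since the
hypotheses are directional; a two-tailed option applies the same
transform to the negated map). Two numerical conventions matter:

* t-maps are clipped at |t| = 50 before enhancement. Small-n accuracy
  maps can produce arbitrarily large finite t (and zero-variance cells
  would be infinite); the cap bounds the fixed-step threshold loop, and
  the permutation rank logic is unaffected because observed and null maps
  receive the identical transform. Zero-variance cells take the cap as a
  signed sentinel rather than propagating NaN.
* 1-D (time-axis) nulls use a batched run-length implementation of the
  max-TFCE computation, tested to agree with the generic labelling path
  to 1e-9.

Clusters are reported as maximal contiguous runs of the significant mask
with their grid extents, peak t, and minimum corrected p.

**Resampled group null.** For scalar accuracies (the frequency-domain
analysis), each subject contributes `n_perm = 100` label-permuted
accuracies; a group-level null draw picks one permuted value per subject
uniformly at random and averages, repeated `n_draws = 10,000` times. The
observed group mean is located as a percentile of the draws with the
midrank convention (`100·(#below + ½·#equal)/n_draws` — the tie rule is a
documented choice), and the verdict threshold is the 95th percentile.
This empirical construction is used instead of a parametric test against
0.5 because balanced-CV accuracies are not symmetrically distributed
around chance under the null.

**Bayes factors.** The JZS BF₁₀ integral is evaluated by adaptive
quadrature at relative tolerance 1e-8, integrating piecewise with
breakpoints at {r², 1, t²/n} — the prior scale and the likelihood peak —
which keeps the rule convergent for extreme statistics (the integrand is
evaluated relative to the null likelihood to avoid underflow). Prior
scale r = √2⁄2 by default. Evidence bands follow the conventional scale:
1/3–3 inconclusive, 3–20 substantial, 20–150 strong, >150 very strong
(mirrored for BF₀₁). The per-cell map variant caches by rounded t, since
neighbouring cells often share a t value after discretized accuracies.

`d_av` is the paired Cohen's d with the average-SD denominator
`|M₁−M₂| / ((SD₁+SD₂)/2)`, available both from raw vectors and from
published summary statistics. Spearman correlations use midranks with a
t-approximation p-value.

## Preprocessing conventions

Time is in milliseconds with stimulus onset at 0; all windows are closed
intervals on the sample grid; channel order is canonical (alphabetical).
Filtering is a Hamming-windowed sinc FIR band-pass (defaults 0.5–100 Hz:
keeps the 1–50 Hz feature range with margin under the 125 Hz Nyquist of
250 Hz data), applied zero-phase as a single forward pass of the
symmetric kernel with group-delay compensation. The transition bandwidth
is `min(max(0.25·hp, 2 Hz), 0.25·lp, 2·hp)`; the final cap keeps the
lower stopband edge at or above DC, without which a 0.5 Hz high-pass
would leave drift essentially unattenuated. Kernel length is
`ceil(3.3·fs/tb)`, odd. Decimation requires an integer factor, keeps
t = 0 on the grid, and relies on the chain's low-pass as its anti-alias
filter.

Baseline correction subtracts the 0–200 ms *post-stimulus* mean per trial
and channel. This window is implemented as stated in the procedures the
pipeline models; it is unusual (the classical convention is pre-stimulus)
and is therefore prominently configurable (`baseline_window=(-200, 0)`).
Trial screening drops no-response trials, responses faster than 100 ms
(premature; the threshold is configurable since published rules are often
verbal), and responses slower than a per-task maximum (defaults: 1800 ms
change detection, 1500 ms Simon, 4000 ms Stroop). Decoding uses all
response trials by default; a correct-only mode exists because published
trial counts are sometimes reported correct-only.

## Synthetic data: what it emulates, and what it does not

The generator emulates the structure that matters for the
shared-vs-specific question: several tasks with task-specific epoch
windows and realistic unequal trial counts (~50–230 per condition); a
conflict effect carried by (a) an evoked spatial pattern with a Gaussian
(or strictly box-car) time course and (b) an induced theta-band
(3–7 Hz) oscillation with uniform random phase per trial, gated to
0–1000 ms — invisible to trial averages, visible to power features, which
is exactly why both time- and frequency-domain decoding exist; a
fronto-central shared template with per-task unique components
(`α·shared + √(1−α²)·unique`, both unit-norm, unique orthogonalized
against shared); 1/f background noise (exponent 1.0, per-channel SD 10 µV)
mixed across channels by a fixed row-normalized blend of the identity
with a random rotation (`spatial_mixing = 0.3`); lognormal RTs (medians
580/500 ms conflict/non-conflict, σ = 0.25) and Bernoulli correctness
(0.85/0.95) — the conventional direction and a plausible order of
magnitude for conflict costs; and an optional response-locked lateralized
motor pattern shared across tasks for the response-hand control.

Default effect amplitudes (evoked 6 µV, theta 10 µV on a unit-norm
topography) were chosen once so that planted effects are recoverable at
the 20-subject scale of the demo configuration; published studies of this
kind do not report single-trial effect sizes, so these are free
parameters of the artifact, not estimates. Draw order is fixed and
documented (response hands → noise → effect phases → RT → correctness),
and all randomness descends from one SeedSequence spawned per
subject × task in declaration order, so identical (config, seed) pairs
are bit-identical.

What the generator does *not* emulate: biophysical forward models or
realistic head geometry, eye/muscle artifacts, autocorrelated behavioral
dynamics (no congruency-sequence structure), between-subject topography
variability (patterns are fixed across subjects; subjects differ only in
noise), or realistic effect-size heterogeneity. Passing recovery tests
therefore demonstrates that the *pipeline* recovers planted structure at
synthetic SNR, not that real data of any particular study would yield the
same power.

## Problem sizes in the shipped tests

The demo configuration used by the acceptance suite runs 20 subjects,
three tasks (A and B sharing the conflict topography, C orthogonal) at a
100 Hz grid over −200…1200 ms epochs, with cluster permutation at
n_iter = 500 — sizes chosen so the full suite runs comfortably on one
CPU while keeping every qualitative contrast (within-task decoding in all
tasks; transfer only between A and B; theta-band peak; 250–450 ms
localization) decidable. The same code paths run unchanged at 250 Hz /
10,000 iterations; only runtime scales.

## Known limitations

* The cross-task balancing count is taken per subject-pair, not per
  matrix cell; alternatives exist in the literature and would change
  absolute accuracies slightly.
* TFCE's dh is interpreted in t-units with the map maximum as upper
  limit; statistics other than t would need a rescaled dh.
* The EEGLAB importer reads epoch event types only; response hand, RT and
  correctness must be merged from a trial table.
* The JZS integral's quadrature is scalar; per-cell Bayes-factor maps on
  very large grids rely on the t-value cache for speed.
* Under the exact null at 20 subjects, the two-sided JZS Bayes factor
  favors the null (BF₀₁ > 3) only for |t| < 0.902, i.e. in ≈62% of null
  cells in expectation — a sample-size property of the default Bayes
  factor worth keeping in mind when summarizing "evidence of absence"
  over map cells (roughly 45+ subjects would be needed before ~80% of
  null cells reach BF₀₁ > 3).
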