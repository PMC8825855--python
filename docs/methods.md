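# Methods

`seqmem` reimplements, as a tested pipeline, a family of statistical
machine-learning analyses of hippocampal CA1 ensemble activity recorded
while rats judge whether odors of a learned five-item sequence (ABCDE) are
presented in or out of order. Every stage is verified by parameter recovery
against a synthetic session generator whose ground truth is recorded but
never read by the analyses.

## The task and the session data model

A session holds per-neuron spike times (seconds from session start),
per-tetrode LFP at 1 kHz, and a trial table: one row per odor presentation
with sequence id, position 1–5, odor A–E, an InSeq/OutSeq flag, port-entry
and port-withdrawal times, and the correctness of the animal's judgment.
Position 1 is always odor A presented InSeq; an incorrect judgment
terminates the sequence. InSeq judgments are expressed by holding the
nosepoke until a 1.2 s tone, OutSeq judgments by withdrawing earlier
(mean ≈ 0.75 s). All analyses bind to this structure only.

## Bayesian time reconstruction

Assuming independent Poisson spiking, the posterior over reconstructed time
t given the count vector n observed in an actual-time bin of length τ is

    P(t | n, odor) ∝ P(t | odor) · Π_i (τ f_i(t, odor))^{n_i} / n_i! ·
                     exp(−τ Σ_i f_i(t, odor))

with f_i the mean training-set firing rate of neuron i and a uniform prior
over the analysis window (InSeq holds share a duration). The decoder is
memoryless: overlapping bins (width τ, step s ≤ τ) are decoded
independently. Reconstruction accuracy of a trial is the mean Pearson
correlation between matching rows and columns of its posterior matrix;
undefined (zero-variance) row/column pairs are skipped, and a trial whose
pairs are all undefined is excluded with a log entry.

Numerical choices: likelihoods are evaluated in log space; a rate floor of
ε = 1e−3 Hz is applied to f before the logarithm so an observed spike at a
zero-rate bin cannot produce −∞; neurons whose training rate is identically
zero for the decoded odor are dropped from that decode. Default bins are
τ = 50 ms with 25 ms steps for single-odor windows and τ = 500 ms with
100 ms steps for full-sequence decoding — coarser steps than a
figure-resolution 5 ms raster, chosen because the accuracy statistic is
insensitive to the step once bins overlap.

Protocols. Leave-one-out: each trial is decoded with a rate map refit from
the remaining trials. Lag analysis: models are trained per odor at its
proper position on trials from intact sequences (all five positions InSeq,
consecutive, correct) and tested on other odors (lag = sequence-position
distance); lag 0 is tested on same-odor InSeq-correct trials outside the
training set. Chance levels come from permutations of the time factor of
the rate map (one joint permutation of the time bins across neurons).
Split-half controls (first/second, Q1&Q3 vs Q2&Q4, odd/even) replace
leave-one-out with 50:50 train/test. The informative-neuron filter runs the
single-neuron decoder against its own time-shuffled null.

A calibration caveat worth stating precisely: when bins overlap (s < τ),
neighboring rate-map bins share spikes and the map is smooth in time, so a
permutation of its bins is not an exchangeable null operation — measured
type-I error of the 95th-percentile rule is ~20 % rather than 5 % on null
generators. With non-overlapping bins (s = τ) the map bins are iid under
the null and the test is exactly calibrated; the calibration analyses use
that configuration, and chance levels quoted for overlapping-bin decodes
should be read as descriptive.

Outcome comparison: the model is trained on intact full sequences and
tested on the 250 ms window preceding port entry of OutSeq trials
(positions 2–4), where behavior is matched across outcomes. Each OutSeq
trial's posterior over sequence time is compared with the mean posterior of
same-position InSeq trials by KL divergence; correct vs incorrect KL
distributions are compared with a two-sample Kolmogorov–Smirnov test, with
an optional seeded downsampled repetition.

## PSTHs and trial-wise correlation

PSTHs bin each neuron's activity at 1 ms, smooth with a Gaussian kernel
(150 ms sd for single-odor windows, 250 ms for full sequences; kernel
truncated at ±4 sd, reflected boundaries), average across trials, and
peak-normalize each row; neurons silent on all included trials are dropped
and logged. Sorting is by peak latency (argmax of the smoothed normalized
row, first bin wins among equal maxima; ties broken by neuron id). The
similarity analysis vectorizes per-trial PSTHs (balanced trial counts per
odor, canonical neuron order) and correlates all pairs; same-odor vs
different-odor pair classes are compared with a one-way ANOVA and Dunnett
contrasts from scipy.

## Autoencoder latent embedding

Each 250 ms analysis window (0–250 and 250–500 ms after port entry, −250–0
and 0–250 ms around withdrawal — the four epochs where behavior is matched
across trial types) is cut into sixteen 100 ms sub-windows advancing by
10 ms; each sub-window's spike counts (10 ms bins × all neurons) form one
input vector. A fully connected autoencoder (encoder 500–500, linear 2-unit
bottleneck, mirrored decoder; rectifier activations elsewhere) is trained
per window by mini-batch SGD with momentum on mean squared reconstruction
error, without any trial labels.

Numerical choices, in this implementation's normalization (MSE summed over
features, averaged over the batch): learning rate 0.01, momentum 0.9, batch
64, 200 epochs, global gradient-norm clipping at 1.0, inputs standardized
per feature. The output layer is linear — standardized targets are signed,
so a rectified output could not reach the MSE optimum. Training runs two
seeded restarts and keeps the run with the lower final loss, because a
single SGD run occasionally stalls at the predict-the-mean optimum; with a
fixed seed the procedure is deterministic (single-threaded numpy). The
desk-scale analyses use 128-unit encoder layers and 80 epochs, which
already drive reconstruction loss below the 2-component PCA bound.

Separability is quantified post hoc by k-NN with k = 2 on the embedded
points (70 % of trials train, 30 % test, stratified): each test point takes
the label of its two nearest training points, a split vote resolving to the
nearer neighbor (note that this tie rule makes the classifier equivalent to
1-NN at the point level — implemented as specified); a trial's label is the
majority over its 16 point votes, distance-sum tie-broken. Chance is the
2.5–97.5 percentile band of 100 label-shuffled accuracies; accuracy above
the upper bound is significant. Cluster-lag analysis computes per-trial
centroids, Mahalanobis distances under the pooled centroid covariance
(Euclidean fallback if singular, logged), pair lags from odor distance
(InSeq) or position distance of the same odor (OutSeq), and linear trend
tests.

## CNN odor decoding

The decoder consumes, per tetrode, a multivariate time series on a common
10 ms grid: the tetrode's LFP (z-scored against whole-session statistics,
block-averaged to the grid) plus each unit's spike counts. 1-D convolution
filters (8 per tetrode, width 5 grid steps; weights not shared across
tetrodes) feed rectified, time-averaged features that are concatenated and
passed through dense layers (64, 32) with dropout 0.5 to a softmax over
odors A–D. Training uses correct InSeq trials in the 150–400 ms window
after port entry, SGD with momentum and early stopping (stratified 15 %
validation split; package-default patience 10, with patience 30 and
learning rate 0.05 used in the desk-scale analyses where tiny validation
sets make early stops noisy). The trained model is applied to seven 250 ms
windows from −400 to +1350 ms relative to port entry; the penultimate
hidden layer is the supervised latent space, visualized through its top two
principal components with multinomial-logistic linearized class boundaries.

Statistics: pooled per-window argmax counts get Goodman simultaneous
multinomial confidence intervals (non-overlap read as a significant
difference, the conservative rule) corroborated by chi-square tests;
within-trial reactivation is measured as the per-trial least-squares slope
of probability differences (e.g. P_C − P_B) across the window grid, tested
against zero with a one-sample t-test. Held-out accuracy uses stratified
k-fold cross-validation, optionally on a balanced subset (each class
downsampled to the smallest class count) so that chance is exactly 1/4;
the benchmark is a multinomial logistic regression on the same flattened
inputs. The subject control builds leave-one-session-out confusion
matrices, re-stratifies by true odor, and applies the generalized
Cochran–Mantel–Haenszel test of general association (implemented here,
as only the 2×2×K special case ships with statsmodels; verified against an
independent reference implementation). Note the statistic sums stratum
deviations before the quadratic form, so it detects consistent
subject effects, not arbitrary per-stratum heterogeneity.

## Theta-cycle decoding

The LFP channel with maximal 4–7 Hz power is band-passed (Butterworth,
zero-phase) and Hilbert-transformed; phase 0° is the filtered-trace peak,
180° the trough. Cycles run peak-to-peak; cycle 1 is the first full cycle
starting ≥ 100 ms after port entry, with pre-entry cycles indexed −1, −2, …
Trials whose cycle-1 amplitude falls in the weakest 20th percentile are
excluded. The phase partition is descending [0, 120), trough [120, 240),
ascending [240, 360).

A LASSO (L1) multinomial logistic regression is trained on each neuron's
firing rate during the trough of cycle 1 (correct InSeq trials; counts
divided by trough duration; features standardized; penalty set by
stratified 10-fold cross-validation, folds reduced with a warning for small
classes). Decoding slides a 120° window in 10° steps (windows centered on
their bin label and restricted to the same cycle, borrowing phase-wrapped
samples within it); rates come from circular sums of 10° occupancy and
spike histograms, so empty windows yield NaN bins rather than zero rates.
Decoded odor probabilities are mapped to past / present / future from the
trial table: past = previously presented odor of the sequence, present =
presented odor, future = expected odor at the next position of ABCDE.

Hypothesis tests on cycle 1 use paired t-tests across trials (odor B and C
trials pooled): past > future at the descending phase, future > past at the
ascending phase, present maximal at the trough. Cross-cycle analysis
z-normalizes each role over its whole normalization set, collapses phase
per cycle over the equidistant cycles {pre-2, 1, 3, 5}, and reports
linear/quadratic trends plus the stimulus × cycle interaction (identical
significance pattern asserted with and without normalization). Trial-type
comparisons average the expected-stimulus probability over the two
pre-entry cycles (correct vs incorrect OutSeq, positions 2–3) or take
cycle-1 reference-stimulus probabilities per phase (InSeq vs OutSeq), with
two-way ANOVAs and Bonferroni-corrected per-phase t-tests; at desk scale
the incorrect-OutSeq sample is ~10 trials, so the per-phase outcome test is
reported but only its direction is asserted in the test suite.

Single-cell phase maps train one univariate logistic model per neuron on
its trough rate, z-score each role's decoded probabilities over all bins
and trials, and classify each 10° bin by the arg-max z. Neurons pass a
phase-modulation screen (one-way test of decoded probability across the
three phase windows, α = 0.05, for at least one odor). The diagonal of the
3 × 3 (phase window × decoded role) proportion table is quantified as the
weighted correlation between row and column indices; the null permutes each
neuron's bin assignments (preserving its decoded-role distribution,
disturbing phase), 1000 draws.

Phase precession. Per neuron, the circular–linear correlation between
in-trial spike time and theta phase is computed by fitting the regression
phase ~ 2π·a·t (slope bounded at ±2 cycles per trial span, grid search plus
bounded refinement) and correlating measured against fitted phase; the
coefficient is signed by the fitted slope, so precession is negative, with
an asymptotic normal p-value; neurons with fewer than 10 in-trial spikes
are skipped, and significance is declared at p < 0.01. The ensemble
statistic computes, per cycle and 10° bin, each neuron's mean
present-stimulus decoding over B/C trials, brings neurons to a common scale
by z-scoring per neuron across bins within the cycle, sums across neurons,
normalizes each cycle's curve to [−1, 1], and takes the arg-max bin as the
cycle's peak phase (after a 10° circular smoothing for stability at small
ensembles). Two choices here deserve emphasis: z-scoring across neurons
within each bin and then summing across neurons — the literal "common
scale" recipe — is identically zero, hence the per-neuron normalization;
and the peak-phase vs cycle correlation runs over post-entry cycles only
(decoding still spans pre-3…6), because pre-entry "present"-stimulus
coding is predictive ascending-phase coding whose phase is not generated by
within-field precession and would contaminate the zero-precession null.
The permutation null shuffles the order of each trial's cycles and
recomputes the correlation.

## Sharp-wave-ripple control

Band events are supra-threshold (3 SD above the mean) excursions of the
analytic envelope of the filtered trace (ripple: 150–250 Hz bandpass on the
pyramidal-layer tetrode; sharp wave: > 4 Hz high-pass on the
stratum-radiatum tetrode), z-scored against whole-session envelope
statistics, with excursions within 15 ms merged. A SWR is the temporal
overlap of a sharp-wave and a ripple event, with union boundaries. The
envelope is the analytic-signal magnitude — the natural reading of an
instantaneous power estimate (a literal "real component of the Hilbert
transform" is just the filtered trace and is not a power). Trial exclusion
removes trials whose odor period or ±250 ms flanks intersect any event and
reports counts per window.

## The synthetic session generator

The generator emulates the statistical structure each stage assumes; its
defaults are the study conditions.

Trials: `n_sequences` (default 40) five-position sequences; position 1
always odor A InSeq; OutSeq substitution per position 2–5 with probability
`p_outseq` (default 0.125 each, so roughly half the sequences contain a
probe); error rates split by trial type (`p_incorrect` = 0.05 for InSeq —
rare anticipation errors with withdrawals just before the tone — and
`p_incorrect_outseq` = 0.25, since OutSeq judgments are the hard ones); an
error terminates the sequence. InSeq holds are 1.2 s plus a small jitter,
correct OutSeq withdrawals are N(0.751, 0.229) s clipped to [0.35, 1.15];
inter-odor intervals are log-normal with a 5 s median (poke-in to poke-in)
and a 0.8 s floor, with 12 s between sequences.

Time cells (role "none", 40 % of neurons by default): inhomogeneous
Poisson with rate baseline + peak · ρ^{|lag|} · exp(−(t−t0)²/2σ²) inside
the odor window, where lag is the sequence distance between the presented
and preferred odor; t0 ~ U[0, 1.2] s, σ ~ U[0.08, 0.25] s, peak ~ U[8, 20]
Hz, baseline ~ U[0.5, 2] Hz, ρ = 0.6. The lag gain is symmetric in ±lag.
Spikes are drawn per 1 ms grid cell; the homogeneous baseline process spans
the whole session.

Theta: the LFP is a shared sinusoidal carrier (6 Hz, 100 µV) plus
independent Gaussian noise (30 µV) per tetrode, so the true phase track is
closed-form. Theta-coding neurons represent one odor and carry three
multiplicative von Mises phase lobes (κ = 4, unit mean over uniform phase,
so phase coding leaves mean rates unchanged): the neuron fires for its
odor in its role as past, present, or future stimulus at 60°, 180°, or
300°; the configured role sets the dominant lobe (gain 1.0 vs 0.6). This
multi-lobe design is what lets a trough-trained classifier generalize
across phases — with single-lobe neurons the classifier would attribute
descending-phase activity to the odor those neurons weakly signalled at
the trough, and the within-cycle sequence could not be recovered. The
relational frame shifts at port entry (before the poke, the present lobe
codes the just-sampled odor and the future lobe the expected upcoming
odor), which produces the pre-entry predictive coding and the cross-cycle
past/present/future trends. Slow within-trial envelopes (present decaying,
future ramping) shape the cross-cycle dynamics. Optional phase precession
shifts every lobe's preferred phase by `precession_slope` (e.g.
−20°/cycle) times the cycle index.

Predictive coding and outcome: neurons preferring the expected odor
receive a rate pulse in the 400 ms before port entry (gain 0.8 × peak);
on incorrect trials only the predictive components (future lobe and
pre-entry pulse) are degraded (× 0.2) — the representation of already
experienced odors stays intact, which matters: silencing all pre-entry
activity on error trials would push the decoder into extrapolation and
bias comparisons. Outcome-modulated units (15 %) add 8 Hz for 500 ms after
withdrawal on incorrect trials. An injectable (default off) reactivation
schedule gives the current, next, and next-next expected odors' coding
neurons Gaussian gain pulses at 0.3, 0.7, and 1.1 s — off by default
because an always-on replay schedule would superimpose lag-nonmonotone
structure on the time-cell code that the lag analysis attributes to ρ
alone. Injectable SWR transients (default off) place co-timed ripple
(200 Hz burst) and sharp-wave (negative deflection) events on designated
tetrodes; their amplitudes are expressed in SD units of each channel's
background envelope — the scale the detector thresholds against — with the
carrier amplitude added to the deflection so destructive interference with
theta cannot mask a nominal 6 SD event.

What the generator does not emulate: spike-sorting artifacts, non-Poisson
firing statistics (bursting, refractoriness), cross-frequency coupling,
theta frequency drift and asymmetry, behavioral learning across the
session, and electrode drift. Passing recovery tests therefore shows the
analysis code is faithful to its stated model, not that the biological
effects would be detectable in any given recording.

## Problem sizes used by the test suite and acceptance script

Chosen once to fit a desk-scale run: lag-effect sweeps use 60 neurons / 40
sequences over 20 seeds (τ = 50 ms, step 25 ms; 100–200 time-shuffle
permutations); the null-calibration sweep uses 12 neurons / 10 sequences /
100 permutations over 200 seeds with non-overlapping bins; latent analyses
use 128-unit encoders, 80 epochs, 100 label shuffles; CNN and theta sweeps
use 40 neurons / 24 sequences over 20 seeds, with 200 cycle-order
permutations per seed for the precession null and 500–1000 permutations
for single-cell diagonals.

## Known limitations

- Chance levels for overlapping-bin time decoding are anti-conservative
  (see above); calibrated inference uses non-overlapping bins.
- The per-phase outcome comparison is underpowered at desk scale (~10
  incorrect OutSeq trials); only its direction is asserted.
- Generator effect sizes (lobe gains, degradation factors, pulse gains)
  are free parameters of the emulation, fixed in `GeneratorConfig`; they
  are calibrated to produce clearly detectable effects at desk scale, not
  to match any recorded effect size.
- The k = 2 nearest-neighbor rule with nearer-neighbor tie-breaking is
  point-wise equivalent to 1-NN; it is kept for protocol fidelity.
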