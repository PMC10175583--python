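# Methods

This note documents the models and numerical choices behind `napqeeg`: what
each stage computes, the defaults and why, what the synthetic cohort does
and does not emulate, and the package's known limitations.

## Recording model and staging

A recording is a synchronized block of µV-valued channels at 400 Hz: four
EEG leads (Fz, Cz, F3, F4, referenced occipitally), one bipolar EOG and one
bipolar EMG. Conditioning applies a 0.53–70 Hz band-pass and a 60 Hz
notch, both forward–backward (zero phase) so 3-s epoch boundaries are not
skewed by group delay.

Behavioral state is scored per 3-s epoch over {W, Drow, NREM, REM} from
three features: EMG RMS, relative delta power at Cz (coarse 1 Hz grid,
scorer-internal only), and EOG deflection counts (0.5–5 Hz smoothed,
25 µV threshold, pooled over a centered 15-s window). Rules apply in a
fixed priority: wake (EMG ≥ 10.5 µV with eye movements present), then
drowsiness (EMG in (1.7, 10.5) µV with relative delta < 0.30), then NREM
(relative delta ≥ 0.40, EMG below wake), then REM (EMG ≤ 1.7 µV, fast EEG,
eye movements present). Unclassified epochs inherit the previous label
(first epoch W), and a 3-epoch majority vote smooths the result. The
thresholds live in `ScorerConfig`; the defaults were calibrated once on
the synthetic state model *after* acquisition filtering (which attenuates
broadband EMG, so thresholds sit below the raw synthesis amplitudes).
Externally scored hypnogram CSVs can be supplied instead, bypassing the
scorer.

Macrostructure uses **all** epochs, including artifact-flagged ones:
latency to a state is the onset of its first epoch from recording start
(in minutes; missing if never entered), percentages are per-state epoch
shares of total recorded time, and sleep efficiency is
(NREM + REM time)/total time. Artifact flags matter only for quantitative
EEG, which uses exclusively artifact-free epochs whose both neighbours
share the same label (recording-boundary epochs count as transitions). A
trailing partial epoch is dropped.

Two genuinely open conventions were settled as follows: REM latency is
referenced to recording start (keeping all three latencies on one scale;
latency from sleep onset is a plausible alternative), and drowsiness never
counts as sleep in the efficiency formula.

## Spectral estimation

Power and coherence use 1-s Hamming windows with 50 % overlap inside each
selected 3-s epoch (five windows per epoch), zero-padded to a 4-s
transform so the bin grid is 0.25 Hz; the analysis grid is 0.5–50 Hz
inclusive, 199 bins. A 1-s window natively resolves 1 Hz, so the padding
realizes the stated grid by interpolation without pretending to finer
resolution. Relative power is normalized over exactly these 199 bins.
Band powers sum relative power over half-open intervals [low, high), so a
bin at exactly 4 Hz belongs to theta, not delta.

Coherence averages auto- and cross-spectra over all windows pooled across
epochs, then forms MSC per bin. Per-window MSC is identically 1 and
estimation from fewer than two windows is refused. Estimator bias for
independent signals is E[MSC] ≈ 1/K at K windows (slightly above with
overlapping windows — measured ≈ 1.3/K at 50 % overlap). The cross-spectrum
accumulates explicit real/imaginary sums so that swapping the channels is
bitwise symmetric. Fisher's variance-stabilizing transform is applied as
z = atanh(√MSC) — i.e. to the magnitude coherence, with MSC clipped to
1 − 1e−12; applying atanh to MSC itself is the other defensible reading,
and the transform function is exposed so either can be screened.

## Lempel–Ziv complexity

Each selected epoch is prefiltered (order-5 Butterworth band-pass 1–50 Hz,
zero-phase), binarized at its median (1 where sample > median; an option
for mean-thresholding exists), and parsed with the LZ76 exhaustive
production scheme: each new phrase is the shortest extension not
reproducible from the prior history by copy-extension (the copy may
overrun into the phrase being built). The phrase count is normalized by
log₂(n)/n, making white-noise epochs approach 1. Per subject and state the
value is the mean over selected epochs; parsing one concatenated state
signal instead would mix nonstationary segments and make the value depend
on epoch count, so it was not used. Binarization is rank-based, so LZC is
invariant to amplitude scale and offset.

## Cohort screening

Scalar sleep variables are screened by Spearman correlation with pairwise
deletion of missing values (subjects who never entered a state contribute
nothing for it); fewer than 4 complete pairs or a zero-variance side flags
the result as not computable. Two-sided p-values use the t approximation
t = ρ√((n−2)/(1−ρ²)) on n−2 df, except |ρ| = 1, which receives its exact
permutation tail 2/n!.

Multiplicity is handled per results table (macrostructure; LZC per
channel), mirroring the granularity at which such tables are reported,
with the two-stage adaptive FDR procedure: stage 1 is the linear step-up
at level q′ = q/(1+q); if it rejects nothing or everything, stop;
otherwise stage 2 is the step-up at q′·m/(m−r₁). q-values are defined
operationally as the smallest FDR level at which the full procedure
rejects the test (bisection; the rejection count is monotone in the
level), then made monotone in p. A caveat worth knowing: the two-stage
procedure is *not* uniformly a superset of the plain step-up — when stage
1 rejects less than about a 1/(1+q) fraction adjustment's worth of the
family, its stage-2 level dips below the nominal one. The property tests
assert the superset behaviour exactly in the regime where it provably
holds (stage-1 rejections ≥ (1 − q′/q)·m).

Frequency-resolved variables (relative power, Fisher-z coherence) are
screened bin-by-bin, and multiplicity is handled by Rüger's areas: maximal
runs of adjacent bins with p < 0.05 are significant as a whole iff at
least half their p-values are strictly below 0.05/2 and at least a third
strictly below 0.05/3. Fractions (not ceilings) implement "at least
half/a third", and a single bin with p < 0.05/3 is a legal significant
area. Bin-to-bin correlation makes clusters of spuriously significant
bins more common than independence would suggest; the null behaviour is
therefore *measured* in the tests rather than assumed, and small-cohort
runs can show many nominally significant areas — the rule is a screening
device, not a calibrated error rate.

## Synthetic cohort

The generator defines the study conditions under which everything is
tested. Its defaults mirror the published cohort structure: n = 28
subjects, 2-h naps (optionally uniform 1.01–2 h to mirror early
drop-outs), ages truncated-normal 13.25 ± 1.57 in [10.4, 16.2] years,
dementia-scale scores 0–70 with median ≈ 18, memory thresholds 0–120 s,
inhibitory-control percent piled near 100, detour percent near 50 (one
subject in ~28 missing), gaze 1.3–60 s with median ≈ 17.

**Hypnograms** come from a first-order Markov chain at 3-s resolution with
ordered entry (REM enterable only from NREM; parameterizations granting
rates to unreachable states are rejected). Default per-epoch rates
(W→D 0.025, D→W 0.035, D→N 0.022, N→D 0.012, N→R 0.0045, R→W 0.010,
R→N 0.020) give plausible nap macrostructure (median latencies ≈ 1–2 min
to drowsiness and ≈ 20 min to NREM, REM reached by roughly two thirds of
subjects in 2 h, so the missingness structure downstream code must
tolerate arises naturally).

**Signals** are sums of band-limited Gaussian noise per canonical band
with state-dependent amplitudes (NREM delta strictly dominant; EMG tone
ordered W > Drow > NREM > REM ≈ 0), a 1/f background, EOG baseline noise
plus biphasic ~0.5-s deflections at state-dependent Poisson rates, and a
shared cortical source per band mixed into each EEG channel with amplitude
a = m^{1/4} so the pooled MSC plateau of a channel pair equals m
(defaults 0.30–0.45 by state). Amplitude envelopes are smoothed over
~0.5 s at epoch boundaries. Everything is deterministic given the seed.

**Covariate effects** use a Gaussian copula: each targeted response gets a
latent standard-normal score correlated with the covariate's normal score
at r = 2·sin(πρ/6), and the latent multiplies the relevant chain rates
(e.g. D→N up and N→D down for NREM%) or signal-model amplitudes
(band amplitude for power effects, shared-component logit for coherence,
fast-band amplitudes for LZC) through exp(k·z), k = 0.6 for chain edges
and 0.35/0.8 for amplitudes/logits. Because the chain adds sampling noise
between the latent and the realized readout, requested effect sizes are
pre-compensated by attenuation constants measured once by simulation at
the defaults (rank correlation between latent and readout over ~800
subjects: 0.74 for NREM%, 0.63 for REM%, 0.85 for W%, 0.60 for Drow%,
0.20–0.36 for latencies — latency readouts are noisy because a nap
contains few entry events, so large latency targets saturate). The same
latents provide between-subject heterogeneity when no effect targets them.
Requested combined effects whose latent weights exceed unit variance are
rejected as infeasible rather than silently rescaled.

The summary-level fixture for screen-power experiments
(`synthetic_bin_screen`) builds a covariate correlated (default ρ = 0.8)
with the 1–1.75 Hz bins *only*: the remaining bins are residualized
against the covariate's rank scores, so "only" is literal in-sample rather
than in expectation, and a detected area's extent reflects the injected
band rather than chance flanking significance.

What the generator does **not** emulate: spindles/K-complexes, real
artifact morphology (artifact flags are sampled, not rendered),
ECG contamination (an optional toggle exists, off by default), volume
conduction, electrode-specific gains, or correlated covariates (covariates
are drawn independently; the published cohort's age–cognition correlation
is absent unless injected). Consequently, passing tests demonstrate that
the *analysis* recovers what the generative model encodes — not that the
scorer or screens would perform identically on recorded data.

## Problem sizes and numerical choices

Test and verification runs use sizes chosen to exercise each claim at
useful precision: effect-size recovery uses hypnogram-level cohorts
(no signal synthesis) at n = 28 × 100 seeds and n = 200 × 30 seeds; null
FDR calibration uses 500 hypnogram-level cohorts; scorer fidelity uses
20 seeds of 30-min naps (agreement is insensitive to nap length beyond a
few minutes); the full signal pipeline is exercised end to end on compact
cohorts (e.g. 4–12 subjects at 0.3–0.75 h) and scales linearly to the
full n = 28 × 2 h study (about 8 minutes on one CPU).

Numerical conventions: spectra are one-sided with DC and Nyquist outside
the analysis grid; MSC is clipped to [0, 1] before the Fisher transform;
EDF export quantizes each channel symmetrically to 16 bits over its own
range (round-trip error ≤ 1 quantization step, verified against an
independent reader); manifest hashes are SHA-256 of the written TSV bytes,
so identical seeds produce byte-identical studies.

## Limitations

The scorer is a rule-based emulation tuned to the synthetic signal model;
its near-perfect agreement there says nothing about inter-rater-grade
performance on clinical recordings. Rüger's-areas screening has no
formal family-wise guarantee (see above). Correlations are reported raw,
unadjusted for age, so age-driven confounding between cognition and sleep
variables is inherited by design. Phase-lag-index-style connectivity,
tonic/phasic REM subdivision, and multiscale entropy are out of scope.
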