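# Methods

## The measurement model

A brief optogenetic pulse at intensity `x` (on an arbitrary linearized level
scale, 1..L) evokes a network-wide population discharge (PD) with
probability

    f(x) = 1 / (1 + exp((a − x) / b)),

the Hodgkin–Huxley form of the Boltzmann sigmoid.  `a` is the I50 — the
intensity with P(PD) = 0.5 — and `b` the slope (level units).  The I50 is
the excitability metric: manipulations that increase excitability shift the
curve leftward (smaller `a`).  By construction `f(a) = 0.5` exactly, and the
fit is equivariant under shifts of the level axis (shifting levels by δ
shifts `a` by δ and leaves `b` unchanged); both properties are enforced by
tests.

The level scale is paired with an optical-power calibration table (default:
20 equally spaced levels spanning 0.43–4.15 mW at the fiber tip).  The mW
calibration is deliberately a user-supplied table: fiber transmission varies
per preparation, which is the main source of between-animal I50 variability,
and the linearized level scale is the default fitting axis for the same
reason (fits on the mW axis are supported via `axis="power"`).

## Stimulus designs

- **Pulse series**: every block presents each level exactly once, order
  independently randomized per block (per-block child seeds of one master
  seed, so designs are reproducible and block orders mutually independent).
  Onsets are spaced onset-to-onset at the ISI; this is the convention that
  makes the design arithmetic work (6 blocks × 20 stimuli × 1-s ISI = 120 s
  per bin).
- **Trains**: a train of frequency `f` and duration `T` contains
  `floor(T·f)` complete periods with onsets at `k/f` (6.67 Hz for 10 s gives
  66 pulses).  Whether the final incomplete period should count is
  ambiguous; the floor-of-complete-periods convention is the one consistent
  reading that reproduces the standard 66-pulse train, and it is pinned by a
  loop-based oracle test.

## Detection

Per channel: 5–300 Hz zero-phase Butterworth bandpass (corners pre-warped so
the forward-backward pass is −3 dB at the edges — an explicit filter
contract, since "bandpass filtered" alone underdetermines the realization),
peri-stimulus epochs (default 50 ms pre / 150 ms post), discrete second
derivative (central second difference × fs², edge-replicated), 10-ms
centered sliding RMS, and the per-trial statistic = max RMS inside a search
window of 5–100 ms post-onset.  The window start excludes the stimulus-onset
transient; the end covers the ~10-ms network latency plus the PD duration.
Both are configurable.

Because the PD is all-or-none, the per-trial statistics are bimodal.  The
automatic threshold is the midpoint of the largest gap between consecutive
sorted statistics, restricted to the inner 5–95% quantile range so single
outliers cannot define the gap; the separation score is gap width / IQR.
Any threshold inside the gap yields identical calls (tested), which is what
makes the procedure robust to threshold choice.  Channel selection maximizes
the separation score across candidates (ties break in candidate order), and
a manual threshold always overrides the suggestion.  Edge-clipped trials are
excluded with a warning and recorded in the result — never silently.

Afterdischarge detection: the 100-ms sliding-RMS envelope of the band-limited
trace must exceed `k = 4` × the pre-stimulus baseline median for ≥ 5
cumulative seconds (gaps ≤ 0.5 s merged) within 35 s of the train end;
duration runs from train start to the last supra-baseline spike (|x| > 5
baseline SD).  The ≥ 5-s persistence rule is the definitional criterion; the
envelope constants `k = 4` and the 5-SD spike threshold are surrogates for a
visual judgement and are exposed as parameters.

## Fitting

Per-level PD ratios are fit by nonlinear least squares (trust-region, `a`
initialized at the level whose ratio is nearest 0.5, `b` at 1, bounds keeping
`a` within half a scale-span of the fitted range and `b` positive).  A
trial-level Bernoulli likelihood would be better behaved at extreme ratios
but the ratio least-squares target is the procedure's definition, so it is
the implementation; fits require observed ratios on both sides of 0.5 and
otherwise raise a non-identifiability error rather than extrapolate (all-0,
all-1 and all-0.5 curves are rejected).  Uncertainty comes from resampling
whole blocks with replacement (default 200 resamples): blocks are the
exchangeable design unit, trials within a block are not.  Binned time
courses fit each bin of `blocks_per_bin` consecutive blocks independently
and subtract the whole-session I50; non-identifiable bins stay missing.
Condition comparisons are paired per subject (treatment − baseline, negative
= leftward), with an exact sign-flip permutation p-value (all 2^n flips for
n ≤ 20) and a subject-level bootstrap CI.

## Sequential statistics

Conditional probabilities are exact relative frequencies returned with their
numerator and denominator; empty conditioning sets raise rather than return
0/0.  `n-back` counts stimulus events, not seconds, and each n is computed
independently.  The near-I50 subset rule keeps trials at levels within
±0.25 of the session I50.  Pooling across sessions is trial-weighted (each
trial counts once); session-weighted pooling would be an alternative the
data do not distinguish.  Fisher's exact test uses the two-sided
probability-mass convention — sum hypergeometric probabilities of all tables
(same margins) no more probable than the observed one, with 1e-7 relative
slack for floating-point ties — implemented directly and cross-checked
against an exact integer enumeration and against scipy.  Holm–Šidák is the
step-down `1 − (1 − p)^(m−i+1)` with enforced monotonicity, cross-checked
against statsmodels.

## The synthetic-data generator

The simulator produces what the analysis assumes, with known ground truth:

- **PD truth**: Bernoulli per trial with p = f(level; a_true, b_true) ×
  suppression.  Suppression multiplies p by `suppress_rho = 0.5` when the
  most recent PD trial began strictly less than `suppress_window_s = 2` s
  before the current stimulus (onset-to-onset, matching the ISI convention).
  With a 1-s ISI this suppresses 1-back only (2-back is exactly at the
  window edge and unaffected); with a 3-s ISI trials are independent.
- **Waveforms**: PD trials place a stereotyped difference-of-Gaussians sharp
  wave (~30 ms, sharp component σ = 2 ms, amplitude 400 µV × site gain,
  ~10% lognormal jitter) at the 10-ms network latency on downstream
  channels; every trial places a graded evoked deflection (8 µV per level)
  at the stimulation site only.  The 8-channel layout mirrors a
  hippocampal/perihippocampal array with contralateral CA1 carrying the
  largest PD gain.
- **Desensitization**: an exponential state (recovery τ = 5 s) accumulates
  0.005 per level unit of each stimulus and scales the evoked amplitude —
  strong preceding stimuli reduce the next response, reproducing the
  negative 1-back amplitude slope at short ISIs.
- **Noise**: Gaussian noise spectrally shaped to 1/f (exponent 1), 6 µV RMS
  per channel, synthesized in the frequency domain.
- **Trains and ADs**: per-pulse PD probability decays geometrically (0.97
  per pulse, channelrhodopsin desensitization within the train); the AD is
  drawn from a logistic in the cumulative PD count (p50 = 5 PDs, steepness
  0.8 per PD, zero at zero PDs since an AD requires the PD), giving
  P(AD) ≈ 0.92 at 8 PDs and > 0.99 at 17.  AD duration (train start to last
  spike) is drawn from N(23.1 s, 4.84 s), truncated to at least 5.5 s of
  post-train activity, and rendered as a 12-Hz poly-spike envelope.
- **Spontaneous IIS**: Poisson-timed PD waveforms at stimulus-independent
  times, with injection times recorded for specificity scoring.

Defaults are fixed: sessions default to 20 levels × 60 blocks; the packaged
scenarios (`pharma-baseline` a = 16.4, `pharma-ptz` a = 14.5,
`pharma-ptz-lev` a = 15.7 levels) differ only in the generating I50 and use
a 3-s ISI, where trials are independent by the suppression window above.
The slope is b = 1.5 levels for all scenarios (a transition spanning roughly
six levels, consistent with observed single-session curves); sessions are
synthesized at 2 kHz, which preserves the whole 5–300 Hz analysis band at a
fraction of the acquisition-rate cost, and the rate is configurable.

What the generator does **not** emulate: biophysical network dynamics,
volume conduction, behavioral-state fluctuations of excitability, electrode
drift, movement or photovoltaic artifacts, or pathologic high-frequency
oscillations.  Waveform amplitudes are set for detector separability, not
biological fidelity — the generator gives clean sub/supra bimodality, so
passing recovery tests demonstrates correctness of the pipeline under the
model's assumptions, not detector performance on marginal recordings.

## Numerical and policy choices

- All randomness flows through numpy `SeedSequence`; identical seeds give
  bit-identical sessions and artifacts.
- Least-squares tolerances are 1e-14, tight enough that noiseless curves
  are recovered to 1e-6 and refitting a fit's own predictions is a fixed
  point to 1e-9.
- Undefined conditionals, degenerate threshold inputs (all-equal
  statistics), schema violations and out-of-range calibration queries are
  errors with diagnostic messages, each with its own exception type.
- Racine staging is data entry (video scoring is outside the package);
  kindling summaries use Spearman rank correlations with permutation
  p-values (exact for n ≤ 8).
- The staircase reports the first AD-evoking power (the operational
  definition), never a midpoint, and never stimulates past the first AD.

## Problem sizes used in validation

Parameter-recovery checks use 50 sessions per scenario at the full
20 × 60 design; detector sensitivity/specificity uses 50 compact sessions
(20 levels × 6 blocks); AD calibration uses 2000 simulated trains;
conditional-probability operations are verified exhaustively on all outcome
sequences of length ≤ 8 and Fisher's test on all 2×2 tables with N ≤ 40.

## Known limitations

- The detector is validated on synthetic data only; real recordings with
  weak sub/supra separation may need manual thresholds and channel choice
  (both supported).
- The AD envelope constants are surrogates for a visual criterion and may
  need retuning per preparation.
- The bootstrap CI requires the randomized-block design; curves built
  without block structure report point estimates only.
- Irradiance modelling (mW/mm²) is out of scope; power conversion is the
  calibration table only.
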