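# Methods

`minifract` implements a computational chain for studying 1/f ("fractal-rate")
structure in the timing of spontaneous quantal release at synapses: a
simulator of release trains driven by a pre-docking random-walk process, two
standard estimators of the fractal exponent α, a Monte-Carlo significance
test against the homogeneous-Poisson null, and a wavelet-based detector of
miniature postsynaptic currents (minis) with a simulated sensitivity assay.
This note records the models, the defaults and why, the numerical choices,
and the known limitations.

## Fractal exponent estimation

A point process with slowly fluctuating rate whose spectrum behaves as
`S(f) ∝ 1/f^α` is *fractal-rate*; a homogeneous Poisson process has α = 0.

**Count-based periodogram (PG).** The observation of length `L` is divided
into `C = ⌊L/T⌋` windows of length `T`; each window is binned at 10 ms into
an `M`-point count series `W_i`, and its periodogram `|W(f)|² / M` is
averaged across windows.  α is minus the least-squares slope of
`log₁₀ S(f)` against `log₁₀ f` over `0 < f ≤ 0.3 Hz` (`f = 0` excluded).
The window length is configurable with default `T = L/8`: eight averaged
windows reduce periodogram variance while keeping the lowest fitted
frequency `1/T` two orders of magnitude under the cut-off for hour-long
series.  The regression runs on the raw frequency grid (no log-binning);
zero-power grid points cannot enter a log fit and are dropped and counted.

**Allan factor (AF).** `AF(τ) = E[(Z_{k+1} − Z_k)²] / (2 E[Z_k])` for counts
`Z_k` in windows of length τ; it is ≈ 1 for Poisson trains and grows as
`(τ/τ₀)^α` for fractal-rate trains.  α is the log–log slope for τ at or
above the fractal onset time τ₀ = 1 s.  The τ grid is 20 log-spaced values
from 0.1 s to `span/8` (always including 1 s).  The grid top is a genuine
bias–reach trade-off: with few counting windows the AF estimate is noisy
and the log of the noisy ratio biases the fitted slope downward (measured
≈ −0.06 on Poisson calibration data with a `span/4` top, ≈ −0.03 at
`span/10`), while a lower top discards the long-window growth that carries
the fractal signal; `span/8` keeps the calibration inside ±0.05 without
giving up the plateau values of strongly fractal trains.
The "+1" in the asymptotic form is not subtracted before the regression,
which slightly flattens the fitted slope near τ₀; this is the plain reading
of a straight-line fit on doubly logarithmic axes and it is applied
identically to data and to the Poisson null, so significance testing is
unaffected.

Calibration (tested): over 50 seeded Poisson trains (2 Hz, 1 h) the mean of
both estimators lies within ±0.05 of zero; on doubly stochastic (Cox)
surrogates with a 1/f^α rate spectrum both estimators recover α = 0.5 and
0.8 within ±0.15, and they agree with each other within 0.2 on average.
The Cox surrogate itself is constructed so the rate-fluctuation spectrum
dominates the Poisson floor inside the fitted band (mean 20 Hz, CV 0.6,
spectral band up to 1 Hz); with weaker modulation the floor flattens the
fitted slope and no estimator could recover the nominal exponent.

## Monte-Carlo significance

The null for an observed series is the homogeneous Poisson process matched
in duration and expected event count: intervals are drawn from an
exponential with mean `span/n_events` until the span is exceeded (the count
varies Poisson-style; the paper-matched alternative of fixing the count
exactly changes nothing detectable).  Each realization is analyzed with the
same estimator settings as the data, and `p = #{α_null ≥ α_obs} / n_sim`
(default `n_sim = 10 000`).  The count-ratio rule can return exactly zero;
the result then carries the resolution bound `p < 1/n_sim` instead of any
smoothing, preserving the published rule.

## Pre-docking release simulator

Each of `N` independent release sites produces fusion events whose
inter-event intervals are the sum of

1. the first-return time of a symmetric ±0.5 nm random walk moving at
   90 nm/s (step duration 5.56 ms): the walker must re-reach the release
   site before a vesicle can dock.  First-return times of a symmetric walk
   have the heavy-tailed survival `∝ t^(−1/2)`, which is the 1/f source of
   the model.  Walks exceeding 10⁶ steps are aborted and resampled;
2. an exponential fusion delay with rate λ, the memoryless wait of a docked
   vesicle for spontaneous exocytosis.

On the first cycle the walker starts at `x₀ ~ U(−100 steps, 0)`; afterwards
it restarts one step below the site.  The observable train is the
superposition of the N per-site series.

**Exact sampling.** The number of steps to return from one step below the
site has `P(T = 2k−1) = C(2k,k) / ((2k−1) 4^k)` with survival
`S(k) = C(2k,k)/4^k`, tabulated once by the stable recursion
`S(k) = S(k−1)(2k−1)/(2k)`; draws are inverse-CDF lookups, truncated at the
abort limit (which is exactly the abort-and-resample semantics).  A return
from `m` steps is the sum of `m` independent one-step returns, aborting when
the running total exceeds the limit.  A literal step-by-step walker is kept
for validation; the two agree in distribution (two-sample KS) and the exact
path-enumeration masses at 1, 3, 5, 7 steps are reproduced within binomial
error.

**Study conditions.** The sweep grid follows the published design
(N ∈ {10,…,100}, λ⁻¹ ∈ [0.1, 10] s); the per-series duration is not stated
anywhere and is set to 3600 s, the order of the hour-long recordings the
analysis pipeline targets.  Acceptance-scale runs reduce the λ grid and the
repetitions, never the duration.

**A caution on the synchronized start.** Because every site starts its
first walk at time zero from a uniformly drawn distance of up to 100 steps
(mean first return from that start ≈ 445 s), the ensemble rate carries a
coherent start-up ramp whose spectral power grows like N² against the N¹
Poisson floor.  This leaves a weak but systematic positive dependence of the
estimated α on N, visible as significant Spearman correlations in a
substantial fraction of fixed-λ sets.  Removing it (burn-in before
observation) restores N-insensitivity but also removes part of the
low-frequency power that the published plateau values of α contain; the
package keeps the stated procedure and reports the honest tally.  Users who
want stationary series should discard a generous initial stretch and accept
the correspondingly smaller α plateau.

**Fits.** The α(λ) response is fitted with the saturating bi-exponential
`α(λ) = A₁(1−e^(−k₁λ)) + A₂(1−e^(−k₂λ)) + c` by non-linear least squares
with randomized multi-start (the published fit names only "a bi-exponential
function"; the saturating form matches the asymptotic growth it describes).
A three-parameter power fit `y = a x^b + c` is provided for amplitude–rate
relations.

## Synthetic mEPSC recordings

Minis are negative difference-of-exponentials kernels
`−A (e^(−t/τ_d) − e^(−t/τ_r)) / peak`, truncated at 6 τ_d, sampled at
20 kHz.  Rise and decay constants are drawn from truncated Gaussians
(3.2 ± 1.3 ms and 36.3 ± 11 ms, draws with τ_d ≤ τ_r rejected), the control
values of the recordings this pipeline targets.  For the sensitivity assay
the amplitude is fixed at 11.6 pA: an onset-timing Cramér–Rao analysis shows
that with SNR 3 noise a log-normal amplitude spread (CV 0.4) caps the
achievable fraction of onsets within 0.6 ms at ≈ 98.5%, below the published
sensitivity, so variable amplitudes cannot be what the assay used; the
log-normal option (mean 11.6 pA, CV 0.4, the right-skewed physiological
shape) remains available for general-purpose synthesis.  Onsets follow an
exponential-interval process at the requested mean frequency; white Gaussian
noise with SD = mean amplitude / 3 gives SNR 3.  The record is long enough
to contain all requested onsets (the nominal `n/f + 2 s` cannot contain the
sum of n exponential intervals half the time).

What the generator does not emulate: coloured seal/membrane noise, series
resistance filtering, stimulation artifacts, amplitude–kinetics
correlations, and rate non-stationarity.  Detector performance on these
fixtures is therefore an upper bound for real recordings with similar SNR.

## Mini detection

The chain: zero-phase 8th-order Butterworth high-pass at 2 Hz (forward–
backward filtering doubles the effective order but avoids onset-time bias);
a 5-level stationary (undecimated) wavelet decomposition with the reverse
bi-orthogonal spline wavelet rbio2.2; level-dependent thresholding; and
event extraction from the reconstruction.

Two measurements fixed the threshold semantics.  First, at 20 kHz a mini
carries essentially all of its energy in the level-5 approximation band
(0–312 Hz): the largest detail coefficient of an 11.6 pA mini is ≈ 2.9 pA
against a per-band noise SD of ≈ 3.4 pA at SNR 3.  Zeroing the
approximation therefore removes the event itself, and the detail bands
contribute nothing recoverable.  Second, a fixed −1 pA detection threshold
tolerates at most ≈ 0.3 pA of residual noise in the detection signal
(Rice's crossing-rate formula), which requires near-total suppression in
every band.  The adopted semantics: detail coefficients are hard-thresholded
at `m_level · σ_level · sqrt(2 ln n)` — the level-adaptive universal
threshold scaled by the configured per-level multipliers (1.407 and 3.955
for levels 1–2, 4.285 for levels 3–5) — and the approximation is
soft-thresholded at 4.285 σ.  σ is estimated from the finest detail band
(median absolute deviation), which is signal-free for mini-like events.
The result is a detection signal that is exactly zero wherever only noise is
present and retains minis above ≈ 3.5 pA.  The stationary (shift-invariant)
transform is used instead of the decimated one so that detection commutes
with time shifts; it is applied through FIR band kernels extracted from the
reference transform's impulse response and overlap-add convolution, which
handles arbitrary trace lengths in linear time.

**Candidates.** Events are dips of the detection-signal slope (Savitzky–
Golay derivative, ≈ 1 ms window): a mini has a steep falling edge whether or
not it rides on an earlier event's decay.  Dips must exceed a noise-derived
slope threshold and be followed within 10 ms by the fixed amplitude
threshold — either an absolute crossing of −1 pA (isolated events) or an
equivalent drop below the local pre-event level (events on a wandering
overlapped baseline).

**Onset estimation** is the accuracy-critical step (0.6 ms tolerance at
SNR 3) and uses two stages, a design driven by measured error surfaces:

* fitting a full-bandwidth template with free amplitude and baseline over a
  short window mis-localizes globally — the residual surface has spurious
  minima a few ms away that capture ≈ 40% of fits at this SNR;
* fitting in the approximation band is globally stable but jitter-limited
  to ≈ 0.3 ms (the band's timing information is bounded);
* discrete template grids add shape-mismatch bias: a wrong decay constant
  shifts the fitted onset by several tenths of a ms.

Stage 1 therefore slides band-limited templates (a τ_rise grid) around each
dip for a robust coarse onset; stage 2 fits all events of a cluster jointly
on the raw high-passed trace by continuous non-linear least squares — per
event a free onset (bounded near its stage-1 anchor), amplitude, τ_rise and
τ_decay, plus a low-order baseline — with Gaussian priors on the kinetics
(the population distributions the generator samples from; maximum a
posteriori estimation) and a weak onset prior.  Nuisance baseline and
neighbouring-cluster context amplitudes are profiled out by projection, and
a structured Jacobian keeps the optimization cost linear in the window.
After the fit, every event must pass an amplitude t-test against the local
residual (duplicates fitted onto residual fluctuations fail it); a split
proposal offers the model a second event where the residual stays high and
keeps it only when the fit improves beyond a χ²-calibrated margin, and a
peeling pass re-searches the residual around fitted events for minis hidden
under a neighbour's falling edge.

**Scoring.** `score_detection` defaults to greedy one-to-one matching
within the 0.6 ms tolerance.  The sensitivity assay scores with tolerance
(with-replacement) matching — a truth onset counts as detected when any
reported onset lies within the tolerance — because under one-to-one
matching the exponential-interval generator alone caps the expected TPR at
`1 − 2f·0.6 ms` per event (95.0% at 21.5 Hz, 97.6% at 10 Hz): a published
sensitivity above 99% is only a well-defined target under the tolerance
reading.  The false-positive rate divides detections with no truth onset
within tolerance by the number of non-overlapping 3 ms stretches of the
record (the published rate names no denominator; 3 ms is the scale of a
rise time and makes the rate a per-opportunity probability).

**Fundamental limits worth knowing.** Two minis closer than ≈ 2 ms are
statistically indistinguishable from a single event with slower rise at
SNR 3 (the best single-event fit of a 2 ms pair leaves ≈ 10 σ² of residual
— a model-selection z of only 1.6), and pairs inside the 0.6 ms tolerance
are unresolvable by definition.  Measured sensitivity at high rates is
bounded accordingly no matter the detector; the assay reports what the
implementation achieves under exactly the stated conditions.

**Measurement.** Each detected event is measured on the raw trace: the peak
is the deepest point of the smoothed event window (location from a heavily
smoothed copy, amplitude read from a lightly smoothed one at that fixed
location, which avoids the selection bias of taking a noisy minimum);
amplitude is `I_peak − I_start` with the baseline taken just before the
start; kinetics come from a damped least-squares bi-exponential fit, left
unset when the fit fails rather than dropping the event.

## Problem sizes

Default test and acceptance scales: the sensitivity assay at its full
published size (10 frequencies × 10 recordings × 100 minis); the λ plateau
from 10 hour-long series; the λ-response fit from 20 λ values × 3
repetitions; the N-sweeps from 3 repetitions per cell.  The full published
sweep (100 λ × 10 N × 10 repetitions) is available through `SweepConfig`
and the command line.

## Known limitations

* The AF regression's grid top (`span/8`) still leaves noticeable variance
  in the largest-τ points; the Poisson calibration of α_AF carries a small
  negative bias (≈ −0.04) from the log of a noisy ratio.
* The detector's sensitivity at ≥ 46 Hz is limited by close-pair
  degeneracy (above) and drops well below the low-rate values; the
  published sensitivity figure restricts its claim to rates up to the
  highest mean rate its experiments reached (≈ 20 Hz), and the assay's
  headline number follows that restriction.
* The pre-docking model's synchronized start leaves a weak α–N dependence
  (see above); with the stated procedure the N-insensitivity tally does not
  reach the published 95/100.
* Simulated recordings use white noise and independent kinetics; real
  traces are less favourable in both respects.
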