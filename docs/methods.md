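# Methods

## Transfer-function convention

Published ECG filter designs are usually printed as ratios of polynomials
in descending powers of a variable that, despite often being written "s",
is analyzed with z-plane pole-zero plots and unit-circle stability
arguments. This package therefore interprets every coefficient vector in
the delay variable: `b[k]` multiplies `z^{-k}`, i.e. the k-th delay of the
input, with the highest printed power mapping to delay 0. This is the only
reading under which the registry filters' published impulse magnitudes
(e.g. 14/41 = 0.34146 for the reduced-order filter) and unit-circle
stability analyses are coherent. True analog (s-domain) design, bilinear
transforms and quantized arithmetic are out of scope.

Responses are always computed on the normalized view (both vectors divided
by `a[0]`). Cost accounting deliberately is not — see below.

The registry transcribes the published coefficient vectors digit for
digit, including three defects that the test suite documents rather than
repairs: the 16-order ECG IIR and the 16-order speech IIR both have poles
outside the unit circle as printed (maximum moduli 3.06 and 1.07 — the
former driven by an implausibly small 113 among otherwise
thousands-scale denominator coefficients), and the 60-order FIR's printed
polynomial has one missing operator, resolved by the palindromic symmetry
of the remaining 60 coefficients (asserted programmatically).

## Response battery

* **Grid**: 512 equally spaced normalized frequencies on [0, π), endpoint
  excluded. Points where |H| < 1e−12 (or the denominator is exactly zero)
  are flagged undefined; summaries skip them. The Pan–Tompkins band-pass
  is 0/0 at DC, and the 60-order FIR has stopband nulls, so erroring
  would be wrong.
* **Group delay** is computed analytically as the ramp-weighted transform
  ratio τ(ω) = Re[B̃/B] − Re[Ã/A] with B̃ = Σ k·b_k e^{−jωk}, never by
  differencing the phase numerically. Accumulation runs in extended
  precision (`clongdouble`): near the FIR's deep magnitude nulls
  (|H| ≈ 1e−5) float64 cancellation costs about 2e−6 samples of accuracy,
  extended precision holds ~1e−12, and the test suite checks agreement
  with an independent phase-differentiation oracle at 1e−6.
* **Phase delay** is −φ/ω with φ unwrapped along the grid (2π-jump
  unwrapping anchored at the first defined point); the ω = 0 limit is the
  DC group delay.
* **Impulse summary** simulates the difference equation from zero state,
  extending the horizon (minimum 64 samples, cap 8192) until eight
  consecutive samples fall below 1e−8; a response still alive at the cap
  (an unstable filter) is flagged rather than raised, and a diverging
  response is truncated to its finite prefix.
* **Noise power spectrum**: analytic σ²|H|², one-sided on [0, π), whose
  band mean equals the output variance (Parseval). The Monte-Carlo
  companion filters seeded white noise (2¹⁶ samples by default) and
  Welch-averages periodograms (Hann, segment 1024, 50% overlap); the
  variance's standard error is estimated by batching the output into 64
  segments to respect filter-induced correlation.
* Group-delay units are samples throughout.

## Stability

Poles and zeros are roots of the coefficient vectors viewed as z
polynomials, padded so structural origin roots make the counts equal;
root finding is companion-matrix eigenvalues with balancing. The verdict
is three-way with tolerance 1e−10 on the maximum pole modulus, because the
Pan–Tompkins filter sits exactly on the circle (double pole at z = 1, which
the eigenvalue solver returns exactly). Classification ignores pole-zero
cancellation on purpose: the Pan–Tompkins numerator's double zero at z = 1
exactly cancels its poles (the filter is a squared 6-sample moving sum,
so its step response settles at 36 · 0.03125 = 1.125), but a direct-form
realization of the printed coefficients still carries the marginal modes,
and that is what the verdict describes. Coefficient round-trips through
roots are only well-conditioned to degree ~20; the 60-degree numerator is
instead verified by per-root residuals, evaluated through the reversed
polynomial at 1/z for roots outside the circle (palindromic taps give
reciprocal root pairs of huge modulus).

## Minimax order reduction

The objective is the weighted Chebyshev norm of the complex response
difference on the grid — the literal worst-case reading of "min-max" —
with a magnitude-only variant behind a config switch. Free parameters are
the `num_order+1` numerator and `den_order` trailing denominator
coefficients (`a0` fixed at 1), each boxed to [−20, 20]. The search is
scipy differential evolution (population 15 per free coefficient, up to
2000 iterations, tolerance 1e−10, seeded and hence bit-reproducible)
followed by a Nelder–Mead polish — a simplex method, because the max-norm
objective is non-smooth and gradient polishing would stall on the kinks.
A "consecutive" mode optimizes one coefficient at a time by bounded scalar
minimization, cycling until the largest change falls below 1e−9.

Stability is enforced by penalty (error + `stability_penalty`·(max pole
modulus − 1) for candidates on or outside the circle) rather than by
reparameterizing the denominator, keeping the search space the plain
coefficient vectors; a final safeguard radially shrinks any residual
boundary pole to modulus 0.995. An optional warm-start candidate `x0`
joins the initial population, which makes the nesting property (a larger
model class warm-started at a smaller optimum never does worse) hold by
construction.

Reducing the 16-order IIR to orders (1, 0) reproduces the published
reduced filter's quality: the optimizer's error (0.44 on the default grid)
is below the published (3z+14)/41's error (0.67) against the same
reference. Recovering the exact printed integers 3, 14, 41 is not claimed:
the reduction problem is under-determined without the original grid and
objective, and only the error bound is asserted.

## Implementation cost

Counts are taken on the as-printed coefficient vectors for a single-rate
direct form: multipliers are coefficients outside {0, +1, −1} (the leading
denominator coefficient counts once when not ±1 — realizing (3z+14)/41
costs a division by 41); adders are nonzero numerator taps minus one plus
nonzero trailing denominator taps; states are max(length) − 1 with
interior and trailing zeros kept in the lengths. This convention is the
unique simple one that reproduces the published Pan–Tompkins column
(4 multipliers, 4 adders, 12 states, lengths 13/3) and reduced-filter
column (3, 1, 1, lengths 2/1) simultaneously — which is also why costs use
as-printed rather than normalized coefficients: normalization would turn
the 41 into 1 and break the count of 3.

## Synthetic ECG

The generator is a Gaussian-bump morphology model, not a dynamical-system
ECG simulator: each beat is the sum of five Gaussians (P 0.15 mV/40 ms at
−0.2 s, Q −0.1 mV/10 ms at −0.03 s, R 1.0 mV/12 ms at 0, S −0.15 mV/15 ms
at +0.03 s, T 0.3 mV/70 ms at +0.25 s), all freely overridable. Defaults:
360 Hz sampling, 72 bpm, RR jitter sd 20 ms (truncated at ±3 sd, RR floor
0.25 s), first beat half an RR into the record. R-peak ground truth is the
rounded apex sample of each beat, exact by construction.

Noise classes are generated as separate named traces from independent
seeded streams and summed in sorted name order, so component additivity is
exact to the bit and removing one trace reproduces the remaining sum:
powerline is a pure mains sinusoid (50 Hz default, switchable) with
seeded phase; baseline wander is a 0.15 Hz sinusoid plus a random walk
low-passed below 0.7 Hz (2nd-order Butterworth, forward-backward); EMG is
white Gaussian noise; motion artefacts are Poisson-timed raised-cosine
bursts of random polarity (default 2/min, 0.5 s, 0.5 mV).

What this does and does not show: the generator exercises filtering and
detection under controlled, spectrally realistic contamination with exact
truth, but real recordings add morphology variability between beats,
ectopy and arrhythmia, electrode-contact transients correlated with the
QRS, and non-stationary noise. Perfect scores on clean synthetic data
validate the pipeline's mechanics, not clinical performance.

## R-peak detection

The detector is the classical Pan–Tompkins chain with the front-end filter
made pluggable: front-end filtering (bidirectional reduced-order IIR by
default) → five-point derivative (fs/8 · [1, 2, 0, −2, −1]) → squaring →
150 ms moving-window integration → adaptive dual thresholds
(signal/noise running estimates with gains 0.125, threshold = noise +
0.25·(signal − noise), initialized from the first 2 s) → 200 ms refractory
→ searchback at 1.66× the running 8-beat RR mean at half threshold. The
derivative and integration are centered (zero-delay) convolutions, and
each accepted detection is refined to the local maximum of the
band-filtered signal within ±50 ms; with a zero-phase front end the median
signed offset against truth is 0 samples, while forward-only filtering
shifts detections by the filter's group delay (≈1 sample for the
reduced-order filter). Scoring matches detections to truth one-to-one,
nearest first, within ±50 ms (the common ECG benchmarking tolerance).

## Problem sizes and determinism

Default analyses use the 512-point grid; dense-grid cross-checks use up to
8192 points. The Monte-Carlo noise check uses 2¹⁶ samples; detector
evaluations use 30–60 s records; reduction demos optimize 2–5 free
coefficients. Every stochastic component (generator, noise, optimizer,
Monte-Carlo) takes an explicit integer seed and is bit-reproducible for a
fixed seed.

## Known limitations

* The registry reflects the published coefficient vectors as printed,
  including their instabilities and transcription artifacts; it does not
  attempt to reconstruct the filters their authors likely intended.
* The minimax optimizer is a global heuristic: it carries no optimality
  certificate, only the seeded-search result plus the independent
  coarse-grid and baseline-bound checks in the test suite.
* WFDB record I/O is not provided; signals exchange as CSV (header
  `fs,<Hz>`, one sample per line).
* The detector targets normal sinus morphology; no beat classification,
  arrhythmia handling, or HRV analysis.
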