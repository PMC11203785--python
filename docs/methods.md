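# Methods

`palsfv` analyzes positron annihilation lifetime spectroscopy (PALS)
measurements of soft biological materials — specifically the free-volume
nanospaces in stratum corneum lipid bilayers — and ships a simulator that
generates statistically faithful spectra so the whole chain can be
validated without instrument data.

## The measurement model

A PALS spectrum is a histogram of positron annihilation times.  In soft
matter three discrete decay channels dominate:

| component | process | lifetime scale | intensity scale |
|---|---|---|---|
| tau1 | para-positronium self-annihilation | ~0.125 ns (vacuum value) | I3/3 |
| tau2 | free-positron annihilation | ~0.4 ns | balance |
| tau3 | ortho-positronium pick-off | 1.5–2.5 ns | ~9% |

Positronium forms with 1:3 para:ortho spin statistics, which is why the
simulator's ground-truth builder sets I1 = I3/3 and hands the remainder to
the free-positron channel.  The o-Ps pick-off lifetime tau3 carries the
free-volume information: the larger the cavity the o-Ps localizes in, the
lower the electron density it overlaps and the longer it lives.

Each component contributes a normalized exponential convolved with the
Gaussian timing response of the coincidence spectrometer (IRF).  The
expected count in a channel is the exponentially-modified-Gaussian (EMG)
probability mass integrated between the channel edges, computed in closed
form through the EMG survival function.  The survival form matters
numerically: channel masses are edge differences, and differencing the CDF
(which saturates at 1) destroys all relative accuracy in the tail, while
the survival function keeps the tail monotone and accurate down to
~1e-300.  An erfcx-stabilized branch avoids overflow in channels far
before the peak.  Components are renormalized over the finite acquisition
window, so the expectation sums exactly to the requested total counts even
for long lifetimes.

Default acquisition settings are 6.5 ps channels, 8192 channels, 1e6
counts under the curve, time zero at channel 1000 and a flat random
background fraction of zero.  The IRF FWHM defaults to 250 ps, a
conventional value for fast-fast coincidence setups with BaF2
scintillators; the instrument the data emulate did not have a published
resolution function, so this is a configurable convention, not a measured
value.  The same applies to the optional source term (annihilation in the
Kapton foil wrapping the positron source): it is off by default and
defaults to (0.382 ns, 10%) when enabled, a literature-conventional
choice.

Counts are drawn per channel from a Poisson law seeded by the ground
truth's seed, making every simulation a pure function of (settings, truth,
seed).

## Decomposition

`fit_components` re-implements the conventional discrete-component PALS
decomposition: the same channel-integrated EMG model is fitted to the
histogram with the component lifetimes, intensity fractions, time-zero
channel, IRF width, background level and signal normalization free.
Intensity closure is built into the parameterization (the bulk
free-positron fraction is derived as one minus the others), so reported
intensities always sum to 100%.

The default objective is the exact Poisson likelihood, minimized by
Levenberg-Marquardt on signed deviance residuals
`sign(c - mu) * sqrt(2*(mu - c + c*ln(c/mu)))`.  The more traditional
count-weighted least squares (variance = max(count, 1)) is available as
`weighting="counts"` but is not the default for a measured reason: in the
sparse o-Ps tail, channels that fluctuate low are over-weighted (the
Neyman chi-square effect) and the fitted tau3 is pulled several percent
below truth at 1e6 counts — far outside the percent-level accuracy the
method is expected to deliver.  Poisson-ML recovery at the default
settings is unbiased well below 0.1% in the mean with a seed-to-seed CV
of ~0.8% on tau3.

Numerical choices worth knowing:

- **Starting values and bounds.**  tau = (0.125, 0.40, 1.8) ns with bounds
  (0.05–0.3, 0.2–1.0, 1.0–5.0) ns; the physics fixes the ordering and
  rough scales, the near-disjoint windows prevent components from swapping
  roles mid-fit, and the output is sorted by lifetime regardless.
- **Time-zero start.**  The histogram mode lags t0 by roughly
  sigma^2/tau of the dominant component (~20 channels at the defaults), so
  the start is anchored on the rising-edge half-maximum, which sits within
  a few channels of the true time zero and is robust to Poisson noise.
- **Background.**  Estimated as the median of the pre-peak region (or the
  final 5% of channels when no pre-peak region exists) and then fitted
  freely — except when the estimate is zero, in which case the parameter
  is fixed at zero so it does not sit on its bound and degrade the
  covariance estimate.
- **Fit window.**  The full spectrum by default, which is optimal for
  Poisson counts.  An explicit `(first, last)` channel window is
  available, as in interactive PALS programs; it is the right tool for
  data whose low-count tail is not Poisson-like (for example, a
  deterministic model curve rounded to integers, where long runs of equal
  small integers systematically distort the likelihood).
- **Uncertainties** come from the local curvature (covariance) of the
  objective at the optimum.
- **Reduced chi-square** is the summed squared (deviance) residual per
  degree of freedom over the fitted window.  With thousands of empty
  far-tail channels included it sits well below 1 for a good fit; it is a
  relative diagnostic, not an absolute goodness probability.

Non-convergence is reported through the `converged` flag and the
optimizer message, never as an exception.

## Tao–Eldrup free-volume chain

The Tao–Eldrup model treats the o-Ps as a particle in a spherical well of
radius R + dR, where dR = 0.1656 nm is the electron-layer thickness on
the cavity wall, and gives

    tau3(R) = 0.5 * [1 - R/(R+dR) + sin(2*pi*R/(R+dR))/(2*pi)]^-1  ns.

The relation rises monotonically from the 0.5 ns pick-off limit and is
valid for R below about 1 nm; beyond that the package warns rather than
fails.  The inverse is solved by bracketed Brent iteration to a residual
below 1e-10 ns, and forward/inverse round-trip to better than 1e-9 nm.
Lifetimes at or below 0.5 ns, or above the image of R_max, are domain
errors.  A cavity diameter below 0.106 nm — the minimum able to host a
positronium atom — triggers a reporting warning.

From the radius, Vf = (4/3)*pi*R^3, and the fractional free volume is
estimated as fv = C * Vf * I3 with C = 0.0018 (conventional range
0.001–0.002; values outside it warn).  **I3 enters in percent, not as a
fraction.**  This convention is deliberate and load-bearing: it is the
one under which the published skin free-volume tables are internally
consistent cell by cell (e.g. 0.0018 * 0.084 * 8.96 = 0.00135), and it
places fv near 1.3e-3, often quoted as ~1.3 "a.u.".  All chains compute
at full precision and round only for display.

One published inconsistency is worth recording: the sample-IV row
(tau3 = 1.84 ns) prints R = 0.269 nm, but full-precision inversion gives
0.2697 ≈ 0.270 nm — the published table was evidently computed from
unrounded lifetimes.  Row-level anchors therefore use rows I and X, which
are self-consistent at printed precision.

## Replicate statistics

`summarize` reports the arithmetic mean, sample (n−1) standard deviation
and CV% per parameter.  Two CV bases are distinguished and labelled in
every output: the CV over per-sample rows (each already a replicate mean)
is systematically smaller than the CV over all raw repetitions — for the
published table, ~2.3% versus 3.21% on tau3 — and conflating them would
misstate the measurement scatter.  Normality is delegated to the standard
Shapiro–Wilk routine (decision: normal iff p > alpha, default 0.05).
The per-sample stability screen regresses tau3 and I3 on measurement time
and flags a sample when |slope| exceeds twice its standard error; the
2-SE rule is this package's own screen (replicate stability is
conventionally judged by eye) and has an expected per-parameter false-flag
rate of ~7% at 15 time points.

## Pipeline

`run_pipeline` chains simulate (or read) → fit → free-volume → summarize,
writing a fit CSV, free-volume CSV, full-precision summary, a
printed-precision report (2 decimals for tau3 and I3, 3 for R and Vf, 5
for fv), a normality block and a run log echoing the configuration.
Replicate seeds are derived from the master seed through a seed sequence,
so re-running a config is byte-identical in every CSV body.  A stage
failure aborts with the stage named and removes partial outputs.

## What the simulator does and does not emulate

It reproduces the statistical structure the analysis assumes:
three-component exponential decay with the 1:3 positronium split, Gaussian
IRF broadening, flat background, an optional source term, and Poisson
counting noise at the acquisition geometry above.  It does not model
detector pile-up or drift, energy-dependent response, 2-gamma/3-gamma
branching physics, source self-absorption, or any biological variability
between samples beyond their (tau3, I3) parameters.  Passing recovery
tests therefore demonstrate that the decomposition is faithful when the
data match the assumed model; they do not certify performance against
instrument artifacts the model excludes.

## Problem sizes used in the validation suite

Parameter-recovery checks use twenty seeded 1e6-count spectra at the
default acquisition settings; the end-to-end check simulates the eleven
published sample truths with three repetitions each (33 spectra), a size
chosen to exercise every stage at full spectral resolution while keeping
the suite quick to run.  Dispersion checks use 200 Poisson replicates of
the analytic expectation.
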