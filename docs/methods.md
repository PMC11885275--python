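# Methods

This note documents the models, estimators, and numerical choices behind
`dlsflow`, and what the synthetic-data tests do and do not establish about
real sensor data.

## Signal model

The package operates on two signal tiers, mirroring a device that samples
the speckle photocurrent fast internally but logs processed flow slowly:

- a **fast tier** (default 32,768 Hz) carrying the spectral content of the
  five hemodynamic-index bands up to 15 kHz, used for the band powers and
  the TBF/RBV spectral moments; and
- a **slow tier** (100 Hz) carrying the pulse wave and flowmotion, used for
  HRV and Hurst analysis.

The fast sampling rate is a modelling assumption: it is the smallest power
of two whose Nyquist frequency clears the 15-kHz upper band edge.

### Synthetic speckle trace

The fast trace is synthesised in the frequency domain: within each band the
Fourier magnitudes are flat and scaled so the integrated band power equals
the requested fraction exactly; phases are uniform random, and a global
rescale pins the total variance. This is a *spectrally calibrated
surrogate* — it reproduces the band-power observable the pipeline measures,
not speckle optics (no coherence or scattering geometry). Consequently the
tests establish calibration of the spectral chain, not fidelity to raw
interferometric data.

### Synthetic blood flow

The slow tier is `baseline + flowmotion + pulse train`:

- **Flowmotion** is a fractal process at the requested Hurst exponent. The
  stand-alone generator (`simulate_fractal_flowmotion`) uses exact
  Davies–Harte circulant embedding of fractional Gaussian noise, cumulated
  once when H ≥ 1; it is the ground truth for estimator-recovery tests.
  Inside the pulsatile signal the flowmotion component is instead
  synthesised with a power-law spectrum `S(f) ∝ f^(1−2H)` on a 2-Hz grid,
  spline-interpolated and low-passed at 0.4 Hz. Two reasons: the power-law
  form is continuous across H = 1, so a cohort whose Hurst targets sweep
  through 1 maps monotonically onto estimates (the exact fGn/fBm switch
  has a small-scale amplitude discontinuity at the boundary); and keeping
  vasomotion below the 0.5-Hz pulse floor is what makes beat detection
  with exact ground truth possible.
- **Beats** are marched through a modulated interval function
  `IBI = T0·(1 + m(t))` where `m` mixes a 0.10-Hz tone (LF), a 0.30-Hz
  tone (HF) and 1/f jitter confined to 0.005–0.04 Hz, with variance shares
  `lf : hf : 1 − lf − hf` and overall sd `ibi_cv·T0` (default 3%).
  Confining the remainder below the LF band makes the realized LF/HF
  fractions equal the targets. Each beat is a Gaussian systolic peak
  (σ = 0.12·T0) whose amplitude rides a fractal envelope at the target
  exponent (depth 0.3), so beat-to-beat variability carries long-range
  correlation as real pulse waves do.
- **Morphology jitter** exchanges pulse height against width
  (area-preserving log-normal jitter), degrading pulsatile regularity
  without altering the non-pulsatile flow level. Empirically this moves
  the AC-component Hurst estimate while leaving the DC component unchanged
  (differences < 0.01 across paired seeds). Note the direction: because
  the zero-phase 0.5-Hz high-pass bounds large-scale profile fluctuations,
  a *regular* pulse train scores anti-persistent (≈ 0.25) and morphology
  randomization moves the AC estimate toward the uncorrelated value 0.5 —
  the sensitivity is AC-specific, but in this surrogate the shift is
  upward from a low baseline rather than downward from a high one.

### Cohorts

A cohort is 3 groups × n subjects × 4 timepoints × 2 sites. Per-subject
parameters are drawn from scaled-logistic distributions matched to a group
median and IQR width (quartiles of the logistic sit at `m ± s·ln 3`, hence
`s = IQR/(2 ln 3)`); printed quartile pairs that are asymmetric about the
median are matched in median and width. Draws are rejection-clipped to the
parameter's validity range (e.g. H ∈ (0.05, 1.95)). Seeding fans a single
cohort seed through a `SeedSequence` spawn tree keyed by group, subject,
site and timepoint, so any segment is reproducible independently of
generation order.

The default endotoxemia scenario uses the study profile where printed
(control Hurst ≈ 1.0 throughout; intervention groups falling to ≈ 0.27–0.30
two hours after endotoxin, peripherally already ≈ 0.62–0.64 at one hour;
baseline band fractions 0.880/0.054/0.033/0.020/0.013 shifting toward
larger-vessel bands in the resuscitated group) and fills unprinted cells by
interpolation chosen so that central group differences do not emerge before
the two-hour timepoint, peripheral LF rises at two hours in the intervention
groups, and TBF/RBV/HF show no group effect. These fills are fixed design
choices of the scenario, not fitted quantities.

## Estimators

### Band powers and relHIs

Sliding 0.25-s Hann-tapered windows, mean-removed, one-sided periodogram
summed over half-open bands `[lo, hi)`. The default 0.01-s hop reproduces
the nominal 100-Hz relHI output rate. A 0.25-s window cannot resolve the
0.5-Hz lower edge (bin width 4 Hz); the resulting leakage is negligible
against the 1,000-Hz-wide lowest band and is accepted. The relHI
denominator is the five-band sum — printed index vectors sum to ≈ 1, which
pins that reading. All-zero windows become missing vectors, never zeros.

### TBF and RBV

The device vendor's derivation of TBF/RBV is proprietary; the package uses
documented spectral stand-ins with the same stated semantics: TBF, the
first spectral moment over 0.5–15,000 Hz of a Welch estimate per 1-s
window (scales with squared amplitude — volume-sensitive); RBV, the mean
spectral frequency (amplitude-invariant — a velocity surrogate). Both are
arbitrary-unit quantities; no absolute perfusion calibration is attempted.
The 30-s moving median is centred with partial windows at the edges and an
odd sample count.

### Beat detection and LF/HF

The pulse wave is the AC output of the 0.5-Hz zero-phase second-order
Butterworth split (the forward–backward pass squares the magnitude
response; the stated filter order refers to each one-way pass). Peaks above
0.3× the rolling 5-s peak envelope with a 0.25-s refractory interval are
beat candidates; two gates reject non-pulsatile residue (IBI coefficient of
variation ≤ 0.35, median peak width at half prominence ≤ 0.25 s). The IBI
tachogram drops intervals outside 0.2–2.0 s or deviating more than 30%
from the running 11-beat median, is cubic-interpolated to 4 Hz,
mean-removed, and Welch-transformed (256-s segments, Hann, half overlap).
LF and HF are band integrals normalized by the 0.005–0.400 Hz total;
resolving the 0.005-Hz edge requires ≥ 60 beats spanning ≥ 200 s, below
which the computation refuses rather than degrade silently. Constant
tachograms yield missing values (zero denominator).

### Hurst exponent (DFA)

First-order DFA: the mean-centred segment is cumulated, linearly detrended
in non-overlapping boxes taken from both ends of the profile, with
log-spaced box sizes (factor √2) from 16 samples to a quarter of the
segment; the exponent is the least-squares slope of log RMS fluctuation
against log box size. The 16-sample minimum avoids the well-known
small-box bias of linear detrending (with a 4-sample minimum the recovered
exponent for a true value of 1.1 is biased to ≈ 1.04; with 16 the grid
0.3/0.5/0.7/0.9/1.1 is recovered as 0.296/0.500/0.693/0.894/1.070 at 2^15
samples, 20 seeds). Estimates outside (0, 2.5) and segments with fewer
than four usable box sizes are reported missing. Windowed analysis uses
180-s windows with 90-s steps on the 100-Hz flow stream (a 1-Hz stream
would leave only 180 samples per window); AC/DC components are filtered
once on the whole series before windowing. A rescaled-range implementation
is kept in the test suite as an independent cross-check, not used by the
package.

### Statistics

All tests are two-sided. Wilcoxon tests (both forms) use the exact null
distribution for n ≤ 25 without ties, otherwise the tie- and
continuity-corrected normal approximation; Kruskal–Wallis and Friedman use
the tie-corrected chi-square reference. Pairwise tests run only after a
significant omnibus test, with Bonferroni multipliers equal to the number
of contrasts actually emitted (3 for groups, 6 for timepoint pairs). The
Youden cutoff scans midpoints of adjacent sorted unique values; the final
cutoff is the mean of all candidates attaining the maximal index, and the
reported sensitivity/specificity are re-evaluated at that mean cutoff (so
the reported index can fall below the maximum when ties straddle a class
boundary). The positivity direction follows the class medians per
parameter; whether a fixed a-priori direction should be used instead is
left configurable by the caller.

## Problem sizes

The test suite and acceptance script use scaled problem sizes chosen as
the smallest at which each property is stable: Hurst calibration and
recovery on 2^14–2^15-sample segments (20 seeds), Youden discrimination on
50 replicate 20-subject cohorts with 164-s flow segments per subject,
type-I-error calibration on 1,000 null cohorts at the summary-value level
(the statistical battery is what that calibration concerns; estimator
noise is symmetric across groups and does not alter the null), and
end-to-end pipeline checks on 6-subject cohorts with 240-s segments. The
full 10-subject, 900-s default cohort runs through `dlsflow run-all` in
roughly ten minutes on one core.

## Known limitations

- The speckle trace is a spectral surrogate; optical phenomena (speckle
  statistics, sensor coupling, motion artifacts) are out of scope, so
  robustness to such artifacts is untested.
- TBF/RBV are stand-ins with the stated scaling semantics, not replicas of
  the vendor algorithm; their absolute values are not comparable to device
  output.
- The full-signal Hurst estimate of the *pulsatile* surrogate compresses
  the generating exponent range (pulse energy contributes scale-free
  plateaus), so cohort analyses on pipeline estimates show attenuated but
  order-preserving group effects; recovery at the stated ±0.05 tolerance
  holds on the pure flowmotion path.
- Group scenario cells the study did not print are design choices; the
  scenario reproduces the qualitative effect pattern, and only the printed
  medians/IQRs should be treated as externally anchored.
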