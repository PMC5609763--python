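# Methods

## Signal model and conventions

An FID is modelled in the time domain as a sum of damped sinusoids

    ŷ_n = Σ_k a_k e^{iφ_k} e^{−d_k(1−g_k+g_k t_n) t_n} e^{i 2π f_k t_n},
    t_n = n Δt + t_0,  n = 0 … N−1,

fitted directly against the measured samples (no frequency-window
selection, no apodisation). The dead time `t_0` is a fixed acquisition
constant, never fitted; first-order phase effects enter only through the
time axis. The lineshape parameter `g_k` is prior knowledge, held fixed
per peak during fitting: `g=0` is pure Lorentzian (exponential decay),
`g=1` pure Gaussian (`e^{−d t²}`).

Unit conventions, applied at fixed conversion stages so that the
constraint map stays affine:

* **Chemical shift**: `f_k [Hz] = (δ_k [ppm] − δ_ref [ppm]) · f_0 [MHz]`,
  positive ppm offsets mapping to positive Hz. `δ_ref` is the shift
  placed at 0 Hz (e.g. PCr for ³¹P).
* **Linewidth**: prior knowledge is expressed as full width at half
  maximum (FWHM) in Hz of the absorption-mode line. Pure Lorentzian:
  `d = π·FWHM`. Pure Gaussian: `d = (π·FWHM/2)²/ln 2` (from the Fourier
  transform of `e^{−d t²}`). For intermediate `g` the damping is
  interpolated linearly between the two pure-form values — a package
  convention, since the mixed decay has no closed-form FWHM.
* **Phase**: radians internally, degrees in every user-facing file,
  table and report.
* Multiplet component offsets are kept in Hz (literature J-couplings)
  and added after the ppm→Hz conversion; this is identical to ppm
  offsets of `J/f_0` but exact for any transmitter frequency.

## Prior knowledge and the constraint map

A prior is a list of per-peak records (YAML, versioned, schema shipped):
bounds and starting values for amplitude/phase/linewidth/shift, the
lineshape, and relationships — multiplets (components share one free
amplitude and one free shift, with fixed ratios and J-spacings; a doublet
sits at ±J/2, a triplet at −J, 0, +J), group ids that make several peaks
share one free linewidth/amplitude/phase/shift (with optional additive
phase/shift offsets or amplitude ratios per member), an additive
`base_linewidth` in Hz, and fixed quantities (`lower == upper`).

Compilation produces `p_affine = S·x + c` with at most one nonzero scale
entry per row, followed by the unit conversions above. Free-parameter
bounds of a shared parameter are the **intersection** of the members'
bounds (any member's bound must hold); its starting value is the first
member's, clipped into the intersection. Group references are flat string
ids, so circular references cannot be expressed; offsets or ratios given
without the matching group id are compile-time errors. Relationships that
do not compile to affine form can be attached per row as arbitrary smooth
functions with caller-supplied (or finite-difference) Jacobians
(`ConstraintMap.set_custom_row`); everything shipped is affine.

## The two-step fit

1. **Linear initialisation.** With frequencies, dampings and lineshapes
   pinned at their starting values, the model is linear in the complex
   amplitudes `a_k e^{iφ_k}`; an unconstrained complex least-squares
   solve gives starting amplitudes `|c_k|` and phases `arg c_k`.
   Amplitude estimates are projected onto the constrained ratio
   directions by least squares; a group-shared phase is set to the
   amplitude-weighted circular mean of its members' phases (cheap,
   deterministic, and only a starting value). A rank-deficient basis
   falls back to the declared starting values with a warning.
2. **Nonlinear refinement.** Bounded least squares over the free vector
   with scipy's Trust-Region-Reflective solver, stacked real/imaginary
   residuals, and the analytic Jacobian `−[Re; Im](J_model · D)` chained
   through the constraint map. Defaults: `ftol = xtol = 1e−10`,
   `gtol = 1e−12`, at most 1000 evaluations; all configurable. The fit is
   deterministic — no random restarts. The first data point gets no
   special weighting; truncation of leading points is an option
   (default 0). Non-convergence returns the best iterate flagged rather
   than raising.

## Noise and uncertainty

The per-channel noise SD is estimated from the fit residual as the pooled
standard deviation of the real and imaginary channels with degrees of
freedom `2N − n_free`. With `J` the complex model Jacobian at the
estimates and `D` the constraint Jacobian, the Fisher information of the
free parameters is `D^T Re(J^H J) D / σ²`; its inverse is the CRLB
covariance, pushed back through `D` (and the unit conversions) to the
full-parameter covariance and per-parameter CRLBs in user units. This
`1/σ²` convention is validated two ways: a single undamped sinusoid with
only its amplitude free has CRLB exactly `σ/√N`, and Monte-Carlo
estimate SDs over seeded noise realizations match the CRLBs within
sampling error. Box bounds are ignored in the information matrix
(standard unconstrained CRLB); estimates pinned at a bound, or a
singular/ill-conditioned information matrix (then inverted by
pseudo-inverse), are recorded as warnings on the result — batch
processing flags any voxel carrying such warnings.

Derived quantities are strings over full-parameter labels
(`PCR_am`, `ATP_GAMMA1_am`, …) and named constants (saturation factors).
Value and gradient are compiled symbolically once, the delta method gives
`CRLB = √(g^T C g)` — exact for linear expressions — and the generated
code is persisted in a JSON cache keyed by a canonical hash of the
expression and the parameter-label set, so canonically identical
reformatting hits the cache while a changed label set recompiles. An
unwritable cache directory degrades to in-memory caching with a warning.

## Synthetic data

The generator produces FIDs from the same forward model plus complex
white Gaussian noise (`σ` per channel), and CSI phantoms with a smooth
2-D Gaussian-bump amplitude pattern scaled into [0.4, 1.0] over a
two-peak ³¹P-like template (PCr-like singlet at 0 Hz, second resonance
at −290 Hz; dampings 30 and 40 s⁻¹). Default phantom acquisition:
8×8×1 voxels, 2048 points at 0.25 ms dwell (4 kHz bandwidth), 120.3 MHz
transmitter — representative of 7 T ³¹P protocols; `σ = 0.01` gives
SNR 100 relative to the unit-amplitude template peak. One root seed
spawns an independent counter-based substream per voxel, so any voxel
subset is bit-reproducible in isolation. Designated "dead" voxels carry
all-zero samples (signal and noise) to exercise failure isolation.
Ground truth travels with the data in the fixture file's `truth` section.

What the phantom does *not* emulate — macromolecule baselines,
eddy-current and B₀-inhomogeneity distortions, voxel bleed, motion —
bounds what passing tests show: they verify estimator correctness under
the stated model, not robustness to real-data artefacts.

## DICOM import

Directory scanning builds a study→series→instance tree (DICOMDIR
references are followed) with a versioned JSON cache in the system temp
directory keyed by the directory path; entries are reused when a file's
size and mtime are unchanged, and a corrupt cache is discarded silently.
Siemens CSA private headers (both the CSA1 layout and the `SV10` CSA2
layout, auto-detected) are decoded natively, with parse errors carrying
byte offsets; the test suite cross-checks the codec against an
independent reader. Spectroscopy samples are interleaved 32-bit float
real/imaginary pairs; single voxels load as `FidSeries`, CSI as a
`CsiGrid` whose geometry (position of the first voxel centre, row/column
direction cosines, derived slice normal, voxel sizes) defines the
0-based voxel-index → patient-mm affine. Only the Siemens dialect is
implemented; the reader sits behind a small surface so other vendors can
be added. A synthetic fixture writer emits Siemens-style files (CSA2,
float32 samples) purely to exercise the reader, and a plain-text JSON
fixture format stores samples as base64 complex128 for bit-exact,
DICOM-free round trips.

## Verification problem sizes

The acceptance battery uses two-peak synthetics of 512–1024 points,
100 random draws for the Jacobian check, 500 noise realizations for the
Monte-Carlo CRLB comparison, and the default 8×8 phantom — sizes at
which every sampling-based tolerance is comfortably resolved.

## Known limitations

* Lineshapes beyond the Lorentzian–Gaussian interpolation (true Voigt,
  measured lineshape bases) are out of scope, as are metabolite basis-set
  fits, baseline/macromolecule models and water-reference scaling.
* The delta-method CRLB is first-order; for strongly nonlinear
  expressions at low SNR it can be optimistic.
* CRLBs assume the model is correct and the noise white; neither is
  checked.
* `lineshape_g` is never fitted.
* Phase wrapping: shared-phase initialisation uses a circular mean and
  phase bounds are enforced on the wrapped value; priors whose phase
  bounds span less than the data's true phase spread will bias the fit,
  as with any bounded estimator.
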