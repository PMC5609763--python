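"""Forward model for an FID as a sum of exponentially damped sinusoids.

The complex time-domain signal of ``K`` resonances is

    yhat_n = sum_k  a_k exp(i phi_k) exp(-d_k (1 - g_k + g_k t_n) t_n)
                    exp(i 2 pi f_k t_n),        t_n = n dt + t0,

with amplitude ``a_k`` (signal units), phase ``phi_k`` (radians), damping
``d_k`` (1/s), frequency ``f_k`` (Hz) and lineshape parameter ``g_k``:
``g = 0`` gives a pure Lorentzian (exponential decay), ``g = 1`` a pure
Gaussian (``exp(-d t^2)``) lineshape, intermediate values interpolate the
decay exponent.  The noise on each acquired point is complex white
Gaussian, i.i.d. with standard deviation ``sigma`` per real/imaginary
channel.

This module evaluates the model and its analytic Jacobian with respect to
the per-sinusoid parameters ``(a, phi, d, f)``; lineshape ``g`` and the
dead time ``t0`` are treated as fixed acquisition-side constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError

__all__ = [
    "FidSeries",
    "SinusoidParams",
    "NoiseModel",
    "evaluate_model",
    "model_jacobian",
    "fwhm_to_damping",
    "fwhm_to_damping_deriv",
    "shift_to_freq",
    "PARAM_SUFFIXES",
]

#: Fixed per-sinusoid parameter order used for Jacobian columns, constraint
#: rows and parameter labels: amplitude, phase, linewidth/damping, shift/freq.
PARAM_SUFFIXES = ("am", "ph", "lw", "cs")

_LN2 = math.log(2.0)


@dataclass
class FidSeries:
    """A free-induction decay plus the acquisition metadata needed to fit it.

    Parameters
    ----------
    samples
        Complex time-domain samples (arbitrary signal units), or ``None``
        for a metadata-only record (model evaluation, simulation).
    dwell_time
        Sampling interval ``dt`` in seconds.
    transmitter_freq
        Transmitter (Larmor) frequency ``f0`` in MHz; converts chemical
        shift in ppm to frequency offset in Hz.
    dead_time
        Time ``t0`` in seconds elapsed before the first sample; the time
        axis is ``t_n = n dt + t0``.
    reference_shift
        Chemical shift (ppm) that maps to 0 Hz in this acquisition
        (e.g. 0 ppm for PCr-referenced 31P spectra).
    nucleus
        Label such as ``"31P"`` or ``"1H"``; informational.
    n_points
        Number of points; required when ``samples is None``.
    """

    samples: np.ndarray | None
    dwell_time: float
    transmitter_freq: float
    dead_time: float = 0.0
    reference_shift: float = 0.0
    nucleus: str = "31P"
    n_points: int | None = None

    def __post_init__(self):
        if self.samples is not None:
            self.samples = np.asarray(self.samples, dtype=complex)
            if self.samples.ndim != 1 or self.samples.size < 1:
                raise ValidationError("samples must be a 1-D array of length >= 1")
            if self.n_points is None:
                self.n_points = self.samples.size
            elif self.n_points != self.samples.size:
                raise ValidationError("n_points disagrees with len(samples)")
        elif self.n_points is None or self.n_points < 1:
            raise ValidationError("metadata-only FidSeries needs n_points >= 1")
        if not (self.dwell_time > 0 and math.isfinite(self.dwell_time)):
            raise ValidationError(f"dwell_time must be > 0, got {self.dwell_time}")
        if self.dead_time < 0 or not math.isfinite(self.dead_time):
            raise ValidationError(f"dead_time must be >= 0, got {self.dead_time}")
        if not (self.transmitter_freq > 0 and math.isfinite(self.transmitter_freq)):
            raise ValidationError("transmitter_freq must be a positive MHz value")

    @property
    def n(self) -> int:
        return int(self.n_points)

    @property
    def time_axis(self) -> np.ndarray:
        """``t_n = n dt + t0`` for ``n = 0 .. N-1`` (seconds)."""
        return np.arange(self.n) * self.dwell_time + self.dead_time

    @property
    def bandwidth(self) -> float:
        """Spectral bandwidth ``1/dt`` in Hz."""
        return 1.0 / self.dwell_time

    def meta_only(self) -> "FidSeries":
        """Copy without samples (for model evaluation / simulation)."""
        return replace(self, samples=None, n_points=self.n)

    def with_samples(self, samples: np.ndarray) -> "FidSeries":
        return replace(self, samples=np.asarray(samples, dtype=complex),
                       n_points=len(samples))


@dataclass
class SinusoidParams:
    """Parameters of one damped sinusoid, in internal units.

    Phase is radians here; all user-facing files and tables use degrees.
    """

    amplitude: float
    phase: float
    damping: float
    frequency: float
    lineshape_g: float = 0.0
    name: str = "peak"

    def __post_init__(self):
        vals = (self.amplitude, self.phase, self.damping,
                self.frequency, self.lineshape_g)
        if not all(math.isfinite(v) for v in vals):
            raise ValidationError(f"non-finite parameter in sinusoid {self.name!r}: {vals}")
        if self.damping < 0:
            raise ValidationError(f"damping must be >= 0, got {self.damping}")
        if not (0.0 <= self.lineshape_g <= 1.0):
            raise ValidationError(f"lineshape_g must lie in [0, 1], got {self.lineshape_g}")


@dataclass
class NoiseModel:
    """Complex white Gaussian noise; ``sigma`` is the standard deviation of
    each of the real and imaginary channels."""

    sigma: float = 0.0

    def __post_init__(self):
        if self.sigma < 0 or not math.isfinite(self.sigma):
            raise ValidationError(f"sigma must be >= 0, got {self.sigma}")


# ---------------------------------------------------------------------------
# Linewidth and shift conventions.
#
# Lorentzian (g=0):  spectrum FWHM = d / pi          =>  d = pi * FWHM
# Gaussian  (g=1):   FT of exp(-d t^2) has
#                    FWHM = 2 sqrt(d ln 2) / pi      =>  d = (pi FWHM / 2)^2 / ln 2
# 0 < g < 1:         damping interpolated linearly between the two pure forms.
#
# Shift:  f[Hz] = (delta[ppm] - reference_shift[ppm]) * f0[MHz]; positive ppm
# offsets map to positive Hz.
# ---------------------------------------------------------------------------

def fwhm_to_damping(fwhm_hz: float, g: float) -> float:
    """Convert a full width at half maximum (Hz) to the damping ``d`` (1/s)."""
    d_lor = math.pi * fwhm_hz
    d_gau = (math.pi * fwhm_hz / 2.0) ** 2 / _LN2
    return (1.0 - g) * d_lor + g * d_gau


def fwhm_to_damping_deriv(fwhm_hz: float, g: float) -> float:
    """d(damping)/d(FWHM) at ``fwhm_hz`` for lineshape ``g``."""
    return (1.0 - g) * math.pi + g * math.pi ** 2 * fwhm_hz / (2.0 * _LN2)


def shift_to_freq(shift_ppm: float, meta: FidSeries) -> float:
    """Chemical shift (ppm) to frequency offset (Hz) for this acquisition."""
    return (shift_ppm - meta.reference_shift) * meta.transmitter_freq


def _single_peak(p: SinusoidParams, t: np.ndarray) -> np.ndarray:
    g = p.lineshape_g
    decay = np.exp(-p.damping * (1.0 - g + g * t) * t)
    return p.amplitude * np.exp(1j * p.phase) * decay * np.exp(2j * np.pi * p.frequency * t)


def evaluate_model(peaks: list[SinusoidParams], fid_meta: FidSeries) -> np.ndarray:
    """Evaluate the noiseless model FID, additive over sinusoids.

    Returns a complex array of length ``fid_meta.n``.
    """
    t = fid_meta.time_axis
    out = np.zeros(t.size, dtype=complex)
    for p in peaks:
        out += _single_peak(p, t)
    return out


def model_jacobian(peaks: list[SinusoidParams], fid_meta: FidSeries) -> np.ndarray:
    """Analytic complex Jacobian of the model FID, shape ``(N, 4K)``.

    Column order per sinusoid ``k`` follows :data:`PARAM_SUFFIXES`:
    ``d/da_k``, ``d/dphi_k``, ``d/dd_k``, ``d/df_k``.
    """
    t = fid_meta.time_axis
    jac = np.zeros((t.size, 4 * len(peaks)), dtype=complex)
    for k, p in enumerate(peaks):
        yk = _single_peak(p, t)
        g = p.lineshape_g
        # unit-amplitude contribution; valid even at a_k = 0
        unit = (np.exp(1j * p.phase)
                * np.exp(-p.damping * (1.0 - g + g * t) * t)
                * np.exp(2j * np.pi * p.frequency * t))
        jac[:, 4 * k + 0] = unit
        jac[:, 4 * k + 1] = 1j * yk
        jac[:, 4 * k + 2] = -(1.0 - g + g * t) * t * yk
        jac[:, 4 * k + 3] = 2j * np.pi * t * yk
    return jac
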