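"""Two-step AMARES fit of an FID under an affine constraint map.

Step 1 (:func:`initialize_linear`): with frequencies, dampings and
lineshapes pinned at their starting values the model is linear in the
complex amplitudes ``a_k exp(i phi_k)``, so a complex least-squares solve
gives starting amplitudes and phases essentially for free.

Step 2 (:func:`fit_amares`): bounded nonlinear least squares over the free
parameter vector, minimising the stacked real/imaginary time-domain
residual with the Trust-Region-Reflective algorithm
(``scipy.optimize.least_squares(method="trf")``) and the analytic Jacobian
chained through the constraint map.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, ValidationError
from .prior_knowledge import ConstraintMap, constraint_jacobian, peaks_from_free
from .spectral_model import (
    PARAM_SUFFIXES,
    FidSeries,
    evaluate_model,
    model_jacobian,
)

__all__ = ["FitOptions", "FitResult", "initialize_linear", "fit_amares",
           "estimate_noise"]

logger = logging.getLogger(__name__)


@dataclass
class FitOptions:
    """Solver configuration.

    ftol/xtol
        Function and step tolerances of the trust-region solver.
    max_iterations
        Cap on solver iterations (scipy counts function evaluations; the
        cap is passed as ``max_nfev``).
    truncate_initial_points
        Number of leading FID points dropped before fitting (dead-time
        corrupted points); default keeps everything.
    linear_init
        Run the linear amplitude/phase initialisation before the
        nonlinear step.
    compute_crlbs
        Fill covariance and CRLBs after the fit (needs noise in the data;
        skipped automatically when the residual is numerically zero).
    """

    ftol: float = 1e-10
    xtol: float = 1e-10
    max_iterations: int = 1000
    truncate_initial_points: int = 0
    linear_init: bool = True
    compute_crlbs: bool = True


@dataclass
class FitResult:
    """Everything the fit produced, in user units.

    ``full_estimates`` is ordered like ``labels`` (amplitude in signal
    units, phase in degrees, linewidth in Hz FWHM, shift in ppm per
    sinusoid).  ``covariance`` is over the free parameters (affine-space
    units); ``covariance_full`` over the full user-unit parameters, and
    ``crlbs`` its diagonal square root.  Covariance/CRLB fields are filled
    by the uncertainty module and are ``None`` for noiseless fits.
    """

    free_estimates: np.ndarray
    full_estimates: np.ndarray
    labels: list[str]
    free_labels: list[str]
    residual: np.ndarray
    noise_sigma: float
    converged: bool
    n_iterations: int
    cost: float
    message: str
    cmap: ConstraintMap
    meta: FidSeries
    covariance: np.ndarray | None = None
    covariance_full: np.ndarray | None = None
    crlbs: np.ndarray | None = None
    crlb_warnings: list[str] = field(default_factory=list)

    def estimate(self, label: str) -> float:
        return self.full_estimates[self.labels.index(label)]

    def crlb(self, label: str) -> float:
        if self.crlbs is None:
            raise ValidationError("CRLBs were not computed for this fit")
        return self.crlbs[self.labels.index(label)]

    def peak_table(self) -> list[dict]:
        """One record per sinusoid with estimates (and CRLBs if present)."""
        rows = []
        for k, name in enumerate(self.cmap.sinusoid_names):
            row = {"peak": name}
            for q, key in zip(PARAM_SUFFIXES,
                              ("amplitude", "phase_deg", "linewidth_hz",
                               "shift_ppm")):
                row[key] = self.full_estimates[self.labels.index(f"{name}_{q}")]
                if self.crlbs is not None:
                    row[f"{key}_crlb"] = self.crlbs[self.labels.index(f"{name}_{q}")]
            rows.append(row)
        return rows


def _wrap_into(value: float, lo: float, hi: float, period: float) -> float:
    """Shift ``value`` by multiples of ``period`` into [lo, hi] if possible,
    else clip."""
    v = value
    while v < lo and v + period <= hi:
        v += period
    while v > hi and v - period >= lo:
        v -= period
    return min(max(v, lo), hi)


def initialize_linear(fid: FidSeries, cmap: ConstraintMap,
                      start: np.ndarray | None = None) -> np.ndarray:
    """Linear least-squares initialisation of amplitudes and phases.

    Builds the unit-amplitude, zero-phase basis of every sinusoid at the
    starting frequencies/dampings, solves the complex least-squares
    problem, and folds ``|c_k|`` and ``arg(c_k)`` back onto the free
    amplitude and phase parameters (grouped phases get the
    amplitude-weighted circular mean of their members).  Returns an
    updated copy of the free starting vector; frequencies and linewidths
    are untouched.
    """
    if fid.samples is None:
        raise ValidationError("initialize_linear needs data samples")
    x0 = np.array(cmap.free_start if start is None else start, dtype=float)
    peaks = peaks_from_free(cmap, x0, fid)
    t = fid.time_axis
    basis = np.empty((fid.n, len(peaks)), dtype=complex)
    for k, p in enumerate(peaks):
        g = p.lineshape_g
        basis[:, k] = (np.exp(-p.damping * (1.0 - g + g * t) * t)
                       * np.exp(2j * np.pi * p.frequency * t))
    coef, _, rank, _ = np.linalg.lstsq(basis, fid.samples, rcond=None)
    if rank < len(peaks):
        logger.warning(
            "linear initialisation basis is rank deficient (%d < %d); "
            "keeping declared starting values", rank, len(peaks))
        return x0

    amp = np.abs(coef)
    pha = np.angle(coef)
    for j in range(cmap.n_free):
        suffix = cmap.free_labels[j].rsplit("_", 1)[-1]
        if suffix == "am":
            s = np.array([cmap.scale[4 * k, j] for k in range(len(peaks))])
            if np.any(s != 0):
                est = float(s @ amp / (s @ s))  # LS onto the ratio direction
                x0[j] = min(max(est, cmap.free_lower[j]), cmap.free_upper[j])
        elif suffix == "ph":
            members = [k for k in range(len(peaks))
                       if cmap.scale[4 * k + 1, j] != 0]
            if members:
                z = sum(amp[k] * np.exp(1j * (pha[k] - cmap.offset[4 * k + 1]))
                        for k in members)
                if abs(z) > 0:
                    x0[j] = _wrap_into(float(np.angle(z)), cmap.free_lower[j],
                                       cmap.free_upper[j], 2 * math.pi)
    return x0


def estimate_noise(residual: np.ndarray, n_free: int = 0) -> float:
    """Pooled per-channel noise SD of a complex residual.

    ``sigma^2 = (||Re r||^2 + ||Im r||^2) / (2N - n_free)``; pass the
    number of fitted free parameters to correct the degrees of freedom
    when the residual came out of a fit.
    """
    r = np.asarray(residual)
    if r.size < 8:
        raise ValidationError("need at least 8 residual points")
    dof = 2 * r.size - n_free
    ss = float(np.sum(r.real ** 2) + np.sum(r.imag ** 2))
    return math.sqrt(ss / dof)


def fit_amares(fid: FidSeries, cmap: ConstraintMap,
               options: FitOptions | None = None) -> FitResult:
    """Fit an FID with the two-step AMARES procedure.

    Raises :class:`FitError` on NaN in the data or when the number of
    data points cannot support the free parameters.  A non-converged
    solve returns the best iterate with ``converged=False`` rather than
    raising.
    """
    options = options or FitOptions()
    if fid.samples is None:
        raise FitError("fit_amares needs data samples")
    if not np.all(np.isfinite(fid.samples)):
        raise FitError("data contain NaN or Inf samples")

    if options.truncate_initial_points:
        k = options.truncate_initial_points
        fid = FidSeries(
            samples=fid.samples[k:], dwell_time=fid.dwell_time,
            transmitter_freq=fid.transmitter_freq,
            dead_time=fid.dead_time + k * fid.dwell_time,
            reference_shift=fid.reference_shift, nucleus=fid.nucleus)

    if fid.n <= cmap.n_free:
        raise FitError(
            f"{fid.n} points cannot constrain {cmap.n_free} free parameters")

    y = fid.samples
    x0 = initialize_linear(fid, cmap) if options.linear_init \
        else np.array(cmap.free_start, dtype=float)
    # trf requires a strictly interior start
    eps = 1e-12
    span = np.where(np.isfinite(cmap.free_upper - cmap.free_lower),
                    cmap.free_upper - cmap.free_lower, 1.0)
    x0 = np.minimum(np.maximum(x0, cmap.free_lower + eps * span),
                    cmap.free_upper - eps * span)

    def residual_fn(x):
        model = evaluate_model(peaks_from_free(cmap, x, fid), fid)
        r = y - model
        return np.concatenate([r.real, r.imag])

    def jac_fn(x):
        jm = model_jacobian(peaks_from_free(cmap, x, fid), fid)
        d = constraint_jacobian(cmap, x, fid)
        jfree = jm @ d
        return -np.concatenate([jfree.real, jfree.imag])

    res = least_squares(
        residual_fn, x0, jac=jac_fn,
        bounds=(cmap.free_lower, cmap.free_upper), method="trf",
        ftol=options.ftol, xtol=options.xtol, gtol=1e-12,
        max_nfev=options.max_iterations)

    x = np.minimum(np.maximum(res.x, cmap.free_lower), cmap.free_upper)
    model = evaluate_model(peaks_from_free(cmap, x, fid), fid)
    residual = y - model
    sigma = estimate_noise(residual, n_free=cmap.n_free)

    result = FitResult(
        free_estimates=x,
        full_estimates=cmap.to_user(cmap.affine(x)),
        labels=list(cmap.labels),
        free_labels=list(cmap.free_labels),
        residual=residual,
        noise_sigma=sigma,
        converged=bool(res.status > 0),
        n_iterations=int(res.nfev),
        cost=float(res.cost),
        message=str(res.message),
        cmap=cmap,
        meta=fid,
    )
    if not result.converged:
        logger.warning("fit did not converge: %s", res.message)

    if options.compute_crlbs:
        scale = float(np.max(np.abs(y))) or 1.0
        if sigma > 1e-12 * scale:
            from .uncertainty import compute_crlb
            compute_crlb(result, cmap)
        else:
            result.crlb_warnings.append(
                "residual is numerically zero; CRLBs not computed")
    return result
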