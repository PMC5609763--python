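"""Ground-truth FID and CSI-phantom simulation.

Signals are generated by the same forward model the fitter uses (a sum of
damped sinusoids) plus complex white Gaussian noise with per-channel
standard deviation ``sigma``.  All randomness flows from a single root
seed; each phantom voxel draws from an independent counter-based
substream (``numpy`` ``SeedSequence`` spawn keys), so any voxel subset is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dicom_io import CsiGeometry, CsiGrid
from .errors import ValidationError
from .spectral_model import FidSeries, SinusoidParams, evaluate_model

__all__ = ["PhantomSpec", "simulate_fid", "simulate_csi_phantom",
           "default_phantom_peaks", "truth_record"]


def truth_record(peaks: list[SinusoidParams], sigma: float, seed) -> dict:
    """JSON-serialisable ground-truth description of a simulated FID."""
    return {
        "sigma": float(sigma),
        "seed": None if seed is None else int(seed),
        "peaks": [
            {"name": p.name, "amplitude": p.amplitude, "phase_rad": p.phase,
             "damping": p.damping, "frequency_hz": p.frequency,
             "lineshape_g": p.lineshape_g}
            for p in peaks
        ],
    }


def simulate_fid(peaks: list[SinusoidParams], fid_meta: FidSeries,
                 sigma: float = 0.0,
                 seed: int | np.random.SeedSequence | None = None) -> FidSeries:
    """Simulate an FID: noiseless model plus complex white Gaussian noise.

    ``sigma`` is the SD of each of the real and imaginary channels.  The
    same ``seed`` always reproduces the same samples bit for bit.
    """
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    clean = evaluate_model(peaks, fid_meta)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, sigma, clean.size) \
            + 1j * rng.normal(0.0, sigma, clean.size)
        clean = clean + noise
    return fid_meta.with_samples(clean)


def default_phantom_peaks() -> list[SinusoidParams]:
    """Template peak set of the default phantom: two well-separated
    Lorentzians (a PCr-like singlet and a second resonance)."""
    return [
        SinusoidParams(amplitude=1.0, phase=0.0, damping=30.0,
                       frequency=0.0, lineshape_g=0.0, name="PCR"),
        SinusoidParams(amplitude=0.6, phase=0.0, damping=40.0,
                       frequency=-290.0, lineshape_g=0.0, name="ATP_GAMMA"),
    ]


def default_amplitude_map(dims: tuple[int, int, int]) -> np.ndarray:
    """Smooth 2-D Gaussian-bump amplitude pattern in [0.4, 1.0], shape
    ``(nx, ny, nz)``."""
    nx, ny, nz = dims
    i = np.arange(nx)[:, None, None]
    j = np.arange(ny)[None, :, None]
    k = np.zeros((1, 1, nz))
    ci, cj = (nx - 1) / 2.0, (ny - 1) / 2.0
    w = max(nx, ny) / 2.0
    bump = np.exp(-(((i - ci) / w) ** 2 + ((j - cj) / w) ** 2)) + k
    return 0.4 + 0.6 * (bump - bump.min()) / (bump.max() - bump.min() or 1.0)


@dataclass
class PhantomSpec:
    """Specification of a synthetic CSI phantom.

    ``amplitude_map`` (shape ``dims``) scales every template peak's
    amplitude per voxel; ``None`` selects the default smooth bump.
    ``zero_voxels`` lists voxel indices whose FID is forced to all-zero
    samples — signal *and* noise — emulating dead voxels for
    failure-isolation tests.
    """

    dims: tuple[int, int, int] = (8, 8, 1)
    peaks: list[SinusoidParams] = field(default_factory=default_phantom_peaks)
    amplitude_map: np.ndarray | None = None
    sigma: float = 0.01
    seed: int = 0
    n_points: int = 2048
    dwell_time: float = 2.5e-4
    transmitter_freq: float = 120.3
    nucleus: str = "31P"
    zero_voxels: tuple[tuple[int, int, int], ...] = ()

    def meta(self) -> FidSeries:
        return FidSeries(samples=None, n_points=self.n_points,
                         dwell_time=self.dwell_time,
                         transmitter_freq=self.transmitter_freq,
                         nucleus=self.nucleus)


def simulate_csi_phantom(spec: PhantomSpec) -> tuple[CsiGrid, dict]:
    """Simulate a CSI phantom; returns ``(grid, truth)``.

    ``truth`` holds the amplitude map and the per-voxel truth records in
    flat voxel order, in the same JSON-compatible layout the fixture
    format stores under its ``truth`` section.
    """
    dims = tuple(spec.dims)
    if any(d < 1 for d in dims):
        raise ValidationError(f"phantom dims must be >= 1, got {dims}")
    amp_map = spec.amplitude_map
    if amp_map is None:
        amp_map = default_amplitude_map(dims)
    amp_map = np.asarray(amp_map, dtype=float)
    if amp_map.shape != dims:
        raise ValidationError(
            f"amplitude_map shape {amp_map.shape} != dims {dims}")

    meta = spec.meta()
    root = np.random.SeedSequence(spec.seed)
    zero = {tuple(v) for v in spec.zero_voxels}

    geometry = CsiGeometry(position=np.zeros(3), row_dir=[1, 0, 0],
                           col_dir=[0, 1, 0], slice_dir=[0, 0, 1],
                           voxel_size=[10.0, 10.0, 10.0])
    fids: list[FidSeries] = []
    voxel_truth: list[dict] = []
    nx, ny, nz = dims
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                flat = (k * ny + j) * nx + i
                dead = (i, j, k) in zero
                factor = 0.0 if dead else float(amp_map[i, j, k])
                sigma = 0.0 if dead else spec.sigma
                peaks = [
                    SinusoidParams(
                        amplitude=p.amplitude * factor, phase=p.phase,
                        damping=p.damping, frequency=p.frequency,
                        lineshape_g=p.lineshape_g, name=p.name)
                    for p in spec.peaks
                ]
                sub = np.random.SeedSequence(spec.seed, spawn_key=(flat,))
                fid = simulate_fid(peaks, meta, sigma, seed=sub)
                fids.append(fid)
                rec = truth_record(peaks, sigma, spec.seed)
                rec["voxel"] = [i, j, k]
                voxel_truth.append(rec)

    actual_map = amp_map.copy()
    for (i, j, k) in zero:
        actual_map[i, j, k] = 0.0
    truth = {
        "amplitude_map": actual_map.tolist(),
        "zero_voxels": [list(v) for v in sorted(zero)],
        "voxels": voxel_truth,
        "template_peaks": truth_record(spec.peaks, spec.sigma, spec.seed)["peaks"],
    }
    return CsiGrid(dims=dims, fids=fids, geometry=geometry), truth
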