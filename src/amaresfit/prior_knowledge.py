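"""Declarative prior knowledge and its compilation to an affine constraint map.

Prior knowledge for a spectrum is a list of :class:`PeakPrior` records, one
per named resonance, giving bounds and starting values for the four fitted
quantities (amplitude, phase, linewidth, chemical shift) plus the
relationships between peaks that AMARES-style fitting exploits:

* **multiplets** — one resonance split by J-coupling into components with
  fixed frequency spacings and fixed amplitude ratios, all tied to a single
  free amplitude and a single free shift;
* **groups** — several peaks sharing one free linewidth, amplitude, phase
  or shift (optionally with per-peak additive offsets or ratios);
* **base_linewidth** — a fixed additive Hz term on a peak's linewidth.

Compilation produces a :class:`ConstraintMap`: an affine map
``p = scale @ x + offset`` from the free parameter vector ``x`` to the full
per-sinusoid parameter vector, followed by fixed unit conversions
(ppm -> Hz, FWHM -> damping, with J-coupling offsets applied in Hz).
Every shipped relationship is affine; arbitrary smooth per-row maps can be
attached through :meth:`ConstraintMap.set_custom_row` for extensions.

Affine-space units: amplitude in signal units, phase in **radians**,
linewidth in **Hz FWHM**, shift in **ppm**.  User-facing files and tables
use degrees for phase; conversion happens here and in reporting only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pydantic
import yaml

from .errors import ConstraintError, SchemaError, ValidationError
from .spectral_model import (
    PARAM_SUFFIXES,
    FidSeries,
    SinusoidParams,
    fwhm_to_damping,
    fwhm_to_damping_deriv,
)

__all__ = [
    "Multiplet",
    "PeakPrior",
    "ConstraintMap",
    "compile_prior",
    "apply_constraints",
    "constraint_jacobian",
    "peaks_from_free",
    "load_priors",
    "dump_priors",
    "prior_schema",
]

_DEG = math.pi / 180.0

_AM, _PH, _LW, _CS = 0, 1, 2, 3


class Multiplet(pydantic.BaseModel):
    """J-coupling multiplet structure of a peak.

    ``n_components`` components are placed symmetrically about the parent
    shift at spacings of ``j_hz`` (doublet at -J/2, +J/2; triplet at
    -J, 0, +J) with amplitudes ``amplitude_ratios[i] * free_amplitude``.
    """

    n_components: int = pydantic.Field(ge=2)
    j_hz: float = pydantic.Field(gt=0.0)
    amplitude_ratios: list[float] | None = None

    @pydantic.model_validator(mode="after")
    def _check_ratios(self):
        if self.amplitude_ratios is None:
            self.amplitude_ratios = [1.0] * self.n_components
        if len(self.amplitude_ratios) != self.n_components:
            raise ValueError("amplitude_ratios must have n_components entries")
        if any(r <= 0 for r in self.amplitude_ratios):
            raise ValueError("amplitude_ratios must all be > 0")
        return self

    def offsets_hz(self) -> list[float]:
        c = (self.n_components - 1) / 2.0
        return [(i - c) * self.j_hz for i in range(self.n_components)]


class PeakPrior(pydantic.BaseModel):
    """Bounds, starting values and relationships for one named peak.

    Quantities: shift in ppm, linewidth in Hz FWHM, amplitude in signal
    units, phase in degrees.  ``lower == upper`` fixes a quantity (it is
    removed from the free parameters).  Group ids are arbitrary strings;
    all peaks naming the same id share one free parameter for that
    quantity.  ``phase_offset``/``shift_offset`` are additive constants
    relative to the group value and require the matching group field.
    """

    name: str
    shift_start: float
    shift_lower: float | None = None
    shift_upper: float | None = None
    linewidth_start: float = 10.0
    linewidth_lower: float = 1.0
    linewidth_upper: float = 100.0
    amplitude_start: float = 1.0
    amplitude_lower: float = 0.0
    amplitude_upper: float = math.inf
    phase_start: float = 0.0
    phase_lower: float = -180.0
    phase_upper: float = 180.0
    lineshape_g: float = pydantic.Field(default=0.0, ge=0.0, le=1.0)
    multiplet: Multiplet | None = None
    group_linewidth: str | None = None
    group_amplitude: str | None = None
    group_phase: str | None = None
    group_shift: str | None = None
    amplitude_ratio: float | None = pydantic.Field(default=None, gt=0.0)
    phase_offset: float = 0.0
    shift_offset: float = 0.0
    base_linewidth: float = 0.0

    @pydantic.model_validator(mode="after")
    def _check(self):
        if self.shift_lower is None:
            self.shift_lower = self.shift_start - 0.2
        if self.shift_upper is None:
            self.shift_upper = self.shift_start + 0.2
        for q in ("shift", "linewidth", "amplitude", "phase"):
            lo = getattr(self, f"{q}_lower")
            st = getattr(self, f"{q}_start")
            hi = getattr(self, f"{q}_upper")
            if not (lo <= st <= hi):
                raise ValueError(
                    f"{q}: require lower <= start <= upper, got {lo}, {st}, {hi}")
        if self.linewidth_lower < 0:
            raise ValueError("linewidth_lower must be >= 0")
        if self.amplitude_lower < 0:
            raise ValueError("amplitude_lower must be >= 0 (amplitudes are areas)")
        return self


@dataclass
class _Sinusoid:
    """One expanded sinusoid (a multiplet component or a whole singlet)."""

    label: str          # e.g. ATP_GAMMA1 for component 1 of peak ATP_GAMMA
    peak: PeakPrior
    amp_ratio: float    # multiplet component ratio (1.0 for singlets)
    freq_offset_hz: float


@dataclass
class ConstraintMap:
    """Affine map from free parameters to the full per-sinusoid vector.

    ``p_affine = scale @ x + offset`` with affine-space units (signal,
    rad, Hz FWHM, ppm); rows are ordered ``(am, ph, lw, cs)`` per sinusoid.
    The full internal vector adds the fixed unit conversions and the
    per-sinusoid J-coupling offsets (Hz).
    """

    scale: np.ndarray          # (4K, n_free)
    offset: np.ndarray         # (4K,)
    free_lower: np.ndarray     # (n_free,)
    free_upper: np.ndarray
    free_start: np.ndarray
    labels: list[str]          # length 4K, "<SINUSOID>_<am|ph|lw|cs>"
    free_labels: list[str]     # length n_free
    sinusoid_names: list[str]  # length K
    lineshape_g: np.ndarray    # (K,)
    freq_offset_hz: np.ndarray  # (K,)
    custom_rows: dict[int, tuple[Callable, Optional[Callable]]] = dc_field(
        default_factory=dict)

    @property
    def n_free(self) -> int:
        return self.scale.shape[1]

    @property
    def n_full(self) -> int:
        return self.scale.shape[0]

    @property
    def n_sinusoids(self) -> int:
        return self.n_full // 4

    def set_custom_row(self, row: int, func: Callable[[np.ndarray], float],
                       jac: Callable[[np.ndarray], np.ndarray] | None = None) -> None:
        """Replace the affine map of one full-parameter row by an arbitrary
        smooth function of the free vector.

        ``func(x) -> value`` in affine-space units; ``jac(x) -> d value/dx``
        (length ``n_free``).  When ``jac`` is omitted a central finite
        difference is used.  This is the extension point for relationships
        that do not compile to affine form; everything shipped is affine.
        """
        if not (0 <= row < self.n_full):
            raise ConstraintError(f"custom row {row} out of range")
        self.custom_rows[row] = (func, jac)

    # -- affine stage -------------------------------------------------------
    def affine(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_free,):
            raise ValidationError(
                f"free vector has length {x.size}, expected {self.n_free}")
        p = self.scale @ x + self.offset
        for row, (func, _) in self.custom_rows.items():
            p[row] = func(x)
        return p

    def affine_jacobian(self, x: np.ndarray) -> np.ndarray:
        jac = self.scale.copy()
        for row, (func, jfunc) in self.custom_rows.items():
            if jfunc is not None:
                jac[row] = np.asarray(jfunc(x), dtype=float)
            else:
                h = 1e-6 * np.maximum(np.abs(x), 1.0)
                for j in range(self.n_free):
                    dx = np.zeros_like(x, dtype=float)
                    dx[j] = h[j]
                    jac[row, j] = (func(x + dx) - func(x - dx)) / (2 * h[j])
        return jac

    # -- conversion stage ---------------------------------------------------
    def conversion_diag(self, p_affine: np.ndarray, meta: FidSeries) -> np.ndarray:
        """Diagonal of d(internal)/d(affine) at ``p_affine``."""
        diag = np.ones(self.n_full)
        for k in range(self.n_sinusoids):
            diag[4 * k + _LW] = fwhm_to_damping_deriv(
                p_affine[4 * k + _LW], self.lineshape_g[k])
            diag[4 * k + _CS] = meta.transmitter_freq
        return diag

    def to_internal(self, p_affine: np.ndarray, meta: FidSeries) -> np.ndarray:
        """Affine-space vector -> internal ``(a, phi, d, f)`` per sinusoid."""
        p = np.array(p_affine, dtype=float)
        for k in range(self.n_sinusoids):
            p[4 * k + _LW] = fwhm_to_damping(
                p_affine[4 * k + _LW], self.lineshape_g[k])
            p[4 * k + _CS] = ((p_affine[4 * k + _CS] - meta.reference_shift)
                              * meta.transmitter_freq + self.freq_offset_hz[k])
        return p

    def to_user(self, p_affine: np.ndarray) -> np.ndarray:
        """Affine-space vector -> user units (phase rad -> degrees)."""
        p = np.array(p_affine, dtype=float)
        for k in range(self.n_sinusoids):
            p[4 * k + _PH] /= _DEG
        return p

    def user_conversion_diag(self) -> np.ndarray:
        diag = np.ones(self.n_full)
        for k in range(self.n_sinusoids):
            diag[4 * k + _PH] = 1.0 / _DEG
        return diag


def compile_prior(priors: list[PeakPrior]) -> ConstraintMap:
    """Compile peak priors into a :class:`ConstraintMap`.

    Multiplets are expanded to one sinusoid per component; grouped
    quantities collapse onto a single free parameter whose bounds are the
    intersection of the members' bounds (any member's bound must hold);
    fixed quantities (``lower == upper``) become constants.
    """
    names = [p.name for p in priors]
    if len(set(names)) != len(names):
        raise ConstraintError(f"duplicate peak names in prior: {sorted(names)}")

    for p in priors:
        for attr, grp in (("amplitude_ratio", "group_amplitude"),
                          ("phase_offset", "group_phase"),
                          ("shift_offset", "group_shift")):
            val = getattr(p, attr)
            if val not in (None, 0.0) and getattr(p, grp) is None:
                raise ConstraintError(
                    f"peak {p.name!r}: {attr} specified but {grp} is not set")

    sinusoids: list[_Sinusoid] = []
    for p in priors:
        if p.multiplet is None:
            sinusoids.append(_Sinusoid(p.name, p, 1.0, 0.0))
        else:
            for i, (off, ratio) in enumerate(zip(p.multiplet.offsets_hz(),
                                                 p.multiplet.amplitude_ratios)):
                sinusoids.append(_Sinusoid(f"{p.name}{i + 1}", p, ratio, off))

    n_full = 4 * len(sinusoids)
    rows_scale: list[dict[int, float]] = [dict() for _ in range(n_full)]
    offset = np.zeros(n_full)

    # one free parameter per (quantity, key); key is the group id when the
    # peak is grouped for that quantity, else the peak name
    free_index: dict[tuple[str, str], int] = {}
    free_lo: list[float] = []
    free_hi: list[float] = []
    free_st: list[float] = []
    free_labels: list[str] = []

    def quantity_spec(p: PeakPrior, suffix: str):
        """(lower, start, upper, additive_offset, ratio) in affine units."""
        if suffix == "am":
            return (p.amplitude_lower, p.amplitude_start, p.amplitude_upper,
                    0.0, (p.amplitude_ratio or 1.0))
        if suffix == "ph":
            return (p.phase_lower * _DEG, p.phase_start * _DEG,
                    p.phase_upper * _DEG, p.phase_offset * _DEG, 1.0)
        if suffix == "lw":
            return (p.linewidth_lower, p.linewidth_start, p.linewidth_upper,
                    p.base_linewidth, 1.0)
        return (p.shift_lower, p.shift_start, p.shift_upper, p.shift_offset, 1.0)

    group_field = {"am": "group_amplitude", "ph": "group_phase",
                   "lw": "group_linewidth", "cs": "group_shift"}

    for s_i, s in enumerate(sinusoids):
        p = s.peak
        for q_i, suffix in enumerate(PARAM_SUFFIXES):
            row = 4 * s_i + q_i
            lo, st, hi, add, ratio = quantity_spec(p, suffix)
            if suffix == "am":
                ratio *= s.amp_ratio
            if lo == hi:  # fixed quantity: constant row
                offset[row] = ratio * lo + add
                continue
            gid = getattr(p, group_field[suffix])
            key = (suffix, gid if gid is not None else f"__peak__{p.name}")
            if key not in free_index:
                free_index[key] = len(free_st)
                free_lo.append(-math.inf)
                free_hi.append(math.inf)
                free_st.append((st - add) / ratio)
                free_labels.append(f"{p.name}_{suffix}")
            j = free_index[key]
            # member bound on full value -> bound on free value (ratio > 0)
            free_lo[j] = max(free_lo[j], (lo - add) / ratio)
            free_hi[j] = min(free_hi[j], (hi - add) / ratio)
            if free_lo[j] > free_hi[j]:
                raise ConstraintError(
                    f"empty bound intersection for shared parameter "
                    f"{free_labels[j]!r} (group {key[1]!r})")
            rows_scale[row][j] = ratio
            offset[row] = add

    n_free = len(free_st)
    scale = np.zeros((n_full, n_free))
    for row, entries in enumerate(rows_scale):
        for j, v in entries.items():
            scale[row, j] = v

    start = np.minimum(np.maximum(free_st, free_lo), free_hi)

    labels = [f"{s.label}_{suffix}" for s in sinusoids for suffix in PARAM_SUFFIXES]
    return ConstraintMap(
        scale=scale,
        offset=offset,
        free_lower=np.asarray(free_lo),
        free_upper=np.asarray(free_hi),
        free_start=np.asarray(start),
        labels=labels,
        free_labels=free_labels,
        sinusoid_names=[s.label for s in sinusoids],
        lineshape_g=np.asarray([s.peak.lineshape_g for s in sinusoids]),
        freq_offset_hz=np.asarray([s.freq_offset_hz for s in sinusoids]),
    )


def apply_constraints(cmap: ConstraintMap, x: np.ndarray,
                      meta: FidSeries) -> np.ndarray:
    """Free vector -> full internal parameter vector ``(a, phi, d, f)`` per
    sinusoid.  ``meta`` supplies the ppm->Hz conversion constants."""
    return cmap.to_internal(cmap.affine(x), meta)


def constraint_jacobian(cmap: ConstraintMap, x: np.ndarray,
                        meta: FidSeries) -> np.ndarray:
    """Jacobian ``D = d(internal)/d(free)``, shape ``(4K, n_free)``.

    The unit-conversion chain rule makes the linewidth rows depend on the
    current free vector whenever the lineshape has a Gaussian component.
    """
    p_aff = cmap.affine(x)
    return cmap.conversion_diag(p_aff, meta)[:, None] * cmap.affine_jacobian(x)


def peaks_from_free(cmap: ConstraintMap, x: np.ndarray,
                    meta: FidSeries) -> list[SinusoidParams]:
    """Materialise :class:`SinusoidParams` at free vector ``x``."""
    p = apply_constraints(cmap, x, meta)
    return [
        SinusoidParams(
            amplitude=p[4 * k], phase=p[4 * k + 1], damping=p[4 * k + 2],
            frequency=p[4 * k + 3], lineshape_g=cmap.lineshape_g[k],
            name=cmap.sinusoid_names[k])
        for k in range(cmap.n_sinusoids)
    ]


# ---------------------------------------------------------------------------
# Prior-knowledge files (YAML, versioned)
# ---------------------------------------------------------------------------

PRIOR_FILE_VERSION = 1


def load_priors(path: str | Path) -> list[PeakPrior]:
    """Read a versioned YAML prior-knowledge file.

    Schema errors name the offending peak and field.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "peaks" not in doc:
        raise SchemaError(f"{path}: missing top-level field 'peaks'")
    if doc.get("version") != PRIOR_FILE_VERSION:
        raise SchemaError(
            f"{path}: field 'version' must be {PRIOR_FILE_VERSION}, "
            f"got {doc.get('version')!r}")
    priors = []
    for i, rec in enumerate(doc["peaks"]):
        try:
            priors.append(PeakPrior(**rec))
        except pydantic.ValidationError as err:
            fields = "; ".join(
                (".".join(str(loc) for loc in e["loc"]) + ": " if e["loc"]
                 else "") + e["msg"]
                for e in err.errors())
            name = rec.get("name", f"#{i}") if isinstance(rec, dict) else f"#{i}"
            raise SchemaError(
                f"{path}: peak {name!r}: invalid field(s): {fields}") from err
    return priors


def dump_priors(priors: list[PeakPrior], path: str | Path) -> None:
    doc = {"version": PRIOR_FILE_VERSION,
           "peaks": [p.model_dump(exclude_none=True) for p in priors]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def prior_schema() -> dict:
    """JSON schema of one prior-knowledge peak record."""
    return PeakPrior.model_json_schema()
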