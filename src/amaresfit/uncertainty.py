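"""Cramér-Rao lower bounds and delta-method uncertainty for derived quantities.

With ``J`` the complex model Jacobian at the estimates (``N x 4K``), ``D``
the constraint Jacobian mapping free to full internal parameters, and
``sigma`` the per-channel noise SD, the Fisher information of the free
parameters is ``D^T Re(J^H J) D / sigma^2``; its inverse is the CRLB
covariance.  Pushed back through the constraint map it gives the full
parameter covariance — including the cross-covariances that make CRLBs of
*derived* quantities (ratios, sums, saturation-corrected ratios) exact to
first order via the delta method.

Symbolic gradients of derived expressions are compiled once with sympy and
persisted in a small on-disk cache keyed by a canonical hash of the
expression and the parameter-label set, so repeat calls (and later
processes) never touch the symbolic layer again.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import re
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import sympy
from sympy.printing.pycode import pycode

from .errors import ExpressionError, UnknownIdentifierError, ValidationError
from .fitting import FitResult
from .prior_knowledge import ConstraintMap, constraint_jacobian
from .spectral_model import model_jacobian

__all__ = ["DerivedQuantity", "ExpressionCache", "compute_crlb",
           "derived_param_crlb", "warm_cache", "default_cache"]

logger = logging.getLogger(__name__)

_IDENT = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")

CACHE_SCHEMA_VERSION = 1


def compute_crlb(fit: FitResult, cmap: ConstraintMap,
                 jacobian: np.ndarray | None = None) -> FitResult:
    """Fill ``fit`` with the free/full covariance and per-parameter CRLBs.

    Parameters
    ----------
    fit
        A converged fit with ``noise_sigma > 0``.
    cmap
        The constraint map the fit used.
    jacobian
        Optional precomputed complex model Jacobian at the estimates.

    A singular information matrix falls back to the pseudo-inverse with a
    warning recorded in ``fit.crlb_warnings``; estimates pinned at a box
    bound are flagged the same way (the bounds themselves are ignored in
    the information matrix).
    """
    sigma = fit.noise_sigma
    if not sigma > 0:
        raise ValidationError("CRLB needs a positive noise sigma")
    from .prior_knowledge import peaks_from_free

    x = fit.free_estimates
    if jacobian is None:
        jacobian = model_jacobian(peaks_from_free(cmap, x, fit.meta), fit.meta)
    d = constraint_jacobian(cmap, x, fit.meta)
    fisher = np.real(jacobian.conj().T @ jacobian) / sigma ** 2
    info = d.T @ fisher @ d

    try:
        cov_free = np.linalg.inv(info)
        cond = np.linalg.cond(info)
        if cond > 1e12:
            fit.crlb_warnings.append(
                f"information matrix ill-conditioned (cond={cond:.2e})")
    except np.linalg.LinAlgError:
        cov_free = np.linalg.pinv(info)
        fit.crlb_warnings.append(
            "information matrix singular; pseudo-inverse used")
        logger.warning("singular Fisher information; CRLBs are a pseudo-inverse")
    cov_free = 0.5 * (cov_free + cov_free.T)

    at_bound = (np.isclose(x, cmap.free_lower) | np.isclose(x, cmap.free_upper))
    for j in np.flatnonzero(at_bound):
        fit.crlb_warnings.append(
            f"free parameter {fit.free_labels[j]!r} is at a box bound; "
            "its CRLB ignores the bound")

    # free (affine units) -> full user units
    s_aff = cmap.affine_jacobian(x)
    u = cmap.user_conversion_diag()
    j_user = u[:, None] * s_aff
    cov_full = j_user @ cov_free @ j_user.T
    cov_full = 0.5 * (cov_full + cov_full.T)

    fit.covariance = cov_free
    fit.covariance_full = cov_full
    fit.crlbs = np.sqrt(np.clip(np.diag(cov_full), 0.0, None))
    return fit


@dataclass
class DerivedQuantity:
    """A scalar function of the fitted parameters with its delta-method CRLB.

    ``gradient`` is with respect to the free parameter vector.
    """

    expression: str
    value: float
    crlb: float
    gradient: np.ndarray
    gradient_full: np.ndarray = field(repr=False, default=None)


def _canonical(expression: str) -> tuple[sympy.Expr, str]:
    idents = sorted(set(_IDENT.findall(expression)))
    local = {name: sympy.Symbol(name) for name in idents}
    try:
        expr = sympy.parse_expr(expression, local_dict=local, evaluate=True)
    except Exception as err:  # sympy raises a zoo of exception types
        raise ExpressionError(f"cannot parse expression {expression!r}: {err}")
    return expr, sympy.srepr(expr)


class ExpressionCache:
    """Disk-backed cache of compiled derived-expression value/gradient code.

    One JSON file per (expression, parameter-label set) key, holding the
    generated Python source for the value and each partial derivative.
    ``n_symbolic_compilations`` counts actual symbolic differentiations,
    so cache hits are observable.  An unwritable directory degrades to an
    in-memory cache with a warning.
    """

    def __init__(self, cache_dir: str | Path | None = None):
        self.cache_dir = Path(cache_dir) if cache_dir is not None \
            else Path(tempfile.gettempdir()) / "amaresfit-expr-cache"
        self._mem: dict[str, dict] = {}
        self._compiled: dict[str, tuple] = {}
        self.n_symbolic_compilations = 0
        self._writable = True
        try:
            self.cache_dir.mkdir(parents=True, exist_ok=True)
        except OSError as err:
            self._writable = False
            logger.warning("expression cache dir %s unwritable (%s); "
                           "falling back to in-memory cache", self.cache_dir, err)

    @staticmethod
    def key(expression: str, labels: tuple[str, ...]) -> str:
        _, canon = _canonical(expression)
        payload = canon + "||" + ",".join(sorted(labels))
        return hashlib.sha256(payload.encode()).hexdigest()

    def _path(self, key: str) -> Path:
        return self.cache_dir / f"{key}.json"

    def _load_entry(self, key: str) -> dict | None:
        if key in self._mem:
            return self._mem[key]
        path = self._path(key)
        if path.exists():
            try:
                entry = json.loads(path.read_text())
                if entry.get("schema") == CACHE_SCHEMA_VERSION:
                    self._mem[key] = entry
                    return entry
            except (json.JSONDecodeError, OSError):
                logger.warning("discarding corrupt cache entry %s", path)
        return None

    def get_or_compile(self, expression: str, labels: tuple[str, ...]) -> dict:
        expr, canon = _canonical(expression)
        key = hashlib.sha256(
            (canon + "||" + ",".join(sorted(labels))).encode()).hexdigest()
        entry = self._load_entry(key)
        if entry is None:
            params = sorted(str(s) for s in expr.free_symbols
                            if str(s) in set(labels))
            grads = {}
            for name in params:
                grads[name] = pycode(sympy.diff(expr, sympy.Symbol(name)))
            self.n_symbolic_compilations += 1
            entry = {
                "schema": CACHE_SCHEMA_VERSION,
                "expression": expression,
                "canonical": canon,
                "labels": sorted(labels),
                "value_code": pycode(expr),
                "grad_codes": grads,
            }
            self._mem[key] = entry
            if self._writable:
                try:
                    self._path(key).write_text(json.dumps(entry, indent=1))
                except OSError as err:
                    self._writable = False
                    logger.warning("cache write failed (%s); in-memory only", err)
        if key not in self._compiled:
            value_fn = compile(entry["value_code"], "<expr-cache>", "eval")
            grad_fns = {name: compile(code, "<expr-cache>", "eval")
                        for name, code in entry["grad_codes"].items()}
            self._compiled[key] = (value_fn, grad_fns)
        entry["_key"] = key
        return entry

    def evaluate(self, entry: dict, values: dict[str, float]):
        value_fn, grad_fns = self._compiled[entry["_key"]]
        ns = {"math": math, **values}
        value = eval(value_fn, {"__builtins__": {}}, ns)
        grads = {name: eval(fn, {"__builtins__": {}}, ns)
                 for name, fn in grad_fns.items()}
        return value, grads


_default_cache: ExpressionCache | None = None


def default_cache() -> ExpressionCache:
    global _default_cache
    if _default_cache is None:
        _default_cache = ExpressionCache()
    return _default_cache


def derived_param_crlb(expression: str, fit: FitResult,
                       constants: dict[str, float] | None = None,
                       cache: ExpressionCache | None = None) -> DerivedQuantity:
    """Evaluate a derived expression and its delta-method CRLB.

    ``expression`` is written over full-parameter labels (``PCR_am``,
    ``ATP_GAMMA1_am``, ...) and named scalar constants (e.g. saturation
    factors), all in user units.  The CRLB is
    ``sqrt(g^T Cov_full g)`` with ``g`` the expression gradient over the
    full parameters — exact for linear expressions, first-order otherwise.
    """
    if fit.covariance_full is None:
        raise ValidationError(
            "fit has no covariance; run compute_crlb on a noisy fit first")
    constants = dict(constants or {})
    cache = cache or default_cache()

    expr, _ = _canonical(expression)
    label_set = set(fit.labels)
    for sym in sorted(str(s) for s in expr.free_symbols):
        if sym not in label_set and sym not in constants:
            raise UnknownIdentifierError(sym)

    entry = cache.get_or_compile(expression, tuple(fit.labels))
    values = {lab: float(v) for lab, v in zip(fit.labels, fit.full_estimates)}
    values.update(constants)
    try:
        value, grads = cache.evaluate(entry, values)
    except ZeroDivisionError as err:
        raise ExpressionError(
            f"division by zero evaluating {expression!r} at the estimates") \
            from err
    value = float(value)
    if not math.isfinite(value):
        raise ExpressionError(
            f"expression {expression!r} is non-finite at the estimates")

    g_full = np.zeros(len(fit.labels))
    for name, gval in grads.items():
        g_full[fit.labels.index(name)] = float(gval)
    var = float(g_full @ fit.covariance_full @ g_full)
    crlb = math.sqrt(max(var, 0.0))

    cmap = fit.cmap
    j_user = cmap.user_conversion_diag()[:, None] \
        * cmap.affine_jacobian(fit.free_estimates)
    gradient_free = j_user.T @ g_full
    return DerivedQuantity(expression=expression, value=value, crlb=crlb,
                           gradient=gradient_free, gradient_full=g_full)


def warm_cache(expressions: list[str], labels: list[str] | tuple[str, ...],
               cache: ExpressionCache | None = None) -> Path:
    """Precompile derived expressions so later calls never differentiate.

    Returns the cache directory.
    """
    cache = cache or default_cache()
    for expression in expressions:
        cache.get_or_compile(expression, tuple(labels))
    return cache.cache_dir
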