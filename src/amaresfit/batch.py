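"""Batch fitting of CSI grids and FID collections into tidy result tables."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dicom_io import CsiGrid
from .errors import ValidationError
from .fitting import FitOptions, FitResult, fit_amares
from .prior_knowledge import ConstraintMap
from .spectral_model import FidSeries
from .uncertainty import ExpressionCache, derived_param_crlb

__all__ = ["BatchResult", "batch_fit", "write_results_csv", "read_results_csv"]

logger = logging.getLogger(__name__)

CSV_SCHEMA_VERSION = 1

#: Tidy result-table columns, one row per (voxel, peak).
TABLE_COLUMNS = [
    "voxel_i", "voxel_j", "voxel_k", "flat_index", "peak",
    "amplitude", "phase_deg", "linewidth_hz", "shift_ppm",
    "amplitude_crlb", "phase_deg_crlb", "linewidth_hz_crlb", "shift_ppm_crlb",
    "converged", "flagged",
]


@dataclass
class BatchResult:
    """Batch output: tidy table plus the per-voxel fit objects (or ``None``
    where a voxel failed outright)."""

    table: pd.DataFrame
    results: list[FitResult | None]
    dims: tuple[int, int, int]

    @property
    def n_flagged(self) -> int:
        return int(self.table.groupby("flat_index")["flagged"].any().sum())


def _voxel_rows(result: FitResult | None, index, flat, peak_names,
                derived, cache):
    i, j, k = index
    rows = []
    if result is None:
        for name in peak_names:
            rows.append({"voxel_i": i, "voxel_j": j, "voxel_k": k,
                         "flat_index": flat, "peak": name,
                         "converged": False, "flagged": True})
        return rows
    # any CRLB caveat (no noise estimate, singular/ill-conditioned
    # information, estimates pinned at bounds) flags the voxel
    flagged = ((not result.converged) or result.crlbs is None
               or bool(result.crlb_warnings))
    for rec in result.peak_table():
        row = {"voxel_i": i, "voxel_j": j, "voxel_k": k, "flat_index": flat,
               "peak": rec["peak"], "amplitude": rec["amplitude"],
               "phase_deg": rec["phase_deg"],
               "linewidth_hz": rec["linewidth_hz"],
               "shift_ppm": rec["shift_ppm"],
               "converged": result.converged, "flagged": flagged}
        for key in ("amplitude", "phase_deg", "linewidth_hz", "shift_ppm"):
            row[f"{key}_crlb"] = rec.get(f"{key}_crlb", np.nan)
        rows.append(row)
    if derived and not flagged:
        for name, expression, constants in derived:
            try:
                dq = derived_param_crlb(expression, result, constants,
                                        cache=cache)
                rows[0][name] = dq.value
                rows[0][f"{name}_crlb"] = dq.crlb
            except Exception as err:  # noqa: BLE001 - keep the batch alive
                logger.warning("derived quantity %r failed on voxel %s: %s",
                               name, index, err)
    return rows


def batch_fit(source: CsiGrid | list[FidSeries], cmap: ConstraintMap,
              options: FitOptions | None = None,
              derived: list[tuple[str, str, dict]] | None = None,
              cache: ExpressionCache | None = None) -> BatchResult:
    """Fit every voxel (or every FID in a list) independently.

    Per-voxel failures are logged and flagged without aborting the run;
    rows appear in flat (row-major) voxel order.  ``derived`` is an
    optional list of ``(column_name, expression, constants)`` evaluated
    per voxel through the derived-CRLB machinery.
    """
    if isinstance(source, CsiGrid):
        fids = source.fids
        dims = source.dims
        indices = list(source.indices())
    else:
        fids = list(source)
        dims = (len(fids), 1, 1)
        indices = [(i, 0, 0) for i in range(len(fids))]
    if not fids:
        raise ValidationError("batch_fit: empty source")

    peak_names = cmap.sinusoid_names
    rows: list[dict] = []
    results: list[FitResult | None] = []
    for flat, (index, fid) in enumerate(zip(indices, fids)):
        result: FitResult | None
        try:
            result = fit_amares(fid, cmap, options)
        except Exception as err:  # noqa: BLE001 - isolate voxel failures
            logger.warning("voxel %s failed: %s", index, err)
            result = None
        results.append(result)
        rows.extend(_voxel_rows(result, index, flat, peak_names,
                                derived, cache))
        status = "ok" if result is not None and result.converged else "FLAGGED"
        logger.info("voxel %s: %s", index, status)

    table = pd.DataFrame(rows)
    for col in TABLE_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan
    ordered = TABLE_COLUMNS + [c for c in table.columns
                               if c not in TABLE_COLUMNS]
    return BatchResult(table=table[ordered], results=results, dims=dims)


def write_results_csv(batch: BatchResult, path) -> None:
    """Write the tidy table as CSV (12 significant digits)."""
    batch.table.to_csv(path, index=False, float_format="%.12g")


def read_results_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def amplitude_map(batch: BatchResult, peak: str) -> np.ma.MaskedArray:
    """Fitted amplitude of ``peak`` per voxel, masked where flagged.

    Shape ``(nx, ny, nz)`` in voxel-index order.
    """
    sub = batch.table[batch.table["peak"] == peak]
    if sub.empty:
        raise ValidationError(f"unknown peak name {peak!r}")
    nx, ny, nz = batch.dims
    data = np.full((nx, ny, nz), np.nan)
    mask = np.ones((nx, ny, nz), dtype=bool)
    for _, row in sub.iterrows():
        i, j, k = int(row.voxel_i), int(row.voxel_j), int(row.voxel_k)
        if not row.flagged and np.isfinite(row.amplitude):
            data[i, j, k] = row.amplitude
            mask[i, j, k] = False
    return np.ma.MaskedArray(data, mask=mask)
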