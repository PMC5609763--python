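"""Static fit and amplitude-map figures.

Figures are rendered with the non-interactive Agg backend.  Every plotting
function also returns the arrays it drew, so tests (and downstream code)
can assert on the plotted data rather than on pixels.  In the fit figure
each individual peak's frequency-domain trace is truncated to a window of
2.5x its fitted full width at half maximum centred on its fitted
frequency — a display-only convention that keeps small peaks visible next
to dominant ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .batch import BatchResult, amplitude_map  # noqa: E402
from .fitting import FitResult  # noqa: E402
from .prior_knowledge import peaks_from_free  # noqa: E402
from .spectral_model import FidSeries, evaluate_model  # noqa: E402

__all__ = ["FitPlotData", "plot_fit", "plot_amplitude_map",
           "DISPLAY_FWHM_FACTOR"]

#: Displayed per-peak frequency support, as a multiple of the fitted FWHM.
DISPLAY_FWHM_FACTOR = 2.5


def spectrum(samples: np.ndarray) -> np.ndarray:
    """Centred complex spectrum of an FID (plain FFT, no apodisation)."""
    return np.fft.fftshift(np.fft.fft(samples))


@dataclass
class FitPlotData:
    """The arrays behind a fit figure."""

    time_axis: np.ndarray
    freq_axis: np.ndarray
    data_spectrum: np.ndarray
    model_spectrum: np.ndarray
    residual_spectrum: np.ndarray
    data_time: np.ndarray
    model_time: np.ndarray
    residual_time: np.ndarray
    #: peak name -> real spectrum with NaN outside the display window
    peak_spectra: dict[str, np.ndarray]
    #: peak name -> (centre frequency Hz, full display width Hz)
    peak_windows: dict[str, tuple[float, float]]


def fit_plot_data(fid: FidSeries, result: FitResult) -> FitPlotData:
    """Compute everything :func:`plot_fit` draws."""
    peaks = peaks_from_free(result.cmap, result.free_estimates, fid)
    model = evaluate_model(peaks, fid)
    residual = fid.samples - model
    freq = np.fft.fftshift(np.fft.fftfreq(fid.n, fid.dwell_time))

    peak_spectra: dict[str, np.ndarray] = {}
    peak_windows: dict[str, tuple[float, float]] = {}
    for k, peak in enumerate(peaks):
        name = result.cmap.sinusoid_names[k]
        fwhm = result.estimate(f"{name}_lw")
        width = DISPLAY_FWHM_FACTOR * fwhm
        spec = spectrum(evaluate_model([peak], fid)).real
        windowed = np.where(np.abs(freq - peak.frequency) <= width / 2.0,
                            spec, np.nan)
        peak_spectra[name] = windowed
        peak_windows[name] = (peak.frequency, width)

    return FitPlotData(
        time_axis=fid.time_axis,
        freq_axis=freq,
        data_spectrum=spectrum(fid.samples),
        model_spectrum=spectrum(model),
        residual_spectrum=spectrum(residual),
        data_time=fid.samples,
        model_time=model,
        residual_time=residual,
        peak_spectra=peak_spectra,
        peak_windows=peak_windows,
    )


def plot_fit(fid: FidSeries, result: FitResult, out_path) -> FitPlotData:
    """Render the standard fit figure (time + frequency domain, residual,
    per-peak spectra) to ``out_path`` and return the plotted arrays."""
    d = fit_plot_data(fid, result)
    fig, axes = plt.subplots(2, 2, figsize=(11, 7))

    ax = axes[0, 0]
    ax.plot(d.time_axis * 1e3, d.data_time.real, "k", lw=0.7, label="data")
    ax.plot(d.time_axis * 1e3, d.model_time.real, "r", lw=0.9, label="fit")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("Re FID")
    ax.legend(frameon=False)

    ax = axes[0, 1]
    ax.plot(d.freq_axis, d.data_spectrum.real, "k", lw=0.7, label="data")
    ax.plot(d.freq_axis, d.model_spectrum.real, "r", lw=0.9, label="fit")
    ax.invert_xaxis()
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("Re spectrum")
    ax.legend(frameon=False)

    ax = axes[1, 0]
    ax.plot(d.freq_axis, d.residual_spectrum.real, "b", lw=0.7)
    ax.invert_xaxis()
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("residual")

    ax = axes[1, 1]
    for name, spec in d.peak_spectra.items():
        ax.plot(d.freq_axis, spec, lw=0.9, label=name)
    ax.invert_xaxis()
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("peaks (2.5 x FWHM windows)")
    ax.legend(frameon=False, fontsize=7)

    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return d


def plot_amplitude_map(batch: BatchResult, peak: str, out_path,
                       slice_k: int = 0) -> np.ma.MaskedArray:
    """Render the fitted amplitude of one peak across a CSI slice.

    Flagged (failed) voxels are masked out of the image.  Returns the
    masked 2-D array that was drawn.
    """
    amap = amplitude_map(batch, peak)[:, :, slice_k]
    fig, ax = plt.subplots(figsize=(5, 4.4))
    im = ax.imshow(amap.T, origin="lower", cmap="viridis",
                   interpolation="nearest")
    ax.set_xlabel("voxel i")
    ax.set_ylabel("voxel j")
    ax.set_title(f"{peak} amplitude")
    fig.colorbar(im, ax=ax, label="amplitude (signal units)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return amap
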