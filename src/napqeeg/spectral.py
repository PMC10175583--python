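"""Welch power spectra and magnitude-squared coherence on a 0.25 Hz grid.

Estimation follows the nap-PSG qEEG convention: 1-s tapered windows with 50 %
overlap are taken inside every selected 3-s epoch (five windows per epoch),
zero-padded to a 4-s transform so the frequency grid has 0.25 Hz spacing, and
periodograms / cross-spectra are averaged over all windows pooled across
epochs.  The analysis grid runs from 0.5 to 50 Hz inclusive (199 bins);
relative power is normalized over exactly these bins.

A 1-s window natively yields 1 Hz spacing; the 0.25 Hz grid is obtained by
zero-padding each window to 4 s before the transform, which interpolates the
spectrum without changing the underlying resolution.  Coherence is computed
from the pooled averaged auto- and cross-spectra (per-window coherence is
identically 1 and is refused).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import get_window

__all__ = [
    "BANDS",
    "SpectralEstimationConfig",
    "PowerSpectrum",
    "CoherenceSpectrum",
    "welch_power",
    "band_power",
    "coherence",
    "fisher_z",
]

#: canonical canine EEG bands, half-open intervals [low, high) in Hz
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (12.0, 16.0),
    "beta": (16.0, 30.0),
    "gamma": (30.0, 45.0),
}


@dataclass(frozen=True)
class SpectralEstimationConfig:
    """Parameters of the Welch / coherence estimators."""

    sampling_rate: float = 400.0
    window_length: float = 1.0  # seconds
    overlap: float = 0.5  # fraction of the window
    taper: str = "hamming"
    grid_resolution: float = 0.25  # Hz
    f_min: float = 0.5  # Hz
    f_max: float = 50.0  # Hz

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")
        span = self.f_max - self.f_min
        if abs(span / self.grid_resolution - round(span / self.grid_resolution)) > 1e-9:
            raise ValueError("grid_resolution must divide f_max - f_min")

    @property
    def nperseg(self) -> int:
        return int(round(self.window_length * self.sampling_rate))

    @property
    def step(self) -> int:
        return max(1, int(round(self.nperseg * (1.0 - self.overlap))))

    @property
    def nfft(self) -> int:
        # zero-padded transform length realizing the requested grid spacing
        return int(round(self.sampling_rate / self.grid_resolution))

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.f_max - self.f_min) / self.grid_resolution)) + 1
        return self.f_min + self.grid_resolution * np.arange(n)

    @property
    def grid_slice(self) -> slice:
        full = np.fft.rfftfreq(self.nfft, 1.0 / self.sampling_rate)
        i0 = int(np.searchsorted(full, self.f_min - 1e-9))
        i1 = int(np.searchsorted(full, self.f_max + 1e-9))
        return slice(i0, i1)


@dataclass
class PowerSpectrum:
    """Per-bin power estimates for one subject / state / channel."""

    bins: np.ndarray
    absolute: np.ndarray  # µV² per bin
    relative: np.ndarray  # fractions summing to 1 over the grid
    total_power: float
    n_windows: int
    channel: str = ""
    state: str = ""
    subject_id: str = ""


@dataclass
class CoherenceSpectrum:
    """Magnitude-squared coherence per bin for one channel pair."""

    bins: np.ndarray
    msc: np.ndarray
    fisher_z: np.ndarray
    pair: str = ""
    n_windows: int = 0
    state: str = ""
    subject_id: str = ""


def _window_matrix(segment: np.ndarray, config: SpectralEstimationConfig) -> np.ndarray:
    """Overlapping analysis windows of one contiguous segment, as rows."""
    segment = np.asarray(segment, dtype=float)
    nper, step = config.nperseg, config.step
    if len(segment) < nper:
        raise ValueError(
            f"segment of {len(segment)} samples shorter than the "
            f"{nper}-sample analysis window"
        )
    starts = np.arange(0, len(segment) - nper + 1, step)
    idx = starts[:, None] + np.arange(nper)[None, :]
    return segment[idx]


def _accumulate_spectra(
    segments, config: SpectralEstimationConfig, pair_segments=None
):
    """Sum one-sided (cross-)periodograms over all windows of all segments.

    Returns ``(sxx, syy, sxy, n_windows)``; ``syy``/``sxy`` are None for the
    single-channel case.  Scaling is µV² per frequency bin (periodogram scaled
    so that summing bins of a full-band signal recovers its variance up to the
    taper's processing loss).
    """
    taper = get_window(config.taper, config.nperseg, fftbins=True)
    # spectrum-per-bin scaling: |X|^2 / sum(w)^2, one-sided doubling applied later
    scale = 1.0 / taper.sum() ** 2
    nfft = config.nfft
    n_bins_full = nfft // 2 + 1
    sxx = np.zeros(n_bins_full)
    syy = np.zeros(n_bins_full) if pair_segments is not None else None
    # cross-spectrum kept as explicit (re, im) sums so that swapping the two
    # channels is bitwise symmetric (re identical, im exactly negated)
    sxy_re = np.zeros(n_bins_full) if pair_segments is not None else None
    sxy_im = np.zeros(n_bins_full) if pair_segments is not None else None
    n_windows = 0
    if pair_segments is None:
        pair_segments = [None] * len(segments)
    elif len(pair_segments) != len(segments):
        raise ValueError("segment lists for the two channels must be aligned")
    for seg_x, seg_y in zip(segments, pair_segments):
        wx = _window_matrix(seg_x, config) * taper
        fx = np.fft.rfft(wx, n=nfft, axis=1)
        if seg_y is None:
            sxx += (np.abs(fx) ** 2).sum(axis=0)
        else:
            seg_y = np.asarray(seg_y, dtype=float)
            if len(seg_y) != len(np.asarray(seg_x)):
                raise ValueError("paired segments must have identical lengths")
            wy = _window_matrix(seg_y, config) * taper
            fy = np.fft.rfft(wy, n=nfft, axis=1)
            sxx += (np.abs(fx) ** 2).sum(axis=0)
            syy += (np.abs(fy) ** 2).sum(axis=0)
            sxy_re += (fx.real * fy.real + fx.imag * fy.imag).sum(axis=0)
            sxy_im += (fx.real * fy.imag - fx.imag * fy.real).sum(axis=0)
        n_windows += wx.shape[0]
    sxy = None if sxy_re is None else sxy_re + 1j * sxy_im
    for arr in (sxx, syy, sxy):
        if arr is not None:
            arr *= scale
    return sxx, syy, sxy, n_windows


def welch_power(
    segments,
    config: SpectralEstimationConfig | None = None,
    *,
    channel: str = "",
    state: str = "",
    subject_id: str = "",
) -> PowerSpectrum:
    """Average periodogram over all windows of all epoch segments.

    Parameters
    ----------
    segments
        Iterable of 1-D sample arrays, one per selected epoch, all from one
        channel.  Each must be at least one analysis window long.
    """
    config = config or SpectralEstimationConfig()
    segments = list(segments)
    if not segments:
        raise ValueError("no selected epochs: subject contributes no spectrum")
    sxx, _, _, n_windows = _accumulate_spectra(segments, config)
    sxx /= n_windows
    sel = config.grid_slice
    absolute = 2.0 * sxx[sel]  # one-sided; grid excludes DC and Nyquist
    total = float(absolute.sum())
    relative = absolute / total if total > 0 else np.full_like(absolute, np.nan)
    return PowerSpectrum(
        bins=config.grid,
        absolute=absolute,
        relative=relative,
        total_power=total,
        n_windows=n_windows,
        channel=channel,
        state=state,
        subject_id=subject_id,
    )


def band_power(spectrum: PowerSpectrum, band: tuple[float, float] | str) -> float:
    """Relative power summed over the bins in ``[low, high)``."""
    if isinstance(band, str):
        band = BANDS[band]
    low, high = band
    bins = spectrum.bins
    if low < bins[0] - 1e-9 or high > bins[-1] + 1e-9:
        raise ValueError(f"band [{low}, {high}) outside the analysis grid")
    mask = (bins >= low - 1e-9) & (bins < high - 1e-9)
    return float(spectrum.relative[mask].sum())


def coherence(
    x_segments,
    y_segments,
    config: SpectralEstimationConfig | None = None,
    *,
    pair: str = "",
    state: str = "",
    subject_id: str = "",
) -> CoherenceSpectrum:
    """Magnitude-squared coherence from pooled averaged cross/auto spectra.

    MSC(f) = |Sxy(f)|² / (Sxx(f) · Syy(f)) with the averages taken over all
    windows of all epochs; at least two windows are required (single-window
    MSC is identically 1 and carries no information).
    """
    config = config or SpectralEstimationConfig()
    x_segments, y_segments = list(x_segments), list(y_segments)
    if len(x_segments) != len(y_segments):
        raise ValueError("segment lists for the two channels must be aligned")
    if not x_segments:
        raise ValueError("no selected epochs: subject contributes no coherence")
    sxx, syy, sxy, n_windows = _accumulate_spectra(
        x_segments, config, pair_segments=y_segments
    )
    if n_windows < 2:
        raise ValueError("coherence requires at least two analysis windows")
    sel = config.grid_slice
    sxx, syy, sxy = sxx[sel], syy[sel], sxy[sel]
    with np.errstate(divide="ignore", invalid="ignore"):
        msc = np.abs(sxy) ** 2 / (sxx * syy)
    msc = np.clip(np.nan_to_num(msc, nan=0.0), 0.0, 1.0)
    return CoherenceSpectrum(
        bins=config.grid,
        msc=msc,
        fisher_z=fisher_z(msc),
        pair=pair,
        n_windows=n_windows,
        state=state,
        subject_id=subject_id,
    )


def fisher_z(msc: np.ndarray) -> np.ndarray:
    """Variance-stabilizing transform z = atanh(√MSC), clipped below 1."""
    msc = np.clip(np.asarray(msc, dtype=float), 0.0, 1.0 - 1e-12)
    return np.arctanh(np.sqrt(msc))
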