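"""Signal conditioning, rule-based 3-s epoch staging, and macrostructure.

The scorer is a rule-based emulation of visual staging criteria: wakefulness
shows high EMG tone with frequent eye movements, drowsiness wake-like EEG
with reduced EMG, NREM delta-dominant EEG with low EMG, and REM fast EEG
with muscle atonia and rapid eye movements.  Rules are applied per epoch in
a fixed order, unclassifiable epochs inherit the previous label, and a
3-epoch majority pass smooths the result.

Macrostructure (state latencies, state percentages, sleep efficiency) is
computed over *all* epochs including artifact-flagged ones; artifacts are
excluded only from quantitative-EEG epoch selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, iirnotch, filtfilt, get_window, sosfiltfilt

from .recording import EPOCH_S, Hypnogram, PSGRecording, STATES

__all__ = [
    "ScorerConfig",
    "MacrostructureSummary",
    "EpochSelection",
    "acquisition_filter",
    "epoch_features",
    "score_epochs",
    "select_analysis_epochs",
    "compute_macrostructure",
]

ACQ_BAND = (0.53, 70.0)  # Hz
NOTCH_HZ = 60.0

#: names of the per-epoch scorer features, in order
FEATURE_BANDS = ("delta", "theta", "alpha", "sigma", "beta", "gamma")
_FEATURE_BAND_EDGES = {
    "delta": (1, 4), "theta": (4, 8), "alpha": (8, 12),
    "sigma": (12, 16), "beta": (16, 30), "gamma": (30, 45),
}


def acquisition_filter(recording: PSGRecording) -> PSGRecording:
    """Acquisition-style conditioning: 0.53-70 Hz band-pass plus 60 Hz notch.

    Both filters are applied forward-backward (zero phase) so epoch
    boundaries are not skewed.
    """
    fs = recording.sampling_rate
    if fs < 200.0:
        raise ValueError(f"sampling rate {fs} Hz too low for the 70 Hz band edge")
    sos = butter(4, ACQ_BAND, btype="bandpass", fs=fs, output="sos")
    b_notch, a_notch = iirnotch(NOTCH_HZ, Q=30.0, fs=fs)
    filtered = {}
    for ch, x in recording.signals.items():
        y = sosfiltfilt(sos, np.asarray(x, dtype=float))
        filtered[ch] = filtfilt(b_notch, a_notch, y)
    return PSGRecording(
        signals=filtered,
        sampling_rate=fs,
        subject_id=recording.subject_id,
    )


@dataclass(frozen=True)
class ScorerConfig:
    """Thresholds of the rule-based scorer (µV and relative-power units).

    Defaults are calibrated on the synthetic state model after acquisition
    filtering (which attenuates broadband EMG, so thresholds sit below the
    raw synthesis levels).
    """

    emg_wake: float = 10.5  # µV RMS at or above which tone says wake
    emg_atonia: float = 1.7  # µV RMS at or below which muscle is atonic
    delta_nrem: float = 0.40  # relative delta power for NREM
    fast_delta_max: float = 0.30  # below this the EEG counts as "fast"
    eog_threshold: float = 25.0  # µV excursion defining an eye-movement event
    eog_window_epochs: int = 5  # centered window for event-rate estimates
    eog_wake_events: int = 1  # events in the window for "frequent" movements
    smoothing_epochs: int = 3


def _epoch_matrix(x: np.ndarray, spe: int) -> np.ndarray:
    n_epochs = len(x) // spe
    return x[: n_epochs * spe].reshape(n_epochs, spe)


def _relative_band_powers(cz: np.ndarray, fs: float, spe: int) -> np.ndarray:
    """Per-epoch relative band powers at Cz on a coarse 1 Hz grid.

    1-s Hamming windows with 50 % overlap inside each epoch; relative power
    is normalized over 0.5-50 Hz.  (Scorer feature only; the reporting-grade
    spectra live in :mod:`napqeeg.spectral`.)
    """
    nper = int(fs)
    step = nper // 2
    epochs = _epoch_matrix(cz, spe)
    n_epochs = epochs.shape[0]
    starts = np.arange(0, spe - nper + 1, step)
    win = epochs[:, starts[:, None] + np.arange(nper)[None, :]]
    taper = get_window("hamming", nper)
    spec = np.abs(np.fft.rfft(win * taper, axis=2)) ** 2
    psd = spec.mean(axis=1)  # (n_epochs, nper//2+1), 1 Hz spacing
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    grid = (freqs >= 0.5) & (freqs <= 50.0)
    total = psd[:, grid].sum(axis=1)
    out = np.zeros((n_epochs, len(FEATURE_BANDS)))
    for j, band in enumerate(FEATURE_BANDS):
        lo, hi = _FEATURE_BAND_EDGES[band]
        sel = (freqs >= lo) & (freqs < hi)
        out[:, j] = psd[:, sel].sum(axis=1) / np.maximum(total, 1e-30)
    return out


def _eog_event_counts(eog: np.ndarray, fs: float, spe: int,
                      threshold: float) -> np.ndarray:
    """Per-epoch threshold-crossing deflection counts after 0.5-5 Hz smoothing."""
    sos = butter(3, [0.5, 5.0], btype="bandpass", fs=fs, output="sos")
    smooth = sosfiltfilt(sos, eog)
    above = np.abs(smooth) > threshold
    # event onsets: rising edges separated by > 0.1 s
    edges = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        edges = np.concatenate([[0], edges])
    if len(edges) > 1:
        keep = np.concatenate([[True], np.diff(edges) > 0.1 * fs])
        edges = edges[keep]
    n_epochs = len(eog) // spe
    counts = np.bincount(np.minimum(edges // spe, n_epochs - 1),
                         minlength=n_epochs) if len(edges) else np.zeros(n_epochs)
    return counts[:n_epochs].astype(float)


def _all_epoch_features(recording: PSGRecording,
                        config: ScorerConfig | None = None) -> dict[str, np.ndarray]:
    config = config or ScorerConfig()
    fs = recording.sampling_rate
    spe = int(round(fs * EPOCH_S))
    bands = _relative_band_powers(recording.signals["Cz"], fs, spe)
    emg = np.sqrt((_epoch_matrix(recording.signals["EMG"], spe) ** 2).mean(axis=1))
    eog = _eog_event_counts(recording.signals["EOG"], fs, spe, config.eog_threshold)
    k = config.eog_window_epochs
    window_counts = np.convolve(eog, np.ones(k), mode="same")
    return {
        "band_rel": bands,
        "emg_rms": emg,
        "eog_events": eog,
        "eog_events_window": window_counts,
    }


def epoch_features(recording: PSGRecording, epoch_index: int,
                   config: ScorerConfig | None = None) -> dict:
    """Scorer features of one epoch: relative band powers at Cz, EMG RMS,
    and the EOG deflection count."""
    if not 0 <= epoch_index < recording.n_epochs:
        raise IndexError(f"epoch {epoch_index} outside recording")
    feats = _all_epoch_features(recording, config)
    return {
        "band_rel": dict(zip(FEATURE_BANDS, feats["band_rel"][epoch_index])),
        "emg_rms": float(feats["emg_rms"][epoch_index]),
        "eog_events": float(feats["eog_events"][epoch_index]),
    }


def _majority_smooth(codes: np.ndarray, k: int) -> np.ndarray:
    """k-epoch centered majority vote; the center label wins ties."""
    n = len(codes)
    half = k // 2
    out = codes.copy()
    counts = np.zeros((n, 4), dtype=np.int16)
    for off in range(-half, half + 1):
        shifted = codes[np.clip(np.arange(n) + off, 0, n - 1)]
        counts[np.arange(n), shifted] += 1
    best = counts.max(axis=1)
    center_count = counts[np.arange(n), codes]
    replace = best > center_count
    out[replace] = counts[replace].argmax(axis=1)
    return out


def score_epochs(recording: PSGRecording,
                 config: ScorerConfig | None = None) -> Hypnogram:
    """Rule-based staging of a conditioned recording into W/D/N/R epochs.

    Decision order per epoch: (1) wake -- EMG tone at/above the wake
    threshold with frequent eye movements; (2) drowsiness -- EMG reduced but
    present with fast EEG; (3) NREM -- delta-dominant EEG with sub-wake EMG;
    (4) REM -- atonia, fast EEG and eye movements present.  Unclassified
    epochs inherit the previous label (the first epoch defaults to W); a
    majority-vote smoothing pass follows.
    """
    config = config or ScorerConfig()
    f = _all_epoch_features(recording, config)
    delta = f["band_rel"][:, 0]
    emg = f["emg_rms"]
    eogw = f["eog_events_window"]
    n = len(emg)

    idx = {s: i for i, s in enumerate(STATES)}
    codes = np.full(n, -1, dtype=np.int8)
    wake = (emg >= config.emg_wake) & (eogw >= config.eog_wake_events)
    drow = (emg > config.emg_atonia) & (emg < config.emg_wake) \
        & (delta < config.fast_delta_max)
    nrem = (delta >= config.delta_nrem) & (emg < config.emg_wake)
    rem = (emg <= config.emg_atonia) & (delta < config.fast_delta_max) \
        & (eogw >= 1)
    codes[rem] = idx["R"]
    codes[nrem] = idx["N"]
    codes[drow] = idx["D"]
    codes[wake] = idx["W"]  # assigned last: rule order = priority

    # unclassified epochs inherit the previous label
    if codes[0] < 0:
        codes[0] = idx["W"]
    for i in range(1, n):
        if codes[i] < 0:
            codes[i] = codes[i - 1]

    codes = _majority_smooth(codes, config.smoothing_epochs)
    labels = np.array(STATES, dtype="U1")[codes]
    return Hypnogram(labels=labels, subject_id=recording.subject_id)


@dataclass
class EpochSelection:
    """Artifact-free, non-transition epochs per state, for quantitative EEG."""

    per_state: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, state: str) -> np.ndarray:
        return self.per_state[state]

    def counts(self) -> dict[str, int]:
        return {s: len(v) for s, v in self.per_state.items()}


def select_analysis_epochs(hypnogram: Hypnogram) -> EpochSelection:
    """Epochs eligible for qEEG: artifact-free and flanked by the same state.

    An epoch is selected for state s iff its label is s, it carries no
    artifact flag, and both neighbours share the label (recording boundary
    epochs count as transitions).
    """
    labels = hypnogram.labels
    n = len(labels)
    sel: dict[str, np.ndarray] = {}
    if n == 0:
        return EpochSelection({s: np.array([], dtype=int) for s in STATES})
    same_prev = np.zeros(n, dtype=bool)
    same_next = np.zeros(n, dtype=bool)
    same_prev[1:] = labels[1:] == labels[:-1]
    same_next[:-1] = labels[:-1] == labels[1:]
    eligible = same_prev & same_next & ~hypnogram.artifact
    for s in STATES:
        sel[s] = np.flatnonzero(eligible & (labels == s))
    return EpochSelection(sel)


@dataclass
class MacrostructureSummary:
    """State latencies (min), state percentages, and sleep efficiency."""

    latency_drow: float  # minutes from recording start, NaN if never entered
    latency_nrem: float
    latency_rem: float
    pct_w: float
    pct_drow: float
    pct_nrem: float
    pct_rem: float
    sleep_efficiency: float  # (time NREM + time REM) / total recorded time
    total_recorded: float  # minutes
    subject_id: str = ""

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "latency_drow": self.latency_drow,
            "latency_nrem": self.latency_nrem,
            "latency_rem": self.latency_rem,
            "pct_w": self.pct_w,
            "pct_drow": self.pct_drow,
            "pct_nrem": self.pct_nrem,
            "pct_rem": self.pct_rem,
            "sleep_efficiency": self.sleep_efficiency,
            "total_recorded": self.total_recorded,
        }


def compute_macrostructure(hypnogram: Hypnogram) -> MacrostructureSummary:
    """Latencies, state percentages and sleep efficiency of one hypnogram.

    Latency to a state is the onset time of its first epoch measured from
    recording start; states never entered yield missing latency and 0 %.
    All epochs count, including artifact-flagged ones.
    """
    labels = hypnogram.labels
    n = len(labels)
    if n == 0:
        raise ValueError("empty hypnogram")
    epoch_min = hypnogram.epoch_length / 60.0

    def latency(state: str) -> float:
        hits = np.flatnonzero(labels == state)
        return float(hits[0]) * epoch_min if len(hits) else np.nan

    pct = {s: 100.0 * float(np.sum(labels == s)) / n for s in STATES}
    return MacrostructureSummary(
        latency_drow=latency("D"),
        latency_nrem=latency("N"),
        latency_rem=latency("R"),
        pct_w=pct["W"],
        pct_drow=pct["D"],
        pct_nrem=pct["N"],
        pct_rem=pct["R"],
        sleep_efficiency=(pct["N"] + pct["R"]) / 100.0,
        total_recorded=n * epoch_min,
        subject_id=hypnogram.subject_id,
    )
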