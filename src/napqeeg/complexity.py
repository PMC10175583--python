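"""Lempel-Ziv (LZ76) complexity of EEG epochs.

The signal is band-pass filtered (order-5 Butterworth, 1-50 Hz, zero-phase),
binarized against the epoch median, and parsed with the LZ76 exhaustive
production scheme: scanning left to right, each new phrase is the shortest
extension that cannot be reproduced from the prior history by copy-extension.
The phrase count c(n) is normalized as c(n) * log2(n) / n, which tends to 1
for maximally random binary sequences, so normalized values are comparable
across epoch lengths.

Per subject and behavioral state, LZC is computed per selected 3-s epoch and
averaged across epochs (pooling epochs into one long sequence would mix
nonstationary segments and make the value depend on epoch count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .recording import EPOCH_S, PSGRecording

__all__ = [
    "LZCResult",
    "lzc_prefilter",
    "binarize_median",
    "lz76_count",
    "normalized_lzc",
    "subject_state_lzc",
]


@dataclass
class LZCResult:
    """Subject/state Lempel-Ziv summary (mean over selected epochs)."""

    raw_count: float  # mean LZ76 phrase count per epoch
    normalized: float  # mean of raw * log2(n)/n per epoch
    n: int  # samples per epoch
    n_epochs: int
    channel: str = ""
    state: str = ""
    subject_id: str = ""


def lzc_prefilter(signal: np.ndarray, sampling_rate: float = 400.0) -> np.ndarray:
    """Order-5 Butterworth band-pass 1-50 Hz, applied forward-backward."""
    sos = butter(5, [1.0, 50.0], btype="bandpass", fs=sampling_rate, output="sos")
    return sosfiltfilt(sos, np.asarray(signal, dtype=float))


def binarize_median(segment: np.ndarray) -> np.ndarray:
    """Binary symbols: 1 where the sample exceeds the segment median.

    A constant segment maps to all zeros (the median equals every sample).
    Rank-based, hence invariant to positive scaling and offsets.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValueError("cannot binarize an empty segment")
    return (segment > np.median(segment)).astype(np.uint8)


def binarize_mean(segment: np.ndarray) -> np.ndarray:
    """Mean-threshold alternative to :func:`binarize_median`."""
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValueError("cannot binarize an empty segment")
    return (segment > segment.mean()).astype(np.uint8)


def _lz76_core(s: np.ndarray) -> int:
    # Kaspar-Schuster scan; numba-compiled when available (see below)
    n = len(s)
    complexity = 1
    u, v, vmax, w = 0, 1, 1, 1
    while w + v <= n:
        if w + v - 1 < n and s[u + v - 1] == s[w + v - 1]:
            v += 1
            if w + v > n:
                complexity += 1
                break
        else:
            if v > vmax:
                vmax = v
            u += 1
            if u == w:
                complexity += 1
                w += vmax
                if w >= n:
                    break
                u, v, vmax = 0, 1, 1
            else:
                v = 1
    return complexity


try:  # epoch-scale sequences make the pure-Python scan the bottleneck
    from numba import njit

    _lz76_fast = njit("int64(uint8[::1])")(_lz76_core)
except Exception:  # pragma: no cover - numba is an optional accelerator
    _lz76_fast = None


def lz76_count(sequence) -> int:
    """Number of phrases in the LZ76 exhaustive parsing of a binary sequence.

    Linear-scan production algorithm: maintain the current phrase start ``w``
    and search the longest prefix of the remainder reproducible from any
    earlier starting point (copy-extension may overrun into the phrase being
    built); the phrase is that prefix plus one terminating symbol.
    """
    s = _as_array(sequence)
    if len(s) == 0:
        raise ValueError("LZ76 is undefined for an empty sequence")
    if _lz76_fast is not None:
        return int(_lz76_fast(s))
    return _lz76_core(s)


def _as_array(sequence) -> np.ndarray:
    if isinstance(sequence, str):
        arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8) - ord("0")
    else:
        arr = np.ascontiguousarray(np.asarray(sequence).ravel(), dtype=np.uint8)
    if arr.size and arr.max() > 1:
        raise ValueError("sequence must be binary (alphabet {0, 1})")
    return arr


def normalized_lzc(sequence) -> tuple[int, float]:
    """(raw phrase count, count normalized by log2(n)/n)."""
    s = _as_array(sequence)
    c = lz76_count(s)
    n = len(s)
    return c, c * np.log2(n) / n


def subject_state_lzc(
    recording: PSGRecording,
    selected_epochs,
    channel: str,
    *,
    state: str = "",
    binarize=binarize_median,
) -> LZCResult:
    """Mean per-epoch normalized LZC of one channel over selected epochs.

    The whole channel is prefiltered once (zero-phase, so epoch boundaries are
    not skewed), then each selected 3-s epoch is binarized and parsed
    independently.
    """
    epochs = list(selected_epochs)
    if not epochs:
        raise ValueError("no selected epochs: subject contributes no LZC")
    filtered = lzc_prefilter(recording.signals[channel], recording.sampling_rate)
    n = int(recording.sampling_rate * EPOCH_S)
    raws, norms = [], []
    for e in epochs:
        seg = filtered[e * n : (e + 1) * n]
        c, z = normalized_lzc(binarize(seg))
        raws.append(c)
        norms.append(z)
    return LZCResult(
        raw_count=float(np.mean(raws)),
        normalized=float(np.mean(norms)),
        n=n,
        n_epochs=len(epochs),
        channel=channel,
        state=state,
        subject_id=recording.subject_id,
    )
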