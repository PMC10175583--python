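"""EDF interchange for PSG recordings.

Writing uses a minimal built-in EDF encoder (plain EDF, one 1-s data record
per second, 16-bit samples, symmetric physical range per channel); reading
goes through :mod:`mne`, which also serves as an independent check on the
writer in the round-trip tests.  Amplitudes are microvolts on both sides.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

from .recording import CHANNELS, PSGRecording

__all__ = ["write_edf", "read_edf"]

_RECORD_S = 1.0


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(recording: PSGRecording, path) -> None:
    """Write a recording as plain EDF (16-bit), channel order as stored."""
    fs = recording.sampling_rate
    spr = int(round(fs * _RECORD_S))
    if abs(spr - fs * _RECORD_S) > 1e-9:
        raise ValueError("sampling rate must give integer samples per 1-s record")
    names = list(recording.signals)
    n = recording.n_samples
    n_records = int(np.ceil(n / spr))
    ns = len(names)

    phys_max = {}
    digital = {}
    for ch in names:
        x = np.asarray(recording.signals[ch], dtype=float)
        pm = float(np.max(np.abs(x))) if n else 0.0
        pm = pm * 1.0001 if pm > 0 else 1.0
        phys_max[ch] = pm
        # exact EDF affine: phys = pmin + (dig - dmin) * (pmax-pmin)/(dmax-dmin)
        slope = 2.0 * pm / 65535.0
        d = np.zeros(n_records * spr, dtype="<i2")
        d[:n] = np.clip(
            np.round((x + pm) / slope) - 32768, -32768, 32767
        ).astype("<i2")
        digital[ch] = d

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _pad("0", 8),
        _pad(recording.subject_id, 80),
        _pad("napqeeg synthetic PSG", 80),
        _pad(now.strftime("%d.%m.%y"), 8),
        _pad(now.strftime("%H.%M.%S"), 8),
        _pad(str(256 * (1 + ns)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad(f"{_RECORD_S:g}", 8),
        _pad(str(ns), 4),
    ])
    fields = [
        ("%s", 16, names),
        ("", 80, None),  # transducer
        ("uV", 8, None),
        ("%s", 8, [f"{-phys_max[ch]:.6g}"[:8] for ch in names]),
        ("%s", 8, [f"{phys_max[ch]:.6g}"[:8] for ch in names]),
        ("-32768", 8, None),
        ("32767", 8, None),
        ("", 80, None),  # prefiltering
        (str(spr), 8, None),
        ("", 32, None),
    ]
    sig_header = b""
    for fmt, width, values in fields:
        for i, ch in enumerate(names):
            text = values[i] if values is not None else fmt
            if text == "%s":
                text = ch
            sig_header += _pad(text, width)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            for ch in names:
                fh.write(digital[ch][r * spr : (r + 1) * spr].tobytes())


def read_edf(path, required_channels=CHANNELS,
             expected_rate: float = 400.0) -> PSGRecording:
    """Read an EDF recording via mne; refuses resampling and missing channels."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    missing = [ch for ch in required_channels if ch not in raw.ch_names]
    if missing:
        raise ValueError(f"EDF lacks required channels: {', '.join(missing)}")
    fs = float(raw.info["sfreq"])
    if expected_rate is not None and abs(fs - expected_rate) > 1e-6:
        raise ValueError(
            f"EDF sampled at {fs:g} Hz, expected {expected_rate:g} Hz; "
            "resample externally before analysis"
        )
    data = raw.get_data(picks=list(required_channels)) * 1e6  # V -> µV
    signals = {ch: data[i] for i, ch in enumerate(required_channels)}
    return PSGRecording(signals=signals, sampling_rate=fs,
                        subject_id=_subject_from_path(path))


def _subject_from_path(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]
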