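"""Core containers for polysomnographic recordings and hypnograms.

A nap-PSG montage of four active EEG leads (Fz, Cz, F3, F4, referenced to an
occipital electrode), one bipolar EOG and one bipolar EMG channel, sampled at
400 Hz.  Behavioral state is scored in 3-s epochs over a 4-state alphabet:
wakefulness (W), drowsiness (D), NREM (N) and REM (R) sleep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: default sampling rate, Hz
FS = 400.0
#: scoring epoch length, seconds
EPOCH_S = 3.0
#: samples per scoring epoch at the default rate
EPOCH_SAMPLES = int(FS * EPOCH_S)

#: behavioral-state alphabet, in conventional depth order
STATES = ("W", "D", "N", "R")
STATE_NAMES = {"W": "wake", "D": "drowsiness", "N": "NREM", "R": "REM"}
STATE_INDEX = {s: i for i, s in enumerate(STATES)}

EEG_CHANNELS = ("Fz", "Cz", "F3", "F4")
CHANNELS = EEG_CHANNELS + ("EOG", "EMG")
#: coherence is evaluated interhemispherically (F3-F4) and intrahemispherically (Fz-Cz)
COHERENCE_PAIRS = (("F3", "F4"), ("Fz", "Cz"))


@dataclass
class PSGRecording:
    """Synchronized multi-channel PSG signal block, amplitudes in microvolts."""

    signals: dict[str, np.ndarray]
    sampling_rate: float = FS
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.signals.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have equal length")
        if self.sampling_rate <= 2 * 50.0:
            raise ValueError(
                "sampling rate must exceed twice the highest analysis frequency (50 Hz)"
            )

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.signals.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def n_epochs(self) -> int:
        # a partial trailing epoch is dropped
        return int(self.n_samples // (self.sampling_rate * EPOCH_S))

    def epoch(self, channel: str, index: int) -> np.ndarray:
        """Samples of one 3-s scoring epoch of one channel."""
        n = int(self.sampling_rate * EPOCH_S)
        if index < 0 or index >= self.n_epochs:
            raise IndexError(f"epoch {index} outside recording ({self.n_epochs} epochs)")
        return self.signals[channel][index * n : (index + 1) * n]


@dataclass
class Hypnogram:
    """Per-epoch behavioral-state labels with artifact flags.

    ``labels`` is a sequence over :data:`STATES`; ``artifact`` flags epochs to
    be excluded from quantitative EEG (they still count toward macrostructure).
    """

    labels: np.ndarray
    epoch_length: float = EPOCH_S
    artifact: np.ndarray = field(default=None)  # type: ignore[assignment]
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="U1")
        bad = set(np.unique(self.labels)) - set(STATES)
        if bad:
            raise ValueError(f"unknown state labels: {sorted(bad)}")
        if self.artifact is None:
            self.artifact = np.zeros(len(self.labels), dtype=bool)
        else:
            self.artifact = np.asarray(self.artifact, dtype=bool)
        if len(self.artifact) != len(self.labels):
            raise ValueError("artifact flags must match label length")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> float:
        return len(self.labels) * self.epoch_length

    def state_mask(self, state: str) -> np.ndarray:
        if state not in STATES:
            raise ValueError(f"unknown state {state!r}")
        return self.labels == state
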