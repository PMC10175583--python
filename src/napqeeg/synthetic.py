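"""Synthetic nap-PSG cohort generator.

Emulates the statistical structure a senior-dog afternoon-nap study assumes,
so the whole analysis chain is testable without recorded data:

* a first-order Markov chain over {W, D, N, R} at 3-s epoch resolution with
  ordered entry (REM reachable only from NREM) produces ground-truth
  hypnograms;
* state-dependent signal synthesis: EEG as a mixture of band-filtered noise
  (delta-dominant NREM, fast-frequency wake/REM) over a 1/f background, with
  a shared cortical component so interhemispheric / intrahemispheric
  coherence is tunable; EMG as amplitude-modulated broadband noise with
  state-graded tone (atonia in REM); EOG as smoothed biphasic deflections at
  state-dependent rates;
* covariate effects enter through Gaussian-copula latents that multiply the
  chain's dwell/entry rates or the per-subject signal-model amplitudes, so a
  requested rank correlation between a covariate and a downstream readout is
  realized while every marginal keeps its shape.

Amplitudes are in microvolts at a plausible canine surface-EEG scale; the
absolute scale cancels in every downstream relative quantity.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, sosfilt

from .recording import (
    CHANNELS,
    EEG_CHANNELS,
    EPOCH_S,
    FS,
    Hypnogram,
    PSGRecording,
    STATES,
    STATE_INDEX,
)
from .spectral import BANDS

__all__ = [
    "SubjectProfile",
    "Effect",
    "StateParams",
    "StateSignalModel",
    "TransitionParams",
    "SubjectData",
    "Cohort",
    "default_state_model",
    "default_effects",
    "generate_hypnogram",
    "synthesize_signals",
    "generate_cohort",
]

COVARIATES = ("age", "cades", "memory", "inhibitory", "detour", "gaze")

#: macrostructure responses and the chain edges each latent multiplies
#: (sign: +1 means the edge rate scales by exp(+k z))
MACRO_MECHANISM: dict[str, dict[tuple[str, str], int]] = {
    "pct_nrem": {("D", "N"): +1, ("N", "D"): -1},
    "pct_rem": {("N", "R"): +1, ("R", "W"): -1, ("R", "N"): -1},
    "pct_w": {("W", "D"): -1, ("D", "W"): +1},
    "pct_drow": {("W", "D"): +1, ("D", "N"): -1, ("D", "W"): -1},
    "latency_drow": {("W", "D"): -1},
    "latency_nrem": {("D", "N"): -1},
    "latency_rem": {("N", "R"): -1},
}

#: latents drawn for every subject (heterogeneity even without effects)
ALWAYS_LATENT = ("pct_nrem", "pct_rem", "pct_w")

#: chain-edge modulation strength per latent s.d.
MACRO_EFFECT_K = 0.6
#: band-amplitude modulation per latent s.d. (power / LZC effects)
POWER_EFFECT_K = 0.35
#: shared-component logit shift per latent s.d. (coherence effects)
COH_EFFECT_K = 0.8

#: rank-correlation attenuation between a latent and the realized
#: macrostructure readout, measured once by simulation at the chain defaults
#: (2-h recordings, default latent set); used to pre-compensate requested
#: effect sizes.  Latency readouts are noisy (few entry events per nap), so
#: large latency effect targets saturate.
MACRO_ATTENUATION = {
    "pct_nrem": 0.74,
    "pct_rem": 0.63,
    "pct_w": 0.85,
    "pct_drow": 0.60,
    "latency_drow": 0.36,
    "latency_nrem": 0.26,
    "latency_rem": 0.20,
}
#: same for band-power / coherence / LZC readouts (amplitude link is nearly
#: deterministic, attenuation dominated by estimator noise)
QEEG_ATTENUATION = 0.90


@dataclass
class SubjectProfile:
    """Per-subject covariates: demographics and cognitive scores."""

    subject_id: str
    age: float  # years
    cades: int  # dementia-scale score, 0 (normal) .. 95 (severe)
    memory: float  # working-memory threshold, seconds 0-120
    inhibitory: float  # % correct, 0-100
    detour: float | None  # % correct, 0-100, may be missing
    gaze: float  # sustained gaze, seconds

    def __post_init__(self) -> None:
        if not 0 <= self.cades <= 95:
            raise ValueError("cades must lie in [0, 95]")
        if self.age <= 0:
            raise ValueError("age must be positive")
        for name in ("memory", "inhibitory"):
            v = getattr(self, name)
            lo, hi = (0, 120) if name == "memory" else (0, 100)
            if not lo <= v <= hi:
                raise ValueError(f"{name} must lie in [{lo}, {hi}]")
        if self.detour is not None and not 0 <= self.detour <= 100:
            raise ValueError("detour must lie in [0, 100] or be missing")

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "age": self.age,
            "cades": self.cades,
            "memory": self.memory,
            "inhibitory": self.inhibitory,
            "detour": np.nan if self.detour is None else self.detour,
            "gaze": self.gaze,
        }


@dataclass(frozen=True)
class Effect:
    """A requested rank correlation between a covariate and a response.

    ``response`` names a macrostructure metric (e.g. ``pct_nrem``), a band
    power (``power:Fz:N:delta``), a coherence band (``coh:F3-F4:W:alpha``)
    or a complexity value (``lzc:Fz:R``).
    """

    covariate: str
    response: str
    target_rho: float

    def __post_init__(self) -> None:
        if self.covariate not in COVARIATES:
            raise ValueError(f"unknown covariate {self.covariate!r}")
        if abs(self.target_rho) > 1:
            raise ValueError("|target_rho| must be <= 1")
        _validate_response(self.response)


def _validate_response(response: str) -> None:
    if response in MACRO_MECHANISM:
        return
    parts = response.split(":")
    pairs = {"F3-F4", "Fz-Cz"}
    if parts[0] == "power" and len(parts) == 4:
        ch, state, band = parts[1:]
        if ch in ("Fz", "Cz") and state in STATES and band in BANDS:
            return
    elif parts[0] == "coh" and len(parts) == 4:
        pair, state, band = parts[1:]
        if pair in pairs and state in STATES and band in BANDS:
            return
    elif parts[0] == "lzc" and len(parts) == 3:
        ch, state = parts[1:]
        if ch in ("Fz", "Cz") and state in STATES:
            return
    raise ValueError(f"effect references an undefined response: {response!r}")


def default_effects() -> list[Effect]:
    """Default study conditions: the strongest observed cohort correlations.

    Higher dementia-scale scores go with less NREM and REM sleep; older
    subjects spend more time awake.
    """
    return [
        Effect("cades", "pct_nrem", -0.554),
        Effect("cades", "pct_rem", -0.553),
        Effect("age", "pct_w", 0.408),
    ]


# ---------------------------------------------------------------------------
# state signal model
# ---------------------------------------------------------------------------

@dataclass
class StateParams:
    """Signal-model parameters of one behavioral state."""

    band_amps: dict[str, float]  # µV RMS per canonical band
    pink_amp: float  # µV RMS of the 1/f background
    pink_exponent: float  # spectral slope of the background
    emg_rms: float  # µV
    eog_rate: float  # eye-movement events per minute
    eog_amp: float  # µV, typical event amplitude


@dataclass
class StateSignalModel:
    """Per-state signal parameters plus coherence plateaus per channel pair."""

    states: dict[str, StateParams]
    #: target magnitude-squared-coherence plateau per (pair, state)
    pair_msc: dict[tuple[str, str], float]
    #: optional per-subject multipliers keyed (channel, state, band)
    band_scale: dict[tuple[str, str, str], float] = field(default_factory=dict)

    def validate(self) -> None:
        deltas = {s: p.band_amps["delta"] for s, p in self.states.items()}
        if max(deltas, key=deltas.get) != "N":
            raise ValueError("NREM delta amplitude must be the largest among states")
        emg = {s: p.emg_rms for s, p in self.states.items()}
        if not (emg["W"] > emg["D"] > emg["N"] > emg["R"]):
            raise ValueError("EMG tone must be ordered W > D > N > R")


def default_state_model() -> StateSignalModel:
    """Qualitative scoring criteria turned into numbers.

    Wake: fast EEG, high EMG tone, frequent large eye movements.  Drowsiness:
    wake-like EEG, reduced EMG, slower/smaller eye movements.  NREM:
    delta-dominant high-amplitude EEG, low EMG, rare eye movements.  REM:
    fast low-amplitude EEG, muscle atonia, frequent rapid eye movements.
    """
    mk = lambda d, t, a, s, b, g: {
        "delta": d, "theta": t, "alpha": a, "sigma": s, "beta": b, "gamma": g,
    }
    states = {
        "W": StateParams(mk(4, 6, 8, 6, 7, 4), 5.0, 1.0, 30.0, 12.0, 80.0),
        "D": StateParams(mk(6, 7, 8, 5, 5, 3), 6.0, 1.2, 12.0, 4.0, 40.0),
        "N": StateParams(mk(25, 8, 5, 5, 3, 2), 8.0, 1.6, 5.0, 0.3, 20.0),
        "R": StateParams(mk(4, 7, 7, 5, 7, 5), 5.0, 1.0, 0.5, 20.0, 70.0),
    }
    pair_msc = {}
    for pair in ("F3-F4", "Fz-Cz"):
        for s, m in (("W", 0.35), ("D", 0.35), ("N", 0.45), ("R", 0.30)):
            pair_msc[(pair, s)] = m
    model = StateSignalModel(states=states, pair_msc=pair_msc)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# hypnogram chain
# ---------------------------------------------------------------------------

@dataclass
class TransitionParams:
    """First-order state chain at 3-s epoch resolution.

    ``base`` holds per-epoch transition probabilities for the off-diagonal
    edges; self-transitions take the remainder.  REM must only be enterable
    from NREM (ordered entry).
    """

    base: dict[tuple[str, str], float] = field(default_factory=lambda: {
        ("W", "D"): 0.025,
        ("D", "W"): 0.035,
        ("D", "N"): 0.022,
        ("N", "D"): 0.012,
        ("N", "R"): 0.0045,
        ("R", "W"): 0.010,
        ("R", "N"): 0.020,
    })
    modulation_k: float = MACRO_EFFECT_K

    def rates_for(self, latents: dict[str, float] | None) -> dict:
        rates = dict(self.base)
        if latents:
            for response, z in latents.items():
                for edge, sign in MACRO_MECHANISM[response].items():
                    if edge in rates:
                        # cap so extreme latents keep a valid stochastic matrix
                        rates[edge] = min(0.45, rates[edge] * float(
                            np.exp(self.modulation_k * sign * z)
                        ))
        return rates


def _transition_matrix(rates: dict) -> np.ndarray:
    P = np.zeros((4, 4))
    for (a, b), r in rates.items():
        if a not in STATES or b not in STATES or a == b:
            raise ValueError(f"bad edge {(a, b)}")
        if r < 0:
            raise ValueError("transition rates must be non-negative")
        if b == "R" and a != "N":
            raise ValueError(
                "ordered entry violated: REM may only be entered from NREM"
            )
        P[STATE_INDEX[a], STATE_INDEX[b]] = min(r, 1.0)
    off = P.sum(axis=1)
    if np.any(off > 1.0 + 1e-12):
        raise ValueError("outgoing transition probabilities exceed 1")
    P[np.arange(4), np.arange(4)] = 1.0 - off
    _check_reachability(P)
    return P


def _check_reachability(P: np.ndarray) -> None:
    """Reject rates attached to states the chain can never occupy."""
    reachable = {STATE_INDEX["W"]}
    frontier = [STATE_INDEX["W"]]
    while frontier:
        s = frontier.pop()
        for t in range(4):
            if t != s and P[s, t] > 0 and t not in reachable:
                reachable.add(t)
                frontier.append(t)
    for s in range(4):
        if s not in reachable and np.any(np.delete(P[s], s) > 0):
            raise ValueError(
                f"unreachable-state parameterization: state {STATES[s]!r} has "
                "outgoing transition rates but can never be entered"
            )


def _simulate_chains(
    P: np.ndarray, n_epochs: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulate ``P.shape[0]`` chains for ``n_epochs`` steps, start state W."""
    n_subj = P.shape[0]
    cum = np.cumsum(P, axis=2)
    out = np.zeros((n_subj, n_epochs), dtype=np.int8)
    cur = np.zeros(n_subj, dtype=np.intp)
    rows = np.arange(n_subj)
    u = rng.random((n_epochs, n_subj))
    for t in range(1, n_epochs):
        c = cum[rows, cur]
        cur = (u[t][:, None] > c).sum(axis=1)
        out[:, t] = cur
    return out


def generate_hypnogram(
    duration_s: float,
    transition_params: TransitionParams | None = None,
    seed: int = 0,
    *,
    latents: dict[str, float] | None = None,
    artifact_rate: float = 0.0,
    subject_id: str = "subject",
) -> Hypnogram:
    """Ground-truth hypnogram from the covariate-modulated state chain."""
    if duration_s <= 0 or abs(duration_s / EPOCH_S - round(duration_s / EPOCH_S)) > 1e-9:
        raise ValueError(
            f"duration must be a positive multiple of the {EPOCH_S:.0f}-s epoch "
            f"length, got {duration_s}"
        )
    tp = transition_params or TransitionParams()
    P = _transition_matrix(tp.rates_for(latents))[None, :, :]
    n_epochs = int(round(duration_s / EPOCH_S))
    rng = np.random.default_rng(seed)
    codes = _simulate_chains(P, n_epochs, rng)[0]
    labels = np.array(STATES, dtype="U1")[codes]
    artifact = rng.random(n_epochs) < artifact_rate
    return Hypnogram(labels=labels, artifact=artifact, subject_id=subject_id)


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

_CHANNEL_PAIR = {"F3": "F3-F4", "F4": "F3-F4", "Fz": "Fz-Cz", "Cz": "Fz-Cz"}
_STATE_CODE = {s: i for i, s in enumerate(STATES)}
_SYNTH_BANDS = dict(BANDS)
_EPS = 1e-12


def _band_noise(n: int, low: float, high: float, fs: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (causal filter, then normalized)."""
    sos = butter(4, [low, min(high, fs / 2 * 0.98)], btype="bandpass",
                 fs=fs, output="sos")
    x = sosfilt(sos, rng.standard_normal(n))
    return x / (x.std() + _EPS)


def _pink_noise(n: int, exponent: float, fs: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise via spectral shaping, band 0.3-55 Hz."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(freqs)
    band = (freqs >= 0.3) & (freqs <= 55.0)
    shape[band] = freqs[band] ** (-exponent / 2.0)
    spec = shape * (rng.standard_normal(len(freqs))
                    + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n)
    return x / (x.std() + _EPS)


def _smooth_envelope(per_epoch: np.ndarray, n_samples: int, spe: int) -> np.ndarray:
    """Per-sample envelope from per-epoch values, with ~0.5 s soft edges.

    Smoothing runs on a decimated grid (two box passes ~ triangular kernel)
    since the envelope is piecewise constant within epochs.
    """
    dec = max(1, spe // 60)
    reps = spe // dec
    coarse = np.repeat(per_epoch, reps)
    coarse = uniform_filter1d(coarse, size=5, mode="nearest")
    coarse = uniform_filter1d(coarse, size=5, mode="nearest")
    return np.repeat(coarse, dec)[:n_samples]


def synthesize_signals(
    hypnogram: Hypnogram,
    model: StateSignalModel | None = None,
    seed: int = 0,
    sampling_rate: float = FS,
) -> PSGRecording:
    """Render a multichannel PSG recording from a hypnogram and state model.

    EEG channels mix a shared cortical source with channel-independent noise
    per band; the mixing amplitude is set per channel pair so the pooled MSC
    plateau matches ``model.pair_msc``.  Deterministic given ``seed``.
    """
    model = model or default_state_model()
    model.validate()
    labels = hypnogram.labels
    unknown = set(np.unique(labels)) - set(STATES)
    if unknown:
        raise ValueError(f"unknown state labels: {sorted(unknown)}")
    spe = int(round(sampling_rate * hypnogram.epoch_length))
    n_epochs = len(labels)
    n = n_epochs * spe
    rng = np.random.default_rng(seed)

    out = {ch: np.zeros(n) for ch in CHANNELS}
    # per-channel shared-mixing amplitude a so that MSC plateau = a^4
    mix = {}
    for ch in EEG_CHANNELS:
        pair = _CHANNEL_PAIR[ch]
        msc_by_state = {s: model.pair_msc[(pair, s)] for s in STATES}
        mix[ch] = {s: float(np.clip(m, 0.0, 1.0)) ** 0.25
                   for s, m in msc_by_state.items()}

    codes = np.array([_STATE_CODE[s] for s in labels])
    _env_cache: dict[bytes, np.ndarray] = {}

    def _env_from_state_values(by_state: np.ndarray) -> np.ndarray:
        key = by_state.tobytes()
        if key not in _env_cache:
            _env_cache[key] = _smooth_envelope(by_state[codes], n, spe)
        return _env_cache[key]

    def env(ch: str, band: str) -> np.ndarray:
        vals = np.array([
            model.states[s].band_amps[band]
            * model.band_scale.get((ch, s, band), 1.0)
            for s in STATES
        ])
        return _env_from_state_values(vals)

    mix_env = {
        ch: _env_from_state_values(np.array([mix[ch][s] for s in STATES]))
        for ch in EEG_CHANNELS
    }

    for band, (lo, hi) in _SYNTH_BANDS.items():
        shared = _band_noise(n, lo, hi, sampling_rate, rng)
        for ch in EEG_CHANNELS:
            indep = _band_noise(n, lo, hi, sampling_rate, rng)
            a = mix_env[ch]
            out[ch] += env(ch, band) * (a * shared + np.sqrt(1.0 - a**2) * indep)

    # 1/f background (exponent follows the per-epoch state's slope only in
    # amplitude; one representative slope keeps synthesis O(n))
    pink_amp = _env_from_state_values(
        np.array([model.states[s].pink_amp for s in STATES])
    )
    exp_mean = float(np.mean([model.states[s].pink_exponent for s in labels]))
    shared_pink = _pink_noise(n, exp_mean, sampling_rate, rng)
    for ch in EEG_CHANNELS:
        indep = _pink_noise(n, exp_mean, sampling_rate, rng)
        a = mix_env[ch]
        out[ch] += pink_amp * (a * shared_pink + np.sqrt(1.0 - a**2) * indep)

    # EMG: amplitude-modulated broadband noise, atonia in REM
    emg_env = _env_from_state_values(
        np.array([model.states[s].emg_rms for s in STATES])
    )
    out["EMG"] = emg_env * _band_noise(n, 20.0, 180.0, sampling_rate, rng) \
        + 0.3 * rng.standard_normal(n)

    # EOG: baseline noise plus biphasic smooth deflections at state rates
    eog = 4.0 * _pink_noise(n, 1.0, sampling_rate, rng)
    width = int(round(0.5 * sampling_rate))
    t = np.linspace(-2.5, 2.5, width)
    waveform = -t * np.exp(-t * t / 2.0)
    waveform /= np.abs(waveform).max()
    for e, s in enumerate(labels):
        lam = model.states[s].eog_rate * hypnogram.epoch_length / 60.0
        for _ in range(rng.poisson(lam)):
            pos = e * spe + int(rng.integers(0, max(1, spe - width)))
            amp = model.states[s].eog_amp * rng.lognormal(0.0, 0.35)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            seg = eog[pos : pos + width]
            seg += sign * amp * waveform[: len(seg)]
    out["EOG"] = eog

    return PSGRecording(
        signals=out, sampling_rate=sampling_rate, subject_id=hypnogram.subject_id
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def synthetic_bin_screen(
    n: int = 28,
    bins: np.ndarray | None = None,
    effect_band: tuple[float, float] = (1.0, 1.75),
    target_rho: float = 0.8,
    seed: int = 0,
    *,
    exact_null: bool = True,
):
    """Summary-level fixture for the bin-to-bin screen: a covariate built to
    correlate with the bins inside ``effect_band`` only.

    Returns ``(responses, covariate, bins)`` with ``responses`` of shape
    (n, n_bins).  Effect bins follow a Gaussian copula at the requested
    Spearman rho; with ``exact_null`` the remaining bins are residualized
    against the covariate's rank scores, so the *only* in the construction is
    literal (their sample association is ~0, not merely 0 in expectation).
    """
    cfg_bins = bins if bins is not None else (0.5 + 0.25 * np.arange(199))
    cfg_bins = np.asarray(cfg_bins, dtype=float)
    rng = np.random.default_rng(seed)
    cov = rng.standard_normal(n)
    responses = rng.standard_normal((n, len(cfg_bins)))
    lo, hi = effect_band
    effect = (cfg_bins >= lo - 1e-9) & (cfg_bins <= hi + 1e-9)
    w = 2.0 * np.sin(np.pi * np.clip(target_rho, -0.99, 0.99) / 6.0)
    responses[:, effect] = (
        w * cov[:, None]
        + np.sqrt(1.0 - w * w) * rng.standard_normal((n, int(effect.sum())))
    )
    if exact_null:
        r = stats.norm.ppf((stats.rankdata(cov) - 0.375) / (n + 0.25))
        r = r / np.sqrt(r @ r)
        null = ~effect
        proj = r @ responses[:, null]
        responses[:, null] -= np.outer(r, proj)
    return responses, cov, cfg_bins


@dataclass
class SubjectData:
    profile: SubjectProfile
    hypnogram: Hypnogram
    recording: PSGRecording | None = None


@dataclass
class Cohort:
    subjects: list[SubjectData]
    effects: list[Effect]
    seed: int
    latents: dict[str, np.ndarray] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)

    def covariates_frame(self):
        import pandas as pd

        return pd.DataFrame([s.profile.as_dict() for s in self.subjects])


def _covariate_marginal(name: str, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF transform of uniforms into each covariate's marginal.

    Shapes follow the published cohort summaries: ages 10.4-16.2 y (mean
    13.25, s.d. 1.57), dementia scores 0-70 with median ~18, memory threshold
    0-120 s, inhibitory-control percent piled near 100, detour percent near
    50, gaze 1.3-60 s with median ~17.
    """
    if name == "age":
        a, b = (10.4 - 13.25) / 1.57, (16.2 - 13.25) / 1.57
        return stats.truncnorm.ppf(u, a, b, loc=13.25, scale=1.57)
    if name == "cades":
        return np.round(stats.beta.ppf(u, 1.1, 3.0) * 70.0)
    if name == "memory":
        return np.round(stats.beta.ppf(u, 1.5, 2.5) * 120.0 / 5.0) * 5.0
    if name == "inhibitory":
        return np.clip(np.round(stats.beta.ppf(u, 4.0, 1.0) * 115.0), 13.0, 100.0)
    if name == "detour":
        return np.round(stats.beta.ppf(u, 1.5, 1.5) * 10.0) * 10.0
    if name == "gaze":
        return np.clip(np.round(17.0 * np.exp(0.6 * stats.norm.ppf(u)), 1), 1.3, 60.0)
    raise KeyError(name)


def _copula_weight(target_rho: float, attenuation: float) -> float:
    """Latent Gaussian correlation realizing a requested Spearman rho.

    Pre-compensates the chain/estimator attenuation, then converts Spearman
    to Pearson on the Gaussian scale via r = 2 sin(pi rho / 6).
    """
    r = float(np.clip(target_rho / attenuation, -0.97, 0.97))
    return 2.0 * np.sin(np.pi * r / 6.0)


def _response_latents(
    effects: list[Effect], z_cov: dict[str, np.ndarray], n: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """One latent N(0,1) vector per targeted (or always-on) response."""
    targeted: dict[str, list[Effect]] = {}
    for eff in effects:
        targeted.setdefault(eff.response, []).append(eff)
    responses = sorted(set(targeted) | set(ALWAYS_LATENT))
    out: dict[str, np.ndarray] = {}
    for resp in responses:
        effs = targeted.get(resp, [])
        att = MACRO_ATTENUATION.get(resp, QEEG_ATTENUATION)
        w = np.array([_copula_weight(e.target_rho, att) for e in effs])
        if w @ w > 1.0:
            raise ValueError(
                f"combined effect targets on {resp!r} are infeasible "
                f"(sum of squared latent weights {w @ w:.2f} > 1)"
            )
        z = np.sqrt(max(0.0, 1.0 - w @ w)) * rng.standard_normal(n)
        for e, wi in zip(effs, w):
            z = z + wi * z_cov[e.covariate]
        out[resp] = z
    return out


def _subject_model(
    base: StateSignalModel, latents: dict[str, np.ndarray], i: int
) -> StateSignalModel:
    """Per-subject signal model with qEEG effect latents applied."""
    model = copy.deepcopy(base)
    for resp, z in latents.items():
        if resp in MACRO_MECHANISM:
            continue
        parts = resp.split(":")
        zi = float(z[i])
        if parts[0] == "power":
            _, ch, state, band = parts
            key = (ch, state, band)
            model.band_scale[key] = model.band_scale.get(key, 1.0) * float(
                np.exp(POWER_EFFECT_K * zi)
            )
        elif parts[0] == "coh":
            _, pair, state, band = parts
            m = model.pair_msc[(pair, state)]
            logit = np.log(m / (1.0 - m)) + COH_EFFECT_K * zi
            model.pair_msc[(pair, state)] = float(1.0 / (1.0 + np.exp(-logit)))
        elif parts[0] == "lzc":
            _, ch, state = parts
            for band in ("beta", "gamma"):
                key = (ch, state, band)
                model.band_scale[key] = model.band_scale.get(key, 1.0) * float(
                    np.exp(POWER_EFFECT_K * zi)
                )
    return model


def generate_cohort(
    n: int = 28,
    effects: list[Effect] | None = None,
    seed: int = 0,
    *,
    duration_h: float = 2.0,
    duration_range_h: tuple[float, float] | None = None,
    with_signals: bool = True,
    artifact_rate: float = 0.01,
    transition_params: TransitionParams | None = None,
    state_model: StateSignalModel | None = None,
) -> Cohort:
    """Generate a full synthetic cohort, reproducible from ``seed``.

    With ``duration_range_h`` set, per-subject recording lengths are uniform
    in that range (rounded to whole epochs), mirroring early drop-outs;
    otherwise all recordings last ``duration_h`` hours.  ``with_signals=False``
    skips signal synthesis for macrostructure-level studies.
    """
    if n < 3:
        raise ValueError("cohort size must be at least 3")
    effects = default_effects() if effects is None else list(effects)
    for eff in effects:
        _validate_response(eff.response)
    tp = transition_params or TransitionParams()
    base_model = state_model or default_state_model()
    rng = np.random.default_rng(seed)

    # covariates via Gaussian copula so effect latents can share their scores
    z_cov = {c: rng.standard_normal(n) for c in COVARIATES}
    u = {c: stats.norm.cdf(z) for c, z in z_cov.items()}
    values = {c: _covariate_marginal(c, u[c]) for c in COVARIATES}
    detour_missing = rng.random(n) < 1.0 / 28.0

    latents = _response_latents(effects, z_cov, n, rng)

    # per-subject transition matrices
    Ps = np.stack([
        _transition_matrix(
            tp.rates_for({r: float(z[i]) for r, z in latents.items()
                          if r in MACRO_MECHANISM})
        )
        for i in range(n)
    ])

    if duration_range_h is not None:
        lo, hi = duration_range_h
        hours = lo + (hi - lo) * rng.random(n)
    else:
        hours = np.full(n, duration_h)
    n_epochs = np.maximum(1, np.round(hours * 3600.0 / EPOCH_S)).astype(int)
    max_epochs = int(n_epochs.max())

    codes = _simulate_chains(Ps, max_epochs, rng)
    state_arr = np.array(STATES, dtype="U1")

    signal_seeds = rng.integers(0, 2**31 - 1, size=n) if with_signals else None

    subjects: list[SubjectData] = []
    for i in range(n):
        sid = f"dog{i + 1:03d}"
        profile = SubjectProfile(
            subject_id=sid,
            age=float(values["age"][i]),
            cades=int(values["cades"][i]),
            memory=float(values["memory"][i]),
            inhibitory=float(values["inhibitory"][i]),
            detour=None if detour_missing[i] else float(values["detour"][i]),
            gaze=float(values["gaze"][i]),
        )
        labels = state_arr[codes[i, : n_epochs[i]]]
        artifact = rng.random(n_epochs[i]) < artifact_rate
        hyp = Hypnogram(labels=labels, artifact=artifact, subject_id=sid)
        rec = None
        if with_signals:
            model_i = _subject_model(base_model, latents, i)
            rec = synthesize_signals(hyp, model_i, seed=int(signal_seeds[i]))
        subjects.append(SubjectData(profile=profile, hypnogram=hyp, recording=rec))
    return Cohort(subjects=subjects, effects=effects, seed=seed, latents=latents)
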