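"""Synthetic epoched-EEG studies with known ground truth.

Generates multi-participant, multi-class epoched EEG with the statistical
structure the downstream analysis assumes: class-dependent ERP templates,
stereotyped frontal blink artifacts (optionally class-dependent, to emulate
ocular confounds), idiosyncratic large-amplitude step/drift artifacts on
random trials, and spatially-correlated AR(1) ongoing noise.  Every injected
component is recorded in a :class:`GroundTruth` so detection/correction
stages can be scored against truth.

Amplitudes are in microvolts (μV), times in milliseconds, rates in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "Montage",
    "EpochSet",
    "GroundTruth",
    "SimulationConfig",
    "ParadigmPreset",
    "PARADIGM_PRESETS",
    "get_paradigm_preset",
    "make_montage",
    "blink_waveform",
    "class_template",
    "simulate_participant",
    "simulate_study",
    "veog_bipolar",
]


# --------------------------------------------------------------------------
# Domain containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Montage:
    """Channel layout on the unit sphere.

    ``eog_lower`` is the infra-orbital EOG electrode; ``veog_upper`` is the
    frontopolar electrode paired with it for the vertical-EOG bipolar
    derivation (large deflections in ``veog_upper - eog_lower`` indicate
    blinks).
    """

    channel_names: tuple[str, ...]
    n_scalp: int
    eog_lower: str
    veog_upper: str
    positions: np.ndarray  # (n_channels, 3), unit vectors

    def __post_init__(self) -> None:
        names = self.channel_names
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if self.eog_lower not in names or self.veog_upper not in names:
            raise ValueError("eog_lower and veog_upper must be montage channels")
        if self.n_scalp < 2:
            raise ValueError("need at least 2 scalp channels")
        if self.positions.shape != (len(names), 3):
            raise ValueError("positions must be (n_channels, 3)")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        return self.channel_names.index(name)

    @property
    def scalp_indices(self) -> np.ndarray:
        """Indices of scalp channels (everything but the infra-orbital EOG)."""
        return np.array(
            [i for i, n in enumerate(self.channel_names) if n != self.eog_lower]
        )


@dataclass
class EpochSet:
    """Epoched multichannel EEG: ``data[epoch, channel, sample]`` in μV."""

    data: np.ndarray
    times: np.ndarray  # ms
    srate: float  # Hz
    labels: np.ndarray  # per-epoch class index, 0..M-1
    M: int
    montage: Montage
    keep: np.ndarray  # per-epoch boolean
    participant_id: str = "sub-00"
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.keep = np.asarray(self.keep, dtype=bool)
        n_ep, n_ch, n_sa = self.data.shape
        if len(self.times) != n_sa:
            raise ValueError("times length must equal the sample dimension")
        dt = np.diff(self.times)
        if not (np.all(dt > 0) and np.allclose(dt, 1000.0 / self.srate, rtol=1e-6)):
            raise ValueError("times must increase in steps of 1000/srate ms")
        if n_ch != self.montage.n_channels:
            raise ValueError("channel dimension does not match montage")
        if self.labels.shape != (n_ep,) or self.keep.shape != (n_ep,):
            raise ValueError("labels/keep must have one entry per epoch")
        if self.labels.size and not (
            (self.labels >= 0).all() and (self.labels < self.M).all()
        ):
            raise ValueError("labels must lie in [0, M)")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            times=self.times.copy(),
            srate=self.srate,
            labels=self.labels.copy(),
            M=self.M,
            montage=self.montage,
            keep=self.keep.copy(),
            participant_id=self.participant_id,
            log=list(self.log),
        )


@dataclass
class GroundTruth:
    """Everything injected into one simulated participant's data."""

    blink_trials: set[int]
    blink_topography: np.ndarray  # per-channel gain, unitless
    blink_amplitudes: dict[int, float]  # μV per blink trial
    blink_onsets: dict[int, float]  # ms, pulse onset per blink trial
    artifact_trials: set[int]
    class_templates: np.ndarray  # (M, channels, samples), μV
    noise_sd: float
    seed: int


@dataclass(frozen=True)
class ParadigmPreset:
    """Per-paradigm epoch geometry and class/channel counts."""

    name: str
    epoch_window: tuple[float, float]  # ms
    baseline_window: tuple[float, float]  # ms
    measurement_window: tuple[float, float]  # ms
    M: int
    n_channels: int  # scalp channels
    srate: float  # Hz

    def __post_init__(self) -> None:
        e0, e1 = self.epoch_window
        for lo, hi in (self.baseline_window, self.measurement_window):
            if not (e0 <= lo < hi <= e1):
                raise ValueError("baseline/measurement windows must lie inside the epoch")


def _erp_core(name: str, meas: tuple[float, float]) -> ParadigmPreset:
    return ParadigmPreset(name, (-200, 800), (-200, 0), meas, 2, 28, 256.0)


PARADIGM_PRESETS: dict[str, ParadigmPreset] = {
    "N170": _erp_core("N170", (110, 150)),
    "MMN": _erp_core("MMN", (125, 225)),
    "P3b": _erp_core("P3b", (300, 600)),
    "N400": _erp_core("N400", (300, 500)),
    "ERN": ParadigmPreset("ERN", (-600, 400), (-400, -200), (0, 100), 2, 28, 256.0),
    "LRP": ParadigmPreset("LRP", (-800, 200), (-800, -600), (-100, 0), 2, 28, 256.0),
    "N2pc": _erp_core("N2pc", (200, 275)),
    # Orientation working-memory paradigms: accuracy is summarized in a
    # perception window (100-500 ms, the default here) or a memory-maintenance
    # window (500-1000 ms).
    "Orientations-1": ParadigmPreset(
        "Orientations-1", (-500, 1500), (-500, 0), (100, 500), 16, 27, 250.0
    ),
    "Orientations-2": ParadigmPreset(
        "Orientations-2", (-500, 1500), (-500, 0), (100, 500), 16, 27, 250.0
    ),
    "Orientations-Community": ParadigmPreset(
        "Orientations-Community", (-500, 1500), (-500, 0), (100, 500), 12, 59, 250.0
    ),
}


def get_paradigm_preset(name: str) -> ParadigmPreset:
    """Look up a paradigm preset by name; unknown names raise KeyError."""
    try:
        return PARADIGM_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {sorted(PARADIGM_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level generator settings.

    ``blink_prob_per_class`` has one Bernoulli probability per class so that
    blink rates can be made class-dependent (the ocular-confound scenario).
    ``noise_sd`` is the stationary per-channel SD of the ongoing noise;
    ``noise_ar`` its AR(1) coefficient (0.97 at ~250 Hz gives the strong
    low-frequency autocorrelation typical of EEG).
    """

    preset: str = "P3b"
    n_participants: int = 20
    M: int | None = None  # default: preset's class count
    trials_per_class: int = 80
    effect_amplitude: float = 2.0  # μV peak class-difference
    tuning_concentration: float = 2.0  # κ, multiclass circular tuning
    blink_prob_per_class: tuple[float, ...] | None = None  # default 0.2 each
    blink_amplitude_mean: float = 150.0  # μV at the frontopolar peak
    blink_amplitude_sd: float = 30.0
    blink_duration: float = 300.0  # ms
    blink_latency_mean: float = 400.0  # ms of the pulse peak, after time 0
    blink_latency_sd: float = 100.0
    artifact_prob: float = 0.05
    artifact_amplitude_range: tuple[float, float] = (150.0, 500.0)  # μV
    noise_sd: float = 10.0  # μV
    noise_ar: float = 0.97
    master_seed: int = 0

    def resolved(self) -> "SimulationConfig":
        """Fill preset-dependent defaults and validate."""
        preset = get_paradigm_preset(self.preset)
        M = preset.M if self.M is None else self.M
        probs = self.blink_prob_per_class
        if probs is None:
            probs = (0.2,) * M
        probs = tuple(float(p) for p in probs)
        out = replace(self, M=M, blink_prob_per_class=probs)
        if len(probs) != M:
            raise ValueError("blink_prob_per_class must have one entry per class")
        if not all(0.0 <= p <= 1.0 for p in probs) or not 0.0 <= self.artifact_prob <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.trials_per_class < 3:
            raise ValueError("need at least 3 trials per class")
        if not 0.0 <= self.noise_ar < 1.0:
            raise ValueError("noise_ar must lie in [0, 1)")
        return out


# --------------------------------------------------------------------------
# Montage construction
# --------------------------------------------------------------------------

_ERP_CORE_28 = (
    "Fp1 Fp2 Fz F3 F4 F7 F8 FCz FC3 FC4 Cz C3 C4 C5 C6 CPz "
    "Pz P3 P4 P7 P8 PO3 PO4 PO7 PO8 Oz O1 O2"
).split()

_ORIENTATIONS_27 = (
    "Fp1 Fp2 Fz F3 F4 F7 F8 Cz C3 C4 Pz P3 P4 P5 P6 P7 P8 P9 P10 "
    "POz PO3 PO4 PO7 PO8 Oz O1 O2"
).split()

_COMMUNITY_59 = (
    "Fp1 Fp2 AFz AF3 AF4 AF7 AF8 "
    "Fz F1 F2 F3 F4 F5 F6 F7 F8 "
    "FCz FC1 FC2 FC3 FC4 FC5 FC6 "
    "Cz C1 C2 C3 C4 C5 C6 "
    "CPz CP1 CP2 CP3 CP4 CP5 CP6 TP7 TP8 "
    "Pz P1 P2 P3 P4 P5 P6 P7 P9 P10 "
    "POz PO3 PO4 PO7 PO8 Oz O1 O2 TP9 TP10"
).split()

_SCALP_SETS = {28: _ERP_CORE_28, 27: _ORIENTATIONS_27, 59: _COMMUNITY_59}

EOG_LOWER = "VEOGlow"

_pos_cache: dict[str, np.ndarray] = {}


def _standard_positions(names: list[str]) -> np.ndarray:
    """Unit-sphere positions for standard 10-20 channel names."""
    missing = [n for n in names if n not in _pos_cache]
    if missing:
        import warnings

        import mne

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            std = mne.channels.make_standard_montage("standard_1020").get_positions()
        chpos = std["ch_pos"]
        for n in missing:
            p = np.asarray(chpos[n], dtype=float)
            _pos_cache[n] = p / np.linalg.norm(p)
    return np.array([_pos_cache[n] for n in names])


def make_montage(n_scalp: int) -> Montage:
    """Build the synthetic montage for a preset's scalp-channel count.

    Appends one infra-orbital EOG channel (below the right eye) to the scalp
    set; the VEOG-bipolar pairs it with Fp2.
    """
    try:
        scalp = list(_SCALP_SETS[n_scalp])
    except KeyError:
        raise ValueError(f"no montage defined for {n_scalp} scalp channels") from None
    pos = _standard_positions(scalp)
    # infra-orbital electrode: Fp2 shifted downward, back onto the unit sphere
    fp2 = pos[scalp.index("Fp2")]
    lower = fp2 - np.array([0.0, 0.0, 0.6])
    lower /= np.linalg.norm(lower)
    return Montage(
        channel_names=tuple(scalp + [EOG_LOWER]),
        n_scalp=n_scalp,
        eog_lower=EOG_LOWER,
        veog_upper="Fp2",
        positions=np.vstack([pos, lower]),
    )


# --------------------------------------------------------------------------
# Signal components
# --------------------------------------------------------------------------

def blink_waveform(
    times: np.ndarray, onset: float, duration: float, amplitude: float
) -> np.ndarray:
    """Raised-cosine blink pulse: peak ``amplitude`` at onset + duration/2,
    zero outside [onset, onset + duration]."""
    if duration <= 0:
        raise ValueError("blink duration must be positive")
    t = np.asarray(times, dtype=float)
    phase = (t - onset) / duration
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    w[(phase < 0) | (phase > 1)] = 0.0
    return amplitude * w


def _posterior_weights(montage: Montage) -> tuple[np.ndarray, np.ndarray]:
    """(channel indices, smooth gains in (0, 1]) of posterior scalp channels.

    Posterior = negative y (behind the vertex) in head coordinates.
    """
    y = montage.positions[:, 1]
    idx = np.array(
        [
            i
            for i in montage.scalp_indices
            if y[i] < 0
        ]
    )
    g = (-y[idx]) ** 2
    return idx, g / g.max()


def class_template(
    class_idx: int,
    M: int,
    montage: Montage,
    preset: ParadigmPreset,
    effect_amplitude: float,
    kappa: float,
    times: np.ndarray,
) -> np.ndarray:
    """Decodable class signal: Gaussian time course centered in the
    measurement window, carried on posterior channels.

    Binary designs use two opposite-sign posterior topographies whose peak
    difference equals ``effect_amplitude``.  Multiclass designs use circular-
    Gaussian tuning exp(κ·cos(θ_class − θ_channel)) over posterior channels
    (peak-normalized, scaled by ``effect_amplitude``); κ = 0 removes all class
    information.
    """
    if M < 2:
        raise ValueError("need at least 2 classes")
    if not 0 <= class_idx < M:
        raise ValueError("class_idx out of range")
    n_ch = montage.n_channels
    t = np.asarray(times, dtype=float)
    lo, hi = preset.measurement_window
    mid, sd = 0.5 * (lo + hi), (hi - lo) / 4.0
    course = np.exp(-0.5 * ((t - mid) / sd) ** 2)

    gains = np.zeros(n_ch)
    idx, w = _posterior_weights(montage)
    if M == 2:
        sign = 1.0 if class_idx == 0 else -1.0
        gains[idx] = sign * 0.5 * effect_amplitude * w
    else:
        theta_ch = 2.0 * np.pi * np.arange(len(idx)) / len(idx)
        theta_cl = 2.0 * np.pi * class_idx / M
        tuning = np.exp(kappa * (np.cos(theta_cl - theta_ch) - 1.0))
        gains[idx] = effect_amplitude * tuning
    return gains[:, None] * course[None, :]


def _blink_topography(montage: Montage) -> np.ndarray:
    """Fixed frontal blink scalp distribution: gain 1 at the frontopolar
    sites, smooth fall-off with distance, sign-inverted below the eye."""
    pos = montage.positions
    anchor = pos[montage.index(montage.veog_upper)]
    d2 = np.sum((pos - anchor) ** 2, axis=1)
    gain = np.exp(-d2 / (2 * 0.35**2))
    gain /= gain[montage.index(montage.veog_upper)]
    gain[montage.index(montage.eog_lower)] = -0.8
    return gain


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------

def _ar1_noise(
    rng: np.random.Generator, shape: tuple[int, int, int], a: float
) -> np.ndarray:
    """Stationary unit-variance AR(1) series along the last axis."""
    e = rng.standard_normal(shape)
    if a == 0.0:
        return e
    e[..., 1:] *= np.sqrt(1.0 - a * a)  # innovations; e[...,0] is the
    return lfilter([1.0], [1.0, -a], e, axis=-1)  # stationary start draw


def _smooth_mixing(rng: np.random.Generator, montage: Montage, noise_sd: float) -> np.ndarray:
    """Random channels × sources mixing, smooth over the montage, with rows
    scaled so every channel has stationary SD ``noise_sd``."""
    n_ch = montage.n_channels
    src = rng.standard_normal((n_ch, 3))
    src /= np.linalg.norm(src, axis=1, keepdims=True)
    d2 = np.sum((montage.positions[:, None, :] - src[None, :, :]) ** 2, axis=2)
    A = np.exp(-d2 / (2 * 0.6**2)) + 0.05 * rng.standard_normal((n_ch, n_ch))
    A *= noise_sd / np.linalg.norm(A, axis=1, keepdims=True)
    return A


def simulate_participant(
    cfg: SimulationConfig, participant_index: int
) -> tuple[EpochSet, GroundTruth]:
    """Generate one participant's epochs plus the injected ground truth.

    All randomness flows from a stream derived from
    ``(master_seed, participant_index)``, so the call is a pure function of
    its arguments.
    """
    cfg = cfg.resolved()
    preset = get_paradigm_preset(cfg.preset)
    montage = make_montage(preset.n_channels)
    rng = np.random.default_rng([cfg.master_seed, participant_index])

    M = cfg.M
    n_trials = M * cfg.trials_per_class
    n_samples = int(round((preset.epoch_window[1] - preset.epoch_window[0])
                          * preset.srate / 1000.0)) + 1
    times = preset.epoch_window[0] + np.arange(n_samples) * (1000.0 / preset.srate)

    labels = rng.permutation(np.repeat(np.arange(M), cfg.trials_per_class))

    # ongoing noise: AR(1) sources mixed through smooth spatial patterns
    A = _smooth_mixing(rng, montage, cfg.noise_sd)
    sources = _ar1_noise(rng, (n_trials, montage.n_channels, n_samples), cfg.noise_ar)
    data = np.einsum("cs,est->ect", A, sources)

    # class-dependent ERP templates
    templates = np.stack(
        [
            class_template(
                k, M, montage, preset, cfg.effect_amplitude,
                cfg.tuning_concentration, times,
            )
            for k in range(M)
        ]
    )
    data += templates[labels]

    # blinks: fixed frontal topography, Bernoulli per trial by class
    topo = _blink_topography(montage)
    probs = np.asarray(cfg.blink_prob_per_class)
    blink_mask = rng.random(n_trials) < probs[labels]
    blink_trials = np.flatnonzero(blink_mask)
    amplitudes, onsets = {}, {}
    for i in blink_trials:
        amp = max(0.0, rng.normal(cfg.blink_amplitude_mean, cfg.blink_amplitude_sd))
        peak = rng.normal(cfg.blink_latency_mean, cfg.blink_latency_sd)
        onset = peak - cfg.blink_duration / 2.0
        data[i] += topo[:, None] * blink_waveform(
            times, onset, cfg.blink_duration, amp
        )[None, :]
        amplitudes[int(i)] = amp
        onsets[int(i)] = onset

    # idiosyncratic step/drift artifacts on random channel subsets
    art_mask = rng.random(n_trials) < cfg.artifact_prob
    art_trials = np.flatnonzero(art_mask)
    lo, hi = cfg.artifact_amplitude_range
    scalp = montage.scalp_indices
    for i in art_trials:
        n_aff = int(rng.integers(1, 4))
        chans = rng.choice(scalp, size=n_aff, replace=False)
        amp = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
        if rng.random() < 0.5:  # step
            onset = int(rng.integers(0, n_samples))
            data[i, chans, onset:] += amp
        else:  # linear drift
            data[i, chans, :] += amp * np.linspace(0.0, 1.0, n_samples)

    epochs = EpochSet(
        data=data,
        times=times,
        srate=preset.srate,
        labels=labels,
        M=M,
        montage=montage,
        keep=np.ones(n_trials, dtype=bool),
        participant_id=f"sub-{participant_index:02d}",
        log=[f"simulate(preset={cfg.preset}, seed={cfg.master_seed}/{participant_index})"],
    )
    truth = GroundTruth(
        blink_trials=set(int(i) for i in blink_trials),
        blink_topography=topo,
        blink_amplitudes=amplitudes,
        blink_onsets=onsets,
        artifact_trials=set(int(i) for i in art_trials),
        class_templates=templates,
        noise_sd=cfg.noise_sd,
        seed=cfg.master_seed,
    )
    return epochs, truth


def simulate_study(cfg: SimulationConfig) -> list[tuple[EpochSet, GroundTruth]]:
    """Simulate ``cfg.n_participants`` independent participants."""
    cfg = cfg.resolved()
    if cfg.n_participants < 1:
        raise ValueError("need at least one participant")
    return [simulate_participant(cfg, i) for i in range(cfg.n_participants)]


def veog_bipolar(epochs: EpochSet) -> np.ndarray:
    """Vertical-EOG bipolar derivation, ``(n_epochs, n_samples)`` μV:
    frontopolar channel minus infra-orbital channel."""
    m = epochs.montage
    try:
        iu, il = m.index(m.veog_upper), m.index(m.eog_lower)
    except ValueError as err:
        raise ValueError("montage lacks the VEOG channel pair") from err
    return epochs.data[:, iu, :] - epochs.data[:, il, :]
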