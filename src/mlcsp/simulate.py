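"""Synthetic combined motor-imagery EEG sessions.

The generator emulates the physiology the decoders rely on: three
oscillatory sensorimotor sources (left hand -> C4, feet -> Cz, right hand ->
C3) carrying mu (~11 Hz) and beta (~21 Hz) rhythms, whose amplitude drops
(ERD) while the corresponding body part is engaged during the cue window and
may rise slightly (surround ERS) when other parts are engaged.  Sources are
projected to the 26-channel montage through a Gaussian spatial kernel and
buried in 1/f background noise.

Oscillators are narrowband-filtered white noise rather than pure sinusoids:
CSP needs trial-to-trial variance structure, and deterministic tones would
make the class covariances rank deficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .core import (
    ALL_LABELS,
    MONTAGE_26,
    BodyPart,
    EpochSet,
    Montage,
    ParadigmSpec,
    TaskLabel,
    engages,
)

__all__ = [
    "SimulationConfig",
    "build_mixing_matrix",
    "simulate_continuous",
    "simulate_session",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic session.

    erd_depth ``d``: fraction of source amplitude suppressed while the part
    is engaged (band power drops by ``1 - (1-d)**2``).  surround_ers_gain
    ``g``: fractional amplitude increase of non-engaged sources during
    non-rest trials.  noise_amplitude: RMS microvolts of the per-channel 1/f
    background.  Defaults put single-session 8-class decoding in the
    mid-range (neither chance nor ceiling) for the multilabel methods.
    """

    paradigm: ParadigmSpec = field(default_factory=ParadigmSpec)
    montage: Montage = field(default_factory=lambda: MONTAGE_26)
    source_centers: dict[BodyPart, str] = field(
        default_factory=lambda: {
            BodyPart.LEFT_HAND: "C4",
            BodyPart.FEET: "Cz",
            BodyPart.RIGHT_HAND: "C3",
        }
    )
    spatial_spread: float = 0.25
    osc_components: tuple[tuple[float, float], ...] = ((11.0, 2.0), (21.0, 1.0))
    erd_depth: dict[BodyPart, float] = field(
        default_factory=lambda: {part: 0.6 for part in BodyPart}
    )
    surround_ers_gain: float = 0.0
    noise_amplitude: float = 8.0
    n_background_sources: int = 0
    background_amplitude: float = 2.0
    ramp_duration: float = 0.25
    lead_in: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        for part, depth in self.erd_depth.items():
            if not 0.0 <= depth <= 1.0:
                raise ValueError(f"erd_depth[{part.name}] must be in [0, 1]")
        if self.surround_ers_gain < 0:
            raise ValueError("surround_ers_gain must be >= 0")
        if self.spatial_spread <= 0:
            raise ValueError("spatial_spread must be positive")
        for part, name in self.source_centers.items():
            self.montage.index(name)  # raises KeyError on unknown channel


def build_mixing_matrix(montage: Montage, config: SimulationConfig) -> np.ndarray:
    """Source-to-channel projection, one column per body part.

    Column ``p`` is a Gaussian of head-plane distance centred on the source
    channel of part ``p``, normalized to unit maximum (so the source's band
    power at its centre channel equals its nominal power).
    """
    mixing = np.empty((montage.n_channels, len(BodyPart)))
    for part in BodyPart:
        center = montage.position(config.source_centers[part])
        dist = np.linalg.norm(montage.positions - center[None, :], axis=1)
        col = np.exp(-0.5 * (dist / config.spatial_spread) ** 2)
        mixing[:, part.value] = col / col.max()
    return mixing


def _trial_schedule(config: SimulationConfig, rng: np.random.Generator) -> list[TaskLabel]:
    """Randomized trial order: each run holds trials_per_class/runs of each class."""
    paradigm = config.paradigm
    per_run = paradigm.trials_per_class // paradigm.runs
    order: list[TaskLabel] = []
    for _ in range(paradigm.runs):
        block = [lab for lab in ALL_LABELS for _ in range(per_run)]
        order.extend(block[i] for i in rng.permutation(len(block)))
    return order


def _narrowband_noise(
    rng: np.random.Generator, n: int, fs: float, f0: float, half_bw: float = 1.5
) -> np.ndarray:
    """Unit-RMS band-limited noise centred at f0 (random phase per call)."""
    sos = signal.butter(4, [f0 - half_bw, f0 + half_bw], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Unit-RMS 1/f-power noise along the last axis via spectral shaping."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1])
    freqs[0] = freqs[1]
    spec *= freqs ** -0.5
    x = np.fft.irfft(spec, n=shape[-1], axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _amplitude_envelopes(
    config: SimulationConfig, schedule: list[TaskLabel], n_samples: int
) -> np.ndarray:
    """Per-source amplitude multipliers over the continuous recording.

    Baseline 1 everywhere; during the cue window of trial with label y the
    multiplier of source p is (1 - d_p) if y engages p, (1 + g) if y is a
    non-rest trial not engaging p, and 1 during rest trials and pauses.
    Transitions are smoothed with a ramp to mimic gradual ERD onset.
    """
    paradigm = config.paradigm
    fs = paradigm.sampling_rate
    env = np.ones((len(BodyPart), n_samples))
    lead = int(round(config.lead_in * fs))
    trial_len = int(round(paradigm.trial_duration * fs))
    cue0 = int(round(paradigm.cue_window[0] * fs))
    cue1 = int(round(paradigm.cue_window[1] * fs))
    for i, label in enumerate(schedule):
        start = lead + i * trial_len
        for part in BodyPart:
            if engages(label, part):
                level = 1.0 - config.erd_depth[part]
            elif not label.is_rest:
                level = 1.0 + config.surround_ers_gain
            else:
                continue
            env[part.value, start + cue0 : start + cue1] = level
    ramp = int(round(config.ramp_duration * fs))
    if ramp > 1:
        kernel = np.hanning(ramp + 2)[1:-1]
        kernel /= kernel.sum()
        env = signal.fftconvolve(env, kernel[None, :], mode="same", axes=-1)
    return env


def simulate_continuous(
    config: SimulationConfig,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate one continuous session.

    Returns the ``(n_channels, n_samples)`` recording in microvolts and an
    events table with columns ``trial``, ``onset_s``, ``class_index``
    (onsets are cue onsets; trials are contiguous 12-s blocks following a
    short lead-in).
    """
    paradigm = config.paradigm
    fs = paradigm.sampling_rate
    rng = np.random.default_rng(config.seed)
    schedule = _trial_schedule(config, rng)
    n_samples = int(round((config.lead_in + len(schedule) * paradigm.trial_duration) * fs))

    env = _amplitude_envelopes(config, schedule, n_samples)
    sources = np.zeros((len(BodyPart), n_samples))
    for part in BodyPart:
        for f0, amp in config.osc_components:
            sources[part.value] += amp * _narrowband_noise(rng, n_samples, fs, f0)
    sources *= env

    mixing = build_mixing_matrix(config.montage, config)
    data = mixing @ sources

    # task-independent background rhythms: narrowband generators scattered
    # over the montage, constant across conditions (ongoing mu/alpha/beta
    # activity unrelated to the task)
    if config.n_background_sources > 0 and config.background_amplitude > 0:
        positions = config.montage.positions
        for _ in range(config.n_background_sources):
            center = positions[rng.integers(len(positions))]
            dist = np.linalg.norm(positions - center[None, :], axis=1)
            gain = np.exp(-0.5 * (dist / (2.0 * config.spatial_spread)) ** 2)
            f0 = rng.uniform(9.0, 25.0)
            wave = _narrowband_noise(rng, n_samples, fs, f0)
            data += config.background_amplitude * np.outer(gain, wave)

    if config.noise_amplitude > 0:
        n_ch = config.montage.n_channels
        data += config.noise_amplitude * _pink_noise(rng, (n_ch, n_samples))
        # small spatially correlated background, shared across channels
        data += 0.3 * config.noise_amplitude * _pink_noise(rng, (1, n_samples))

    onsets = config.lead_in + np.arange(len(schedule)) * paradigm.trial_duration
    events = pd.DataFrame(
        {
            "trial": np.arange(len(schedule)),
            "onset_s": onsets,
            "class_index": [lab.class_index for lab in schedule],
        }
    )
    return data, events


def simulate_session(config: SimulationConfig) -> tuple[EpochSet, pd.DataFrame]:
    """Simulate a session and epoch it into 12-s raw trials at cue onset."""
    from .preprocessing import epoch_continuous

    data, events = simulate_continuous(config)
    epochs = epoch_continuous(
        data,
        events,
        t0=0.0,
        t1=config.paradigm.trial_duration,
        sampling_rate=config.paradigm.sampling_rate,
        montage=config.montage,
    )
    return epochs, events
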