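"""ERD/ERS time courses, projected power spectra and r-squared diagnostics.

ERD/ERS is quantified with the classical band-power convention
``100 * (A - R) / R`` where ``A`` is the trial-averaged smoothed band power
and ``R`` its mean over a pre-cue reference window.  Negative values are
desynchronization (ERD), positive values synchronization (ERS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .core import BodyPart, EpochSet, TaskLabel, engages

__all__ = [
    "ERDCurve",
    "band_power_envelope",
    "erd_percent",
    "erd_curve",
    "class_spectra",
    "r_squared",
]


@dataclass
class ERDCurve:
    times: np.ndarray  # seconds relative to cue onset
    values: np.ndarray  # percent
    sem: np.ndarray  # percent, standard error of the mean across trials
    channel: str
    condition: str


def band_power_envelope(epochs: EpochSet, smooth_window: float = 0.25) -> np.ndarray:
    """Squared signal smoothed by a moving average (trials, channels, samples)."""
    size = int(round(smooth_window * epochs.sampling_rate))
    if size > epochs.n_samples:
        raise ValueError("smoothing window longer than the epoch")
    power = epochs.data ** 2
    if size > 1:
        power = uniform_filter1d(power, size=size, axis=-1, mode="nearest")
    return power


def erd_percent(
    power: np.ndarray,
    times: np.ndarray,
    reference_window: tuple[float, float] = (-2.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """ERD/ERS% and its SEM from a (trials, ..., samples) power tensor.

    The reference power is the trial-averaged power over the reference
    window (pre-cue baseline); SEM is computed across per-trial normalized
    curves sharing that reference.
    """
    ref_mask = (times >= reference_window[0]) & (times < reference_window[1])
    if not ref_mask.any():
        raise ValueError("reference window outside the epoch")
    mean_power = power.mean(axis=0)
    ref = mean_power[..., ref_mask].mean(axis=-1, keepdims=True)
    if np.any(ref <= 0):
        raise ValueError("zero reference power")
    values = 100.0 * (mean_power - ref) / ref
    per_trial = 100.0 * (power - ref[None]) / ref[None]
    sem = per_trial.std(axis=0, ddof=1) / np.sqrt(power.shape[0])
    return values, sem


def erd_curve(
    epochs: EpochSet,
    channel: str,
    condition: set[TaskLabel] | None = None,
    reference_window: tuple[float, float] = (-2.0, 0.0),
    smooth_window: float = 0.25,
) -> ERDCurve:
    """ERD/ERS% time course at one channel for a set of task labels.

    ``epochs`` must be band-pass filtered and extend back over the
    reference window (negative ``t_start``).
    """
    if epochs.montage is None:
        raise ValueError("epochs carry no montage; cannot resolve channel names")
    ch = epochs.montage.index(channel)
    if condition is not None:
        keep = [i for i, lab in enumerate(epochs.labels) if lab in condition]
        if not keep:
            raise ValueError("no trials match the requested condition")
        epochs = epochs.subset(keep)
        cond_name = " | ".join(sorted(lab.name for lab in condition))
    else:
        cond_name = "all"
    power = band_power_envelope(epochs, smooth_window)[:, ch, :]
    values, sem = erd_percent(power, epochs.times, reference_window)
    return ERDCurve(
        times=epochs.times, values=values, sem=sem, channel=channel, condition=cond_name
    )


def engaged_condition(part: BodyPart, engaged: bool = True) -> set[TaskLabel]:
    """The 4 labels that do (or do not) engage a body part."""
    from .core import ALL_LABELS

    return {lab for lab in ALL_LABELS if engages(lab, part) == engaged}


def class_spectra(
    projected: np.ndarray,
    labels: np.ndarray,
    sampling_rate: float,
    segment_duration: float = 1.0,
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Per-class mean amplitude spectra of a projected component.

    Welch periodograms (1-s segments, 50% overlap by default) are averaged
    within each of the two label groups; amplitude is the square root of the
    power density, so a doubled signal doubles the spectrum.
    """
    projected = np.asarray(projected, dtype=float)
    labels = np.asarray(labels)
    nperseg = min(int(round(segment_duration * sampling_rate)), projected.shape[-1])
    spectra: dict[int, np.ndarray] = {}
    freqs = None
    for c in np.unique(labels):
        trials = projected[labels == c]
        if len(trials) < 2:
            raise ValueError(f"class {c} needs at least 2 trials")
        freqs, psd = signal.welch(trials, fs=sampling_rate, nperseg=nperseg, axis=-1)
        spectra[int(c)] = np.sqrt(psd.mean(axis=0))
    return freqs, spectra


def r_squared(values: np.ndarray, labels: np.ndarray) -> float:
    """Squared point-biserial correlation between a feature and binary labels."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("r_squared needs exactly two label values")
    x = (labels == groups[1]).astype(float)
    if values.std() == 0 or x.std() == 0:
        return 0.0
    r = np.corrcoef(values, x)[0, 1]
    return float(r ** 2)
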