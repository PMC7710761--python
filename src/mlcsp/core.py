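"""Domain model for 8-class combined motor-imagery decoding.

The paradigm combines three body parts (left hand, feet, right hand); every
subset of engaged parts is a class, giving 2**3 = 8 classes including rest.
A class is therefore equivalently a 3-bit engagement vector, which is what
the multilabel decoders exploit.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class BodyPart(enum.IntEnum):
    """The three motor-imagery effectors, in canonical order."""

    LEFT_HAND = 0
    FEET = 1
    RIGHT_HAND = 2


@dataclass(frozen=True, order=True)
class TaskLabel:
    """One of the 8 combined-MI classes.

    ``class_index`` encodes the engagement bits with LEFT_HAND as the least
    significant bit: index = LH + 2*FEET + 4*RH.  This reproduces the
    conventional listing order rest, left hand, feet, left hand and feet,
    right hand, both hands, right hand and feet, both hands and feet.
    """

    class_index: int

    def __post_init__(self) -> None:
        if not 0 <= self.class_index <= 7:
            raise ValueError(f"class_index must be in 0..7, got {self.class_index}")

    @property
    def engaged(self) -> tuple[bool, bool, bool]:
        return tuple(bool(self.class_index >> p & 1) for p in range(3))

    @property
    def is_rest(self) -> bool:
        return self.class_index == 0

    @property
    def name(self) -> str:
        return LABEL_NAMES[self.class_index]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"TaskLabel({self.class_index}: {self.name!r})"


LABEL_NAMES: tuple[str, ...] = (
    "rest",
    "left hand",
    "feet",
    "left hand and feet",
    "right hand",
    "both hands",
    "right hand and feet",
    "both hands and feet",
)

ALL_LABELS: tuple[TaskLabel, ...] = tuple(TaskLabel(i) for i in range(8))
SINGLE_MI_LABELS: dict[BodyPart, TaskLabel] = {
    part: TaskLabel(1 << part.value) for part in BodyPart
}
REST = TaskLabel(0)


def encode_label(engaged: Sequence[bool]) -> TaskLabel:
    """Map a (left hand, feet, right hand) engagement triple to its class."""
    if len(engaged) != 3:
        raise ValueError("engagement triple must have exactly 3 entries")
    index = sum(int(bool(e)) << p for p, e in enumerate(engaged))
    return TaskLabel(index)


def engages(label: TaskLabel, part: BodyPart) -> bool:
    """True iff ``part`` is engaged in the motor task of ``label``."""
    return bool(label.class_index >> part.value & 1)


def label_by_name(name: str) -> TaskLabel:
    return TaskLabel(LABEL_NAMES.index(name))


@dataclass(frozen=True)
class Montage:
    """Electrode names with schematic 2-D head-plane coordinates.

    Coordinates are a flattened top view of the extended 10-20 layout,
    normalized to unit head radius; they are used only by the simulator's
    source-projection model.
    """

    channel_names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2)

    def __post_init__(self) -> None:
        if len(self.channel_names) != self.positions.shape[0]:
            raise ValueError("positions must have one row per channel")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        lowered = [c.lower() for c in self.channel_names]
        try:
            return lowered.index(name.lower())
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None

    def position(self, name: str) -> np.ndarray:
        return self.positions[self.index(name)]


def _standard_26() -> Montage:
    # x: left negative; y: nose positive.  Lateral spacing of 0.2 per
    # 10-10 step along the central rows, frontal/parietal midline sites at
    # their usual 10-20 radii.
    coords = {
        "Fp1": (-0.31, 0.95), "Fpz": (0.0, 1.0), "Fp2": (0.31, 0.95),
        "Fz": (0.0, 0.50),
        "FC5": (-0.59, 0.31), "FC3": (-0.40, 0.28), "FC1": (-0.20, 0.26),
        "FCz": (0.0, 0.25),
        "FC2": (0.20, 0.26), "FC4": (0.40, 0.28), "FC6": (0.59, 0.31),
        "C5": (-0.60, 0.0), "C3": (-0.40, 0.0), "C1": (-0.20, 0.0),
        "Cz": (0.0, 0.0),
        "C2": (0.20, 0.0), "C4": (0.40, 0.0), "C6": (0.60, 0.0),
        "CP5": (-0.59, -0.31), "CP3": (-0.40, -0.28), "CP1": (-0.20, -0.26),
        "CPz": (0.0, -0.25),
        "CP2": (0.20, -0.26), "CP4": (0.40, -0.28), "CP6": (0.59, -0.31),
        "Pz": (0.0, -0.50),
    }
    names = tuple(coords)
    positions = np.array([coords[n] for n in names], dtype=float)
    return Montage(channel_names=names, positions=positions)


#: The 26-electrode sensorimotor montage used throughout the package.
MONTAGE_26: Montage = _standard_26()


@dataclass(frozen=True)
class ParadigmSpec:
    """Timing and counting constants of the 8-class combined-MI session.

    Each 12-s trial shows the task cue for 6 s followed by a 6-s pause;
    a session comprises ``runs`` runs of ``trials_per_class // runs`` trials
    per class presented in randomized order.
    """

    n_classes: int = 8
    trials_per_class: int = 40
    runs: int = 4
    trial_duration: float = 12.0
    cue_window: tuple[float, float] = (0.0, 6.0)
    pause_window: tuple[float, float] = (6.0, 12.0)
    sampling_rate: float = 256.0

    def __post_init__(self) -> None:
        if self.n_classes != 8:
            raise ValueError("the combined-MI paradigm has exactly 8 classes")
        if self.trials_per_class % self.runs:
            raise ValueError("trials_per_class must divide evenly across runs")
        cue = self.cue_window[1] - self.cue_window[0]
        pause = self.pause_window[1] - self.pause_window[0]
        if abs((cue + pause) - self.trial_duration) > 1e-9:
            raise ValueError("trial duration must equal cue + pause durations")

    @property
    def n_trials(self) -> int:
        return self.n_classes * self.trials_per_class

    @property
    def trials_per_run(self) -> int:
        return self.n_trials // self.runs


@dataclass
class EpochSet:
    """Epoched multichannel EEG with per-trial class labels.

    data
        ``(n_trials, n_channels, n_samples)`` array in microvolts.
    labels
        One :class:`TaskLabel` per trial.
    t_start
        Time of the first sample in seconds relative to cue onset.
    band
        ``(low, high)`` in Hz if band-pass filtered, else ``"raw"``.
    """

    data: np.ndarray
    labels: list[TaskLabel]
    sampling_rate: float
    t_start: float = 0.0
    band: tuple[float, float] | str = "raw"
    montage: Montage | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per trial required")
        if self.montage is not None and self.montage.n_channels != self.data.shape[1]:
            raise ValueError("channel count does not match montage")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_samples) / self.sampling_rate

    @property
    def class_indices(self) -> np.ndarray:
        return np.array([lab.class_index for lab in self.labels], dtype=int)

    def subset(self, indices: Sequence[int] | np.ndarray) -> "EpochSet":
        indices = np.asarray(indices, dtype=int)
        return EpochSet(
            data=self.data[indices],
            labels=[self.labels[i] for i in indices],
            sampling_rate=self.sampling_rate,
            t_start=self.t_start,
            band=self.band,
            montage=self.montage,
        )

    def with_data(self, data: np.ndarray, **changes) -> "EpochSet":
        new = EpochSet(
            data=data,
            labels=list(self.labels),
            sampling_rate=self.sampling_rate,
            t_start=self.t_start,
            band=self.band,
            montage=self.montage,
        )
        for key, value in changes.items():
            setattr(new, key, value)
        return new
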