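"""Session container I/O: HDF5 read/write, EDF import, decoder serialization.

The native container is an HDF5 file holding either epoched data
(``/eeg`` as trials x channels x samples, float32 microvolts, plus
``/labels``) or a continuous recording (``/continuous`` plus an events
table), with channel names, sampling rate and provenance stored as
attributes.  Events tables use seconds relative to recording start with
time 0 at recording onset and half-open windows [t0, t1).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import MONTAGE_26, EpochSet, Montage, TaskLabel

__all__ = [
    "SessionContainer",
    "write_session",
    "read_session",
    "import_edf",
    "save_decoder",
    "load_decoder",
]


@dataclass
class SessionContainer:
    """In-memory image of the HDF5 session file."""

    channels: list[str]
    sampling_rate: float
    eeg: np.ndarray | None = None  # (trials, channels, samples)
    labels: np.ndarray | None = None  # class indices 0..7
    continuous: np.ndarray | None = None  # (channels, samples)
    events: pd.DataFrame | None = None
    t_start: float = 0.0
    band: tuple[float, float] | str = "raw"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.eeg is None and self.continuous is None:
            raise ValueError("container must hold epoched or continuous data")
        if self.eeg is not None:
            if self.labels is None:
                raise ValueError("epoched data requires labels")
            if len(self.labels) != self.eeg.shape[0]:
                raise ValueError("one label per trial required")
            if self.eeg.shape[1] != len(self.channels):
                raise ValueError("channel list does not match data")
        if self.labels is not None and (
            np.any(np.asarray(self.labels) < 0) or np.any(np.asarray(self.labels) > 7)
        ):
            raise ValueError("labels must be class indices in 0..7")

    def to_epochs(self, montage: Montage | None = None) -> EpochSet:
        if self.eeg is None:
            raise ValueError("container holds no epoched data")
        if montage is None and list(MONTAGE_26.channel_names) == list(self.channels):
            montage = MONTAGE_26
        return EpochSet(
            data=np.asarray(self.eeg, dtype=float),
            labels=[TaskLabel(int(c)) for c in self.labels],
            sampling_rate=self.sampling_rate,
            t_start=self.t_start,
            band=self.band,
            montage=montage,
        )

    @classmethod
    def from_epochs(cls, epochs: EpochSet, provenance: dict | None = None):
        return cls(
            channels=list(epochs.montage.channel_names) if epochs.montage else
            [f"ch{i}" for i in range(epochs.n_channels)],
            sampling_rate=epochs.sampling_rate,
            eeg=epochs.data.astype(np.float32),
            labels=epochs.class_indices,
            t_start=epochs.t_start,
            band=epochs.band,
            provenance=provenance or {},
        )


def write_session(container: SessionContainer, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["sampling_rate"] = container.sampling_rate
        fh.attrs["channels"] = [str(c) for c in container.channels]
        fh.attrs["t_start"] = container.t_start
        fh.attrs["band"] = (
            "raw" if container.band == "raw" else json.dumps(list(container.band))
        )
        fh.attrs["provenance"] = json.dumps(container.provenance)
        if container.eeg is not None:
            fh.create_dataset("eeg", data=np.asarray(container.eeg, dtype=np.float32))
            fh.create_dataset("labels", data=np.asarray(container.labels, dtype=np.int8))
        if container.continuous is not None:
            fh.create_dataset(
                "continuous", data=np.asarray(container.continuous, dtype=np.float32)
            )
        if container.events is not None:
            grp = fh.create_group("events")
            grp.create_dataset("onset_s", data=container.events["onset_s"].to_numpy())
            grp.create_dataset(
                "class_index", data=container.events["class_index"].to_numpy(dtype=np.int8)
            )


def read_session(path: str | Path) -> SessionContainer:
    with h5py.File(path, "r") as fh:
        for attr in ("sampling_rate", "channels"):
            if attr not in fh.attrs:
                raise ValueError(f"malformed session file: missing attribute {attr!r}")
        band_attr = fh.attrs.get("band", "raw")
        band = "raw" if band_attr == "raw" else tuple(json.loads(band_attr))
        eeg = labels = continuous = events = None
        if "eeg" in fh:
            if "labels" not in fh:
                raise ValueError("malformed session file: missing dataset 'labels'")
            eeg = fh["eeg"][()]
            labels = fh["labels"][()]
        if "continuous" in fh:
            continuous = fh["continuous"][()]
            if "events" in fh:
                events = pd.DataFrame(
                    {
                        "onset_s": fh["events/onset_s"][()],
                        "class_index": fh["events/class_index"][()],
                    }
                )
        if eeg is None and continuous is None:
            raise ValueError("malformed session file: missing dataset 'eeg' or 'continuous'")
        return SessionContainer(
            channels=[str(c) for c in fh.attrs["channels"]],
            sampling_rate=float(fh.attrs["sampling_rate"]),
            eeg=eeg,
            labels=labels,
            continuous=continuous,
            events=events,
            t_start=float(fh.attrs.get("t_start", 0.0)),
            band=band,
            provenance=json.loads(fh.attrs.get("provenance", "{}")),
        )


def import_edf(
    path: str | Path, events_csv: str | Path, montage: Montage = MONTAGE_26
) -> SessionContainer:
    """Import a continuous EDF/EDF+ recording plus an events CSV.

    Channels are matched against the montage case-insensitively; unmatched
    channels are dropped with a warning.  The events CSV needs columns
    ``onset_s`` and ``class_index`` (0..7).
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    wanted = {name.lower(): name for name in montage.channel_names}
    keep, dropped = [], []
    for ch in raw.ch_names:
        (keep if ch.lower() in wanted else dropped).append(ch)
    if not keep:
        raise ValueError("no montage channels found in the EDF file")
    if dropped:
        warnings.warn(f"dropping channels not in the montage: {dropped}")
    raw.pick(keep)
    # reorder to montage order (of the channels present)
    order = sorted(raw.ch_names, key=lambda ch: montage.index(ch))
    raw.reorder_channels(order)
    data = raw.get_data() * 1e6  # volts -> microvolts
    fs = float(raw.info["sfreq"])

    events = pd.read_csv(events_csv)
    for col in ("onset_s", "class_index"):
        if col not in events.columns:
            raise ValueError(f"events CSV missing column {col!r}")
    if events["class_index"].min() < 0 or events["class_index"].max() > 7:
        raise ValueError("events CSV contains class_index outside 0..7")
    if (events["onset_s"] < 0).any() or (events["onset_s"] * fs > data.shape[1]).any():
        raise ValueError("event beyond the recording extent")
    return SessionContainer(
        channels=[wanted[ch.lower()] for ch in order],
        sampling_rate=fs,
        continuous=data,
        events=events[["onset_s", "class_index"]].copy(),
        provenance={"source": str(path)},
    )


def save_decoder(decoder, path: str | Path) -> None:
    """Serialize a fitted decoder (single .npz archive with a JSON header)."""
    from .baselines import EnsembleDecoder
    from .multilabel import MultilabelDecoder

    arrays: dict[str, np.ndarray] = {}
    if isinstance(decoder, MultilabelDecoder):
        header = {"kind": "multilabel", "method": decoder.method, "m": decoder.m}
        for p, model in enumerate(decoder.models):
            arrays[f"W_{p}"] = model.W
            arrays[f"eig_{p}"] = model.eigenvalues
            arrays[f"A_{p}"] = model.A
        _pack_lda(arrays, "lda", decoder.lda)
    elif isinstance(decoder, EnsembleDecoder):
        header = {
            "kind": "ensemble",
            "scheme": decoder.scheme,
            "m": decoder.members[0].m,
            "members": [
                {
                    "positive": sorted(l.class_index for l in mem.positive_labels),
                    "negative": sorted(l.class_index for l in mem.negative_labels),
                    "n_train": mem.n_train,
                }
                for mem in decoder.members
            ],
        }
        for i, mem in enumerate(decoder.members):
            arrays[f"W_{i}"] = mem.csp.W
            arrays[f"eig_{i}"] = mem.csp.eigenvalues
            arrays[f"A_{i}"] = mem.csp.A
            _pack_lda(arrays, f"lda_{i}", mem.lda)
    else:
        raise TypeError(f"cannot serialize {type(decoder).__name__}")
    arrays["header"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_decoder(path: str | Path):
    from .baselines import BinaryCSPClassifier, EnsembleDecoder
    from .core import ALL_LABELS
    from .csp import CSPModel
    from .multilabel import MultilabelDecoder, mc2cmi_problems, mc2smi_problems

    with np.load(path) as archive:
        header = json.loads(bytes(archive["header"]).decode())
        if header["kind"] == "multilabel":
            m = header["m"]
            models = tuple(
                CSPModel(W=archive[f"W_{p}"], eigenvalues=archive[f"eig_{p}"],
                         m=m, A=archive[f"A_{p}"])
                for p in range(3)
            )
            problems = (
                mc2cmi_problems() if header["method"] == "mc2cmi" else mc2smi_problems()
            )
            return MultilabelDecoder(
                method=header["method"], problems=problems, models=models, m=m,
                lda=_unpack_lda(archive, "lda"),
            )
        members = []
        for i, info in enumerate(header["members"]):
            members.append(
                BinaryCSPClassifier(
                    positive_labels=frozenset(ALL_LABELS[c] for c in info["positive"]),
                    negative_labels=frozenset(ALL_LABELS[c] for c in info["negative"]),
                    csp=CSPModel(W=archive[f"W_{i}"], eigenvalues=archive[f"eig_{i}"],
                                 m=header["m"], A=archive[f"A_{i}"]),
                    m=header["m"],
                    lda=_unpack_lda(archive, f"lda_{i}"),
                    n_train=info["n_train"],
                )
            )
        return EnsembleDecoder(scheme=header["scheme"], members=members)


def _pack_lda(arrays: dict, prefix: str, lda) -> None:
    arrays[f"{prefix}_classes"] = lda.class_labels
    arrays[f"{prefix}_means"] = lda.means
    arrays[f"{prefix}_cov"] = lda.pooled_covariance
    arrays[f"{prefix}_priors"] = lda.priors
    arrays[f"{prefix}_ridge"] = np.array(lda.ridge)


def _unpack_lda(archive, prefix: str):
    from .lda import LDAModel

    return LDAModel(
        class_labels=archive[f"{prefix}_classes"],
        means=archive[f"{prefix}_means"],
        pooled_covariance=archive[f"{prefix}_cov"],
        priors=archive[f"{prefix}_priors"],
        ridge=float(archive[f"{prefix}_ridge"]),
    )
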