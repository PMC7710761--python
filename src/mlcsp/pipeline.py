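"""Convenience pipelines chaining simulation, preprocessing and epoching."""

from __future__ import annotations

from .core import EpochSet
from .preprocessing import bandpass, common_average_reference, epoch_continuous
from .simulate import SimulationConfig, simulate_continuous


def preprocessed_session(
    config: SimulationConfig,
    band: tuple[float, float] = (8.0, 30.0),
    order: int = 5,
    car: bool = True,
    window: tuple[float, float] = (0.5, 3.5),
) -> EpochSet:
    """Simulate a session and return band-passed, re-referenced analysis epochs.

    Filtering happens on the continuous recording (no per-epoch edge
    transients); epochs are then cut directly at the analysis window.
    """
    data, events = simulate_continuous(config)
    data = bandpass(data, config.paradigm.sampling_rate, *band, order=order)
    if car:
        data = common_average_reference(data, channel_axis=0)
    return epoch_continuous(
        data,
        events,
        t0=window[0],
        t1=window[1],
        sampling_rate=config.paradigm.sampling_rate,
        montage=config.montage,
        band=band,
    )


def erd_epochs(
    config: SimulationConfig,
    band: tuple[float, float] = (8.0, 30.0),
    order: int = 5,
    window: tuple[float, float] = (-2.0, 6.0),
) -> EpochSet:
    """Band-passed epochs extending over a pre-cue baseline, for ERD/ERS% curves.

    No common average reference: ERD is a per-channel band-power measure and
    the curves are easiest to read against the physical channel signals.
    """
    data, events = simulate_continuous(config)
    data = bandpass(data, config.paradigm.sampling_rate, *band, order=order)
    return epoch_continuous(
        data,
        events,
        t0=window[0],
        t1=window[1],
        sampling_rate=config.paradigm.sampling_rate,
        montage=config.montage,
        band=band,
    )
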