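"""Minimal EDF writer used only to build synthetic test fixtures.

Writes a plain EDF file (256-byte header, per-signal headers, int16 data
records) good enough for reader round trips; not a general-purpose exporter.
"""

import numpy as np

PHYS_MAX = 1000.0  # microvolts
DIG_MAX = 32767


def _field(value, width):
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, data, sampling_rate, channel_names):
    """data: (n_channels, n_samples) in microvolts; whole seconds only."""
    data = np.asarray(data, dtype=float)
    n_ch, n_samples = data.shape
    fs = int(sampling_rate)
    assert n_samples % fs == 0, "synthetic fixture uses whole-second recordings"
    n_records = n_samples // fs
    assert np.abs(data).max() < PHYS_MAX

    header = b"".join(
        [
            _field(0, 8),  # version
            _field("synthetic fixture", 80),
            _field("synthetic recording", 80),
            _field("01.01.20", 8),
            _field("00.00.00", 8),
            _field(256 * (n_ch + 1), 8),
            _field("", 44),
            _field(n_records, 8),
            _field(1, 8),  # record duration, seconds
            _field(n_ch, 4),
        ]
    )
    fields = [
        (16, lambda i: channel_names[i]),
        (80, lambda i: ""),  # transducer
        (8, lambda i: "uV"),
        (8, lambda i: -PHYS_MAX),
        (8, lambda i: PHYS_MAX),
        (8, lambda i: -DIG_MAX - 1),
        (8, lambda i: DIG_MAX),
        (80, lambda i: ""),  # prefiltering
        (8, lambda i: fs),  # samples per record
        (32, lambda i: ""),
    ]
    sig_header = b"".join(
        b"".join(_field(make(i), width) for i in range(n_ch)) for width, make in fields
    )
    scale = DIG_MAX / PHYS_MAX
    digital = np.round(data * scale).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for rec in range(n_records):
            block = digital[:, rec * fs : (rec + 1) * fs]
            fh.write(block.tobytes())
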