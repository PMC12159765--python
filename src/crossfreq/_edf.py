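"""Minimal EDF (European Data Format) writer.

Standard 16-bit EDF: one ASCII header of 256 bytes plus 256 bytes per
signal, then data records of little-endian int16 samples. Each channel is
scaled independently to its physical min/max. Only what the package needs
to round-trip its own recordings is implemented; reading goes through
``mne.io.read_raw_edf``, which serves as an independent check that the
files written here are valid EDF.

Constraint: the record duration is 1 s, so the sampling rate must be a
positive integer and the recording is truncated to whole seconds.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

_DIGITAL_MIN, _DIGITAL_MAX = -32768, 32767


def _field(text: str, width: int) -> bytes:
    s = str(text)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    data_uv: np.ndarray,
    fs: float,
    channel_labels: list[str],
) -> None:
    """Write channels × samples data (µV) as a standard EDF file."""
    data = np.atleast_2d(np.asarray(data_uv, dtype=float))
    n_ch, n_samp = data.shape
    if len(channel_labels) != n_ch:
        raise ValueError("one label per channel required")
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    n_rec = n_samp // spr
    if n_rec == 0:
        raise ValueError("recording shorter than one 1-s EDF record")
    data = data[:, : n_rec * spr]

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min < 1e-12
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    gain = (_DIGITAL_MAX - _DIGITAL_MIN) / (phys_max - phys_min)
    digital = np.rint(
        (data - phys_min[:, None]) * gain[:, None] + _DIGITAL_MIN
    ).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),  # patient id
            _field("Startdate X X X X", 80),  # recording id
            _field(now.strftime("%d.%m.%y"), 8),
            _field(now.strftime("%H.%M.%S"), 8),
            _field(str(256 * (1 + n_ch)), 8),
            _field("", 44),
            _field(str(n_rec), 8),
            _field("1", 8),  # record duration seconds
            _field(str(n_ch), 4),
        ]
    )
    per_signal = b"".join(
        [
            b"".join(_field(lbl, 16) for lbl in channel_labels),
            b"".join(_field("EEG", 80) for _ in range(n_ch)),
            b"".join(_field("uV", 8) for _ in range(n_ch)),
            b"".join(_field(f"{v:.6g}", 8) for v in phys_min),
            b"".join(_field(f"{v:.6g}", 8) for v in phys_max),
            b"".join(_field(str(_DIGITAL_MIN), 8) for _ in range(n_ch)),
            b"".join(_field(str(_DIGITAL_MAX), 8) for _ in range(n_ch)),
            b"".join(_field("", 80) for _ in range(n_ch)),
            b"".join(_field(str(spr), 8) for _ in range(n_ch)),
            b"".join(_field("", 32) for _ in range(n_ch)),
        ]
    )
    records = digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        fh.write(records.tobytes())
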