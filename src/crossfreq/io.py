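"""EEG containers and the preprocessing chain.

A :class:`Recording` is a continuous channels × samples block in µV with
its sampling rate and an append-only history of applied operations. The
standard chain is band-pass 0.5–150 Hz + 50 Hz notch, resampling to
500 Hz, segmentation into 2-s epochs, and automated peak-to-peak epoch
rejection.

Manual artifact screening (visual inspection, ICA component removal) is
out of scope: rejection here is a deterministic amplitude criterion —
an epoch is kept only when every channel's peak-to-peak amplitude lies
within [flatline_threshold, abs_threshold].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps

from ._edf import write_edf

__all__ = [
    "Recording",
    "EpochedData",
    "read_recording",
    "write_recording",
    "bandpass_notch",
    "resample_epoch",
    "reject_epochs",
]


@dataclass(frozen=True)
class Recording:
    """Continuous multichannel EEG in µV."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    channel_labels: tuple[str, ...]
    history: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        d = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != d.shape[0]:
            raise ValueError("one label per channel required")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        object.__setattr__(self, "history", tuple(self.history))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    def with_data(self, data: np.ndarray, step: str, fs: float | None = None) -> "Recording":
        return replace(
            self,
            data=data,
            fs=self.fs if fs is None else fs,
            history=self.history + (step,),
        )


@dataclass(frozen=True)
class EpochedData:
    """Fixed-length epochs × channels × samples block."""

    data: np.ndarray
    fs: float
    epoch_len_s: float
    kept_mask: np.ndarray  # over the original epoch count
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3:
            raise ValueError("epoched data must be 3-D (epochs, channels, samples)")
        expected = int(round(self.fs * self.epoch_len_s))
        if d.shape[2] != expected:
            raise ValueError(
                f"epoch length {d.shape[2]} samples != fs·epoch_len = {expected}"
            )
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "kept_mask", np.asarray(self.kept_mask, dtype=bool))

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


def read_recording(path: str | Path, fmt: str | None = None) -> Recording:
    """Load a Recording from EDF or from the package's delimited format.

    The delimited layout is: a ``# fs: <Hz>`` comment line, a tab-separated
    header row of channel labels, then one row of samples per channel in
    header order. Format is inferred from the suffix when ``fmt`` is None.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"cannot read recording: {path} is missing or empty")
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if fmt == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # mne loads EEG in volts
        return Recording(
            data=data,
            fs=float(raw.info["sfreq"]),
            channel_labels=tuple(raw.ch_names),
            history=(f"read_edf:{path.name}",),
        )
    if fmt == "delimited":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("# fs:"):
                raise ValueError(f"{path}: missing '# fs:' header line")
            fs = float(first.split(":", 1)[1])
            labels = fh.readline().rstrip("\n").split("\t")
            rows = []
            for ln, line in enumerate(fh, start=3):
                vals = line.split()
                if not vals:
                    continue
                rows.append(np.array(vals, dtype=float))
        if not rows:
            raise ValueError(f"{path}: no sample rows")
        lengths = {r.size for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"{path}: inconsistent row lengths {sorted(lengths)}")
        if len(rows) != len(labels):
            raise ValueError(f"{path}: {len(labels)} labels but {len(rows)} channel rows")
        return Recording(
            data=np.vstack(rows),
            fs=fs,
            channel_labels=tuple(labels),
            history=(f"read_delimited:{path.name}",),
        )
    raise ValueError(f"unknown format {fmt!r}; use 'edf' or 'delimited'")


def write_recording(rec: Recording, path: str | Path, fmt: str | None = None) -> None:
    """Write a Recording as EDF (16-bit) or the delimited text layout."""
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if fmt == "edf":
        write_edf(path, rec.data, rec.fs, list(rec.channel_labels))
    elif fmt == "delimited":
        with open(path, "w") as fh:
            fh.write(f"# fs: {rec.fs:.10g}\n")
            fh.write("\t".join(rec.channel_labels) + "\n")
            np.savetxt(fh, rec.data, fmt="%.8g", delimiter="\t")
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'edf' or 'delimited'")


def bandpass_notch(
    rec: Recording,
    low: float = 0.5,
    high: float = 150.0,
    notch: float = 50.0,
    notch_q: float = 30.0,
) -> Recording:
    """Zero-phase FIR band-pass plus IIR notch.

    Band-pass: windowed-sinc FIR applied forward–backward (phase
    estimates downstream stay undistorted). Notch: second-order IIR,
    also forward–backward.
    """
    if high >= rec.fs / 2:
        raise ValueError(f"band edge {high} Hz ≥ Nyquist {rec.fs / 2} Hz")
    ntaps = min(3 * int(round(rec.fs / low)) | 1, rec.data.shape[1] // 3 | 1)
    if ntaps < 11:
        raise ValueError("recording too short for the band-pass filter")
    b = sps.firwin(ntaps, [low, high], pass_zero=False, fs=rec.fs)
    from .pac import _zero_phase

    out = np.stack([_zero_phase(b, ch) for ch in rec.data])
    if notch is not None and notch < rec.fs / 2:
        bn, an = sps.iirnotch(notch, notch_q, fs=rec.fs)
        out = sps.filtfilt(bn, an, out, axis=1)
    return rec.with_data(out, f"bandpass_notch:{low}-{high}Hz,notch={notch}Hz")


def resample_epoch(
    rec: Recording, fs_target: float = 500.0, epoch_len_s: float = 2.0
) -> EpochedData:
    """Polyphase resampling followed by segmentation into whole epochs.

    Upsampling is refused; a trailing partial epoch is discarded. A
    recording shorter than one epoch yields zero epochs (with a warning)
    rather than an error.
    """
    if fs_target > rec.fs:
        raise ValueError(
            f"upsampling refused: target {fs_target} Hz > recording {rec.fs} Hz"
        )
    if fs_target == rec.fs:
        data = rec.data
    else:
        frac = Fraction(fs_target / rec.fs).limit_denominator(1000)
        data = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    spe = int(round(fs_target * epoch_len_s))
    n_ep = data.shape[1] // spe
    if n_ep == 0:
        import warnings

        warnings.warn(
            f"recording shorter than one {epoch_len_s}-s epoch; zero epochs",
            stacklevel=2,
        )
    epochs = (
        data[:, : n_ep * spe].reshape(rec.n_channels, n_ep, spe).transpose(1, 0, 2)
    )
    return EpochedData(
        data=epochs,
        fs=fs_target,
        epoch_len_s=epoch_len_s,
        kept_mask=np.ones(n_ep, dtype=bool),
        channel_labels=rec.channel_labels,
    )


def reject_epochs(
    ep: EpochedData,
    abs_threshold_uv: float = 100.0,
    flatline_threshold_uv: float = 1e-3,
) -> EpochedData:
    """Keep epochs where every channel's peak-to-peak is in range.

    ``abs_threshold_uv`` bounds transient artifacts (spikes, movement);
    ``flatline_threshold_uv`` catches dead channels. Raises if nothing
    survives, with advice to revisit the thresholds.
    """
    if abs_threshold_uv <= 0 or flatline_threshold_uv <= 0:
        raise ValueError("thresholds must be positive")
    ptp = ep.data.max(axis=2) - ep.data.min(axis=2)  # (epochs, channels)
    keep = np.all((ptp <= abs_threshold_uv) & (ptp >= flatline_threshold_uv), axis=1)
    if not keep.any():
        raise ValueError(
            "all epochs rejected — raise abs_threshold_uv or check the data scale"
        )
    return EpochedData(
        data=ep.data[keep],
        fs=ep.fs,
        epoch_len_s=ep.epoch_len_s,
        kept_mask=keep,
        channel_labels=ep.channel_labels,
    )
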