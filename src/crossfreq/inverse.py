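"""Minimum-norm source inverse and ROI time-series extraction.

Sensor epochs X (sensors × samples) are projected to source space by the
L2 minimum-norm estimate

    Ŝ = Lᵀ (L Lᵀ + λ I)⁻¹ X,

with the regularisation default set by the standard SNR rule
λ = trace(L Lᵀ) / (n_sensors · SNR²), SNR = 3. Sources are scalar
(fixed orientation). ROI series are the signed mean over each ROI's
sources; signed averaging can cancel opposed sources — accepted and
documented, alternatives are pluggable by aggregating yourself.

The ROI registry ships the 26 bilateral AAL labels the analysis targets
(auditory, temporal, orbitofrontal, cingulate, hippocampal, insular).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import EpochedData
from .synthetic import Leadfield

__all__ = [
    "ROISeries",
    "RoiRegistry",
    "default_registry",
    "default_lambda",
    "mne_inverse",
    "detrend_noise",
    "aggregate_rois",
]


@dataclass(frozen=True)
class RoiRegistry:
    """Ordered ROI label set with hemispheres."""

    labels: tuple[str, ...]
    hemispheres: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("ROI labels must be unique")
        if len(self.hemispheres) != len(self.labels):
            raise ValueError("one hemisphere per label required")
        bad = set(self.hemispheres) - {"L", "R"}
        if bad:
            raise ValueError(f"hemisphere must be L or R, got {bad}")

    def __len__(self) -> int:
        return len(self.labels)


def default_registry() -> RoiRegistry:
    """The packaged 26-ROI AAL registry (13 bilateral pairs)."""
    ref = importlib.resources.files("crossfreq") / "data" / "aal_rois.tsv"
    df = pd.read_csv(str(ref), sep="\t")
    return RoiRegistry(tuple(df["label"]), tuple(df["hemisphere"]))


@dataclass(frozen=True)
class ROISeries:
    """ROI time courses: epochs × rois × samples."""

    data: np.ndarray
    fs: float
    roi_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3:
            raise ValueError("ROI series must be 3-D (epochs, rois, samples)")
        if d.shape[1] != len(self.roi_labels):
            raise ValueError("one label per ROI required")
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError("ROI labels must be unique")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))


def default_lambda(leadfield: Leadfield, snr: float = 3.0) -> float:
    """λ = trace(L Lᵀ) / (n_sensors · SNR²)."""
    g = leadfield.gain
    return float(np.trace(g @ g.T) / (g.shape[0] * snr**2))


def mne_inverse(
    ep: EpochedData | np.ndarray,
    leadfield: Leadfield,
    lam: float | None = None,
) -> np.ndarray:
    """Minimum-norm projection of sensor epochs to source epochs.

    Returns an (epochs, sources, samples) array. ``lam=None`` applies the
    SNR-based default; ``lam=0`` is exact only for a full-row-rank
    leadfield and raises otherwise with advice to regularise.
    """
    data = ep.data if isinstance(ep, EpochedData) else np.asarray(ep, dtype=float)
    squeeze = False
    if data.ndim == 2:
        data = data[None]
        squeeze = True
    if data.shape[1] != leadfield.n_sensors:
        raise ValueError(
            f"epochs have {data.shape[1]} channels but leadfield has "
            f"{leadfield.n_sensors} sensors"
        )
    if lam is None:
        lam = default_lambda(leadfield)
    if lam < 0:
        raise ValueError("regularisation λ must be ≥ 0")
    g = leadfield.gain
    gram = g @ g.T + lam * np.eye(g.shape[0])
    if lam == 0 and np.linalg.matrix_rank(gram) < gram.shape[0]:
        raise np.linalg.LinAlgError(
            "L Lᵀ is singular at λ=0 (rank-deficient leadfield); use λ > 0"
        )
    kernel = g.T @ np.linalg.solve(gram, np.eye(g.shape[0]))
    src = np.einsum("ms,est->emt", kernel, data)
    return src[0] if squeeze else src


def detrend_noise(ep: EpochedData) -> EpochedData:
    """Remove per-epoch, per-channel mean and linear trend (idempotent)."""
    if ep.data.shape[2] < 2:
        raise ValueError("need at least 2 samples per epoch to detrend")
    out = sps.detrend(ep.data, axis=2, type="linear")
    return EpochedData(
        data=out,
        fs=ep.fs,
        epoch_len_s=ep.epoch_len_s,
        kept_mask=ep.kept_mask,
        channel_labels=ep.channel_labels,
    )


def aggregate_rois(
    src_epochs: np.ndarray,
    roi_map: Sequence[str],
    registry: RoiRegistry | Sequence[str],
    fs: float,
) -> ROISeries:
    """Signed mean over each ROI's sources, ordered by the registry."""
    labels = registry.labels if isinstance(registry, RoiRegistry) else tuple(registry)
    src_epochs = np.asarray(src_epochs, dtype=float)
    if src_epochs.ndim == 2:
        src_epochs = src_epochs[None]
    roi_map = np.asarray(roi_map)
    if roi_map.size != src_epochs.shape[1]:
        raise ValueError("roi_map length must equal source count")
    out = np.empty((src_epochs.shape[0], len(labels), src_epochs.shape[2]))
    for r, roi in enumerate(labels):
        idx = np.flatnonzero(roi_map == roi)
        if idx.size == 0:
            raise ValueError(f"ROI {roi!r} owns no sources in roi_map")
        out[:, r, :] = src_epochs[:, idx, :].mean(axis=1)
    return ROISeries(data=out, fs=fs, roi_labels=labels)
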