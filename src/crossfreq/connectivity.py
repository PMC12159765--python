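"""Frequency-domain functional connectivity between ROI time series.

Per 2-s epoch, each ROI series is Hann-windowed and Fourier transformed;
cross-spectra S_xy(f) are retained per epoch so that the four estimators
can take their expectations over epochs:

    coherence  Coh = |⟨S_xy⟩|² / (⟨S_xx⟩ ⟨S_yy⟩)
    PLV            = |⟨ e^{i arg S_xy} ⟩|
    PLI            = |⟨ sign Im S_xy ⟩|
    wPLI           = |⟨ Im S_xy ⟩| / ⟨ |Im S_xy| ⟩   (0 when the
                     denominator vanishes, e.g. exactly zero-lag signals)

Band values are unweighted means over the in-band FFT bins. PLI and wPLI
discount zero-lag coupling and are therefore less sensitive to the
instantaneous mixing a linear inverse leaves behind.

Group contrasts run a two-sided Welch t-test per edge — on Fisher
z-transformed values for coherence/PLV, raw values for PLI/wPLI — with
Benjamini–Hochberg FDR across edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

from .inverse import ROISeries

__all__ = [
    "CrossSpectra",
    "ConnectivityMatrix",
    "cross_spectra",
    "connectivity_matrix",
    "coherence",
    "plv",
    "pli",
    "wpli",
    "group_contrast_fdr",
]

METRICS = ("coherence", "plv", "pli", "wpli")


@dataclass(frozen=True)
class CrossSpectra:
    """Per-epoch Fourier coefficients; cross-products taken lazily."""

    coeffs: np.ndarray  # complex (epochs, rois, freqs)
    freqs: np.ndarray
    roi_labels: tuple[str, ...]

    @property
    def epoch_count(self) -> int:
        return self.coeffs.shape[0]


@dataclass(frozen=True)
class ConnectivityMatrix:
    metric: str
    band: tuple[float, float]
    values: np.ndarray  # (rois, rois)
    roi_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("connectivity values must lie in [0, 1]")


def cross_spectra(roi_series: ROISeries, band: tuple[float, float] | None = None) -> CrossSpectra:
    """Hann-windowed per-epoch FFT of every ROI, optionally band-limited."""
    data = roi_series.data
    if data.shape[0] < 2:
        raise ValueError("need ≥2 epochs for epoch-wise estimators")
    n = data.shape[2]
    freqs = np.fft.rfftfreq(n, 1 / roi_series.fs)
    if band is not None:
        if band[1] > roi_series.fs / 2:
            raise ValueError(f"band {band} exceeds Nyquist {roi_series.fs / 2} Hz")
        keep = (freqs >= band[0]) & (freqs <= band[1])
    else:
        keep = np.ones_like(freqs, dtype=bool)
    win = np.hanning(n)
    coeffs = np.fft.rfft(data * win, axis=2)[:, :, keep]
    return CrossSpectra(
        coeffs=coeffs, freqs=freqs[keep], roi_labels=roi_series.roi_labels
    )


def _pairwise_cross(cs: CrossSpectra) -> np.ndarray:
    """S_xy per epoch: complex (epochs, rois, rois, freqs)."""
    c = cs.coeffs
    return np.einsum("erf,esf->ersf", c, np.conj(c))


def _band_mean(values_f: np.ndarray) -> np.ndarray:
    return values_f.mean(axis=-1)


def _finish(metric: str, band: tuple[float, float], vals: np.ndarray, labels) -> ConnectivityMatrix:
    vals = np.clip((vals + vals.T) / 2, 0.0, 1.0)
    np.fill_diagonal(vals, 1.0 if metric in ("coherence", "plv") else 0.0)
    return ConnectivityMatrix(metric=metric, band=band, values=vals, roi_labels=tuple(labels))


def coherence(cs: CrossSpectra, band: tuple[float, float] | None = None) -> ConnectivityMatrix:
    sxy = _pairwise_cross(cs).mean(axis=0)
    auto = np.real(np.einsum("erf,erf->rf", cs.coeffs, np.conj(cs.coeffs))) / cs.epoch_count
    denom = auto[:, None, :] * auto[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(sxy) ** 2 / denom
    coh = np.nan_to_num(coh)
    return _finish("coherence", band or (cs.freqs[0], cs.freqs[-1]), _band_mean(coh), cs.roi_labels)


def plv(cs: CrossSpectra, band: tuple[float, float] | None = None) -> ConnectivityMatrix:
    sxy = _pairwise_cross(cs)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(np.abs(sxy) > 0, sxy / np.abs(sxy), 0)
    vals = np.abs(unit.mean(axis=0))
    return _finish("plv", band or (cs.freqs[0], cs.freqs[-1]), _band_mean(vals), cs.roi_labels)


def pli(cs: CrossSpectra, band: tuple[float, float] | None = None) -> ConnectivityMatrix:
    sxy = _pairwise_cross(cs)
    vals = np.abs(np.sign(np.imag(sxy)).mean(axis=0))
    return _finish("pli", band or (cs.freqs[0], cs.freqs[-1]), _band_mean(vals), cs.roi_labels)


def wpli(cs: CrossSpectra, band: tuple[float, float] | None = None) -> ConnectivityMatrix:
    im = np.imag(_pairwise_cross(cs))
    num = np.abs(im.mean(axis=0))
    den = np.abs(im).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(den > 0, num / den, 0.0)
    return _finish("wpli", band or (cs.freqs[0], cs.freqs[-1]), _band_mean(vals), cs.roi_labels)


_METRIC_FUNCS = {"coherence": coherence, "plv": plv, "pli": pli, "wpli": wpli}


def connectivity_matrix(
    roi_series: ROISeries, metric: str, band: tuple[float, float]
) -> ConnectivityMatrix:
    """Band-limited connectivity for one metric (epoch-wise estimator)."""
    if metric not in _METRIC_FUNCS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    cs = cross_spectra(roi_series, band)
    return _METRIC_FUNCS[metric](cs, band)


def _fisher_z(v: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(v, 0.0, 1.0 - 1e-10))


def group_contrast_fdr(
    matrices_by_group: Mapping[str, Sequence[ConnectivityMatrix] | np.ndarray],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Edge-wise Welch t contrast between two groups with BH-FDR.

    ``matrices_by_group`` maps the two group labels to either a list of
    ConnectivityMatrix (one per subject) or a (subjects, rois, rois)
    stack. Coherence/PLV values are Fisher z-transformed before testing;
    degenerate (zero-variance) edges get p = 1 and a flag.
    """
    if len(matrices_by_group) != 2:
        raise ValueError("exactly two groups required")
    (g1, m1), (g2, m2) = matrices_by_group.items()

    def to_stack(ms):
        if isinstance(ms, np.ndarray):
            return ms, None, None
        metric = ms[0].metric
        labels = ms[0].roi_labels
        return np.stack([m.values for m in ms]), metric, labels

    a, metric, labels = to_stack(m1)
    b, metric2, _ = to_stack(m2)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need ≥2 subjects per group")
    metric = metric or metric2
    if metric in ("coherence", "plv"):
        a, b = _fisher_z(a), _fisher_z(b)
    r = a.shape[1]
    iu = np.triu_indices(r, k=1)
    rows = []
    for i, j in zip(*iu):
        x, y = a[:, i, j], b[:, i, j]
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            p, t, flag = 1.0, 0.0, True
        else:
            t, p = spstats.ttest_ind(x, y, equal_var=False)
            flag = False
        rows.append(
            {
                "roi_i": labels[i] if labels else i,
                "roi_j": labels[j] if labels else j,
                "diff": float(np.mean(a[:, i, j]) - np.mean(b[:, i, j])),
                "t": float(t),
                "p": float(p),
                "degenerate": flag,
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["significant"] = df["q"] < alpha
    df.attrs["groups"] = (g1, g2)
    return df
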