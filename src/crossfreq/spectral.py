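"""Spectral power, power–power coupling and amplitude–amplitude coupling.

PSD is the mean over non-overlapping 2-s Hann-windowed epochs (0.5 Hz
resolution at the default epoch length). Band power integrates the PSD
over theta (4–8 Hz), beta (13–30 Hz) and gamma (30–70 Hz), optionally
normalised by broadband (0.5–150 Hz) power. Power–power coupling is a
Spearman rank correlation between two band-power series; AAC correlates
per-epoch spectral power between every frequency pair on a 2–70 Hz grid.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

__all__ = [
    "BandScheme",
    "Spectrum",
    "AACMatrix",
    "psd",
    "band_power",
    "power_power_coupling",
    "aac",
]


@dataclass(frozen=True)
class BandScheme:
    theta: tuple[float, float] = (4.0, 8.0)
    beta: tuple[float, float] = (13.0, 30.0)
    gamma: tuple[float, float] = (30.0, 70.0)
    broadband: tuple[float, float] = (0.5, 150.0)

    def items(self):
        return {
            "theta": self.theta,
            "beta": self.beta,
            "gamma": self.gamma,
        }.items()


@dataclass(frozen=True)
class Spectrum:
    freqs: np.ndarray
    power: np.ndarray  # (..., n_freqs), PSD in units²/Hz
    window: str
    epoch_count: int

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(np.asarray(self.power) < -1e-15):
            raise ValueError("power must be non-negative")


@dataclass(frozen=True)
class AACMatrix:
    freqs: np.ndarray
    values: np.ndarray  # (n_freqs, n_freqs) correlations

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("AAC matrix must be symmetric")


def psd(epochs: np.ndarray, fs: float, window: str = "hann") -> Spectrum:
    """Epoch-averaged Hann periodogram (Welch with non-overlapping segments)."""
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    if not np.all(np.isfinite(epochs)):
        raise ValueError("non-finite samples in input")
    n = epochs.shape[-1]
    freqs, p = sps.welch(
        epochs, fs=fs, window=window, nperseg=n, noverlap=0, axis=-1,
        detrend=False,
    )
    return Spectrum(
        freqs=freqs,
        power=p.mean(axis=0) if epochs.ndim == 2 else p,
        window=window,
        epoch_count=epochs.shape[0],
    )


def band_power(
    spec: Spectrum,
    scheme: BandScheme = BandScheme(),
    normalize: bool = True,
) -> dict[str, float]:
    """Integrated PSD per band; normalised values divide by broadband power."""
    freqs = np.asarray(spec.freqs)
    power = np.asarray(spec.power)

    def integrate(lo: float, hi: float) -> float:
        m = (freqs >= lo) & (freqs <= hi)
        if not m.any():
            raise ValueError(f"no PSD grid points inside [{lo}, {hi}] Hz")
        return float(np.trapezoid(power[..., m], freqs[m], axis=-1))

    out = {name: integrate(*band) for name, band in scheme.items()}
    if normalize:
        total = integrate(*scheme.broadband)
        if total <= 0:
            raise ValueError("broadband power is zero; cannot normalise")
        out = {k: v / total for k, v in out.items()}
    return out


def _exact_spearman_p(a_rank: np.ndarray, b_rank: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for Spearman ρ (small n)."""
    n = a_rank.size
    perms = np.array(list(itertools.permutations(range(n))))
    b_centered = b_rank - b_rank.mean()
    a_centered = a_rank - a_rank.mean()
    denom = np.sqrt((a_centered**2).sum() * (b_centered**2).sum())
    rhos = (a_centered[perms] @ b_centered) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def power_power_coupling(
    band_a: np.ndarray, band_b: np.ndarray
) -> tuple[float, float]:
    """Spearman ρ and two-sided p between two band-power series.

    Exact permutation p for n ≤ 9, t-approximation above.
    """
    a = np.asarray(band_a, dtype=float)
    b = np.asarray(band_b, dtype=float)
    if a.size != b.size or a.size < 4:
        raise ValueError("need ≥4 paired observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    rho, p_t = spstats.spearmanr(a, b)
    if a.size <= 9:
        ar = spstats.rankdata(a)
        br = spstats.rankdata(b)
        return float(rho), _exact_spearman_p(ar, br, float(rho))
    return float(rho), float(p_t)


def aac(
    epochs: np.ndarray,
    fs: float,
    fmin: float = 2.0,
    fmax: float = 70.0,
    step: float = 0.5,
    method: str = "pearson",
) -> AACMatrix:
    """Across-epoch correlation of spectral power between frequency pairs.

    Each epoch is Hann-windowed and Fourier transformed; the squared
    moduli at each grid frequency are correlated across epochs (Pearson
    by default, Spearman optional).
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 2:
        raise ValueError("expects 2-D (epochs, samples)")
    n_ep, n = epochs.shape
    if n_ep < 8:
        raise ValueError("need ≥8 epochs for across-epoch correlation")
    df = fs / n
    if step + 1e-12 < df or abs(step / df - round(step / df)) > 1e-9:
        raise ValueError(
            f"step {step} Hz unreachable at epoch resolution {df:.4g} Hz"
        )
    win = np.hanning(n)
    coeffs = np.fft.rfft(epochs * win, axis=1)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    grid = np.arange(fmin, fmax + step / 2, step)
    idx = np.array([int(round(f / df)) for f in grid])
    power = np.abs(coeffs[:, idx]) ** 2  # (epochs, freqs)
    if method == "spearman":
        power = spstats.rankdata(power, axis=0)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    vals = np.corrcoef(power.T)
    np.fill_diagonal(vals, 1.0)
    vals = (vals + vals.T) / 2
    return AACMatrix(freqs=grid, values=vals)
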