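"""Phase–amplitude coupling via the Kullback–Leibler modulation index.

The estimator follows the Tort lineage: narrow FIR band-pass filters
extract candidate phase (low) and amplitude (high) frequencies; the
Hilbert transform yields instantaneous phase and amplitude; amplitudes
are sorted into 18 phase bins of 20° and the binned mean-amplitude
distribution P is compared against uniform,

    MI = KL(P ‖ U) / log n_bins = (log n_bins − H(P)) / log n_bins,

so MI ∈ [0, 1] with MI = 0 for phase-independent amplitude and MI = 1
when all amplitude mass sits in one bin.

Filter-bank geometry. Phase bands have 2 Hz bandwidth on lower edges
1, 3, 5, 7 Hz (centers 2–8 Hz) with a sharp ~1 Hz transition, so that a
band's phase is not inherited from a strong neighbouring oscillation.
Amplitude extraction is centred on the 8–148 Hz grid (2 Hz steps) but
the window half-width adapts to the phase frequency under test,
1.5 × f_phase with transition ≈ f_phase: amplitude modulation at f_phase
puts its side-bands at ±f_phase around the carrier, and a window
narrower than that is blind to the very coupling being measured. A
(phase, amplitude) cell is admissible when the amplitude window stays
strictly above the phase band.

A comodulogram evaluates MI on the (phase frequency × amplitude
frequency) grid; band-level PAC (theta–beta, theta–gamma) averages MI
over admissible grid cells inside a priori frequency boxes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps
from scipy.fft import next_fast_len

__all__ = [
    "PhaseBinning",
    "Comodulogram",
    "fir_band",
    "hilbert_phase_amp",
    "kl_mi",
    "surrogate_mi",
    "surrogate_max_mi",
    "comodulogram",
    "band_pac",
    "band_pac_direct",
    "pac_pipeline",
    "PHASE_BANK_EDGES",
    "AMP_BANK_EDGES",
]

# Filter banks: lower band edges; each band spans [edge, edge + bandwidth].
# Phase bank 1–7 Hz in 2 Hz steps, amplitude bank 7–150 Hz in 2 Hz steps
# (centers 2,4,6,8 and 8,10,...,148).
PHASE_BANK_EDGES: tuple[float, ...] = tuple(float(e) for e in range(1, 8, 2))
AMP_BANK_EDGES: tuple[float, ...] = tuple(float(e) for e in range(7, 148, 2))
DEFAULT_BANDWIDTH = 2.0

#: amplitude window half-width as a multiple of the phase frequency
AMP_HALFWIDTH_FACTOR = 1.5
#: transition width of the phase-band filters (Hz)
PHASE_TRANSITION_HZ = 1.0

#: seconds trimmed from each epoch edge before pooling phase/amplitude
#: samples, to discard filter and Hilbert edge transients
EDGE_TRIM_S = 0.25


@dataclass(frozen=True)
class PhaseBinning:
    """Partition of the circle (−180°, 180°] into equal phase bins."""

    n_bins: int = 18

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("need at least 2 phase bins")

    @property
    def bin_width_deg(self) -> float:
        return 360.0 / self.n_bins

    def assign(self, phase: np.ndarray) -> np.ndarray:
        """Map phases in radians to bin indices 0..n_bins−1."""
        idx = np.floor((phase + np.pi) / (2 * np.pi) * self.n_bins).astype(np.intp)
        # phase exactly +pi falls in the last bin
        return np.clip(idx, 0, self.n_bins - 1)


@dataclass
class Comodulogram:
    """KL-MI on a (phase center × amplitude center) grid.

    Inadmissible or degenerate cells hold NaN.
    """

    phase_centers: np.ndarray
    amp_centers: np.ndarray
    mi: np.ndarray  # shape (n_phase, n_amp)
    bandwidth: float = DEFAULT_BANDWIDTH

    def argmax(self) -> tuple[float, float]:
        """(phase Hz, amplitude Hz) of the largest MI cell."""
        flat = np.nanargmax(self.mi)
        i, j = np.unravel_index(flat, self.mi.shape)
        return float(self.phase_centers[i]), float(self.amp_centers[j])

    def max_mi(self) -> float:
        return float(np.nanmax(self.mi))


@lru_cache(maxsize=512)
def _design_taps(fs: float, low: float, high: float, order: int) -> np.ndarray:
    return sps.firwin(order + 1, [low, high], pass_zero=False, fs=fs)


def _fir_taps(
    fs: float,
    low_edge: float,
    high_edge: float,
    n_samples: int,
    transition: float | None = None,
) -> np.ndarray:
    """Windowed-sinc band-pass taps; order set by the transition width.

    Default transition = half the bandwidth, i.e. order ≈ 3.3·fs/((hi−lo)/2).
    """
    if low_edge <= 0:
        raise ValueError(f"band lower edge must be positive, got {low_edge}")
    if high_edge >= fs / 2:
        raise ValueError(
            f"band upper edge {high_edge} Hz exceeds Nyquist {fs / 2} Hz"
        )
    if transition is None:
        transition = (high_edge - low_edge) / 2
    order = int(round(3.3 * fs / transition))
    if order % 2:
        order += 1
    if order + 1 > n_samples // 3:
        raise ValueError(
            f"filter order {order} too long for {n_samples} samples; "
            "provide a longer signal or a wider band"
        )
    return _design_taps(float(fs), float(low_edge), float(high_edge), order)


def _zero_phase(b: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Forward–backward FIR filtering with odd edge extension.

    For a linear-phase kernel the cascade equals one convolution with the
    kernel's autocorrelation, done here in the frequency domain for speed.
    """
    m = len(b)
    pad = min(len(x) - 1, 3 * m)
    left = 2 * x[0] - x[pad:0:-1]
    right = 2 * x[-1] - x[-2 : -pad - 2 : -1]
    xp = np.concatenate([left, x, right])
    bb = np.convolve(b, b[::-1])
    y = sps.fftconvolve(xp, bb, mode="same")
    return y[pad : pad + len(x)]


def fir_band(
    x: np.ndarray,
    fs: float,
    center: float,
    bandwidth: float = DEFAULT_BANDWIDTH,
    transition: float | None = None,
) -> np.ndarray:
    """Zero-phase narrow band-pass around ``center`` with ``bandwidth`` Hz."""
    x = np.asarray(x, dtype=float)
    low = center - bandwidth / 2
    high = center + bandwidth / 2
    b = _fir_taps(fs, low, high, x.size, transition)
    return _zero_phase(b, x)


def hilbert_phase_amp(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous phase (−π, π] and amplitude from the analytic signal."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")
    n = x.size
    analytic = sps.hilbert(x, N=next_fast_len(n))[:n]
    return np.angle(analytic), np.abs(analytic)


def kl_mi(
    phase: np.ndarray, amp: np.ndarray, binning: PhaseBinning = PhaseBinning()
) -> float:
    """KL modulation index of the phase-binned mean-amplitude distribution.

    Raises if any phase bin is empty (signal too short to cover the cycle)
    or if the amplitude is identically zero.
    """
    phase = np.asarray(phase, dtype=float).ravel()
    amp = np.asarray(amp, dtype=float).ravel()
    if phase.shape != amp.shape:
        raise ValueError("phase and amplitude series differ in length")
    if np.any(amp < 0):
        raise ValueError("amplitudes must be non-negative")
    n = binning.n_bins
    idx = binning.assign(phase)
    counts = np.bincount(idx, minlength=n)
    if np.any(counts == 0):
        raise ValueError(
            "empty phase bin: signal too short to populate all "
            f"{n} bins; provide more phase cycles"
        )
    sums = np.bincount(idx, weights=amp, minlength=n)
    return _mi_from_binned(sums, counts)


def _mi_from_binned(sums: np.ndarray, counts: np.ndarray) -> float:
    p = sums / counts
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero amplitude: modulation index undefined")
    p = p / total
    nz = p[p > 0]
    entropy = -np.sum(nz * np.log(nz))
    n = p.size
    # clamp float round-off: uniform P can give −1e-16
    return float(max(0.0, (np.log(n) - entropy) / np.log(n)))


def surrogate_mi(
    phase: np.ndarray,
    amp: np.ndarray,
    n_surrogates: int = 200,
    rng: np.random.Generator | int | None = None,
    binning: PhaseBinning = PhaseBinning(),
) -> np.ndarray:
    """Null MI distribution from random circular shifts of the amplitude.

    Circular shifting preserves both marginals while destroying the
    phase–amplitude alignment; shifts are drawn uniformly excluding a
    guard of 5% of the series at each end.
    """
    rng = np.random.default_rng(rng)
    amp = np.asarray(amp, dtype=float).ravel()
    n = amp.size
    guard = max(1, n // 20)
    shifts = rng.integers(guard, n - guard, size=n_surrogates)
    return np.array(
        [kl_mi(phase, np.roll(amp, int(s)), binning) for s in shifts]
    )


def _amp_halfwidth(phase_center: float) -> float:
    return AMP_HALFWIDTH_FACTOR * phase_center


def _admissible(
    phase_center: float, amp_center: float, fs: float,
    bandwidth: float = DEFAULT_BANDWIDTH,
) -> bool:
    """Amplitude window strictly above the phase band and below Nyquist."""
    hw = _amp_halfwidth(phase_center)
    return (
        amp_center - hw > phase_center + bandwidth / 2
        and amp_center + hw < fs / 2
    )


def _phase_series(x: np.ndarray, fs: float, pc: float, bandwidth: float) -> tuple[np.ndarray, int]:
    b = _fir_taps(fs, pc - bandwidth / 2, pc + bandwidth / 2, x.size,
                  transition=PHASE_TRANSITION_HZ)
    phase, _ = hilbert_phase_amp(_zero_phase(b, x))
    return phase, len(b)


def _amp_series(x: np.ndarray, fs: float, pc: float, ac: float) -> tuple[np.ndarray, int]:
    hw = _amp_halfwidth(pc)
    b = _fir_taps(fs, ac - hw, ac + hw, x.size, transition=pc)
    _, amp = hilbert_phase_amp(_zero_phase(b, x))
    return amp, len(b)


def _cell_series(
    x: np.ndarray, fs: float, pc: float, ac: float, bandwidth: float
) -> tuple[np.ndarray, np.ndarray]:
    """Aligned, transient-trimmed (phase, amplitude) for one grid cell.

    1-D input: trim both ends by the longer filter's length. 2-D
    (epochs × samples) input: filter the concatenated record and drop
    EDGE_TRIM_S from each epoch edge before pooling.
    """
    if x.ndim == 1:
        phase, gp = _phase_series(x, fs, pc, bandwidth)
        amp, ga = _amp_series(x, fs, pc, ac)
        g = max(gp, ga, int(round(EDGE_TRIM_S * fs)))
        if 2 * g >= phase.size:
            raise ValueError("signal too short to trim filter transients")
        return phase[g:-g], amp[g:-g]
    n_ep, n_samp = x.shape
    flat = x.ravel()
    phase, _ = _phase_series(flat, fs, pc, bandwidth)
    amp, _ = _amp_series(flat, fs, pc, ac)
    trim = int(round(EDGE_TRIM_S * fs))
    if 2 * trim >= n_samp:
        raise ValueError("epochs too short for edge trimming")
    phase = phase.reshape(n_ep, n_samp)[:, trim:-trim].ravel()
    amp = amp.reshape(n_ep, n_samp)[:, trim:-trim].ravel()
    return phase, amp


def comodulogram(
    x: np.ndarray,
    fs: float,
    phase_edges: Sequence[float] = PHASE_BANK_EDGES,
    amp_edges: Sequence[float] = AMP_BANK_EDGES,
    bandwidth: float = DEFAULT_BANDWIDTH,
    binning: PhaseBinning = PhaseBinning(),
) -> Comodulogram:
    """KL-MI over the (phase × amplitude) grid.

    ``x`` may be a continuous 1-D signal or a 2-D (epochs × samples)
    block (see :func:`_cell_series` for epoch pooling). Cells whose
    amplitude window would overlap the phase band or Nyquist are
    inadmissible (NaN), as are degenerate cells whose phase series
    cannot populate all bins.
    """
    x = np.asarray(x, dtype=float)
    lowest = min(phase_edges)
    if x.size / fs < 10 / lowest:
        raise ValueError(
            f"signal shorter than 10 cycles of the lowest phase band ({lowest} Hz)"
        )
    phase_centers = np.array([e + bandwidth / 2 for e in phase_edges])
    amp_centers = np.array([e + 1.0 for e in amp_edges])
    mi = np.full((len(phase_centers), len(amp_centers)), np.nan)
    for i, pc in enumerate(phase_centers):
        for j, ac in enumerate(amp_centers):
            if not _admissible(pc, ac, fs, bandwidth):
                continue
            try:
                phase, amp = _cell_series(x, fs, pc, ac, bandwidth)
                mi[i, j] = kl_mi(phase, amp, binning)
            except ValueError as err:
                # degenerate cell (empty phase bin / zero amplitude) — other
                # errors (signal too short for the filters) must propagate
                if "empty phase bin" in str(err) or "all-zero" in str(err):
                    mi[i, j] = np.nan
                else:
                    raise
    return Comodulogram(phase_centers, amp_centers, mi, bandwidth)


def surrogate_max_mi(
    x: np.ndarray,
    fs: float,
    n_surrogates: int = 200,
    rng: np.random.Generator | int | None = None,
    phase_edges: Sequence[float] = PHASE_BANK_EDGES,
    amp_edges: Sequence[float] = AMP_BANK_EDGES,
    bandwidth: float = DEFAULT_BANDWIDTH,
    binning: PhaseBinning = PhaseBinning(),
) -> tuple[float, np.ndarray]:
    """Observed grid-max MI and its surrogate-max null distribution.

    Each surrogate applies one common random circular shift to every
    cell's amplitude series and takes the maximum MI over the grid, so
    the null accounts for the maximum over multiple comparisons.
    """
    rng = np.random.default_rng(rng)
    x = np.asarray(x, dtype=float)
    cells = []
    phase_centers = [e + bandwidth / 2 for e in phase_edges]
    amp_centers = [e + 1.0 for e in amp_edges]
    for pc in phase_centers:
        for ac in amp_centers:
            if not _admissible(pc, ac, fs, bandwidth):
                continue
            try:
                phase, amp = _cell_series(x, fs, pc, ac, bandwidth)
                idx = binning.assign(phase)
                counts = np.bincount(idx, minlength=binning.n_bins)
                if np.any(counts == 0):
                    continue
                cells.append((idx, counts, amp))
            except ValueError:
                continue
    if not cells:
        raise ValueError("no admissible comodulogram cells")
    observed = max(
        _mi_from_binned(np.bincount(i, weights=a, minlength=binning.n_bins), c)
        for i, c, a in cells
    )
    n = min(a.size for _, _, a in cells)
    guard = max(1, n // 20)
    shifts = rng.integers(guard, n - guard, size=n_surrogates)
    null = np.empty(n_surrogates)
    for s_i, shift in enumerate(shifts):
        null[s_i] = max(
            _mi_from_binned(
                np.bincount(i, weights=np.roll(a, int(shift)),
                            minlength=binning.n_bins),
                c,
            )
            for i, c, a in cells
        )
    return float(observed), null


def band_pac(
    com: Comodulogram,
    phase_band: tuple[float, float] = (4.0, 8.0),
    amp_band: tuple[float, float] = (30.0, 70.0),
) -> float:
    """Mean MI over admissible grid cells inside the band box."""
    pm = (com.phase_centers >= phase_band[0]) & (com.phase_centers <= phase_band[1])
    am = (com.amp_centers >= amp_band[0]) & (com.amp_centers <= amp_band[1])
    cells = com.mi[np.ix_(pm, am)]
    cells = cells[np.isfinite(cells)]
    if cells.size == 0:
        raise ValueError("no admissible comodulogram cells inside the band box")
    return float(cells.mean())


def band_pac_direct(
    x: np.ndarray,
    fs: float,
    phase_band: tuple[float, float] = (4.0, 8.0),
    amp_band: tuple[float, float] = (30.0, 70.0),
    bandwidth: float = DEFAULT_BANDWIDTH,
    binning: PhaseBinning = PhaseBinning(),
) -> float:
    """Band-averaged PAC computed only on the in-box filter-bank cells.

    Identical to :func:`band_pac` applied to the full comodulogram, but
    filtering only the bands whose centers fall inside the box.
    """
    phase_edges = [
        e for e in PHASE_BANK_EDGES
        if phase_band[0] <= e + bandwidth / 2 <= phase_band[1]
    ]
    amp_edges = [
        e for e in AMP_BANK_EDGES if amp_band[0] <= e + 1.0 <= amp_band[1]
    ]
    com = comodulogram(x, fs, phase_edges, amp_edges, bandwidth, binning)
    return band_pac(com, phase_band, amp_band)


def pac_pipeline(
    roi_series_by_subject: Mapping[str, tuple["np.ndarray | object", str]],
    fs: float | None = None,
    amp_bands: Mapping[str, tuple[float, float]] | None = None,
    phase_band: tuple[float, float] = (4.0, 8.0),
) -> "pandas.DataFrame":
    """One theta–beta and one theta–gamma MI per subject × ROI.

    ``roi_series_by_subject`` maps subject_id → (ROISeries, group label);
    a ROISeries exposes ``data`` (epochs × rois × samples), ``fs`` and
    ``roi_labels``. Plain arrays are accepted when ``fs`` is given, with
    ROIs then labelled by index.
    """
    import pandas as pd

    if amp_bands is None:
        amp_bands = {"theta_beta_mi": (13.0, 30.0), "theta_gamma_mi": (30.0, 70.0)}
    rows = []
    for subject_id, (series, group) in roi_series_by_subject.items():
        data = getattr(series, "data", series)
        sfreq = getattr(series, "fs", fs)
        if sfreq is None:
            raise ValueError("sampling rate unknown: pass ROISeries or fs")
        labels = getattr(
            series, "roi_labels", [f"roi{i}" for i in range(np.asarray(data).shape[1])]
        )
        data = np.asarray(data, dtype=float)
        for r, roi in enumerate(labels):
            row = {"subject_id": subject_id, "group": group, "roi": roi}
            for col, band in amp_bands.items():
                row[col] = band_pac_direct(data[:, r, :], sfreq, phase_band, band)
            rows.append(row)
    return pd.DataFrame(rows)
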