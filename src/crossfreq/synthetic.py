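"""Synthetic resting-EEG cohorts with planted cross-frequency coupling.

Every downstream stage of the pipeline (preprocessing, source inverse,
PAC, connectivity, statistics, classification) is validated against data
from this module, because it knows the ground truth: which ROI carries
how much theta-phase → beta/gamma-amplitude coupling, which group a
subject belongs to, and what the true source time series were before
leadfield mixing.

Signal model per ROI (Tort-style amplitude modulation)::

    x(t) = a_θ sin(2π f_p t + ψ)
         + [1 + m_β cos(2π f_p t + ψ)] a_β sin(2π f_β t + ψ_β)
         + [1 + m_γ cos(2π f_p t + ψ)] a_γ sin(2π f_γ t + ψ_γ)
         + 1/f noise

with modulation depths m ∈ [0, 1] set per ROI per group. The 1/f
(power ∝ 1/f) Gaussian background matches the broadband structure of
resting EEG. Sensors are an abstract full-rank leadfield mixture of the
sources plus sensor noise — no electrode geometry or head physics.

Cohort structure mirrors a three-group tinnitus study design: bothersome
tinnitus (BT, THI > 36), non-bothersome tinnitus (NBT, THI ≤ 36) and
healthy controls (HC, no THI), with THI drawn from per-group truncated
normals (defaults BT 44.43 ± 9.32, NBT 18.52 ± 11.22, clipped to
[0, 100]) and resampled until consistent with the 36-point threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CouplingSpec",
    "RoiProfile",
    "CohortSpec",
    "Leadfield",
    "CohortDataset",
    "SubjectRecord",
    "pink_noise",
    "generate_coupled_signal",
    "generate_leadfield",
    "generate_subject",
    "generate_cohort",
    "default_roi_profiles",
    "THI_THRESHOLD",
]

THI_THRESHOLD = 36.0
GROUPS = ("BT", "NBT", "HC")

# carrier placement inside the analysis bands
PHASE_FREQ = 6.0
BETA_CARRIER = 20.0
GAMMA_CARRIER = 45.0


@dataclass(frozen=True)
class CouplingSpec:
    """A single planted phase→amplitude coupling."""

    phase_freq: float = PHASE_FREQ
    amp_freq: float = GAMMA_CARRIER
    modulation_depth: float = 0.5
    carrier_amplitude: float = 1.0
    noise_sd: float = 1.0  # 1/f background, the resting-EEG condition

    def __post_init__(self) -> None:
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must lie in [0, 1]")
        if self.phase_freq >= self.amp_freq:
            raise ValueError("phase_freq must be below amp_freq")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class RoiProfile:
    """Per-ROI coupling depths and relative band power."""

    roi_label: str
    theta_beta_depth: float = 0.0
    theta_gamma_depth: float = 0.0
    base_power: Mapping[str, float] = field(
        default_factory=lambda: {
            "theta": 1.0,
            "beta": 0.5,
            "gamma": 0.3,
            "broadband": 1.0,
        }
    )

    def __post_init__(self) -> None:
        for d in (self.theta_beta_depth, self.theta_gamma_depth):
            if not 0.0 <= d <= 1.0:
                raise ValueError("coupling depths must lie in [0, 1]")
        missing = {"theta", "beta", "gamma", "broadband"} - set(self.base_power)
        if missing:
            raise ValueError(f"base_power missing bands: {sorted(missing)}")


@dataclass(frozen=True)
class Leadfield:
    """Abstract sensor ← source gain matrix with an ROI ownership map."""

    gain: np.ndarray  # (n_sensors, n_sources)
    roi_map: tuple[str, ...]  # roi label per source

    def __post_init__(self) -> None:
        g = np.asarray(self.gain, dtype=float)
        if g.ndim != 2:
            raise ValueError("gain must be a 2-D matrix")
        if len(self.roi_map) != g.shape[1]:
            raise ValueError("roi_map length must equal source count")
        if np.any(np.all(g == 0, axis=1)) or np.any(np.all(g == 0, axis=0)):
            raise ValueError("leadfield has an all-zero row or column")
        object.__setattr__(self, "gain", g)

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]

    @property
    def roi_labels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.roi_map:
            seen.setdefault(r)
        return tuple(seen)

    def sources_of(self, roi: str) -> np.ndarray:
        return np.flatnonzero(np.array(self.roi_map) == roi)


@dataclass(frozen=True)
class CohortSpec:
    """Study-level design: group sizes, recording geometry, THI model."""

    n_bt: int = 21
    n_nbt: int = 27
    n_hc: int = 21
    duration_s: float = 60.0
    fs: float = 500.0
    n_sensors: int = 32
    sources_per_roi: int = 2
    sensor_snr_db: float = 20.0
    roi_profiles: Mapping[str, Sequence[RoiProfile]] | None = None
    thi_model: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"BT": (44.43, 9.32), "NBT": (18.52, 11.22)}
    )
    epoch_len_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        n_ep = self.duration_s / self.epoch_len_s
        if abs(n_ep - round(n_ep)) > 1e-9:
            raise ValueError("duration_s must divide into whole epochs")
        for grp, (mean, sd) in self.thi_model.items():
            if grp == "BT" and mean <= THI_THRESHOLD and sd == 0:
                raise ValueError(
                    "BT THI model inconsistent with the >36 threshold"
                )
            if grp == "NBT" and mean > THI_THRESHOLD and sd == 0:
                raise ValueError(
                    "NBT THI model inconsistent with the ≤36 threshold"
                )


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    thi: float  # NaN for HC
    seed_key: int  # child-stream key under the cohort seed


@dataclass
class CohortDataset:
    """Cohort metadata plus deterministic per-subject realisation.

    Sensor data are regenerated on demand from per-subject seed keys, so
    a 69-subject cohort never has to sit in memory at once.
    """

    spec: CohortSpec
    leadfield: Leadfield
    subjects: list[SubjectRecord]
    profiles_by_subject: dict[str, tuple[RoiProfile, ...]]

    @property
    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"subject_id": s.subject_id, "group": s.group, "thi": s.thi}
                for s in self.subjects
            ]
        )

    def group_counts(self) -> dict[str, int]:
        out = {g: 0 for g in GROUPS}
        for s in self.subjects:
            out[s.group] += 1
        return out

    def realize(self, subject_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(sensor data µV, ground-truth ROI series) for one subject."""
        rec = next(s for s in self.subjects if s.subject_id == subject_id)
        rng = np.random.default_rng(
            np.random.SeedSequence(self.spec.seed).spawn(rec.seed_key + 1)[-1]
        )
        return generate_subject(
            list(self.profiles_by_subject[subject_id]),
            self.leadfield,
            self.spec.duration_s,
            self.spec.fs,
            rng,
            sensor_snr_db=self.spec.sensor_snr_db,
        )

    def iter_subjects(self) -> Iterator[tuple[SubjectRecord, np.ndarray, np.ndarray]]:
        for s in self.subjects:
            sensors, truth = self.realize(s.subject_id)
            yield s, sensors, truth


def pink_noise(
    n: int, rng: np.random.Generator, sd: float = 1.0
) -> np.ndarray:
    """Gaussian noise with power spectral density ∝ 1/f, unit variance × sd."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** -0.5  # amplitude ∝ f^-1/2 → power ∝ 1/f
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    return sd * x / x.std()


def generate_coupled_signal(
    spec: CouplingSpec,
    duration_s: float,
    fs: float,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """One channel with a single planted phase→amplitude coupling.

    x(t) = sin(2π f_p t) + [1 + m cos(2π f_p t)]·A·sin(2π f_a t) + noise.
    The planted depth m is directly recoverable by the KL-MI estimator.
    """
    if fs < 2 * spec.amp_freq:
        raise ValueError(
            f"fs={fs} Hz aliases the {spec.amp_freq} Hz amplitude carrier"
        )
    n = int(round(duration_s * fs))
    if n < 10 * fs / spec.phase_freq:
        raise ValueError("signal shorter than 10 cycles of the phase frequency")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    lf_phase = 2 * np.pi * spec.phase_freq * t
    envelope = 1.0 + spec.modulation_depth * np.cos(lf_phase)
    x = (
        np.sin(lf_phase)
        + envelope * spec.carrier_amplitude * np.sin(2 * np.pi * spec.amp_freq * t)
        + pink_noise(n, rng, spec.noise_sd)
    )
    return x


def _roi_signal(
    profile: RoiProfile,
    duration_s: float,
    fs: float,
    rng: np.random.Generator,
    noise_sd: float = 1.0,
) -> np.ndarray:
    """ROI source series: theta oscillator + modulated β/γ carriers + 1/f."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    psi = rng.uniform(0, 2 * np.pi, size=3)
    lf_phase = 2 * np.pi * PHASE_FREQ * t + psi[0]
    a_th = np.sqrt(profile.base_power["theta"])
    a_b = np.sqrt(profile.base_power["beta"])
    a_g = np.sqrt(profile.base_power["gamma"])
    env_b = 1.0 + profile.theta_beta_depth * np.cos(lf_phase)
    env_g = 1.0 + profile.theta_gamma_depth * np.cos(lf_phase)
    x = (
        a_th * np.sin(lf_phase)
        + env_b * a_b * np.sin(2 * np.pi * BETA_CARRIER * t + psi[1])
        + env_g * a_g * np.sin(2 * np.pi * GAMMA_CARRIER * t + psi[2])
        + pink_noise(n, rng, noise_sd * np.sqrt(profile.base_power["broadband"]))
    )
    return x


def generate_leadfield(
    n_sensors: int,
    n_sources: int,
    roi_labels: Sequence[str] | int,
    seed: int | np.random.Generator | None = None,
) -> Leadfield:
    """Full-rank Gaussian gain matrix with every ROI owning ≥1 source."""
    if isinstance(roi_labels, int):
        roi_labels = [f"roi{i:02d}" for i in range(roi_labels)]
    n_rois = len(roi_labels)
    if n_rois > n_sources:
        raise ValueError("more ROIs than sources")
    if n_rois < 1:
        raise ValueError("need at least one ROI")
    rng = np.random.default_rng(seed)
    # round-robin ROI ownership guarantees ≥1 source each
    roi_map = tuple(roi_labels[i % n_rois] for i in range(n_sources))
    for _ in range(10):
        g = rng.standard_normal((n_sensors, n_sources)) / np.sqrt(n_sensors)
        if np.linalg.matrix_rank(g) == min(n_sensors, n_sources):
            return Leadfield(gain=g, roi_map=roi_map)
    raise RuntimeError("failed to draw a full-rank leadfield")  # pragma: no cover


def generate_subject(
    profiles: Sequence[RoiProfile],
    leadfield: Leadfield,
    duration_s: float,
    fs: float,
    seed: int | np.random.Generator | None = None,
    sensor_snr_db: float = 20.0,
    source_noise_sd: float = 0.1,
    target_rms_uv: float = 7.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sensor recording + ground-truth ROI series for one subject.

    Sources within an ROI share that ROI's signal plus small independent
    1/f noise; sensors are ``leadfield.gain @ sources`` plus white sensor
    noise at ``sensor_snr_db``. The ground truth returned is the signed
    mean over each ROI's sources — the same aggregation the source
    pipeline applies — scaled identically to the sensors (µV).
    """
    rng = np.random.default_rng(seed)
    labels = [p.roi_label for p in profiles]
    missing = [r for r in labels if len(leadfield.sources_of(r)) == 0]
    if missing:
        raise ValueError(f"profiles reference ROIs absent from leadfield: {missing}")
    n = int(round(duration_s * fs))
    sources = np.zeros((leadfield.n_sources, n))
    truth = np.zeros((len(profiles), n))
    for r, prof in enumerate(profiles):
        roi_sig = _roi_signal(prof, duration_s, fs, rng)
        idx = leadfield.sources_of(prof.roi_label)
        for i in idx:
            sources[i] = roi_sig + pink_noise(n, rng, source_noise_sd)
        truth[r] = sources[idx].mean(axis=0)
    clean = leadfield.gain @ sources
    sig_rms = np.sqrt(np.mean(clean**2))
    noise_sd = sig_rms / 10 ** (sensor_snr_db / 20)
    sensors = clean + rng.standard_normal(clean.shape) * noise_sd
    # normalise to EEG-like µV scale; same factor applied to the truth
    scale = target_rms_uv / np.sqrt(np.mean(sensors**2))
    return sensors * scale, truth * scale


def _draw_thi(
    group: str,
    model: Mapping[str, tuple[float, float]],
    rng: np.random.Generator,
    max_tries: int = 10_000,
) -> float:
    """THI from a [0,100]-clipped normal, rejection-sampled to the group side."""
    if group == "HC":
        return float("nan")
    mean, sd = model[group]
    for _ in range(max_tries):
        v = float(np.clip(rng.normal(mean, sd), 0.0, 100.0))
        if group == "BT" and v > THI_THRESHOLD:
            return v
        if group == "NBT" and v <= THI_THRESHOLD:
            return v
    raise RuntimeError(
        f"THI model for {group} cannot satisfy the {THI_THRESHOLD}-point threshold"
    )


def default_roi_profiles(
    roi_labels: Sequence[str], group: str
) -> tuple[RoiProfile, ...]:
    """Planted group pattern over an ROI set.

    BT subjects get enhanced theta–beta and theta–gamma coupling in
    auditory/limbic ROIs (labels containing HES, STG, MTG, PCG, DCG, HIP,
    PHG, INS, ACG) and attenuated theta–gamma coupling in orbitofrontal
    ROIs (ORB); NBT sits between BT and the HC baseline.
    """
    enhanced = ("HES", "STG", "MTG", "PCG", "DCG", "HIP", "PHG", "INS", "ACG")
    depths = {  # (theta_beta, theta_gamma) for enhanced / orb / other
        "HC": {"enh": (0.15, 0.15), "orb": (0.15, 0.35), "other": (0.15, 0.15)},
        "NBT": {"enh": (0.35, 0.35), "orb": (0.15, 0.25), "other": (0.2, 0.2)},
        "BT": {"enh": (0.65, 0.65), "orb": (0.15, 0.1), "other": (0.2, 0.2)},
    }[group]
    out = []
    for roi in roi_labels:
        if "ORB" in roi:
            tb, tg = depths["orb"]
        elif any(tag in roi for tag in enhanced):
            tb, tg = depths["enh"]
        else:
            tb, tg = depths["other"]
        out.append(RoiProfile(roi, tb, tg))
    return tuple(out)


def generate_cohort(spec: CohortSpec, leadfield: Leadfield | None = None) -> CohortDataset:
    """Full cohort: leadfield, metadata with THI, and per-subject seeds."""
    for name, n in (("n_bt", spec.n_bt), ("n_nbt", spec.n_nbt)):
        if n < 2:
            raise ValueError(f"{name} must be ≥ 2")
    root = np.random.SeedSequence(spec.seed)
    meta_rng = np.random.default_rng(root.spawn(1)[0])

    if spec.roi_profiles is not None:
        profiles = {g: tuple(p) for g, p in spec.roi_profiles.items()}
        roi_labels = [p.roi_label for p in next(iter(profiles.values()))]
    else:
        from .inverse import default_registry

        roi_labels = list(default_registry().labels)[:8]
        profiles = {g: default_roi_profiles(roi_labels, g) for g in GROUPS}

    if leadfield is None:
        leadfield = generate_leadfield(
            spec.n_sensors,
            spec.sources_per_roi * len(roi_labels),
            roi_labels,
            np.random.default_rng(root.spawn(2)[-1]),
        )

    subjects: list[SubjectRecord] = []
    prof_by_subject: dict[str, tuple[RoiProfile, ...]] = {}
    key = 0
    for group, count in (("BT", spec.n_bt), ("NBT", spec.n_nbt), ("HC", spec.n_hc)):
        for i in range(count):
            sid = f"{group.lower()}{i + 1:03d}"
            thi = _draw_thi(group, spec.thi_model, meta_rng)
            subjects.append(SubjectRecord(sid, group, thi, seed_key=key + 10))
            base = profiles.get(group)
            if base is None:
                raise ValueError(f"no ROI profiles for group {group}")
            # per-subject depth jitter keeps subjects distinct but on-pattern
            jit = []
            for p in base:
                jrng = np.random.default_rng(root.spawn(key + 1000)[-1])
                jit.append(
                    replace(
                        p,
                        theta_beta_depth=float(
                            np.clip(p.theta_beta_depth + jrng.normal(0, 0.05), 0, 1)
                        ),
                        theta_gamma_depth=float(
                            np.clip(p.theta_gamma_depth + jrng.normal(0, 0.05), 0, 1)
                        ),
                    )
                )
            prof_by_subject[sid] = tuple(jit)
            key += 1
    return CohortDataset(
        spec=spec,
        leadfield=leadfield,
        subjects=subjects,
        profiles_by_subject=prof_by_subject,
    )
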