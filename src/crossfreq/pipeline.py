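"""End-to-end orchestration: simulate → preprocess → invert → features →
statistics → classification, as one configured, seeded, logged run.

``run(config)`` writes a run directory of TSV tables plus a JSON
manifest recording the config, the fan-out of the master seed, and a
SHA-256 hash of every table, so that re-running with the same config is
bit-identically reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import classify as cl
from . import connectivity as cn
from . import spectral as sp
from . import stats as st
from .inverse import aggregate_rois, detrend_noise, mne_inverse
from .io import EpochedData, Recording, bandpass_notch, reject_epochs, resample_epoch
from .pac import pac_pipeline
from .synthetic import CohortSpec, generate_cohort

logger = logging.getLogger("crossfreq")

__all__ = ["PipelineConfig", "run"]


class CohortConfig(BaseModel):
    n_bt: int = 21
    n_nbt: int = 27
    n_hc: int = 21
    duration_s: float = 60.0
    fs: float = 500.0
    n_sensors: int = 32
    n_rois: int = 8
    sources_per_roi: int = 2
    sensor_snr_db: float = 20.0


class PreprocConfig(BaseModel):
    band_low_hz: float = 0.5
    band_high_hz: float = 150.0
    notch_hz: float = 50.0
    fs_target: float = 500.0
    epoch_len_s: float = 2.0
    abs_threshold_uv: float = 100.0
    flatline_threshold_uv: float = 1e-3


class BandConfig(BaseModel):
    theta: tuple[float, float] = (4.0, 8.0)
    beta: tuple[float, float] = (13.0, 30.0)
    gamma: tuple[float, float] = (30.0, 70.0)


class StatsConfig(BaseModel):
    n_boot: int = 1000
    alpha: float = 0.05


class ClassifierConfig(BaseModel):
    k: int = 5
    n_components: int = 10
    reduce_method: Literal["score", "lda"] = "score"
    combos: tuple[str, ...] = ("FC", "FC+power", "FC+PAC", "PAC", "all")


class PipelineConfig(BaseModel):
    """Validated configuration of a full synthetic-cohort run."""

    cohort: CohortConfig = Field(default_factory=CohortConfig)
    preprocessing: PreprocConfig = Field(default_factory=PreprocConfig)
    inverse_snr: float = 3.0
    bands: BandConfig = Field(default_factory=BandConfig)
    connectivity_metric: Literal["coherence", "plv", "pli", "wpli"] = "wpli"
    stats: StatsConfig = Field(default_factory=StatsConfig)
    classifier: ClassifierConfig = Field(default_factory=ClassifierConfig)
    seed: int = 0
    out_dir: Path = Path("crossfreq_run")

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v: int) -> int:
        if not 0 <= v < 2**31:
            raise ValueError("seed must lie in [0, 2^31)")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


def _write_tsv(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: PipelineConfig, force: bool = False) -> Path:
    """Execute the full pipeline; returns the run directory.

    Refuses to overwrite a directory holding a previous manifest unless
    ``force`` is set.
    """
    out = Path(config.out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(
            f"{out} holds a previous run; pass force=True to overwrite"
        )
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    try:
        return _run_inner(config, out, manifest_path)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_inner(config: PipelineConfig, out: Path, manifest_path: Path) -> Path:
    cc = config.cohort
    pp = config.preprocessing
    seeds = {
        "simulate": config.seed,
        "bootstrap": config.seed + 1,
        "classifier": config.seed + 2,
    }
    spec = CohortSpec(
        n_bt=cc.n_bt, n_nbt=cc.n_nbt, n_hc=cc.n_hc,
        duration_s=cc.duration_s, fs=cc.fs, n_sensors=cc.n_sensors,
        sources_per_roi=cc.sources_per_roi, sensor_snr_db=cc.sensor_snr_db,
        epoch_len_s=pp.epoch_len_s, seed=seeds["simulate"],
    )
    from .inverse import default_registry

    roi_labels = list(default_registry().labels)[: cc.n_rois]
    from .synthetic import GROUPS, default_roi_profiles

    from dataclasses import replace as _dc_replace

    spec = _dc_replace(
        spec,
        roi_profiles={g: default_roi_profiles(roi_labels, g) for g in GROUPS},
    )
    cohort = generate_cohort(spec)
    logger.info("cohort: %s", cohort.group_counts())

    bands = {
        "theta": config.bands.theta,
        "beta": config.bands.beta,
        "gamma": config.bands.gamma,
    }
    pac_rows = []
    conn_by_band: dict[str, dict[str, cn.ConnectivityMatrix]] = {
        b: {} for b in bands
    }
    power_rows = {}
    for rec_meta, sensors, _truth in cohort.iter_subjects():
        rec = Recording(
            data=sensors, fs=cc.fs,
            channel_labels=tuple(f"ch{i:02d}" for i in range(cc.n_sensors)),
        )
        rec = bandpass_notch(rec, pp.band_low_hz, pp.band_high_hz, pp.notch_hz)
        ep = resample_epoch(rec, pp.fs_target, pp.epoch_len_s)
        ep = reject_epochs(ep, pp.abs_threshold_uv, pp.flatline_threshold_uv)
        ep = detrend_noise(ep)
        src = mne_inverse(ep, cohort.leadfield)
        roi = aggregate_rois(src, cohort.leadfield.roi_map, roi_labels, ep.fs)
        sub_pac = pac_pipeline({rec_meta.subject_id: (roi, rec_meta.group)})
        pac_rows.append(sub_pac)
        for bname, band in bands.items():
            conn_by_band[bname][rec_meta.subject_id] = cn.connectivity_matrix(
                roi, config.connectivity_metric, band
            )
        # per-ROI normalised band power
        prow = {}
        for r, lbl in enumerate(roi.roi_labels):
            spec_r = sp.psd(roi.data[:, r, :], roi.fs)
            for bn, v in sp.band_power(spec_r).items():
                prow[f"{bn}_{lbl}"] = v
        power_rows[rec_meta.subject_id] = prow
        logger.info("subject %s done", rec_meta.subject_id)

    pac_table = pd.concat(pac_rows, ignore_index=True)
    power = pd.DataFrame.from_dict(power_rows, orient="index").sort_index()

    hashes = {}
    hashes["pac_table.tsv"] = _write_tsv(pac_table, out / "pac_table.tsv")
    hashes["cohort.tsv"] = _write_tsv(cohort.metadata, out / "cohort.tsv")
    hashes["power.tsv"] = _write_tsv(
        power.reset_index(names="subject_id"), out / "power.tsv"
    )
    for bname in bands:
        mats = conn_by_band[bname]
        stack_rows = []
        for sid, mat in mats.items():
            iu = np.triu_indices(len(mat.roi_labels), k=1)
            row = {"subject_id": sid}
            row.update(
                {
                    f"{mat.roi_labels[i]}|{mat.roi_labels[j]}": mat.values[i, j]
                    for i, j in zip(*iu)
                }
            )
            stack_rows.append(row)
        fname = f"connectivity_{config.connectivity_metric}_{bname}.tsv"
        hashes[fname] = _write_tsv(pd.DataFrame(stack_rows), out / fname)

    # --- statistics: BT vs HC and NBT vs HC mixed ANOVA + post-hoc
    stat_rows, posthoc_rows = [], []
    groups_present = set(pac_table["group"].unique())
    for pair in (("BT", "HC"), ("NBT", "HC")):
        if not set(pair) <= groups_present:
            continue
        subtab = pac_table[pac_table["group"].isin(pair)]
        for dv in ("theta_beta_mi", "theta_gamma_mi"):
            for res in st.rm_anova(subtab, dv=dv):
                stat_rows.append(
                    {"pair": "-".join(pair), "dv": dv, "effect": res.effect,
                     "F": res.F, "df_num": res.df_num, "df_den": res.df_den,
                     "p": res.p, "p_bonferroni": res.p_bonferroni}
                )
            for ph in st.bootstrap_posthoc(
                subtab, dv=dv, n_boot=config.stats.n_boot, seed=seeds["bootstrap"],
                alpha=config.stats.alpha,
            ):
                posthoc_rows.append(
                    {"pair": "-".join(ph.group_pair), "dv": dv,
                     "roi": ph.roi_label, "diff": ph.observed_diff,
                     "p": ph.p, "q": ph.q, "n_boot": ph.n_boot, "seed": ph.seed}
                )
    if stat_rows:
        hashes["anova.tsv"] = _write_tsv(pd.DataFrame(stat_rows), out / "anova.tsv")
        hashes["posthoc.tsv"] = _write_tsv(
            pd.DataFrame(posthoc_rows), out / "posthoc.tsv"
        )

    # --- PAC–THI correlation within tinnitus groups
    thi = cohort.metadata.set_index("subject_id")["thi"]
    corr_rows = []
    for grp in ("BT", "NBT"):
        gt = pac_table[pac_table["group"] == grp]
        if gt["subject_id"].nunique() >= 4:
            for res in st.pac_thi_correlation(gt, thi):
                corr_rows.append(
                    {"group": grp, "roi": res.roi_label, "band": res.band,
                     "r": res.r, "p": res.p, "n": res.n}
                )
    if corr_rows:
        hashes["pac_thi_correlation.tsv"] = _write_tsv(
            pd.DataFrame(corr_rows), out / "pac_thi_correlation.tsv"
        )

    # --- classifier: BT vs NBT feature ablation
    bt_nbt = pac_table[pac_table["group"].isin(("BT", "NBT"))]
    conn_bt_nbt = {
        f"{config.connectivity_metric}_{b}": {
            sid: m for sid, m in conn_by_band[b].items()
            if sid in set(bt_nbt["subject_id"])
        }
        for b in bands
    }
    power_bt_nbt = power.loc[power.index.isin(set(bt_nbt["subject_id"]))]
    tables = {
        combo: cl.assemble_features(
            pac_table=bt_nbt, connectivity=conn_bt_nbt, power=power_bt_nbt,
            combo=combo,
        )
        for combo in config.classifier.combos
    }
    reports = cl.feature_ablation(
        tables, k=config.classifier.k,
        n_components=config.classifier.n_components,
        reduce_method=config.classifier.reduce_method,
        seed=seeds["classifier"],
    )
    hashes["classification.tsv"] = _write_tsv(
        pd.DataFrame(
            [
                {"feature_set": r.feature_set, "accuracy": r.accuracy,
                 "sensitivity": r.sensitivity, "specificity": r.specificity,
                 "tp": r.tp, "tn": r.tn, "fp": r.fp, "fn": r.fn,
                 "k": r.k, "n_components": r.n_components}
                for r in reports
            ]
        ),
        out / "classification.tsv",
    )

    manifest = {
        "config": json.loads(config.model_dump_json()),
        "seeds": seeds,
        "tables": hashes,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("run complete: %s", out)
    return out
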