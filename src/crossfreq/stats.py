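"""Inferential layer: normality screen, mixed ANOVA, bootstrap post-hoc,
FDR, and PAC–symptom correlation.

The group comparison of band PAC is a mixed-design (repeated-measures)
ANOVA with ROI as the within-subject factor and Group as the
between-subject factor, run on one group pair at a time. Post-hoc,
each ROI's group difference in means is tested with a subject-level
bootstrap (1000 resamples, shift-method null: resampled differences are
centered on the observed difference) and Benjamini–Hochberg FDR across
ROIs. PAC–THI relationships are Pearson correlations from the linear
regression slope (Spearman optional).

Shapiro–Wilk screening routes downstream tests: measures flagged
non-normal (p < 0.05) can be compared with a rank-based test instead of
the Welch t inside the bootstrap summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "PosthocResult",
    "CorrelationResult",
    "normality_screen",
    "rm_anova",
    "bootstrap_posthoc",
    "fdr_bh",
    "pac_thi_correlation",
]


@dataclass(frozen=True)
class AnovaResult:
    effect: str  # "Group", "ROI" or "ROI×Group"
    F: float
    df_num: float
    df_den: float
    p: float
    p_bonferroni: float


@dataclass(frozen=True)
class PosthocResult:
    roi_label: str
    group_pair: tuple[str, str]
    observed_diff: float
    p: float
    q: float
    n_boot: int
    seed: int


@dataclass(frozen=True)
class CorrelationResult:
    roi_label: str
    band: str
    r: float
    p: float
    n: int


def normality_screen(values: np.ndarray, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Shapiro–Wilk W, p, and a normal/non-normal routing flag."""
    v = np.asarray(values, dtype=float)
    if v.size < 3 or v.size > 5000:
        raise ValueError("Shapiro–Wilk valid for 3 ≤ n ≤ 5000")
    if np.ptp(v) == 0:
        raise ValueError("constant sample: normality undefined")
    w, p = spstats.shapiro(v)
    return float(w), float(p), bool(p >= alpha)


def rm_anova(
    pac_table: pd.DataFrame,
    dv: str = "theta_gamma_mi",
    family_size: int = 4,
) -> list[AnovaResult]:
    """Mixed ANOVA: ROI within-subject × Group between-subject.

    ``pac_table`` needs columns subject_id, group, roi and the dv, with
    exactly two groups and a balanced ROI set. ``family_size`` scales the
    Bonferroni-adjusted p (default 4: two bands × two group pairs).
    Zero-variance data yield F = 0 for every effect.
    """
    import pingouin as pg

    required = {"subject_id", "group", "roi", dv}
    missing = required - set(pac_table.columns)
    if missing:
        raise ValueError(f"pac_table missing columns {sorted(missing)}")
    groups = sorted(pac_table["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"mixed ANOVA needs exactly two groups, got {groups}")
    counts = pac_table.groupby("subject_id")["roi"].nunique()
    if counts.nunique() != 1:
        raise ValueError("unbalanced ROI set across subjects (missing cells)")
    per_group = pac_table.drop_duplicates("subject_id").groupby("group").size()
    if (per_group < 2).any():
        raise ValueError("need ≥2 subjects per group")

    if np.ptp(pac_table[dv].to_numpy()) == 0:
        dfs = _mixed_dfs(pac_table)
        return [
            AnovaResult(eff, 0.0, dfn, dfd, 1.0, 1.0)
            for eff, (dfn, dfd) in dfs.items()
        ]

    aov = pg.mixed_anova(
        data=pac_table, dv=dv, within="roi", subject="subject_id", between="group",
        correction=False,
    )
    name_map = {"group": "Group", "roi": "ROI", "Interaction": "ROI×Group"}
    pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
    out = []
    for _, row in aov.iterrows():
        eff = name_map.get(row["Source"], row["Source"])
        f = float(row["F"]) if np.isfinite(row["F"]) else 0.0
        p = float(row[pcol]) if np.isfinite(row[pcol]) else 1.0
        out.append(
            AnovaResult(
                effect=eff,
                F=max(f, 0.0),
                df_num=float(row["DF1"]),
                df_den=float(row["DF2"]),
                p=p,
                p_bonferroni=min(1.0, p * family_size),
            )
        )
    return out


def _mixed_dfs(pac_table: pd.DataFrame) -> dict[str, tuple[float, float]]:
    n_roi = pac_table["roi"].nunique()
    n_sub = pac_table["subject_id"].nunique()
    n_grp = pac_table["group"].nunique()
    return {
        "Group": (n_grp - 1, n_sub - n_grp),
        "ROI": (n_roi - 1, (n_sub - n_grp) * (n_roi - 1)),
        "ROI×Group": ((n_roi - 1) * (n_grp - 1), (n_sub - n_grp) * (n_roi - 1)),
    }


def bootstrap_posthoc(
    pac_table: pd.DataFrame,
    dv: str = "theta_gamma_mi",
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[PosthocResult]:
    """Per-ROI two-group bootstrap difference test with BH-FDR across ROIs.

    Subjects are resampled with replacement within each group; the null
    is the resampled difference distribution centered on the observed
    difference; two-sided p = fraction of null draws at least as extreme
    as the observed difference (add-one corrected).
    """
    if n_boot < 100:
        raise ValueError("n_boot < 100 gives unusable p resolution")
    groups = sorted(pac_table["group"].unique())
    if len(groups) != 2:
        raise ValueError("bootstrap post-hoc compares exactly two groups")
    g1, g2 = groups
    rng = np.random.default_rng(seed)
    rois = list(pac_table["roi"].unique())
    results = []
    pvals = []
    for roi in rois:
        sub = pac_table[pac_table["roi"] == roi]
        x = sub.loc[sub["group"] == g1, dv].to_numpy()
        y = sub.loc[sub["group"] == g2, dv].to_numpy()
        if x.size < 5 or y.size < 5:
            raise ValueError(f"ROI {roi}: need ≥5 subjects per group")
        obs = x.mean() - y.mean()
        bx = rng.integers(0, x.size, size=(n_boot, x.size))
        by = rng.integers(0, y.size, size=(n_boot, y.size))
        d_star = x[bx].mean(axis=1) - y[by].mean(axis=1)
        null = d_star - obs
        p = (1 + np.sum(np.abs(null) >= abs(obs))) / (n_boot + 1)
        pvals.append(p)
        results.append((roi, obs, p))
    qvals = fdr_bh(np.array(pvals))
    return [
        PosthocResult(
            roi_label=roi,
            group_pair=(g1, g2),
            observed_diff=float(obs),
            p=float(p),
            q=float(q),
            n_boot=n_boot,
            seed=seed,
        )
        for (roi, obs, p), q in zip(results, qvals)
    ]


def fdr_bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def pac_thi_correlation(
    pac_table: pd.DataFrame,
    thi: pd.Series | dict,
    bands: tuple[str, ...] = ("theta_beta_mi", "theta_gamma_mi"),
    method: str = "pearson",
) -> list[CorrelationResult]:
    """Per-ROI, per-band correlation between PAC and THI score.

    Pearson r is taken from the regression slope's standardised form;
    ``method='spearman'`` ranks both variables first. Subjects without a
    THI score (e.g. controls) are dropped.
    """
    thi = pd.Series(thi)
    out = []
    for roi in pac_table["roi"].unique():
        sub = pac_table[pac_table["roi"] == roi].set_index("subject_id")
        for band in bands:
            pair = pd.concat([sub[band], thi], axis=1, join="inner").dropna()
            x = pair.iloc[:, 1].to_numpy(dtype=float)  # THI
            y = pair.iloc[:, 0].to_numpy(dtype=float)  # PAC
            if x.size < 4:
                raise ValueError(f"ROI {roi}/{band}: need ≥4 subjects with THI")
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                raise ValueError(f"ROI {roi}/{band}: constant variable")
            if method == "spearman":
                r, p = spstats.spearmanr(x, y)
            else:
                res = spstats.linregress(x, y)
                r, p = res.rvalue, res.pvalue
            out.append(
                CorrelationResult(
                    roi_label=roi, band=band, r=float(r), p=float(p), n=int(x.size)
                )
            )
    return out
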