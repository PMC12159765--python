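"""Two-group classification from assembled EEG features.

Feature blocks (band power, connectivity edges, band PAC per ROI) are
joined per subject, then evaluated with leave-one-out cross-validation:
inside each fold the features are z-scored, reduced by a Fisher
criterion, and the held-out subject is classified by a k-nearest-
neighbour majority vote (Euclidean distance, default k = 5). Scaling and
reduction are fit on the training fold only — the held-out subject never
influences them.

Fisher reduction comes in two flavours:

* ``"score"`` (default): rank features by the per-feature discriminant
  ratio (μ₁−μ₂)²/(s₁²+s₂²) and keep the top m (default 10);
* ``"lda"``: project onto the canonical Fisher discriminant direction
  S_w⁻¹(μ₁−μ₂) (one component for two classes), ridge-regularising a
  singular within-class scatter.

Sensitivity is the recall of the positive class (first label
alphabetically reversed → "BT" when labels are BT/NBT), specificity the
recall of the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "CvReport",
    "assemble_features",
    "fisher_scores",
    "fisher_direction",
    "fisher_reduce",
    "knn_loocv",
    "feature_ablation",
]

POSITIVE_CLASS = "BT"


@dataclass(frozen=True)
class FeatureTable:
    """Named feature matrix with per-subject labels."""

    features: pd.DataFrame  # index subject_id, named columns
    labels: pd.Series  # index subject_id

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.labels.index):
            raise ValueError("features and labels must cover the same subjects")
        if self.features.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        if self.features.isna().any().any():
            raise ValueError("missing values in feature table")
        if self.labels.nunique() < 2:
            raise ValueError("need ≥2 classes")


@dataclass(frozen=True)
class CvReport:
    feature_set: str
    accuracy: float
    sensitivity: float
    specificity: float
    tp: int
    tn: int
    fp: int
    fn: int
    k: int
    n_components: int
    seed: int
    predictions: tuple[str, ...] = ()  # per subject, feature-table order

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def assemble_features(
    pac_table: pd.DataFrame | None = None,
    connectivity: Mapping[str, "object"] | None = None,
    power: pd.DataFrame | None = None,
    combo: str = "all",
    labels: pd.Series | Mapping[str, str] | None = None,
) -> FeatureTable:
    """Join feature blocks per subject for one combination.

    combo ∈ {"FC", "FC+power", "FC+PAC", "PAC", "power", "all"}. PAC
    features are theta_beta_mi/theta_gamma_mi per ROI from a long
    pac_table; connectivity maps "metric_band" → {subject_id:
    ConnectivityMatrix} and contributes upper-triangle edges; power is a
    wide DataFrame indexed by subject.
    """
    blocks: list[pd.DataFrame] = []
    want = {
        "FC": {"fc"},
        "FC+power": {"fc", "power"},
        "FC+PAC": {"fc", "pac"},
        "PAC": {"pac"},
        "power": {"power"},
        "all": {"fc", "power", "pac"},
    }.get(combo)
    if want is None:
        raise ValueError(f"unknown combo {combo!r}")

    if "fc" in want:
        if not connectivity:
            raise ValueError(f"combo {combo} requires connectivity matrices")
        for name, by_subject in connectivity.items():
            rows = {}
            for sid, mat in by_subject.items():
                vals = getattr(mat, "values", mat)
                vals = vals.to_numpy() if hasattr(vals, "to_numpy") else np.asarray(vals)
                iu = np.triu_indices(vals.shape[0], k=1)
                rows[sid] = vals[iu]
            block = pd.DataFrame.from_dict(rows, orient="index")
            block.columns = [f"fc_{name}_e{i}" for i in range(block.shape[1])]
            blocks.append(block)
    if "power" in want:
        if power is None:
            raise ValueError(f"combo {combo} requires a power block")
        blocks.append(power.add_prefix("power_"))
    if "pac" in want:
        if pac_table is None:
            raise ValueError(f"combo {combo} requires a pac_table")
        pac_cols = [c for c in ("theta_beta_mi", "theta_gamma_mi") if c in pac_table]
        wide = pac_table.pivot(index="subject_id", columns="roi", values=pac_cols)
        wide.columns = [f"pac_{band}_{roi}" for band, roi in wide.columns]
        blocks.append(wide)

    joined = pd.concat(blocks, axis=1, join="outer").sort_index()
    if joined.isna().any().any():
        missing = joined.index[joined.isna().any(axis=1)].tolist()
        raise ValueError(f"subjects missing from some feature block: {missing}")

    if labels is None:
        if pac_table is None or "group" not in pac_table:
            raise ValueError("labels required when pac_table carries no groups")
        labels = pac_table.drop_duplicates("subject_id").set_index("subject_id")["group"]
    labels = pd.Series(labels).reindex(joined.index)
    if labels.isna().any():
        raise ValueError(
            f"no label for subjects: {labels.index[labels.isna()].tolist()}"
        )
    return FeatureTable(features=joined, labels=labels.rename("label"))


def fisher_scores(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature discriminant ratio (μ₁−μ₂)² / (s₁² + s₂²)."""
    classes = np.unique(y)
    a, b = x[y == classes[0]], x[y == classes[1]]
    num = (a.mean(axis=0) - b.mean(axis=0)) ** 2
    den = a.var(axis=0, ddof=1) + b.var(axis=0, ddof=1)
    return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)


def fisher_direction(x: np.ndarray, y: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    """Canonical discriminant direction S_w⁻¹ (μ₁ − μ₂), unit norm."""
    classes = np.unique(y)
    a, b = x[y == classes[0]], x[y == classes[1]]
    sw = np.cov(a.T, ddof=1) * (len(a) - 1) + np.cov(b.T, ddof=1) * (len(b) - 1)
    sw = np.atleast_2d(sw)
    eps = ridge * np.trace(sw) / sw.shape[0] if np.trace(sw) > 0 else ridge
    try:
        w = np.linalg.solve(sw + eps * np.eye(sw.shape[0]), a.mean(0) - b.mean(0))
    except np.linalg.LinAlgError:  # pragma: no cover
        w = a.mean(0) - b.mean(0)
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


class _FoldReducer:
    """Z-scoring + Fisher reduction fit on a training fold only."""

    def __init__(self, method: str = "score", m: int = 10):
        if method not in ("score", "lda", "none"):
            raise ValueError("method must be 'score', 'lda' or 'none'")
        self.method = method
        self.m = m

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_FoldReducer":
        self.mean_ = x.mean(axis=0)
        sd = x.std(axis=0, ddof=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        z = (x - self.mean_) / self.sd_
        if self.method == "score":
            scores = fisher_scores(z, y)
            m = min(self.m, z.shape[1]) if self.m > 0 else z.shape[1]
            self.keep_ = np.argsort(scores)[::-1][:m]
        elif self.method == "lda":
            self.w_ = fisher_direction(z, y)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        z = (np.atleast_2d(x) - self.mean_) / self.sd_
        if self.method == "score":
            return z[:, self.keep_]
        if self.method == "lda":
            return z @ self.w_[:, None]
        return z


def fisher_reduce(
    ft: FeatureTable, n_components: int = 10, method: str = "score"
) -> FeatureTable:
    """Whole-table Fisher reduction (no cross-validation — exploratory).

    ``n_components=0`` is an identity pass-through. For honest
    generalisation estimates use :func:`knn_loocv`, which refits the
    reduction inside each fold.
    """
    if n_components == 0:
        return ft
    x = ft.features.to_numpy(dtype=float)
    y = ft.labels.to_numpy()
    red = _FoldReducer(method=method, m=n_components).fit(x, y)
    z = red.transform(x)
    cols = (
        [ft.features.columns[i] for i in red.keep_]
        if method == "score"
        else [f"ld{i}" for i in range(z.shape[1])]
    )
    return FeatureTable(
        features=pd.DataFrame(z, index=ft.features.index, columns=cols),
        labels=ft.labels,
    )


def knn_loocv(
    ft: FeatureTable,
    k: int = 5,
    n_components: int = 10,
    reduce_method: str = "score",
    feature_set: str = "features",
    seed: int = 0,
    positive: str = POSITIVE_CLASS,
) -> CvReport:
    """Leave-one-out KNN with fold-wise scaling and Fisher reduction."""
    from sklearn.neighbors import KNeighborsClassifier

    x = ft.features.to_numpy(dtype=float)
    y = ft.labels.to_numpy()
    n = len(y)
    if k >= n:
        raise ValueError(f"k={k} must be below the number of subjects ({n})")
    if k % 2 == 0:
        raise ValueError("use odd k to avoid ties in the two-class vote")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("LOOCV report is defined for two classes")
    if positive not in classes:
        positive = classes[0]
    negative = classes[classes != positive][0]

    preds = np.empty(n, dtype=object)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        red = _FoldReducer(method=reduce_method, m=n_components).fit(x[mask], y[mask])
        clf = KNeighborsClassifier(n_neighbors=k).fit(red.transform(x[mask]), y[mask])
        preds[i] = clf.predict(red.transform(x[i]))[0]

    tp = int(np.sum((preds == positive) & (y == positive)))
    tn = int(np.sum((preds == negative) & (y == negative)))
    fp = int(np.sum((preds == positive) & (y == negative)))
    fn = int(np.sum((preds == negative) & (y == positive)))
    n_pos, n_neg = tp + fn, tn + fp
    return CvReport(
        feature_set=feature_set,
        accuracy=(tp + tn) / n,
        sensitivity=tp / n_pos if n_pos else float("nan"),
        specificity=tn / n_neg if n_neg else float("nan"),
        tp=tp, tn=tn, fp=fp, fn=fn,
        k=k,
        n_components=n_components,
        seed=seed,
        predictions=tuple(str(p) for p in preds),
    )


def feature_ablation(
    tables: Mapping[str, FeatureTable],
    k: int = 5,
    n_components: int = 10,
    reduce_method: str = "score",
    seed: int = 0,
) -> list[CvReport]:
    """LOOCV every feature combination; identical folds, sorted by accuracy."""
    reports = [
        knn_loocv(
            ft, k=k, n_components=n_components, reduce_method=reduce_method,
            feature_set=name, seed=seed,
        )
        for name, ft in tables.items()
    ]
    return sorted(reports, key=lambda r: r.accuracy, reverse=True)
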