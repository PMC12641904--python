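"""CNN classification of subjects from their 50-point recovery curves.

Subjects are classified as AMD or Control from the ordered ramp-cycle
amplitudes (optionally with age appended as a 51st feature), under stratified
five-fold cross-validation.  Per fold, features are standardized with
training-fold statistics only, an inner stratified validation split is carved
from the training portion for early stopping, and the held-out fold is
scored.  Sensitivity treats AMD as the positive class.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from .cnn import CNNConfig, CurveCNN

__all__ = [
    "FeatureMatrix",
    "CVConfig",
    "FoldResult",
    "CVResult",
    "build_features",
    "standardize",
    "build_and_train_cnn",
    "cross_validate",
]

POSITIVE_CLASS = "AMD"
LABELS = ("Control", "AMD")  # index 1 = positive


@dataclass(frozen=True)
class FeatureMatrix:
    """subjects x features matrix with aligned labels."""

    x: np.ndarray
    labels: np.ndarray  # strings, {AMD, Control}
    subject_ids: tuple[str, ...]
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.x) != len(self.labels) or len(self.x) != len(self.subject_ids):
            raise ValueError("rows of x, labels and subject_ids must align")

    @property
    def n_subjects(self) -> int:
        return len(self.x)

    @property
    def y_index(self) -> np.ndarray:
        """0 = Control, 1 = AMD."""
        return (self.labels == POSITIVE_CLASS).astype(int)

    @property
    def y_onehot(self) -> np.ndarray:
        y = self.y_index
        out = np.zeros((len(y), 2))
        out[np.arange(len(y)), y] = 1.0
        return out

    def subset(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            x=self.x[idx],
            labels=self.labels[idx],
            subject_ids=tuple(np.asarray(self.subject_ids)[idx]),
            feature_names=self.feature_names,
        )


@dataclass(frozen=True)
class CVConfig:
    n_folds: int = 5
    seed: int = 0
    stratified: bool = True
    cnn: CNNConfig = field(default_factory=CNNConfig)

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def build_features(
    table: pd.DataFrame,
    include_age: bool = False,
    max_missing_fraction: float = 0.4,
) -> FeatureMatrix:
    """One row per subject: the 50 ramp amplitudes ordered by dark duration.

    Missing cycles are imputed by linear interpolation over dark duration
    from the subject's neighbouring cycles (edge gaps take the nearest
    value).  Subjects with more than ``max_missing_fraction`` missing cycles
    are excluded with a warning.
    """
    ramp = table[table["phase"] == "ramp"]
    if ramp.empty:
        raise ValueError("amplitude table has no ramp rows")
    darks = np.sort(ramp["dark_ms"].unique())
    rows, labels, sids = [], [], []
    for sid, sub in ramp.groupby("subject_id", sort=True):
        sub = sub.sort_values("dark_ms")
        ok = sub[sub["missing_reason"] == ""].dropna(subset=["amplitude"])
        n_missing = len(darks) - len(ok)
        if n_missing > max_missing_fraction * len(darks):
            warnings.warn(
                f"subject {sid}: {n_missing}/{len(darks)} ramp cycles missing; excluded",
                stacklevel=2,
            )
            continue
        amps = np.interp(darks, ok["dark_ms"].to_numpy(), ok["amplitude"].to_numpy())
        feats = list(amps)
        if include_age:
            feats.append(float(sub["age_years"].iloc[0]))
        rows.append(feats)
        labels.append(str(sub["group"].iloc[0]))
        sids.append(str(sid))
    names = [f"amp_{int(d)}ms" for d in darks] + (["age_years"] if include_age else [])
    return FeatureMatrix(
        x=np.asarray(rows, dtype=float),
        labels=np.asarray(labels),
        subject_ids=tuple(sids),
        feature_names=tuple(names),
    )


def standardize(
    train: FeatureMatrix, apply_to: FeatureMatrix
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Per-feature z-score with training statistics only (no leakage).

    Zero-variance features are centered and left unscaled.
    """
    if train.n_subjects == 0:
        raise ValueError("training matrix is empty")
    mean = train.x.mean(axis=0)
    sd = train.x.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)

    def tf(fm: FeatureMatrix) -> FeatureMatrix:
        return FeatureMatrix(
            x=(fm.x - mean) / sd,
            labels=fm.labels,
            subject_ids=fm.subject_ids,
            feature_names=fm.feature_names,
        )

    return tf(train), tf(apply_to)


def build_and_train_cnn(
    train: FeatureMatrix,
    val: FeatureMatrix,
    cfg: CNNConfig,
    rng: np.random.Generator,
) -> CurveCNN:
    """Train the 1-D CNN on standardized features with early stopping."""
    model = CurveCNN(input_len=train.x.shape[1], cfg=cfg)
    model.init_params(rng)
    model.fit(train.x, train.y_onehot, val.x, val.y_onehot, rng)
    return model


@dataclass(frozen=True)
class FoldResult:
    fold: int
    n: int
    accuracy: float
    sensitivity: float
    specificity: float
    confusion: dict  # tp, fn, fp, tn (AMD positive)


@dataclass(frozen=True)
class CVResult:
    folds: tuple[FoldResult, ...]
    mean_accuracy: float
    sd_accuracy: float
    mean_sensitivity: float
    sd_sensitivity: float
    mean_specificity: float
    sd_specificity: float
    pooled_accuracy: float  # from the summed confusion matrix; reported separately

    def to_dict(self) -> dict:
        return {
            "folds": [
                {
                    "fold": f.fold,
                    "n": f.n,
                    "accuracy": f.accuracy,
                    "sensitivity": f.sensitivity,
                    "specificity": f.specificity,
                    "confusion": f.confusion,
                }
                for f in self.folds
            ],
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "mean_sensitivity": self.mean_sensitivity,
            "sd_sensitivity": self.sd_sensitivity,
            "mean_specificity": self.mean_specificity,
            "sd_specificity": self.sd_specificity,
            "pooled_accuracy": self.pooled_accuracy,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _score_fold(fold: int, y_true: np.ndarray, y_pred: np.ndarray) -> FoldResult:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    n = len(y_true)
    return FoldResult(
        fold=fold,
        n=n,
        accuracy=(tp + tn) / n,
        sensitivity=tp / (tp + fn) if (tp + fn) else float("nan"),
        specificity=tn / (tn + fp) if (tn + fp) else float("nan"),
        confusion={"tp": tp, "fn": fn, "fp": fp, "tn": tn},
    )


def cross_validate(features: FeatureMatrix, cfg: CVConfig | None = None) -> CVResult:
    """Stratified k-fold cross-validation of the CNN classifier.

    Fold assignment, inner validation split, weight initialisation and
    dropout are all driven by ``cfg.seed``, so repeated runs are identical.
    """
    if cfg is None:
        cfg = CVConfig()
    y = features.y_index
    counts = np.bincount(y, minlength=2)
    if cfg.stratified and counts.min() < cfg.n_folds:
        raise ValueError(
            f"stratified CV needs >= {cfg.n_folds} subjects per class; got {counts.tolist()}"
        )
    if cfg.stratified:
        splitter = StratifiedKFold(
            n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed
        )
    else:
        splitter = KFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2**20]))
    fold_results = []
    pooled = {"tp": 0, "fn": 0, "fp": 0, "tn": 0}
    for fold, (tr_idx, te_idx) in enumerate(splitter.split(features.x, y)):
        if not cfg.stratified and len(np.unique(y[tr_idx])) < 2:
            raise ValueError(
                "a class is absent from a training fold; use stratified=True"
            )
        train_all = features.subset(tr_idx)
        test = features.subset(te_idx)
        y_tr = train_all.y_index
        if np.bincount(y_tr, minlength=2).min() < 2:
            raise ValueError(
                "training fold too small to carve a stratified validation subset"
            )
        inner_tr, inner_val = train_test_split(
            np.arange(train_all.n_subjects),
            test_size=cfg.cnn.val_fraction,
            stratify=y_tr,
            random_state=cfg.seed + fold,
        )
        # standardization statistics come from the training fold only
        train_std, test_std = standardize(train_all, test)
        model = build_and_train_cnn(
            train_std.subset(inner_tr), train_std.subset(inner_val), cfg.cnn, rng
        )
        y_pred = model.predict(test_std.x)
        res = _score_fold(fold, test.y_index, y_pred)
        for k in pooled:
            pooled[k] += res.confusion[k]
        fold_results.append(res)
    acc = np.array([f.accuracy for f in fold_results])
    sens = np.array([f.sensitivity for f in fold_results])
    spec = np.array([f.specificity for f in fold_results])
    n_pooled = sum(pooled.values())
    return CVResult(
        folds=tuple(fold_results),
        mean_accuracy=float(acc.mean()),
        sd_accuracy=float(acc.std(ddof=1)) if len(acc) > 1 else 0.0,
        mean_sensitivity=float(np.nanmean(sens)),
        sd_sensitivity=float(np.nanstd(sens, ddof=1)) if len(sens) > 1 else 0.0,
        mean_specificity=float(np.nanmean(spec)),
        sd_specificity=float(np.nanstd(spec, ddof=1)) if len(spec) > 1 else 0.0,
        pooled_accuracy=(pooled["tp"] + pooled["tn"]) / n_pooled,
    )
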