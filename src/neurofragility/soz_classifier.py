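"""Channel-level SOZ prediction from fragility heatmaps.

Each retained channel is summarized by seven montage-length-invariant
statistics of its normalized fragility time course; a random forest trained
across patients (labels = clinician SOZE flags) classifies channels as
SOZ/NSOZ under leave-one-patient-out (LOPO) cross-validation, and the
predicted channel set is scored against both the clinician SOZE and the
treatment-target SOZC by precision and recall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .fragility import FragilityMap
from .io_formats import ChannelAnnotation

FEATURE_COLUMNS = ["mean", "sd", "median", "q10", "q90", "top_decile_frac", "n_windows"]


@dataclass
class PatientMetrics:
    """Per-patient concordance of predicted SOZ with SOZE and SOZC.

    Each value is in [0, 1] or ``None`` when its denominator is zero
    (e.g. precision with no predicted-positive channels) — never silently 0.
    """

    precision_soze: float | None
    recall_soze: float | None
    precision_sozc: float | None
    recall_sozc: float | None

    def __post_init__(self) -> None:
        for name in ("precision_soze", "recall_soze", "precision_sozc", "recall_sozc"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def as_dict(self) -> dict:
        return {
            "precision_soze": self.precision_soze,
            "recall_soze": self.recall_soze,
            "precision_sozc": self.precision_sozc,
            "recall_sozc": self.recall_sozc,
        }


@dataclass
class LopoResult:
    """Out-of-fold LOPO predictions plus a final model trained on all patients."""

    model: RandomForestClassifier
    predictions: dict[str, pd.DataFrame]  # patient_id -> per-channel frame
    fold_train_patients: dict[str, list[str]]

    def patient_pred(self, patient_id: str) -> np.ndarray:
        return self.predictions[patient_id]["pred"].to_numpy(dtype=bool)


def extract_channel_features(fmap: FragilityMap) -> pd.DataFrame:
    """Per-channel summary features of the normalized fragility map.

    Features: mean, SD, median, 10th and 90th percentile over windows, the
    fraction of windows in which the channel sits in the *recording's* top
    decile of normalized fragility, and the window count.  Index = channel
    name.
    """
    if fmap.normalized is None:
        raise ValueError("normalized map required; call normalize_map first")
    if fmap.n_windows < 2:
        raise ValueError("need at least 2 windows to summarize a fragility time course")
    values = fmap.normalized
    top_thr = np.quantile(values, 0.9)
    feats = pd.DataFrame(
        {
            "mean": values.mean(axis=1),
            "sd": values.std(axis=1),
            "median": np.median(values, axis=1),
            "q10": np.quantile(values, 0.1, axis=1),
            "q90": np.quantile(values, 0.9, axis=1),
            "top_decile_frac": (values >= top_thr).mean(axis=1),
            "n_windows": float(fmap.n_windows),
        },
        index=pd.Index(fmap.channel_names, name="channel"),
    )
    if not np.isfinite(feats.to_numpy()).all():
        raise ValueError("non-finite channel features")
    return feats


def _stack_cohort(
    cohort: list[tuple[str, pd.DataFrame, ChannelAnnotation]]
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    frames, labels, owners = [], [], []
    for pid, feats, ann in cohort:
        sub = ann.subset(list(feats.index))
        frames.append(feats[FEATURE_COLUMNS])
        labels.append(sub.is_soze)
        owners.append(np.full(len(feats), pid, dtype=object))
    X = pd.concat(frames, axis=0)
    return X, np.concatenate(labels), np.concatenate(owners)


def train_and_crossvalidate(
    cohort: list[tuple[str, pd.DataFrame, ChannelAnnotation]],
    seed: int,
    n_trees: int = 500,
    threshold: float = 0.5,
) -> LopoResult:
    """Leave-one-patient-out random-forest SOZ classification.

    Parameters
    ----------
    cohort
        Triplets ``(patient_id, channel_features, annotation)``; annotations
        supply the SOZE training labels.  Each patient needs >= 1 SOZE
        channel and the cohort >= 2 patients.
    seed
        Fixed seed; identical seeds reproduce predictions bit-exactly.
    n_trees, threshold
        Forest size and the probability cut for calling a channel SOZ.

    The forest uses sqrt-features and balanced class weights.  A training
    fold whose labels collapse to a single class is an error naming the fold.
    """
    if len(cohort) < 2:
        raise ValueError("LOPO cross-validation needs at least 2 patients")
    for pid, feats, ann in cohort:
        if not ann.subset(list(feats.index)).is_soze.any():
            raise ValueError(f"patient {pid} has no SOZE channel; labels unusable")
    ids = [pid for pid, _, _ in cohort]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids in cohort")
    X_all, y_all, owner = _stack_cohort(cohort)

    def make_forest() -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            class_weight="balanced",
            random_state=seed,
            n_jobs=1,
        )

    predictions: dict[str, pd.DataFrame] = {}
    fold_train: dict[str, list[str]] = {}
    for pid, feats, _ in cohort:
        train_mask = owner != pid
        y_train = y_all[train_mask]
        if len(np.unique(y_train)) < 2:
            raise ValueError(f"training fold holding out patient {pid} has a single class")
        clf = make_forest()
        clf.fit(X_all[train_mask], y_train)
        proba = _soz_probability(clf, feats[FEATURE_COLUMNS])
        predictions[pid] = pd.DataFrame(
            {"proba": proba, "pred": proba >= threshold}, index=feats.index
        )
        fold_train[pid] = [p for p in ids if p != pid]

    final = make_forest()
    final.fit(X_all, y_all)
    return LopoResult(model=final, predictions=predictions, fold_train_patients=fold_train)


def _soz_probability(model: RandomForestClassifier, X: pd.DataFrame) -> np.ndarray:
    proba = model.predict_proba(X)
    classes = list(model.classes_)
    if True not in classes:
        return np.zeros(len(X))
    return proba[:, classes.index(True)]


def predict_channels(model: RandomForestClassifier, features: pd.DataFrame, threshold: float = 0.5) -> np.ndarray:
    """Binary SOZ call per channel: 1 where P(SOZ) >= threshold."""
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature schema mismatch; missing columns: {missing}")
    return _soz_probability(model, features[FEATURE_COLUMNS]) >= threshold


def precision_recall(pred: np.ndarray, truth: np.ndarray) -> tuple[float | None, float | None]:
    """Precision = TP/(TP+FP) and recall = TP/(TP+FN) of binary channel sets.

    A zero denominator yields ``None`` (undefined), never 0.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: pred {pred.shape} vs truth {truth.shape}")
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    return precision, recall


def score_patient(pred: np.ndarray, ann: ChannelAnnotation, channel_names: list[str]) -> PatientMetrics:
    """Score one patient's predicted SOZ set against SOZE and SOZC labels."""
    sub = ann.subset(list(channel_names))
    p_e, r_e = precision_recall(pred, sub.is_soze)
    p_c, r_c = precision_recall(pred, sub.is_sozc)
    return PatientMetrics(precision_soze=p_e, recall_soze=r_e, precision_sozc=p_c, recall_sozc=r_c)
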