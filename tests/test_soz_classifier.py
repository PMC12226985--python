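"""soz_classifier: features, LOPO random forest, precision/recall scoring."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from neurofragility.fragility import FragilityMap
from neurofragility.io_formats import ChannelAnnotation
from neurofragility.preprocess import WindowPlan
from neurofragility.soz_classifier import (
    FEATURE_COLUMNS,
    PatientMetrics,
    extract_channel_features,
    precision_recall,
    predict_channels,
    score_patient,
    train_and_crossvalidate,
)


def _map_from_normalized(norm):
    norm = np.asarray(norm, dtype=float)
    n, w = norm.shape
    plan = WindowPlan(win_len=125, hop=63, starts=[63 * i for i in range(w)], fs=500.0)
    return FragilityMap(
        raw=np.ones_like(norm),
        channel_names=[f"c{i}" for i in range(n)],
        window_plan=plan,
        normalized=norm,
    )


class TestExtractChannelFeatures:
    def test_constant_map(self):
        feats = extract_channel_features(_map_from_normalized(np.full((3, 10), 0.5)))
        row = feats.iloc[0]
        assert row["mean"] == 0.5
        assert row["sd"] == 0.0
        assert row["q10"] == row["median"] == row["q90"] == 0.5
        assert row["n_windows"] == 10

    def test_column_max_channel_has_full_top_decile(self):
        rng = np.random.default_rng(0)
        norm = rng.uniform(0, 0.8, size=(5, 40))
        norm[2, :] = 1.0  # the per-window maximum everywhere
        feats = extract_channel_features(_map_from_normalized(norm))
        assert feats.loc["c2", "top_decile_frac"] == 1.0

    def test_loop_oracle(self):
        rng = np.random.default_rng(1)
        norm = rng.uniform(0, 1, size=(6, 30))
        feats = extract_channel_features(_map_from_normalized(norm))
        thr = np.quantile(norm, 0.9)
        for i in range(6):
            ch = norm[i]
            assert feats.iloc[i]["mean"] == pytest.approx(ch.mean())
            assert feats.iloc[i]["sd"] == pytest.approx(ch.std())
            assert feats.iloc[i]["median"] == pytest.approx(np.median(ch))
            assert feats.iloc[i]["q10"] == pytest.approx(np.quantile(ch, 0.1))
            assert feats.iloc[i]["q90"] == pytest.approx(np.quantile(ch, 0.9))
            assert feats.iloc[i]["top_decile_frac"] == pytest.approx(np.mean(ch >= thr))

    def test_quantile_ordering_invariant(self):
        rng = np.random.default_rng(2)
        feats = extract_channel_features(_map_from_normalized(rng.uniform(0, 1, (8, 25))))
        assert (feats["q10"] <= feats["median"]).all()
        assert (feats["median"] <= feats["q90"]).all()
        assert feats["top_decile_frac"].between(0, 1).all()

    def test_too_few_windows(self):
        with pytest.raises(ValueError, match="2 windows"):
            extract_channel_features(_map_from_normalized(np.ones((3, 1))))

    def test_requires_normalized(self):
        fmap = _map_from_normalized(np.ones((3, 5)))
        fmap.normalized = None
        with pytest.raises(ValueError, match="normalize"):
            extract_channel_features(fmap)


def _synthetic_cohort(n_patients, n_channels, seed, separable=True):
    """Cohort of feature frames where 'mean' separates SOZ iff separable."""
    rng = np.random.default_rng(seed)
    cohort = []
    for p in range(n_patients):
        soze = np.zeros(n_channels, dtype=bool)
        soze[rng.choice(n_channels, 2, replace=False)] = True
        mean = np.where(soze, rng.uniform(0.8, 1.0, n_channels), rng.uniform(0.0, 0.2, n_channels))
        if not separable:
            mean = rng.uniform(0, 1, n_channels)
        feats = pd.DataFrame(
            {
                "mean": mean,
                "sd": rng.uniform(0, 0.1, n_channels),
                "median": mean,
                "q10": mean * 0.9,
                "q90": np.minimum(mean * 1.1, 1.0),
                "top_decile_frac": mean,
                "n_windows": 78.0,
            },
            index=pd.Index([f"c{i}" for i in range(n_channels)], name="channel"),
        )
        names = list(feats.index)
        ann = ChannelAnnotation(names, soze, soze.copy(), np.zeros(n_channels, dtype=bool))
        cohort.append((f"P{p}", feats, ann))
    return cohort


class TestTrainAndCrossvalidate:
    def test_separable_cohort_perfect(self):
        cohort = _synthetic_cohort(4, 10, seed=0)
        res = train_and_crossvalidate(cohort, seed=7, n_trees=100)
        for pid, feats, ann in cohort:
            assert np.array_equal(res.patient_pred(pid), ann.is_soze)

    def test_permutation_null_balanced_accuracy(self):
        """With labels shuffled within patients, out-of-fold balanced accuracy
        hovers at chance (0.5) on average."""
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            cohort = []
            for pid, feats, ann in _synthetic_cohort(6, 20, seed=seed):
                perm = rng.permutation(len(ann.channel_names))
                soze = ann.is_soze[perm]
                if not soze.any():
                    soze[0] = True
                cohort.append(
                    (pid, feats, ChannelAnnotation(ann.channel_names, soze, soze.copy(), ann.is_bad))
                )
            res = train_and_crossvalidate(cohort, seed=seed, n_trees=60)
            for pid, feats, ann in cohort:
                pred = res.patient_pred(pid)
                truth = ann.is_soze
                tpr = (pred & truth).sum() / max(truth.sum(), 1)
                tnr = (~pred & ~truth).sum() / max((~truth).sum(), 1)
                accs.append((tpr + tnr) / 2)
        assert 0.4 <= np.mean(accs) <= 0.6

    def test_determinism_same_seed(self):
        cohort = _synthetic_cohort(3, 12, seed=5, separable=False)
        for pid, feats, ann in cohort:
            ann.is_soze[:2] = True
        a = train_and_crossvalidate(cohort, seed=42, n_trees=80)
        b = train_and_crossvalidate(cohort, seed=42, n_trees=80)
        for pid, _, _ in cohort:
            pd.testing.assert_frame_equal(a.predictions[pid], b.predictions[pid])

    def test_lopo_excludes_held_out_patient(self):
        cohort = _synthetic_cohort(4, 8, seed=1)
        res = train_and_crossvalidate(cohort, seed=0, n_trees=20)
        for pid, _, _ in cohort:
            assert pid not in res.fold_train_patients[pid]
            assert len(res.fold_train_patients[pid]) == 3

    def test_errors(self):
        cohort = _synthetic_cohort(1, 8, seed=0)
        with pytest.raises(ValueError, match="2 patients"):
            train_and_crossvalidate(cohort, seed=0)
        cohort = _synthetic_cohort(2, 8, seed=0)
        # make the fold training on patient 1 single-class (all SOZ)
        pid, feats, ann = cohort[1]
        allsoz = np.ones(len(ann.channel_names), dtype=bool)
        cohort[1] = (pid, feats, ChannelAnnotation(ann.channel_names, allsoz, allsoz.copy(), ann.is_bad))
        with pytest.raises(ValueError, match="single class"):
            train_and_crossvalidate(cohort, seed=0, n_trees=10)


class TestPredictAndScore:
    def test_threshold_convention(self):
        class Stub:
            classes_ = np.array([False, True])

            def predict_proba(self, X):
                p = np.array([0.9, 0.2, 0.5])
                return np.column_stack([1 - p, p])

        feats = _synthetic_cohort(1, 3, seed=0)[0][1]
        assert predict_channels(Stub(), feats, 0.5).tolist() == [True, False, True]
        assert predict_channels(Stub(), feats, 1.0).tolist() == [False, False, False]
        assert predict_channels(Stub(), feats, 0.0).tolist() == [True, True, True]

    def test_schema_mismatch(self):
        class Stub:
            classes_ = np.array([False, True])

            def predict_proba(self, X):  # pragma: no cover
                return np.zeros((len(X), 2))

        with pytest.raises(ValueError, match="schema"):
            predict_channels(Stub(), pd.DataFrame({"mean": [0.1]}))

    def test_precision_recall_examples(self):
        truth = np.array([1, 1, 0, 0], dtype=bool)
        pred = np.array([1, 1, 1, 1], dtype=bool)
        assert precision_recall(pred, truth) == (0.5, 1.0)
        assert precision_recall(truth, truth) == (1.0, 1.0)
        p, r = precision_recall(np.zeros(4, dtype=bool), truth)
        assert p is None
        assert r == 0.0

    def test_precision_recall_confusion_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            pred = rng.integers(0, 2, 20).astype(bool)
            truth = rng.integers(0, 2, 20).astype(bool)
            p, r = precision_recall(pred, truth)
            tp = sum(a and b for a, b in zip(pred, truth))
            fp = sum(a and not b for a, b in zip(pred, truth))
            fn = sum(b and not a for a, b in zip(pred, truth))
            assert p == (tp / (tp + fp) if tp + fp else None)
            assert r == (tp / (tp + fn) if tp + fn else None)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            precision_recall(np.zeros(3, dtype=bool), np.zeros(4, dtype=bool))

    def test_score_patient_dual_comparison(self):
        names = ["a", "b", "c", "d"]
        ann = ChannelAnnotation(
            names,
            np.array([1, 1, 0, 0], dtype=bool),
            np.array([1, 1, 1, 0], dtype=bool),
            np.zeros(4, dtype=bool),
        )
        pred = np.array([1, 0, 1, 0], dtype=bool)
        m = score_patient(pred, ann, names)
        assert m.precision_soze == 0.5 and m.recall_soze == 0.5
        assert m.precision_sozc == 1.0 and m.recall_sozc == pytest.approx(2 / 3)

    def test_metrics_range_validated(self):
        with pytest.raises(ValueError, match="outside"):
            PatientMetrics(1.5, 0.5, 0.5, 0.5)
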