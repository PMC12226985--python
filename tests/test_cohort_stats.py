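"""cohort_stats: paired t-tests, logistic outcome model, Engel summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neurofragility.cohort_stats import (
    PREDICTORS,
    engel_group_summary,
    fit_outcome_model,
    paired_fragility_test,
)


def _pairs(diffs, success=True, base=0.5):
    diffs = np.asarray(diffs, dtype=float)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(len(diffs))],
            "soz_fragility": base + diffs,
            "nsoz_fragility": base,
            "success": success,
        }
    )


def _cohort_df(n, rng, coef=None, intercept=0.0):
    """Random cohort with failure probability sigmoid(intercept + coef . x)."""
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "recall_soze": rng.uniform(0, 1, n),
            "precision_soze": rng.uniform(0, 1, n),
            "recall_sozc": rng.uniform(0, 1, n),
            "precision_sozc": rng.uniform(0, 1, n),
            "rftc": rng.integers(0, 2, n),
            "surgery": rng.integers(0, 2, n),
            "mri_lesional": rng.integers(0, 2, n),
            "cc_class": rng.integers(1, 5, n),
        }
    )
    eta = np.full(n, float(intercept))
    if coef:
        for name, b in coef.items():
            eta = eta + b * df[name].to_numpy(dtype=float)
    p_fail = 1 / (1 + np.exp(-eta))
    fail = rng.random(n) < p_fail
    df["engel"] = np.where(fail, rng.integers(2, 5, n), 1)
    return df


class TestPairedFragilityTest:
    def test_textbook_t_oracle(self):
        # d = (0.1, 0.2, 0.3): t = dbar / (s_d / sqrt(n)) = 0.2/(0.1/sqrt(3))
        res = paired_fragility_test(_pairs([0.1, 0.2, 0.3]), "success")
        assert res.t_statistic == pytest.approx(2 * np.sqrt(3), abs=1e-3)
        assert res.t_statistic == pytest.approx(3.464, abs=1e-3)
        assert res.p_value == pytest.approx(0.0742, abs=1e-3)
        assert res.n_pairs == 3
        assert res.mean_difference == pytest.approx(0.2)

    def test_exactly_symmetric_differences_null(self):
        diffs = np.concatenate([np.linspace(0.01, 0.5, 50), -np.linspace(0.01, 0.5, 50)])
        res = paired_fragility_test(_pairs(diffs), "success")
        assert abs(res.t_statistic) < 1e-10
        assert res.p_value > 0.5

    def test_degenerate_variance_error(self):
        with pytest.raises(ValueError, match="variance"):
            paired_fragility_test(_pairs([0.2, 0.2, 0.2]), "success")

    def test_group_selection(self):
        df = pd.concat(
            [_pairs([0.1, 0.3, 0.2], success=True), _pairs([0.05, 0.15], success=False)],
            ignore_index=True,
        )
        assert paired_fragility_test(df, "success").n_pairs == 3
        assert paired_fragility_test(df, "failure").n_pairs == 2
        with pytest.raises(ValueError, match="group"):
            paired_fragility_test(df, "engel3")

    def test_matches_scipy_on_random_fixture(self):
        rng = np.random.default_rng(0)
        soz = rng.uniform(0.4, 0.9, 15)
        nsoz = rng.uniform(0.3, 0.8, 15)
        df = pd.DataFrame(
            {"patient_id": range(15), "soz_fragility": soz, "nsoz_fragility": nsoz, "success": True}
        )
        res = paired_fragility_test(df, "success")
        t, p = stats.ttest_rel(soz, nsoz)
        assert res.t_statistic == pytest.approx(t)
        assert res.p_value == pytest.approx(p)


class TestOutcomeModel:
    def test_single_replicate_recovery(self):
        rng = np.random.default_rng(1)
        df = _cohort_df(500, rng, coef={"recall_sozc": -2.0}, intercept=1.0)
        res = fit_outcome_model(df)
        row = res.table.loc["recall_sozc"]
        assert row["ci_lo"] <= -2.0 <= row["ci_hi"]
        assert res.table.loc["recall_sozc", "p_value"] < 0.05

    def test_constant_predictor_named(self):
        rng = np.random.default_rng(2)
        df = _cohort_df(60, rng)
        df["rftc"] = 1
        with pytest.raises(ValueError, match="rftc"):
            fit_outcome_model(df)

    def test_too_few_patients(self):
        rng = np.random.default_rng(3)
        df = _cohort_df(6, rng)
        with pytest.raises(ValueError, match="predictors"):
            fit_outcome_model(df)

    def test_ci_contains_coefficient_invariant(self):
        rng = np.random.default_rng(4)
        res = fit_outcome_model(_cohort_df(200, rng))
        t = res.table
        assert ((t["ci_lo"] <= t["coef"]) & (t["coef"] <= t["ci_hi"])).all()

    def test_separation_reported(self):
        rng = np.random.default_rng(5)
        df = _cohort_df(80, rng)
        df["engel"] = np.where(df["recall_sozc"] > 0.5, 1, 3)
        res = fit_outcome_model(df)
        assert res.separation

    def test_fitted_probabilities_and_predictor_set(self):
        rng = np.random.default_rng(6)
        res = fit_outcome_model(_cohort_df(100, rng))
        assert set(res.table.index) == set(PREDICTORS) | {"const"}


class TestEngelGroupSummary:
    def test_order_statistics_example(self):
        df = pd.DataFrame(
            {
                "patient_id": range(4),
                "engel": 4,
                "precision_soze": 0.5,
                "recall_soze": 0.5,
                "precision_sozc": 0.5,
                "recall_sozc": [0.13, 0.44, 0.80, 1.00],
            }
        )
        out = engel_group_summary(df)
        row = out[(out["engel"] == 4) & (out["metric"] == "recall_sozc")].iloc[0]
        assert row["min"] == 0.13
        assert row["max"] == 1.00
        assert row["median"] == pytest.approx(0.62)
        assert row["n"] == 4

    def test_all_equal(self):
        df = pd.DataFrame(
            {
                "patient_id": range(3),
                "engel": 2,
                "precision_soze": 0.7,
                "recall_soze": 0.7,
                "precision_sozc": 0.7,
                "recall_sozc": 0.7,
            }
        )
        out = engel_group_summary(df)
        row = out[(out["engel"] == 2) & (out["metric"] == "recall_soze")].iloc[0]
        assert row["min"] == row["q25"] == row["median"] == row["q75"] == row["max"] == 0.7

    def test_empty_group_row_emitted(self):
        df = pd.DataFrame(
            {
                "patient_id": [0],
                "engel": [1],
                "precision_soze": [0.9],
                "recall_soze": [0.9],
                "precision_sozc": [0.9],
                "recall_sozc": [0.9],
            }
        )
        out = engel_group_summary(df)
        row = out[(out["engel"] == 3) & (out["metric"] == "recall_sozc")].iloc[0]
        assert row["n"] == 0
        assert np.isnan(row["median"])

    def test_sorting_oracle(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(0, 1, 11)
        df = pd.DataFrame(
            {
                "patient_id": range(11),
                "engel": 1,
                "precision_soze": vals,
                "recall_soze": vals,
                "precision_sozc": vals,
                "recall_sozc": vals,
            }
        )
        out = engel_group_summary(df)
        row = out[(out["engel"] == 1) & (out["metric"] == "recall_sozc")].iloc[0]
        s = np.sort(vals)

        def interp_quantile(q):  # manual linear interpolation between order stats
            h = q * (len(s) - 1)
            lo = int(np.floor(h))
            hi = min(lo + 1, len(s) - 1)
            return s[lo] + (h - lo) * (s[hi] - s[lo])

        assert row["q25"] == pytest.approx(interp_quantile(0.25))
        assert row["median"] == pytest.approx(interp_quantile(0.5))
        assert row["q75"] == pytest.approx(interp_quantile(0.75))
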