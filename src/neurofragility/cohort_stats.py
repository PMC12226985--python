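"""Cohort-level statistics: paired SOZ/NSOZ fragility tests, the logistic
outcome model over concordance metrics and clinical covariates, and
Engel-group quartile summaries.

Outcome coding: the logistic model's positive class is *failure*
(Engel > 1), so a negative coefficient on a concordance metric means higher
concordance associates with seizure freedom.  Clinical complexity enters as
a single ordinal covariate (a ~30-patient cohort cannot support dummy
coding) and MRI as the binary lesional flag.  No multiple-testing
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PREDICTORS = [
    "recall_soze",
    "precision_soze",
    "recall_sozc",
    "precision_sozc",
    "rftc",
    "surgery",
    "mri_lesional",
    "cc_class",
]

METRICS = ["precision_soze", "recall_soze", "precision_sozc", "recall_sozc"]


@dataclass
class PairedTestResult:
    """Two-sided paired t-test of per-patient SOZ-vs-NSOZ mean fragility."""

    group: str
    n_pairs: int
    t_statistic: float
    p_value: float
    mean_difference: float

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("a paired t-test needs at least 2 pairs")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p-value must lie in (0, 1]")


@dataclass
class OutcomeModelResult:
    """Logistic-regression coefficient table (Wald inference).

    ``table`` has one row per predictor (+ intercept): coefficient, standard
    error, 95% CI bounds and p-value.  ``separation`` flags complete or
    quasi-complete separation detected during the fit.
    """

    table: pd.DataFrame
    converged: bool
    separation: bool
    log_likelihood: float

    def __post_init__(self) -> None:
        bad = self.table[
            (self.table["coef"] < self.table["ci_lo"]) | (self.table["coef"] > self.table["ci_hi"])
        ]
        if len(bad):
            raise ValueError(f"coefficient outside its own CI for {list(bad.index)}")

    def coef(self, predictor: str) -> float:
        return float(self.table.loc[predictor, "coef"])


def paired_fragility_test(
    pairs: pd.DataFrame, group: str
) -> PairedTestResult:
    """Paired t-test of mean SOZ vs NSOZ fragility within an outcome group.

    Parameters
    ----------
    pairs
        One row per patient with columns ``soz_fragility``, ``nsoz_fragility``
        and boolean ``success``.
    group
        ``"success"`` (Engel I) or ``"failure"`` (Engel II-IV).
    """
    if group not in ("success", "failure"):
        raise ValueError("group must be 'success' or 'failure'")
    for col in ("soz_fragility", "nsoz_fragility", "success"):
        if col not in pairs.columns:
            raise ValueError(f"pairs table missing column {col!r}")
    mask = pairs["success"].astype(bool) if group == "success" else ~pairs["success"].astype(bool)
    sub = pairs.loc[mask].dropna(subset=["soz_fragility", "nsoz_fragility"])
    if len(sub) < 2:
        raise ValueError(f"group {group!r} has {len(sub)} usable pairs; need >= 2")
    diff = (sub["soz_fragility"] - sub["nsoz_fragility"]).to_numpy()
    if np.allclose(diff.std(ddof=1), 0.0):
        raise ValueError("zero variance of paired differences; t undefined")
    t, p = stats.ttest_rel(sub["soz_fragility"], sub["nsoz_fragility"])
    return PairedTestResult(
        group=group,
        n_pairs=len(sub),
        t_statistic=float(t),
        p_value=float(p),
        mean_difference=float(diff.mean()),
    )


def fit_outcome_model(cohort_df: pd.DataFrame, maxiter: int = 200) -> OutcomeModelResult:
    """Maximum-likelihood logistic regression of surgical failure (Engel > 1).

    Predictors: the four concordance metrics, RFTC and surgery treatment
    flags, the MRI lesional flag, and ordinal clinical complexity.  Complete
    separation is detected and reported in the result rather than silently
    diverging.
    """
    import statsmodels.api as sm

    needed = PREDICTORS + ["engel"]
    missing = [c for c in needed if c not in cohort_df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    df = cohort_df.dropna(subset=PREDICTORS).copy()
    if len(df) < len(PREDICTORS) + 1:
        raise ValueError(f"n={len(df)} patients < {len(PREDICTORS) + 1} (predictors + 1)")
    X = df[PREDICTORS].astype(float)
    constant = [c for c in PREDICTORS if X[c].nunique() <= 1]
    if constant:
        raise ValueError(f"degenerate constant predictor column(s): {constant}")
    y = (df["engel"].astype(int) > 1).astype(float)
    if y.nunique() < 2:
        raise ValueError("outcome has a single class; logistic model unidentifiable")
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, Xc)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        res = model.fit(disp=0, maxiter=maxiter, method="bfgs")
    params = res.params
    # quasi/complete separation shows as exploding coefficients or perfect fit
    fitted = res.predict(Xc)
    separation = bool((np.abs(params) > 50).any() or np.all((fitted > 0.999) == (y > 0.5)))
    ci = res.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "coef": params,
            "se": res.bse,
            "ci_lo": ci[0],
            "ci_hi": ci[1],
            "p_value": res.pvalues,
        }
    )
    table.index.name = "predictor"
    return OutcomeModelResult(
        table=table,
        converged=bool(res.mle_retvals.get("converged", True)),
        separation=separation,
        log_likelihood=float(res.llf),
    )


def engel_group_summary(cohort_df: pd.DataFrame) -> pd.DataFrame:
    """Quartile table of each concordance metric per Engel group (1-4).

    Quantiles interpolate linearly between order statistics.  Empty groups
    get a row with count 0 and NaN statistics rather than being dropped.
    """
    missing = [c for c in METRICS + ["engel"] if c not in cohort_df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    rows = []
    for engel in (1, 2, 3, 4):
        sub = cohort_df.loc[cohort_df["engel"].astype(int) == engel]
        for metric in METRICS:
            vals = sub[metric].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                rows.append(
                    {"engel": engel, "metric": metric, "n": 0, "min": np.nan, "q25": np.nan,
                     "median": np.nan, "q75": np.nan, "max": np.nan}
                )
                continue
            rows.append(
                {
                    "engel": engel,
                    "metric": metric,
                    "n": int(vals.size),
                    "min": float(vals.min()),
                    "q25": float(np.quantile(vals, 0.25)),
                    "median": float(np.quantile(vals, 0.5)),
                    "q75": float(np.quantile(vals, 0.75)),
                    "max": float(vals.max()),
                }
            )
    return pd.DataFrame(rows)


def plot_forest(result: OutcomeModelResult, path) -> None:
    """Coefficient forest plot: dots = estimates, bars = 95% CI, dashed zero line."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    table = result.table.drop(index="const", errors="ignore")
    y = np.arange(len(table))[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.5 * len(table) + 1.5))
    ax.errorbar(
        table["coef"],
        y,
        xerr=np.vstack([table["coef"] - table["ci_lo"], table["ci_hi"] - table["coef"]]),
        fmt="o",
        color="goldenrod",
        ecolor="firebrick",
        capsize=3,
    )
    ax.axvline(0.0, linestyle="--", color="gray")
    ax.set_yticks(y)
    ax.set_yticklabels(table.index)
    ax.set_xlabel("logistic coefficient (95% CI); positive = higher Engel (worse outcome)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
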