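"""Downstream statistical readouts of the trait predictors.

All operations are pure functions of their inputs: accuracy summaries
(Pearson R, median absolute error, unadjusted two-sided p), per-species
sex-difference verdicts from tissue-stratified Wilcoxon rank-sum tests,
per-stratum age correlations, weight-adjusted accuracy, two-group Wald
contrasts for interventions, age-acceleration residuals and breed-level
aggregation. P-values are reported unadjusted throughout, matching how
these readouts are conventionally presented; callers can apply their
own multiplicity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError, UndefinedCorrelationError

logger = logging.getLogger(__name__)


def accuracy_metrics(observed, predicted) -> dict:
    """Pearson R (with two-sided p from the t transform) and median
    absolute error between observed and predicted log-trait vectors."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 3:
        raise InvalidArgumentError("need two equal-length vectors of size >= 3")
    if obs.std() == 0 or pred.std() == 0:
        raise UndefinedCorrelationError("zero variance vector")
    r, p = stats.pearsonr(obs, pred)
    return {
        "r": float(r),
        "p": float(p),
        "mae": float(np.median(np.abs(obs - pred))),
        "n": int(obs.size),
    }


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Uses the exact null distribution for small tie-free samples and the
    tie-corrected normal approximation otherwise (scipy's Mann-Whitney U,
    which is the same test).
    """
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.pvalue)


def sex_verdict(pvalues, differences, alpha: float = 0.01) -> str:
    """Species-level verdict from per-tissue (p, female-minus-male) pairs.

    ``"+"`` when at least one tissue is significant (p <= alpha) and all
    significant tissues show a positive female-minus-male difference;
    ``"-"`` symmetrically; ``"."`` otherwise (no significant tissue, or
    significant tissues disagreeing in direction). Non-significant
    tissues do not vote.
    """
    sig = [(p, d) for p, d in zip(pvalues, differences) if p <= alpha]
    if not sig:
        return "."
    if all(d > 0 for _, d in sig):
        return "+"
    if all(d < 0 for _, d in sig):
        return "-"
    return "."


@dataclass
class SexDiffResult:
    """Tissue-level statistics and per-species verdicts."""

    tissues: pd.DataFrame  # one row per qualifying (species, tissue)
    verdicts: pd.Series  # species -> "+", "-" or "."


def sex_difference(
    predictions: pd.DataFrame,
    min_n: int = 2,
    alpha: float = 0.01,
) -> SexDiffResult:
    """Classify species by tissue-consistent sex differences in
    predicted log trait.

    ``predictions`` needs columns ``species``, ``tissue``, ``sex`` and
    ``predicted``. Tissues with fewer than ``min_n`` samples of either
    sex are skipped; species with no qualifying tissue get verdict ".".
    """
    rows = []
    verdicts = {}
    for sp, sub in predictions.groupby("species", sort=True):
        pvals, diffs = [], []
        for tissue, tsub in sub.groupby("tissue", sort=True):
            f = tsub.loc[tsub["sex"] == "female", "predicted"].to_numpy()
            m = tsub.loc[tsub["sex"] == "male", "predicted"].to_numpy()
            if len(f) < min_n or len(m) < min_n:
                continue
            p = wilcoxon_rank_sum(f, m)
            d = float(f.mean() - m.mean())
            rows.append(
                {
                    "species": sp,
                    "tissue": tissue,
                    "n_female": len(f),
                    "n_male": len(m),
                    "diff": d,
                    "p": p,
                }
            )
            pvals.append(p)
            diffs.append(d)
        verdicts[sp] = sex_verdict(pvals, diffs, alpha=alpha)
    tissues = pd.DataFrame(
        rows, columns=["species", "tissue", "n_female", "n_male", "diff", "p"]
    )
    return SexDiffResult(
        tissues=tissues, verdicts=pd.Series(verdicts, name="verdict")
    )


def age_association(
    predictions: pd.DataFrame, min_n: int = 4
) -> pd.DataFrame:
    """Per-(species, tissue) Pearson correlation of prediction with age.

    Strata with fewer than ``min_n`` known-age samples, or with constant
    age, are skipped (the latter with a log entry). P-values are
    unadjusted.
    """
    rows = []
    for (sp, tissue), sub in predictions.groupby(["species", "tissue"], sort=True):
        sub = sub.dropna(subset=["age_years"])
        if len(sub) < min_n:
            continue
        ages = sub["age_years"].to_numpy(dtype=float)
        preds = sub["predicted"].to_numpy(dtype=float)
        if ages.std() == 0 or preds.std() == 0:
            logger.info("constant ages or predictions in %s/%s; skipped", sp, tissue)
            continue
        r, p = stats.pearsonr(preds, ages)
        rows.append(
            {"species": sp, "tissue": tissue, "n": len(sub),
             "r": float(r), "p": float(p)}
        )
    return pd.DataFrame(rows, columns=["species", "tissue", "n", "r", "p"])


def weight_adjusted_analysis(observed, predicted, log_weight) -> dict:
    """Does predicted life span add information beyond adult weight?

    Fits OLS of observed log life span on {predicted, log weight} and
    reports Wald p-values per covariate, plus the weight-adjusted R:
    the partial correlation of observed and predicted given weight
    (correlation of the two weight-residual vectors).
    """
    import statsmodels.api as sm

    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    wt = np.asarray(log_weight, dtype=float)
    if not (obs.shape == pred.shape == wt.shape) or obs.size < 10:
        raise InvalidArgumentError("need >= 10 complete cases")
    collinear = abs(stats.pearsonr(pred, wt)[0]) > 0.999
    if collinear:
        logger.warning("predicted and weight nearly collinear (|r| > 0.999)")
    Xm = sm.add_constant(np.column_stack([pred, wt]))
    fit = sm.OLS(obs, Xm).fit()
    res_obs = sm.OLS(obs, sm.add_constant(wt)).fit().resid
    res_pred = sm.OLS(pred, sm.add_constant(wt)).fit().resid
    r_adj, p_adj = stats.pearsonr(res_obs, res_pred)
    return {
        "p_predicted": float(fit.pvalues[1]),
        "p_weight": float(fit.pvalues[2]),
        "adjusted_r": float(r_adj),
        "adjusted_p": float(p_adj),
        "collinear": bool(collinear),
    }


def group_comparison(
    predictions: pd.DataFrame,
    treatment: str,
    control: str,
    group_col: str = "group",
    strata_cols=("tissue",),
    expected_sign: dict | int | None = None,
    min_n: int = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-stratum Wald contrast of predicted trait between two groups.

    The statistic is the two-group OLS Wald Z (mean difference over its
    pooled-variance standard error), standard normal under the null in
    large samples; p-values use the exact t reference with n-2 degrees
    of freedom so small strata stay calibrated. Strata missing either
    group (or with fewer than ``min_n`` samples in one) are skipped.
    """
    strata_cols = list(strata_cols)
    rows = []
    for key, sub in predictions.groupby(strata_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        t = sub.loc[sub[group_col] == treatment, "predicted"].to_numpy(float)
        c = sub.loc[sub[group_col] == control, "predicted"].to_numpy(float)
        if len(t) < min_n or len(c) < min_n:
            logger.info("stratum %s lacks both groups; skipped", key)
            continue
        n1, n2 = len(t), len(c)
        sp2 = ((n1 - 1) * t.var(ddof=1) + (n2 - 1) * c.var(ddof=1)) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        if se == 0:
            logger.info("stratum %s has zero pooled variance; skipped", key)
            continue
        z = float((t.mean() - c.mean()) / se)
        p = float(2 * stats.t.sf(abs(z), df=n1 + n2 - 2))
        row = dict(zip(strata_cols, key))
        exp = (
            expected_sign.get(key[0]) if isinstance(expected_sign, dict)
            else expected_sign
        )
        row.update(
            {
                "n_treatment": n1,
                "n_control": n2,
                "z": z,
                "p": p,
                "significant": p < alpha,
                "sign_concordant": None
                if exp is None
                else bool(np.sign(z) == np.sign(exp)),
            }
        )
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=strata_cols
        + ["n_treatment", "n_control", "z", "p", "significant", "sign_concordant"],
    )


def ageaccel(predicted, ages) -> np.ndarray:
    """Age acceleration: raw residual of predicted trait regressed on age.

    By construction the residuals have zero mean and zero correlation
    with chronological age.
    """
    pred = np.asarray(predicted, dtype=float)
    age = np.asarray(ages, dtype=float)
    if pred.shape != age.shape or pred.size < 3:
        raise InvalidArgumentError("need two equal-length vectors of size >= 3")
    if age.std() == 0:
        raise InvalidArgumentError("constant age")
    slope, intercept = np.polyfit(age, pred, 1)
    return pred - (intercept + slope * age)


def breed_analysis(
    predictions: pd.DataFrame,
    breed_meta: pd.DataFrame,
    max_from_median: float = 1.33,
) -> tuple[pd.DataFrame, dict]:
    """Aggregate sample predictions per breed and correlate with breed traits.

    ``predictions`` needs columns ``breed`` and ``predicted`` (log max
    life span); ``breed_meta`` is indexed by breed with columns
    ``median_lifespan_years`` and ``avg_weight_g``. A breed's maximum
    life span is derived as ``max_from_median`` times its median. All
    correlated quantities are natural-logged.
    """
    sub = predictions.loc[predictions["breed"].astype(str) != ""]
    if sub.empty:
        raise InvalidArgumentError("no breed-labelled samples")
    grouped = sub.groupby("breed")["predicted"]
    table = pd.DataFrame(
        {
            "n": grouped.size(),
            "mean_predicted_log_lifespan": grouped.mean(),
        }
    )
    table = table.join(breed_meta, how="inner")
    table["derived_max_lifespan_years"] = (
        max_from_median * table["median_lifespan_years"]
    )
    x = table["mean_predicted_log_lifespan"].to_numpy(float)
    corrs = {}
    if len(table) >= 3 and x.std() > 0:
        for name, col in (
            ("lifespan", np.log(table["derived_max_lifespan_years"])),
            ("weight", np.log(table["avg_weight_g"])),
        ):
            r, p = stats.pearsonr(x, col.to_numpy(float))
            corrs[f"r_{name}"] = float(r)
            corrs[f"p_{name}"] = float(p)
    else:
        # constant predictions: the correlation is undefined; report 0
        # with p 1 so the negative control remains summarizable
        corrs = {"r_lifespan": 0.0, "p_lifespan": 1.0,
                 "r_weight": 0.0, "p_weight": 1.0}
    return table, corrs
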