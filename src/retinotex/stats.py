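"""Three-group comparison with a random intercept per subject.

Because many subjects contribute both eyes, eye-level observations are not
independent; naive ANOVA would overstate the effective sample size.  Each
(layer, region, metric) cell is therefore analysed with a linear mixed
model ``value ~ group`` plus a per-subject random intercept, fitted by
REML, and the three pairwise group contrasts are tested with Wald tests.
No multiplicity correction is applied beyond the deliberately strict
significance threshold of p < 0.001.

When every subject contributes a single eye the random intercept is
unidentifiable and the contrast is computed as the exact one-way ANOVA
contrast it reduces to.  If a mixed fit fails or degenerates, the pair
falls back to the contrast on subject-averaged values, which respects the
one-value-per-subject information structure; a warning is logged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = ["PairResult", "ComparisonResult", "GROUP_PAIRS", "mixed_model_compare",
           "summarize_groups", "compare_two_groups"]

logger = logging.getLogger(__name__)

#: The pairwise contrasts reported for the three study arms.
GROUP_PAIRS: tuple[tuple[str, str], ...] = (
    ("H", "MSON+"),
    ("H", "MSON-"),
    ("MSON-", "MSON+"),
)

ALPHA = 0.001


@dataclass(frozen=True)
class PairResult:
    """One pairwise group contrast: difference (second minus first), SE, p."""

    group_a: str
    group_b: str
    estimate: float
    std_error: float
    p_value: float
    estimable: bool = True
    method: str = "mixed_model"

    @property
    def significant(self) -> bool:
        return self.estimable and self.p_value < ALPHA


@dataclass
class ComparisonResult:
    """All pairwise contrasts of one (layer, region, metric) cell."""

    layer: str
    region: str
    metric: str
    pairs: dict[tuple[str, str], PairResult] = field(default_factory=dict)


def _ols_contrast(
    values: np.ndarray, indicator: np.ndarray, group_a: str, group_b: str, method: str
) -> PairResult:
    """Two-sample contrast via OLS with a t-based Wald test."""
    n = len(values)
    n_b = indicator.sum()
    n_a = n - n_b
    if n_a < 2 or n_b < 2:
        return PairResult(group_a, group_b, np.nan, np.nan, np.nan, estimable=False)
    mean_a = values[indicator == 0].mean()
    mean_b = values[indicator == 1].mean()
    ss = ((values[indicator == 0] - mean_a) ** 2).sum() + (
        (values[indicator == 1] - mean_b) ** 2
    ).sum()
    df = n - 2
    s2 = ss / df
    se = float(np.sqrt(s2 * (1.0 / n_a + 1.0 / n_b)))
    estimate = float(mean_b - mean_a)
    if se == 0:
        p = 0.0 if estimate != 0 else 1.0
    else:
        p = float(2 * sps.t.sf(abs(estimate / se), df))
    return PairResult(group_a, group_b, estimate, se, p, method=method)


def compare_two_groups(data: pd.DataFrame, group_a: str, group_b: str) -> PairResult:
    """Random-intercept contrast of ``group_b`` minus ``group_a``.

    ``data`` needs columns ``group``, ``subject`` and ``value``; missing
    values are dropped.  Returns a non-estimable result when either group
    has no observations.

    Degenerate designs are routed to their exact special cases rather than
    pushed through a boundary REML fit: with one eye per subject the model
    is an ordinary one-way ANOVA contrast, and when the within-subject
    variance collapses (duplicate-eye data) the contrast is computed on
    subject means.  A REML solution whose standard error falls below the
    i.i.d. OLS bound — impossible under non-negative intra-class correlation
    and diagnostic of a failed fit — triggers a conservative fallback to the
    subject-means contrast, with a logged warning.
    """
    sub = data[data["group"].isin([group_a, group_b])].dropna(subset=["value"])
    if (sub["group"] == group_a).sum() == 0 or (sub["group"] == group_b).sum() == 0:
        return PairResult(group_a, group_b, np.nan, np.nan, np.nan, estimable=False)

    values = sub["value"].to_numpy(dtype=float)
    indicator = (sub["group"] == group_b).to_numpy(dtype=float)
    subjects = sub["subject"].to_numpy()

    # one eye per subject: the random intercept is unidentifiable and the
    # model reduces exactly to the one-way ANOVA contrast
    if pd.Series(subjects).value_counts().max() == 1:
        return _ols_contrast(values, indicator, group_a, group_b, "ols_single_eye")

    eye_level_ols = _ols_contrast(values, indicator, group_a, group_b, "ols")

    def subject_means_fallback(reason: str) -> PairResult:
        logger.warning(
            "mixed model unusable for %s vs %s (%s); using subject-means contrast",
            group_a,
            group_b,
            reason,
        )
        per_subject = sub.groupby(["subject", "group"], observed=True)["value"].mean()
        frame = per_subject.reset_index()
        v = frame["value"].to_numpy(dtype=float)
        ind = (frame["group"] == group_b).to_numpy(dtype=float)
        result = _ols_contrast(v, ind, group_a, group_b, "ols_subject_means")
        return result

    exog = pd.DataFrame({"Intercept": 1.0, "contrast": indicator})
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM(values, exog, groups=subjects)
            fit = model.fit(reml=True)
        estimate = float(fit.params["contrast"])
        se = float(fit.bse["contrast"])
        p = float(fit.pvalues["contrast"])
        if not (np.isfinite(se) and np.isfinite(p)):
            raise ValueError("non-finite inference")
        total_var = values.var(ddof=1)
        if fit.scale < 1e-8 * max(total_var, 1e-300):
            # residual variance collapsed: eyes are exact replicates of
            # their subject; the information unit is the subject
            return subject_means_fallback("within-subject variance is zero")
        if eye_level_ols.estimable and se < 0.95 * eye_level_ols.std_error:
            return subject_means_fallback(
                "REML standard error below the i.i.d. bound"
            )
        return PairResult(group_a, group_b, estimate, se, p)
    except Exception as exc:  # singular / non-converged fit
        return subject_means_fallback(str(exc))


def mixed_model_compare(
    feature_table: pd.DataFrame,
    metric: str,
    pairs: tuple[tuple[str, str], ...] = GROUP_PAIRS,
) -> list[ComparisonResult]:
    """Pairwise mixed-model contrasts for every (layer, region) cell of a metric.

    Each cell is fitted independently.  Requires at least two groups and a
    ``subject`` column; cells where a group is empty get non-estimable
    entries for the affected pairs.
    """
    table = feature_table[feature_table["metric"] == metric]
    if table.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    if table["group"].nunique() < 2:
        raise ValueError("need at least two groups to compare")

    results = []
    for (layer, region), cell in table.groupby(["layer", "region"], observed=True):
        res = ComparisonResult(layer=layer, region=region, metric=metric)
        for group_a, group_b in pairs:
            res.pairs[(group_a, group_b)] = compare_two_groups(cell, group_a, group_b)
        results.append(res)
    return results


def comparison_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Flatten comparison results into a long table (one row per contrast)."""
    rows = []
    for res in results:
        for (a, b), pr in res.pairs.items():
            rows.append(
                {
                    "layer": res.layer,
                    "region": res.region,
                    "metric": res.metric,
                    "group_a": a,
                    "group_b": b,
                    "estimate": pr.estimate,
                    "std_error": pr.std_error,
                    "p_value": pr.p_value,
                    "significant": pr.significant,
                    "estimable": pr.estimable,
                    "method": pr.method,
                }
            )
    return pd.DataFrame(rows)


def summarize_groups(feature_table: pd.DataFrame) -> pd.DataFrame:
    """Per (group, layer, region, metric): n, mean, SD, SE of eye-level values.

    Mirrors the published summary-table layout (means ± dispersion per
    group).  SD is the sample standard deviation and is missing for single
    observations; missing values are excluded from n.
    """
    table = feature_table.dropna(subset=["value"])
    grouped = table.groupby(["group", "layer", "region", "metric"], observed=True)[
        "value"
    ]
    out = grouped.agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1)).reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out
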