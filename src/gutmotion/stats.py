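"""Two-group statistics layer shared by all pipeline stages.

Normality is screened with the Shapiro-Wilk test; group differences use the
two-sided equal-variance Student's t-test with Cohen's d (pooled-sd) effect
sizes, and factorial designs use a standard two-way ANOVA decomposition.
Non-normal Shapiro outcomes do not switch the test — they are recorded and
logged prominently (Welch's t is available behind a flag for modern use).
Significance stars follow p <= 0.05 (*), <= 0.01 (**), <= 0.001 (***).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "GroupComparison",
    "stars",
    "cohens_d",
    "cohens_d_from_summary",
    "shapiro_gate",
    "two_group_test",
    "two_way_anova",
    "compare_cohorts",
]


def stars(p: float) -> str:
    """Significance stars at the 0.05 / 0.01 / 0.001 thresholds."""
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return "ns"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def cohens_d_from_summary(n1: int, mean1: float, sd1: float,
                          n2: int, mean2: float, sd2: float) -> float:
    """Cohen's d from per-group summaries using the pooled sd.

    ``d = (mean1 - mean2) / s_pooled`` with
    ``s_pooled = sqrt(((n1-1) sd1^2 + (n2-1) sd2^2) / (n1 + n2 - 2))``.
    Zero pooled variance gives d = 0 for equal means and NaN otherwise.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    s_pooled = math.sqrt(((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2))
    diff = mean1 - mean2
    if s_pooled == 0:
        return 0.0 if diff == 0 else float("nan")
    return diff / s_pooled


def cohens_d(a, b) -> float:
    """Cohen's d of two samples (pooled sd, ddof=1 within groups)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return cohens_d_from_summary(len(a), a.mean(), a.std(ddof=1),
                                 len(b), b.mean(), b.std(ddof=1))


def shapiro_gate(groups: dict, alpha: float = 0.05) -> dict:
    """Shapiro-Wilk normality screen per group.

    Returns ``{label: (p_value, is_normal)}``; groups with n < 3 are skipped
    with a warning (``(nan, None)``).  A non-normal outcome is logged but
    does not change the downstream test choice.
    """
    out = {}
    for label, values in groups.items():
        values = np.asarray(values, dtype=float)
        if values.size < 3:
            warnings.warn(f"group {label!r}: n={values.size} < 3, normality gate skipped",
                          stacklevel=2)
            out[label] = (float("nan"), None)
            continue
        p = float(sps.shapiro(values).pvalue)
        normal = p > alpha
        if not normal:
            logger.warning("group %r fails the Shapiro-Wilk normality screen (p=%.3g); "
                           "Student's t is still applied", label, p)
        out[label] = (p, normal)
    return out


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison bundle for one endpoint."""

    labels: tuple
    n: tuple
    means: tuple
    sds: tuple
    shapiro_p: tuple
    t_statistic: float
    p_value: float
    cohens_d: float
    test_used: str
    stars: str
    endpoint: str | None = None

    def to_dict(self) -> dict:
        def clean(x):
            if isinstance(x, float) and math.isnan(x):
                return None
            return x
        return {
            "endpoint": self.endpoint,
            "labels": list(self.labels),
            "n": list(self.n),
            "means": [clean(m) for m in self.means],
            "sds": [clean(s) for s in self.sds],
            "shapiro_p": [clean(s) for s in self.shapiro_p],
            "t_statistic": clean(self.t_statistic),
            "p_value": clean(self.p_value),
            "cohens_d": clean(self.cohens_d),
            "test_used": self.test_used,
            "stars": self.stars,
        }


def two_group_test(
    a,
    b,
    labels: tuple = ("group_1", "group_2"),
    welch: bool = False,
    endpoint: str | None = None,
) -> GroupComparison:
    """Two-sided Student's t-test (equal variance) with Cohen's d.

    The Shapiro-Wilk screen is run and recorded but never switches the test;
    pass ``welch=True`` to use Welch's unequal-variance t instead.  Identical
    groups give t = 0, p = 1, d = 0; zero pooled variance with unequal means
    flags d (and p) as missing.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    gate = shapiro_gate({labels[0]: a, labels[1]: b})

    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if var_a == 0 and var_b == 0:
        if diff == 0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = float("nan"), float("nan")
            warnings.warn("zero within-group variance with unequal means: "
                          "t and p undefined", stacklevel=2)
    else:
        res = sps.ttest_ind(a, b, equal_var=not welch)
        t_stat, p = float(res.statistic), float(res.pvalue)
    d = cohens_d(a, b)
    return GroupComparison(
        labels=tuple(labels),
        n=(a.size, b.size),
        means=(float(a.mean()), float(b.mean())),
        sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        shapiro_p=(gate[labels[0]][0], gate[labels[1]][0]),
        t_statistic=t_stat,
        p_value=p,
        cohens_d=d,
        test_used="welch_t" if welch else "student_t",
        stars=stars(p),
        endpoint=endpoint,
    )


def two_way_anova(
    data: pd.DataFrame,
    value: str,
    factor1: str,
    factor2: str,
) -> pd.DataFrame:
    """Two-way ANOVA: main effects and interaction (type-II sums of squares).

    Requires >= 2 levels per factor and at least one observation per cell;
    empty cells are rejected.  With a single observation in every cell the
    interaction is not estimable: an additive model is fitted and the
    interaction row is reported missing.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = data[[value, factor1, factor2]].dropna().copy()
    df.columns = ["y", "f1", "f2"]
    if df["f1"].nunique() < 2 or df["f2"].nunique() < 2:
        raise ValueError("need >= 2 levels per factor")
    cells = df.groupby(["f1", "f2"], observed=True).size().unstack()
    if cells.isna().to_numpy().any() or (cells.to_numpy() == 0).any():
        raise ValueError("empty factor cells: every combination needs >= 1 observation")
    with_interaction = int(cells.to_numpy().max()) > 1

    formula = "y ~ C(f1) + C(f2)" + (" + C(f1):C(f2)" if with_interaction else "")
    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)

    rename = {"C(f1)": factor1, "C(f2)": factor2, "C(f1):C(f2)": "interaction",
              "Residual": "residual"}
    table = table.rename(index=rename)
    if not with_interaction:
        table.loc["interaction"] = [np.nan] * table.shape[1]
        order = [factor1, factor2, "interaction", "residual"]
        table = table.loc[order]
    return table


def compare_cohorts(
    table: pd.DataFrame,
    group_col: str = "group",
    endpoints: list | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-endpoint two-group comparisons for a cohort table.

    ``table`` holds one row per animal/segment with a group-label column and
    numeric endpoint columns (e.g. contraction rate, mean interval,
    velocity).  Missing endpoint values are excluded pairwise; the per-group
    counts actually used are reported.  Exactly two groups are required.
    """
    groups = table[group_col].unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, found {list(groups)}")
    g1, g2 = sorted(groups)
    if endpoints is None:
        endpoints = [c for c in table.columns
                     if c != group_col and pd.api.types.is_numeric_dtype(table[c])]

    rows = []
    for ep in endpoints:
        a = table.loc[table[group_col] == g1, ep].dropna().to_numpy()
        b = table.loc[table[group_col] == g2, ep].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            logger.warning("endpoint %r: fewer than 2 non-missing values per group, skipped", ep)
            continue
        cmp_ = two_group_test(a, b, labels=(g1, g2), welch=welch, endpoint=ep)
        d = cmp_.to_dict()
        rows.append({
            "endpoint": ep,
            f"n_{g1}": cmp_.n[0], f"n_{g2}": cmp_.n[1],
            f"mean_{g1}": cmp_.means[0], f"mean_{g2}": cmp_.means[1],
            f"sd_{g1}": cmp_.sds[0], f"sd_{g2}": cmp_.sds[1],
            "t_statistic": d["t_statistic"], "p_value": d["p_value"],
            "cohens_d": d["cohens_d"], "stars": cmp_.stars,
        })
    return pd.DataFrame(rows).set_index("endpoint") if rows else pd.DataFrame()
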