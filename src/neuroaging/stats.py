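"""Group-level statistics layer matching the study's analysis conventions.

Mixed-design (one between-, one within-subjects factor) and between-subjects
ANOVA with Tukey HSD post hoc tests, Pearson product-moment correlations
reported as r, r^2 and two-sided p, Kaplan-Meier morbidity curves compared by
the generalized Wilcoxon (Gehan-Breslow) chi-square, and the box-plot summary
convention (quartile box, whiskers at the outermost points within 1.5 IQR of
the quartiles, points beyond classified as outliers).

The heavy lifting is delegated to pingouin (ANOVA), scipy (Tukey, Pearson)
and lifelines (survival); this module fixes the conventions — listwise
deletion of subjects with incomplete within-subject data, uncorrected
univariate mixed ANOVA by default with Greenhouse-Geisser on request, and
Gehan-Breslow weighting (w_i = n at risk) for the survival comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SurvivalRecord",
    "BoxplotSummary",
    "AnovaResult",
    "mixed_anova",
    "tukey_hsd",
    "pearson",
    "km_wilcoxon",
    "boxplot_summary",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """Time-to-event for one animal: days on study, event vs censored.

    ``event`` is true for death/removal and false for the end-of-study tissue
    collection, which censors the observation.
    """

    animal: str
    group: str
    time_days: float
    event: bool

    def __post_init__(self):
        if self.time_days <= 0:
            raise ValueError("time must be positive")


@dataclass(frozen=True)
class AnovaResult:
    """One ANOVA effect row: F, numerator/denominator df, p."""

    source: str
    F: float
    df_num: float
    df_den: float
    p: float


def mixed_anova(
    table: pd.DataFrame,
    dv: str,
    between: str,
    within: str | None = None,
    subject: str = "animal",
    correction: bool = False,
) -> tuple[list[AnovaResult], int]:
    """Mixed-design or between-subjects ANOVA.

    With a ``within`` factor, fits the univariate mixed ANOVA (between main
    effect, within main effect, interaction); without one, a one-way
    between-subjects ANOVA.  Subjects missing any within-factor level are
    dropped listwise; the second return value is the number dropped.
    ``correction=True`` applies the Greenhouse-Geisser correction to the
    within and interaction p-values (uncorrected is the default convention).
    """
    import pingouin as pg

    df = table.dropna(subset=[dv]).copy()
    if df[between].nunique() < 2:
        raise ValueError(f"between factor {between!r} needs >= 2 levels")
    n_dropped = 0
    if within is None:
        groups = [g[dv].to_numpy() for _, g in df.groupby(between)]
        if any(len(g) < 2 for g in groups):
            raise ValueError("each group needs >= 2 observations")
        f, p = sps.f_oneway(*groups)
        k = len(groups)
        n = sum(len(g) for g in groups)
        return [AnovaResult(between, float(f), k - 1, n - k, float(p))], 0

    if df[within].nunique() < 2:
        raise ValueError(f"within factor {within!r} needs >= 2 levels")
    levels = df[within].nunique()
    counts = df.groupby(subject)[within].nunique()
    complete = counts[counts == levels].index
    n_dropped = counts.size - complete.size
    df = df[df[subject].isin(complete)]
    if df[subject].nunique() <= df[between].nunique():
        raise ValueError("no residual degrees of freedom after listwise deletion")

    aov = pg.mixed_anova(data=df, dv=dv, within=within, subject=subject,
                         between=between, correction=correction)
    results = []
    for _, row in aov.iterrows():
        src = {"Interaction": f"{between} * {within}"}.get(row["Source"], row["Source"])
        p = row["p-GG-corr"] if correction and "p-GG-corr" in aov.columns and pd.notna(
            row.get("p-GG-corr")) else row["p_unc" if "p_unc" in aov.columns else "p-unc"]
        results.append(AnovaResult(src, float(row["F"]), float(row["DF1"]),
                                   float(row["DF2"]), float(p)))
    return results, int(n_dropped)


def tukey_hsd(table: pd.DataFrame, dv: str, factor: str) -> pd.DataFrame:
    """Tukey HSD adjusted p-values for all pairwise group comparisons.

    Studentized-range based adjustment over the groups of ``factor``;
    returns one row per unordered pair with the mean difference and the
    adjusted p.
    """
    groups = {k: g[dv].dropna().to_numpy() for k, g in table.groupby(factor)}
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    res = sps.tukey_hsd(*[groups[k] for k in names])
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append({
                "group_a": names[i],
                "group_b": names[j],
                "mean_diff": float(np.mean(groups[names[i]]) - np.mean(groups[names[j]])),
                "p_tukey": float(res.pvalue[i, j]),
            })
    return pd.DataFrame(rows)


def pearson(x, y) -> tuple[float, float, float]:
    """Pearson product-moment correlation: (r, r^2, two-sided p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    return float(r), float(r * r), float(p)


def km_wilcoxon(records: list[SurvivalRecord]) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan-Meier curves per group and the generalized Wilcoxon comparison.

    Product-limit survival estimates per group, and the Gehan-Breslow
    generalized Wilcoxon chi-square across all groups (weights equal to the
    number at risk, which emphasizes early events).  Returns
    (curves keyed by group, chi2, p).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    if not records:
        raise ValueError("no survival records")
    df = pd.DataFrame([(r.group, r.time_days, r.event) for r in records],
                      columns=["group", "time", "event"])
    sizes = df.groupby("group").size()
    if len(sizes) < 2:
        raise ValueError("need >= 2 groups")
    curves = {}
    for name, g in df.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(g["time"], event_observed=g["event"], label=str(name))
        curves[str(name)] = kmf.survival_function_.rename(
            columns={str(name): "survival"}).reset_index(names="time")
    res = multivariate_logrank_test(df["time"], df["group"], df["event"],
                                    weightings="wilcoxon")
    chi2 = float(res.test_statistic)
    if df["event"].sum() == 0:  # no deaths anywhere: no evidence, chi2 = 0
        chi2 = 0.0
        p = 1.0
    else:
        p = float(res.p_value)
    return curves, chi2, p


@dataclass(frozen=True)
class BoxplotSummary:
    """The study's box-plot convention for one sample.

    Box at the 25%/75% quartiles with the median midline; whiskers at the
    outermost data points within 1.5 IQR beyond the quartiles; values beyond
    those limits are outliers.
    """

    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...] = ()


def boxplot_summary(values) -> BoxplotSummary:
    """Summarize a sample by the box-plot convention (linear-interpolated quartiles)."""
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values")
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = np.sort(v[(v < lo_fence) | (v > hi_fence)])
    return BoxplotSummary(
        median=float(med), q25=float(q25), q75=float(q75),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=tuple(float(o) for o in outliers),
    )
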