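"""Statistical battery over the monthly series.

* Species-mix group comparison (months with turkey + chicken slaughter vs
  heavy-chicken-only months) on per-month percent condemnation ratios:
  Welch two-sample t test with rank-biserial (headline) and point-biserial
  effect sizes.
* Spearman rank correlation between causes with strength grading on the
  conventional |rho| bands (>=0.9 very high, 0.7-0.9 high, 0.5-0.7
  moderate, 0.3-0.5 low, <0.3 negligible).
* Per-cause seasonal inference on the stage-one annual ratios: one-way
  ANOVA with calendar month as factor and years as replicates, Tukey HSD
  pairwise contrasts, and a per-month one-sample t test against 1 (the
  "as expected for the year" value).

Months are treated as exchangeable replicates; no autocorrelation
modelling is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .data import Dataset, GroupLabel, MonthKey, assign_groups
from .errors import DegenerateSampleError, InsufficientDataError
from .indices import OVERALL

logger = logging.getLogger(__name__)

#: |rho| thresholds for correlation strength grading.
STRENGTH_BANDS = (
    (0.9, "very high"),
    (0.7, "high"),
    (0.5, "moderate"),
    (0.3, "low"),
    (0.0, "negligible"),
)


def strength_label(rho: float) -> str:
    """Grade a correlation coefficient by the standard |rho| bands."""
    if np.isnan(rho):
        return "undefined"
    a = abs(rho)
    for lo, label in STRENGTH_BANDS:
        if a >= lo:
            return label
    return "negligible"


def rank_biserial(a, b) -> float:
    """Rank-biserial correlation between two samples: 2*AUC - 1 from the
    Mann-Whitney U statistic of ``a`` vs ``b``; +1 when every value of
    ``a`` exceeds every value of ``b``, -1 for the reverse."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    u_a = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
    return 2.0 * u_a / (len(a) * len(b)) - 1.0


def _percent_ratio(rec, variable: str) -> float:
    condemned = rec.total_condemned if variable == OVERALL else rec.condemned.get(variable, 0)
    return 100.0 * condemned / rec.total_slaughtered


@dataclass
class GroupStats:
    n: int
    mean: float
    sd: float

    @property
    def se(self) -> float:
        return self.sd / math.sqrt(self.n)


@dataclass
class GroupComparison:
    """A vs B comparison of per-month percent condemnation ratios.

    Effect sizes are signed positive when group A exceeds group B. The
    headline ``effect_size`` is the rank-biserial value; the point-biserial
    coefficient is carried alongside.
    """

    variable: str
    group_a: GroupStats
    group_b: GroupStats
    t: float
    p_value: float
    rank_biserial: float
    point_biserial: float
    effect_kind: str = "rank_biserial"

    @property
    def effect_size(self) -> float:
        return self.rank_biserial if self.effect_kind == "rank_biserial" else self.point_biserial


def compare_groups(
    ds: Dataset,
    variable: str = OVERALL,
    groups: dict[MonthKey, GroupLabel] | None = None,
) -> GroupComparison:
    """Welch t test and effect sizes for one variable (overall or a cause),
    expressed per month as 100 * condemned / slaughtered, between group-A
    and group-B months."""
    groups = groups if groups is not None else assign_groups(ds)
    a_vals, b_vals = [], []
    for rec in ds.included():
        label = groups.get(rec.key, GroupLabel.UNCLASSIFIED)
        if label is GroupLabel.A:
            a_vals.append(_percent_ratio(rec, variable))
        elif label is GroupLabel.B:
            b_vals.append(_percent_ratio(rec, variable))
    if len(a_vals) < 2 or len(b_vals) < 2:
        raise InsufficientDataError(
            f"{variable}: need >=2 months per group, got A={len(a_vals)}, B={len(b_vals)}"
        )
    a = np.asarray(a_vals)
    b = np.asarray(b_vals)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    rb = rank_biserial(a, b)
    indicator = np.concatenate([np.ones(len(a)), np.zeros(len(b))])
    pb = stats.pointbiserialr(indicator, np.concatenate([a, b])).statistic
    return GroupComparison(
        variable,
        GroupStats(len(a), float(a.mean()), float(a.std(ddof=1))),
        GroupStats(len(b), float(b.mean()), float(b.std(ddof=1))),
        float(t), float(p), float(rb), float(pb),
    )


@dataclass
class CorrelationReport:
    """Pairwise Spearman correlations between causes with strength labels.

    ``rho`` is symmetric with unit diagonal; pairs involving a constant
    series are NaN (undefined, not zero) and labelled "undefined".
    """

    causes: list[str]
    rho: pd.DataFrame
    p_values: pd.DataFrame
    strength: pd.DataFrame


def spearman_matrix(ds: Dataset, causes: list[str] | None = None) -> CorrelationReport:
    """Spearman rho (average-rank ties) between causes measured as monthly
    per-slaughter percent ratios over the usable months."""
    if causes is None:
        causes = [c.code for c in ds.causes if c.asi_eligible]
    recs = ds.included()
    if len(recs) < 3:
        raise InsufficientDataError("Spearman matrix needs >=3 usable months")
    data = pd.DataFrame(
        {c: [_percent_ratio(r, c) for r in recs] for c in causes}
    )
    k = len(causes)
    rho = np.eye(k)
    pvals = np.eye(k) * 0.0
    for i in range(k):
        for j in range(i + 1, k):
            x, y = data.iloc[:, i], data.iloc[:, j]
            if x.nunique() < 2 or y.nunique() < 2:
                r, p = np.nan, np.nan
                logger.warning(
                    "constant series: Spearman undefined for (%s, %s)",
                    causes[i], causes[j],
                )
            else:
                r, p = stats.spearmanr(x, y)
            rho[i, j] = rho[j, i] = r
            pvals[i, j] = pvals[j, i] = p
    rho_df = pd.DataFrame(rho, index=causes, columns=causes)
    p_df = pd.DataFrame(pvals, index=causes, columns=causes)
    strength = rho_df.map(strength_label)
    return CorrelationReport(list(causes), rho_df, p_df, strength)


@dataclass
class OneSampleResult:
    month: int
    n: int
    mean: float
    t: float
    p_value: float


def asi_vs_one(ratios: dict[MonthKey, float], month: int) -> OneSampleResult:
    """Two-sided one-sample t test of one calendar month's across-year
    stage-one ratios against the null value 1 (100% of the expected
    condemnation for the year)."""
    vals = np.asarray([r for k, r in ratios.items() if k.month == month], dtype=float)
    if len(vals) < 2:
        raise InsufficientDataError(f"month {month}: need >=2 yearly ratios, got {len(vals)}")
    if vals.std(ddof=1) == 0:
        raise DegenerateSampleError(f"month {month}: zero variance across years")
    t, p = stats.ttest_1samp(vals, popmean=1.0)
    return OneSampleResult(month, len(vals), float(vals.mean()), float(t), float(p))


@dataclass
class MonthInference:
    """Seasonal inference for one cause: ANOVA over calendar months,
    Tukey HSD pairwise contrasts (66 pairs when all 12 months are
    present), and per-month tests against 1."""

    scope: str
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # month_1, month_2, estimate, p_adj, lower, upper, reject
    vs_one: pd.DataFrame  # month, n, mean, t, p_value (NaN where degenerate)


def asi_month_anova(ratios: dict[MonthKey, float], alpha: float = 0.05):
    """One-way ANOVA with calendar month as factor and years as
    replicates, followed by Tukey HSD. Months with fewer than two
    replicates are dropped with a warning. Returns (F, p, tukey_table)."""
    per_month: dict[int, list[float]] = {}
    for k, r in ratios.items():
        per_month.setdefault(k.month, []).append(r)
    usable = {m: v for m, v in per_month.items() if len(v) >= 2}
    for m in sorted(set(per_month) - set(usable)):
        logger.warning("calendar month %d has <2 replicates; dropped from ANOVA", m)
    if len(usable) < 2:
        raise InsufficientDataError("ANOVA needs >=2 calendar months with >=2 replicates")
    groups = [np.asarray(v) for _, v in sorted(usable.items())]
    values = np.concatenate(groups)
    if np.ptp(values) == 0:
        # All values identical: no variance anywhere, nothing to test.
        months = sorted(usable)
        pairs = [(a, b) for i, a in enumerate(months) for b in months[i + 1:]]
        tukey = pd.DataFrame(
            {
                "month_1": [a for a, _ in pairs],
                "month_2": [b for _, b in pairs],
                "estimate": 0.0,
                "p_adj": 1.0,
                "lower": 0.0,
                "upper": 0.0,
                "reject": False,
            }
        )
        return float("nan"), 1.0, tukey
    f, p = stats.f_oneway(*groups)
    labels = np.concatenate([[m] * len(v) for m, v in sorted(usable.items())])
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    tab = pd.DataFrame(
        res.summary().data[1:],
        columns=[str(c) for c in res.summary().data[0]],
    )
    tukey = pd.DataFrame(
        {
            "month_1": tab["group1"].astype(int),
            "month_2": tab["group2"].astype(int),
            "estimate": tab["meandiff"].astype(float),
            "p_adj": np.asarray(res.pvalues, dtype=float),
            "lower": tab["lower"].astype(float),
            "upper": tab["upper"].astype(float),
            "reject": np.asarray(res.reject, dtype=bool),
        }
    )
    return float(f), float(p), tukey


def month_inference(
    ratios: dict[MonthKey, float], scope: str = OVERALL, alpha: float = 0.05
) -> MonthInference:
    """Bundle the ANOVA/Tukey contrasts and the per-month one-sample tests
    for one cause's stage-one ratios."""
    f, p, tukey = asi_month_anova(ratios, alpha=alpha)
    rows = []
    for m in sorted({k.month for k in ratios}):
        try:
            r = asi_vs_one(ratios, m)
            rows.append((m, r.n, r.mean, r.t, r.p_value))
        except (InsufficientDataError, DegenerateSampleError) as exc:
            logger.warning("one-sample test skipped: %s", exc)
            n = sum(1 for k in ratios if k.month == m)
            mean = np.mean([v for k, v in ratios.items() if k.month == m])
            rows.append((m, n, float(mean), float("nan"), float("nan")))
    vs_one = pd.DataFrame(rows, columns=["month", "n", "mean", "t", "p_value"])
    return MonthInference(scope, f, p, tukey, vs_one)


def holm_correction(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default in
    reports, mirroring the within-cause-only Tukey adjustment)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    m = len(p)
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
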