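"""Statistical decision tree and descriptive summaries.

The route mirrors standard practice for these data: normality is checked per
group with the Jarque-Bera and Kolmogorov-Smirnov tests and variance equality
with an F-test (Bartlett for >2 groups).  When every group passes both
normality tests (α = 0.05) and variances are equal, the parametric branch is
taken (Student's t, paired t, or one-way ANOVA with Tukey's post hoc);
otherwise the rank-based branch (Mann-Whitney-Wilcoxon, or Kruskal-Wallis
with Dunn's post hoc, Bonferroni family).

Descriptives follow the box-plot convention used throughout: mean, sample SD,
CV, median, and the 10/25/75/90 percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "Descriptives",
    "TestReport",
    "descriptives",
    "variance_f_test",
    "normality_report",
    "choose_two_group_test",
    "choose_multi_group_test",
    "dunn_posthoc",
    "significance_stars",
]

ALPHA_NORMALITY = 0.05


@dataclass
class Descriptives:
    n: int
    mean: float
    sd: float
    cv: float
    median: float
    p10: float
    p25: float
    p75: float
    p90: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class TestReport:
    """Outcome of one comparison, including the route that was taken."""

    test_name: str
    statistic: float
    p_value: float
    n_per_group: list[int]
    route: str                               # "parametric" | "nonparametric"
    normality_p: dict = field(default_factory=dict)   # group -> (jb_p, ks_p)
    variance_p: float | None = None
    posthoc: pd.DataFrame | None = None
    descriptives: dict = field(default_factory=dict)

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    """Panel-legend convention: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def descriptives(values) -> Descriptives:
    """Mean, sample SD, CV and box-plot percentiles of one sample."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    cv = sd / mean if mean > 0 else float("nan")
    p10, p25, p75, p90 = np.percentile(v, [10, 25, 75, 90])
    return Descriptives(
        n=int(v.size), mean=mean, sd=sd, cv=float(cv), median=float(np.median(v)),
        p10=float(p10), p25=float(p25), p75=float(p75), p90=float(p90),
    )


def _ks_normal(x: np.ndarray) -> float:
    """KS test against a normal with sample-estimated mean/SD."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(sps.kstest((x - x.mean()) / sd, "norm").pvalue)


def normality_report(x) -> tuple[float, float, bool]:
    """(Jarque-Bera p, KS p, passes-both) for one sample at α = 0.05."""
    x = np.asarray(x, dtype=float)
    jb_p = float(sps.jarque_bera(x).pvalue)
    ks_p = _ks_normal(x)
    return jb_p, ks_p, (jb_p > ALPHA_NORMALITY and ks_p > ALPHA_NORMALITY)


def variance_f_test(x, y) -> float:
    """Two-sided F-test of equality of variances."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        return 1.0
    if vy == 0 or vx == 0:
        return 0.0
    f = vx / vy
    p = sps.f.cdf(f, len(x) - 1, len(y) - 1)
    return float(2 * min(p, 1 - p))


def choose_two_group_test(x, y, paired: bool = False) -> TestReport:
    """Two-group comparison with automatic route selection.

    Student's t (paired or unpaired, two-tailed) when both groups are normal
    by both tests and variances are equal; otherwise Mann-Whitney-Wilcoxon
    (unpaired) or Wilcoxon signed-rank (paired).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need n >= 3 per group")
    if paired and len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    jb_x, ks_x, ok_x = normality_report(x)
    jb_y, ks_y, ok_y = normality_report(y)
    var_p = variance_f_test(x, y)
    normal = ok_x and ok_y and var_p > ALPHA_NORMALITY

    if np.array_equal(x, y):
        # degenerate: identical samples, no evidence of difference
        name = "paired t-test" if paired else "Student's t-test"
        return TestReport(
            test_name=name, statistic=0.0, p_value=1.0,
            n_per_group=[len(x), len(y)], route="parametric",
            normality_p={"x": (jb_x, ks_x), "y": (jb_y, ks_y)}, variance_p=var_p,
            descriptives={"x": descriptives(x).as_dict(), "y": descriptives(y).as_dict()},
        )

    if normal:
        if paired:
            stat, p = sps.ttest_rel(x, y)
            name = "paired t-test"
        else:
            stat, p = sps.ttest_ind(x, y)
            name = "Student's t-test"
        route = "parametric"
    else:
        if paired:
            stat, p = sps.wilcoxon(x, y)
            name = "Wilcoxon signed-rank"
        else:
            stat, p = sps.mannwhitneyu(x, y, alternative="two-sided")
            name = "Mann-Whitney-Wilcoxon"
        route = "nonparametric"
    return TestReport(
        test_name=name, statistic=float(stat), p_value=float(p),
        n_per_group=[len(x), len(y)], route=route,
        normality_p={"x": (jb_x, ks_x), "y": (jb_y, ks_y)}, variance_p=float(var_p),
        descriptives={"x": descriptives(x).as_dict(), "y": descriptives(y).as_dict()},
    )


def dunn_posthoc(groups: dict[str, np.ndarray], adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons after Kruskal-Wallis.

    z statistics use the pooled ranks with the standard tie correction;
    p-values are adjusted over all pairwise comparisons (Bonferroni family).
    """
    names = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    all_vals = np.concatenate(data)
    n = len(all_vals)
    ranks = sps.rankdata(all_vals)
    # tie correction term
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1))
    mean_ranks, sizes, start = {}, {}, 0
    for g, d in zip(names, data):
        mean_ranks[g] = ranks[start:start + len(d)].mean()
        sizes[g] = len(d)
        start += len(d)
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in combinations(names, 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p * m) if adjust == "bonferroni" else p
        rows.append({"group_a": a, "group_b": b, "z": z, "p": p, "p_adjusted": p_adj})
    return pd.DataFrame(rows)


def choose_multi_group_test(groups: dict[str, np.ndarray]) -> TestReport:
    """Multi-group comparison with automatic route selection.

    One-way ANOVA + Tukey HSD when every group is normal (both tests) with
    equal variances (Bartlett); otherwise Kruskal-Wallis + Dunn (Bonferroni).
    All pairwise adjusted p-values are returned in ``posthoc``.
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 groups; use choose_two_group_test for two")
    data = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if any(len(v) < 3 for v in data.values()):
        raise ValueError("need n >= 3 in every group")
    normality = {g: normality_report(v) for g, v in data.items()}
    all_normal = all(ok for _, _, ok in normality.values())
    var_p = float(sps.bartlett(*data.values()).pvalue)

    if all_normal and var_p > ALPHA_NORMALITY:
        stat, p = sps.f_oneway(*data.values())
        tk = sps.tukey_hsd(*data.values())
        names = list(data)
        rows = [
            {
                "group_a": names[i],
                "group_b": names[j],
                "statistic": float(tk.statistic[i, j]),
                "p_adjusted": float(tk.pvalue[i, j]),
            }
            for i, j in combinations(range(len(names)), 2)
        ]
        posthoc = pd.DataFrame(rows)
        name, route = "one-way ANOVA + Tukey", "parametric"
    else:
        stat, p = sps.kruskal(*data.values())
        posthoc = dunn_posthoc(data)
        name, route = "Kruskal-Wallis + Dunn", "nonparametric"
    return TestReport(
        test_name=name, statistic=float(stat), p_value=float(p),
        n_per_group=[len(v) for v in data.values()], route=route,
        normality_p={g: (jb, ks) for g, (jb, ks, _) in normality.items()},
        variance_p=var_p, posthoc=posthoc,
        descriptives={g: descriptives(v).as_dict() for g, v in data.items()},
    )
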