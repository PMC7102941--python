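"""Statistical decision tree, robust outlier detection, test dispatch.

The dispatch procedure mirrors common practice in quantitative microscopy:
each group is gated through Shapiro-Wilk normality and a variance-equality
test (F for two groups, Bartlett for more), and the comparison test is
chosen accordingly —

* 2 groups: Student's t (normal) or Mann-Whitney U (non-normal);
* >2 groups, normal + equal variances: one-way ANOVA with Tukey post hoc
  (Dunnett versus a named control group when one is specified);
* >2 groups, normal + unequal variances: Welch (Brown-Forsythe) ANOVA with
  pairwise Welch t post hoc, Holm-adjusted;
* >2 groups, non-normal: Kruskal-Wallis with Dunn's post hoc, Holm-adjusted;
* grouped designs: two-way ANOVA or Holm-Sidak multiple t tests.

Significance is fixed at alpha = 0.05.  Outliers are flagged with a
one-sample ROUT-style procedure at FDR level Q = 1%: residuals from the
median are scaled by the robust SD (the 68.27th percentile of absolute
residuals with a small-sample correction), converted to t-tail
probabilities, and thresholded by a Benjamini-Hochberg step-up at Q.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "OutlierReport",
    "GateResult",
    "ComparisonResult",
    "rout_outliers",
    "gate",
    "dispatch_comparison",
    "holm_adjust",
]

ALPHA = 0.05


@dataclass
class OutlierReport:
    outlier: np.ndarray        # bool per value
    q: float
    center: float              # robust center (median)
    scale: float               # robust SD (RSDR)
    p_values: np.ndarray

    @property
    def n_outliers(self) -> int:
        return int(self.outlier.sum())


def rout_outliers(values, q: float = 0.01) -> OutlierReport:
    """Robust outlier detection at FDR level Q (one-sample form).

    Residuals are taken from the median; the robust scale (RSDR) is the
    68.27th percentile of absolute residuals times n/(n-1).  Each value's
    two-sided t tail probability (df = n-1) is computed from
    residual/RSDR, and the set of outliers is the largest
    Benjamini-Hochberg step-up set at level Q — so with Q = 1% at most
    about 1% of flagged values are expected to be false discoveries.
    Constant data yields no outliers.  Requires n >= 5.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError(f"need at least 5 values, got {n}")
    if not (0 < q < 0.5):
        raise ValueError("Q must be in (0, 0.5)")
    center = float(np.median(x))
    resid = x - center
    rsdr = float(np.percentile(np.abs(resid), 68.27)) * n / (n - 1)
    if rsdr == 0:
        return OutlierReport(outlier=np.zeros(n, dtype=bool), q=q, center=center,
                             scale=0.0, p_values=np.ones(n))
    t = resid / rsdr
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
    order = np.argsort(p)
    thresh = q * (np.arange(1, n + 1)) / n
    passed = p[order] <= thresh
    flags = np.zeros(n, dtype=bool)
    if passed.any():
        k = int(np.max(np.flatnonzero(passed)))
        flags[order[:k + 1]] = True
    return OutlierReport(outlier=flags, q=q, center=center, scale=rsdr, p_values=p)


@dataclass
class GateResult:
    normal: list[bool]
    normality_p: list[float]
    equal_variance: bool
    variance_p: float
    variance_test: str
    alpha: float = ALPHA

    @property
    def all_normal(self) -> bool:
        return all(self.normal)


def gate(groups, alpha: float = ALPHA) -> GateResult:
    """Normality and variance-equality gate.

    Each group is normal iff its Shapiro-Wilk p exceeds alpha; variance
    equality uses the two-sided F test for two groups and Bartlett's test
    for more.  Every group needs n >= 3.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(gs):
        if g.size < 3:
            raise ValueError(f"group {i} has n={g.size} < 3")
    normality_p = []
    for g in gs:
        if np.ptp(g) == 0:
            normality_p.append(1.0)  # constant group: nothing to reject
        else:
            normality_p.append(float(sps.shapiro(g).pvalue))
    normal = [p > alpha for p in normality_p]
    if len(gs) == 2:
        v0, v1 = np.var(gs[0], ddof=1), np.var(gs[1], ddof=1)
        if v0 == 0 and v1 == 0:
            var_p, var_test = 1.0, "F"
        else:
            f = v0 / v1 if v1 > 0 else np.inf
            d0, d1 = gs[0].size - 1, gs[1].size - 1
            cdf = sps.f.cdf(f, d0, d1)
            var_p, var_test = float(2 * min(cdf, 1 - cdf)), "F"
    else:
        if all(np.ptp(g) == 0 for g in gs):
            var_p, var_test = 1.0, "bartlett"
        else:
            var_p, var_test = float(sps.bartlett(*gs).pvalue), "bartlett"
    return GateResult(normal=normal, normality_p=normality_p,
                      equal_variance=var_p > alpha, variance_p=var_p,
                      variance_test=var_test, alpha=alpha)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, >= raw)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = min((m - rank) * p[idx], 1.0)
        running = max(running, val)
        adj[idx] = running
    return adj


@dataclass
class ComparisonResult:
    test_name: str
    p_value: float
    posthoc: pd.DataFrame | None
    gate: GateResult | None
    alpha: float = ALPHA
    details: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha


def _welch_anova(gs: list[np.ndarray]) -> tuple[float, float]:
    """Welch's heteroscedastic one-way ANOVA; returns (F, p)."""
    k = len(gs)
    n = np.array([g.size for g in gs], dtype=float)
    m = np.array([g.mean() for g in gs])
    v = np.array([g.var(ddof=1) for g in gs])
    w = n / v
    W = w.sum()
    mstar = (w * m).sum() / W
    A = (w * (m - mstar) ** 2).sum() / (k - 1)
    tmp = ((1 - w / W) ** 2 / (n - 1)).sum()
    B = 1 + 2 * (k - 2) / (k ** 2 - 1) * tmp
    F = A / B
    df2 = (k ** 2 - 1) / (3 * tmp)
    return float(F), float(sps.f.sf(F, k - 1, df2))


def _dunn_posthoc(gs: list[np.ndarray], names: list[str]) -> pd.DataFrame:
    """Dunn's rank-based pairwise test with tie correction and Holm
    adjustment."""
    all_vals = np.concatenate(gs)
    N = all_vals.size
    ranks = sps.rankdata(all_vals)
    # tie correction
    _, counts = np.unique(all_vals, return_counts=True)
    tie = (counts ** 3 - counts).sum() / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie
    idx = np.cumsum([0] + [g.size for g in gs])
    mean_rank = [ranks[idx[i]:idx[i + 1]].mean() for i in range(len(gs))]
    rows = []
    for i, j in itertools.combinations(range(len(gs)), 2):
        se = math.sqrt(var_base * (1 / gs[i].size + 1 / gs[j].size))
        z = (mean_rank[i] - mean_rank[j]) / se if se > 0 else 0.0
        p = 2 * sps.norm.sf(abs(z))
        rows.append({"group1": names[i], "group2": names[j],
                     "statistic": z, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = holm_adjust(df["p_raw"].to_numpy())
    return df


def _pairwise_t_posthoc(gs, names, equal_var: bool) -> pd.DataFrame:
    rows = []
    for i, j in itertools.combinations(range(len(gs)), 2):
        res = sps.ttest_ind(gs[i], gs[j], equal_var=equal_var)
        rows.append({"group1": names[i], "group2": names[j],
                     "statistic": float(res.statistic), "p_raw": float(res.pvalue)})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = holm_adjust(df["p_raw"].to_numpy())
    return df


def dispatch_comparison(
    groups,
    design: str = "independent",
    names: list[str] | None = None,
    control: str | None = None,
    alpha: float = ALPHA,
    grouped_method: str = "two_way_anova",
    grouped_factors: pd.DataFrame | None = None,
) -> ComparisonResult:
    """Gate the groups and run the appropriate comparison test.

    See the module docstring for the decision table.  ``groups`` is a
    sequence of 1D samples for independent designs.  For ``design ==
    "grouped"`` pass ``grouped_factors``: a DataFrame with columns
    ``value``, ``factor_a``, ``factor_b`` (two-way ANOVA; the reported
    p-value is the interaction term) or, with ``grouped_method ==
    "holm_sidak"``, treat ``groups`` as paired column sets and run
    Holm-Sidak-adjusted t tests per position.
    """
    if design == "grouped":
        return _grouped_comparison(groups, grouped_method, grouped_factors, alpha)
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    names = names or [f"group{i}" for i in range(len(gs))]
    gr = gate(gs, alpha=alpha)
    if len(gs) == 2:
        if gr.all_normal:
            res = sps.ttest_ind(gs[0], gs[1], equal_var=gr.equal_variance)
            name = "t-test" if gr.equal_variance else "welch-t-test"
            return ComparisonResult(name, float(res.pvalue), None, gr, alpha)
        res = sps.mannwhitneyu(gs[0], gs[1], alternative="two-sided")
        return ComparisonResult("mann-whitney", float(res.pvalue), None, gr, alpha)
    # > 2 groups
    if gr.all_normal and gr.equal_variance:
        omni = sps.f_oneway(*gs)
        if control is not None:
            ci = names.index(control)
            others = [g for i, g in enumerate(gs) if i != ci]
            dn = sps.dunnett(*others, control=gs[ci])
            rows = []
            k = 0
            for i, nm in enumerate(names):
                if i == ci:
                    continue
                rows.append({"group1": nm, "group2": control,
                             "statistic": float(dn.statistic[k]),
                             "p_raw": float(dn.pvalue[k]),
                             "p_adjusted": float(dn.pvalue[k])})
                k += 1
            post = pd.DataFrame(rows)
            return ComparisonResult("anova+dunnett", float(omni.pvalue), post, gr, alpha)
        tk = sps.tukey_hsd(*gs)
        raw = _pairwise_t_posthoc(gs, names, equal_var=True)
        rows = []
        for r, (i, j) in zip(raw.itertuples(index=False),
                             itertools.combinations(range(len(gs)), 2)):
            adj = float(tk.pvalue[i, j])
            rows.append({"group1": r.group1, "group2": r.group2,
                         "statistic": r.statistic, "p_raw": r.p_raw,
                         "p_adjusted": max(adj, r.p_raw)})
        return ComparisonResult("anova+tukey", float(omni.pvalue),
                                pd.DataFrame(rows), gr, alpha)
    if gr.all_normal:  # unequal variances
        F, p = _welch_anova(gs)
        post = _pairwise_t_posthoc(gs, names, equal_var=False)
        return ComparisonResult("welch-anova", p, post, gr, alpha,
                                details={"F": F})
    omni = sps.kruskal(*gs)
    post = _dunn_posthoc(gs, names)
    return ComparisonResult("kruskal-wallis+dunn", float(omni.pvalue), post, gr, alpha)


def _grouped_comparison(groups, method: str, factors: pd.DataFrame | None,
                        alpha: float) -> ComparisonResult:
    if method == "two_way_anova":
        if factors is None:
            raise ValueError("two_way_anova needs grouped_factors "
                             "(columns value, factor_a, factor_b)")
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        model = smf.ols("value ~ C(factor_a) * C(factor_b)", data=factors).fit()
        table = sm.stats.anova_lm(model, typ=2)
        p_int = float(table.loc["C(factor_a):C(factor_b)", "PR(>F)"])
        post = table.reset_index().rename(columns={"index": "term"})
        return ComparisonResult("two-way-anova", p_int, post, None, alpha,
                                details={"anova_table": table.to_dict()})
    if method == "holm_sidak":
        pairs = list(groups)
        if len(pairs) != 2:
            raise ValueError("holm_sidak expects two matched lists of samples")
        a_list, b_list = pairs
        raw = [float(sps.ttest_ind(np.asarray(a, float), np.asarray(b, float)).pvalue)
               for a, b in zip(a_list, b_list)]
        m = len(raw)
        order = np.argsort(raw)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            val = 1.0 - (1.0 - raw[idx]) ** (m - rank)
            running = max(running, val)
            adj[idx] = min(running, 1.0)
        post = pd.DataFrame({"comparison": np.arange(m), "p_raw": raw,
                             "p_adjusted": adj})
        return ComparisonResult("holm-sidak-t", float(adj.min()), post, None, alpha)
    raise ValueError(f"unknown grouped method {method!r}")
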