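"""Group-comparison statistics for cohort parameter tables.

Implements the homogeneity-routed workflow commonly used for small
multi-group studies: a Levene test decides per parameter between
one-way ANOVA (with unadjusted Fisher LSD pairwise comparisons) and the
Kruskal-Wallis rank test.

Crucially for reproducing published results, both omnibus tests can be
reconstructed from summary statistics alone:

* :func:`anova_from_summary` rebuilds the exact F statistic from group
  means, SDs and sizes (the between/within decomposition depends on the
  data only through those summaries);
* :func:`kw_from_mean_ranks` rebuilds the Kruskal-Wallis H from per-group
  mean ranks and sizes (without tie correction, which summaries cannot
  supply).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "KWResult",
    "ParameterComparison",
    "ComparisonReport",
    "anova_oneway",
    "anova_from_summary",
    "levene_homogeneity",
    "lsd_pairwise",
    "kruskal_wallis",
    "kw_from_mean_ranks",
    "linfit",
    "compare_groups",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-group mean, SD and size for one parameter."""

    means: tuple[float, ...]
    sds: tuple[float, ...]
    ns: tuple[int, ...]
    labels: tuple = ()

    def __post_init__(self) -> None:
        k = len(self.means)
        if k < 2 or len(self.sds) != k or len(self.ns) != k:
            raise ValueError("need >= 2 groups with matching means/sds/ns")
        if any(s < 0 for s in self.sds):
            raise ValueError("SDs must be non-negative")
        if any(n < 2 for n in self.ns):
            raise ValueError("each group needs n >= 2")


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    infinite_f: bool = False


@dataclass(frozen=True)
class KWResult:
    h: float
    df: int
    p: float


def _check_groups(groups: Sequence[Sequence[float]], min_n: int = 2) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < min_n for g in gs):
        raise ValueError(f"each group needs at least {min_n} observations")
    return gs


def anova_oneway(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA on raw per-subject values."""
    gs = _check_groups(groups)
    k = len(gs)
    dfb, dfw = k - 1, sum(g.size for g in gs) - k
    msw = sum((g.size - 1) * g.var(ddof=1) for g in gs) / dfw
    if msw == 0:
        means = [g.mean() for g in gs]
        if np.ptp(means) > 0:
            return AnovaResult(f=math.inf, df_between=dfb, df_within=dfw,
                               p=0.0, infinite_f=True)
        return AnovaResult(f=0.0, df_between=dfb, df_within=dfw, p=1.0)
    f, p = sps.f_oneway(*gs)
    return AnovaResult(f=float(f), df_between=dfb, df_within=dfw, p=float(p))


def anova_from_summary(summary: GroupSummary) -> AnovaResult:
    """One-way ANOVA reconstructed exactly from group means/SDs/sizes.

    SS_between = sum n_i (xbar_i - xbar)^2;
    MS_within  = sum (n_i - 1) s_i^2 / sum (n_i - 1).
    Identical to :func:`anova_oneway` on any raw data with these
    summaries.
    """
    means = np.asarray(summary.means, dtype=float)
    sds = np.asarray(summary.sds, dtype=float)
    ns = np.asarray(summary.ns, dtype=float)
    k = means.size
    n_tot = ns.sum()
    grand = float((ns * means).sum() / n_tot)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds ** 2).sum())
    dfb, dfw = k - 1, int(n_tot - k)
    if ssw == 0:
        if ssb > 0:
            return AnovaResult(f=math.inf, df_between=dfb, df_within=dfw,
                               p=0.0, infinite_f=True)
        return AnovaResult(f=0.0, df_between=dfb, df_within=dfw, p=1.0)
    f = (ssb / dfb) / (ssw / dfw)
    return AnovaResult(f=f, df_between=dfb, df_within=dfw,
                       p=float(sps.f.sf(f, dfb, dfw)))


def levene_homogeneity(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Levene's variance-homogeneity test (mean-centered).

    Routing convention: p < 0.05 sends the parameter down the
    nonparametric (Kruskal-Wallis) path.
    """
    gs = _check_groups(groups)
    if all(np.ptp(np.abs(g - g.mean())) == 0 for g in gs):
        return 0.0, 1.0  # identical absolute deviations in every group
    stat, p = sps.levene(*gs, center="mean")
    return float(stat), float(p)


def lsd_pairwise(groups: Sequence[Sequence[float]],
                 labels: Sequence | None = None) -> dict[tuple, float]:
    """Fisher least-significant-difference pairwise p-values.

    For each pair (i, j): t = (xbar_i - xbar_j) /
    sqrt(MS_within (1/n_i + 1/n_j)) on the ANOVA within-group df.
    Deliberately unadjusted for multiplicity — that is what LSD is.
    """
    gs = _check_groups(groups)
    if labels is None:
        labels = list(range(len(gs)))
    k = len(gs)
    dfw = sum(g.size for g in gs) - k
    msw = sum((g.size - 1) * g.var(ddof=1) for g in gs) / dfw
    out: dict[tuple, float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            diff = gs[i].mean() - gs[j].mean()
            se = math.sqrt(msw * (1 / gs[i].size + 1 / gs[j].size))
            if se == 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                p = 2 * float(sps.t.sf(abs(diff) / se, dfw))
            out[(labels[i], labels[j])] = p
    return out


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KWResult:
    """Kruskal-Wallis rank test (tie-corrected), chi-square p-value."""
    gs = _check_groups(groups)
    if np.ptp(np.concatenate(gs)) == 0:
        # every observation tied: H defined as 0
        return KWResult(h=0.0, df=len(gs) - 1, p=1.0)
    h, p = sps.kruskal(*gs)
    return KWResult(h=float(h), df=len(gs) - 1, p=float(p))


def kw_from_mean_ranks(mean_ranks: Sequence[float],
                       ns: Sequence[int],
                       rank_tol: float = 1e-6) -> KWResult:
    """Kruskal-Wallis H reconstructed from per-group mean ranks.

    H = 12 / (N (N+1)) * sum n_i (Rbar_i - (N+1)/2)^2.

    No tie correction is possible from summaries, so on tied data this
    reconstruction is a lower bound on the tie-corrected H.  The rank
    sums must conserve the total N(N+1)/2.
    """
    r = np.asarray(mean_ranks, dtype=float)
    n = np.asarray(ns, dtype=float)
    if r.size != n.size or r.size < 2:
        raise ValueError("need >= 2 groups with matching mean_ranks/ns")
    n_tot = n.sum()
    expected = n_tot * (n_tot + 1) / 2
    got = float((n * r).sum())
    if abs(got - expected) > rank_tol * max(1.0, expected):
        raise ValueError(
            f"rank-sum conservation violated: sum n_i*Rbar_i = {got}, "
            f"expected N(N+1)/2 = {expected}"
        )
    h = 12.0 / (n_tot * (n_tot + 1)) * float(
        (n * (r - (n_tot + 1) / 2) ** 2).sum())
    df = r.size - 1
    return KWResult(h=h, df=df, p=float(sps.chi2.sf(h, df)))


def linfit(x: Sequence[float], y: Sequence[float]):
    """OLS line y = slope*x + intercept with Pearson r and slope p-value.

    r is NaN (flagged undefined) when y is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), float("nan"), 1.0
    res = sps.linregress(x, y)
    return (float(res.slope), float(res.intercept),
            float(res.rvalue), float(res.pvalue))


# ---------------------------------------------------------------------------
# cohort-level comparison report


@dataclass(frozen=True)
class ParameterComparison:
    """Omnibus + pairwise result for one parameter."""

    parameter: str
    route: str                      # "anova" or "kruskal-wallis"
    homogeneity_p: float
    statistic: float                # F or H
    df: tuple[int, ...]
    p: float
    significant: bool
    group_means: dict
    group_sds: dict
    mean_ranks: dict | None = None  # populated on the KW route
    pairwise: dict | None = None    # LSD p-values on the ANOVA route

    def pairwise_flags(self, alpha: float = 0.05) -> dict | None:
        if self.pairwise is None:
            return None
        return {k: p < alpha for k, p in self.pairwise.items()}


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


@dataclass
class ComparisonReport:
    """Per-parameter group-comparison results for a cohort."""

    rows: list[ParameterComparison]
    alpha: float = 0.05
    group_labels: tuple = field(default_factory=tuple)

    def __iter__(self):
        return iter(self.rows)

    def __getitem__(self, parameter: str) -> ParameterComparison:
        for row in self.rows:
            if row.parameter == parameter:
                return row
        raise KeyError(parameter)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = {"parameter": r.parameter, "route": r.route,
                   "statistic": r.statistic, "p": r.p,
                   "significant": r.significant,
                   "homogeneity_p": r.homogeneity_p}
            for g in self.group_labels:
                rec[f"mean[{g}]"] = r.group_means.get(g)
                rec[f"sd[{g}]"] = r.group_sds.get(g)
            recs.append(rec)
        return pd.DataFrame(recs)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "groups": [str(g) for g in self.group_labels],
            "parameters": [
                {
                    "parameter": r.parameter,
                    "route": r.route,
                    "homogeneity_p": r.homogeneity_p,
                    "statistic": r.statistic,
                    "df": list(r.df),
                    "p": r.p,
                    "p_formatted": _fmt_p(r.p),
                    "significant": r.significant,
                    "group_means": {str(k): v for k, v in r.group_means.items()},
                    "group_sds": {str(k): v for k, v in r.group_sds.items()},
                    "mean_ranks": (None if r.mean_ranks is None else
                                   {str(k): v for k, v in r.mean_ranks.items()}),
                    "pairwise": (None if r.pairwise is None else
                                 {f"{a} vs {b}": p
                                  for (a, b), p in r.pairwise.items()}),
                }
                for r in self.rows
            ],
        }

    def summary(self) -> str:
        """Plain-text table: one line per parameter, SPSS-style p format."""
        lines = [f"{'parameter':<12} {'test':<15} {'stat':>9} {'p':>8}  "
                 f"sig@{self.alpha:g}"]
        for r in self.rows:
            stat_name = "F" if r.route == "anova" else "chi2"
            lines.append(
                f"{r.parameter:<12} {r.route:<15} "
                f"{stat_name}={r.statistic:7.3f} {_fmt_p(r.p):>8}  "
                f"{'*' if r.significant else ''}"
            )
        return "\n".join(lines)


def compare_groups(params: pd.DataFrame, group_col: str = "dose",
                   parameters: Sequence[str] | None = None,
                   alpha: float = 0.05,
                   homogeneity_alpha: float = 0.05) -> ComparisonReport:
    """Run the homogeneity-routed comparison for every parameter column.

    Each parameter is tested for variance homogeneity across groups
    (Levene); homogeneous parameters get one-way ANOVA with LSD pairwise
    p-values, non-homogeneous ones the Kruskal-Wallis test.  Routing is
    per parameter, not global.
    """
    if group_col not in params.columns:
        raise ValueError(f"missing group column {group_col!r}")
    labels = sorted(params[group_col].unique().tolist())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups to compare")
    if parameters is None:
        parameters = [c for c in params.columns
                      if c != group_col
                      and pd.api.types.is_numeric_dtype(params[c])]
    rows = []
    for param in parameters:
        groups = [params.loc[params[group_col] == g, param].dropna().to_numpy()
                  for g in labels]
        means = {g: float(np.mean(v)) for g, v in zip(labels, groups)}
        sds = {g: float(np.std(v, ddof=1)) for g, v in zip(labels, groups)}
        _, hom_p = levene_homogeneity(groups)
        if hom_p < homogeneity_alpha:
            kw = kruskal_wallis(groups)
            ranks = sps.rankdata(np.concatenate(groups))
            splits = np.cumsum([len(g) for g in groups])[:-1]
            mean_ranks = {g: float(r.mean()) for g, r in
                          zip(labels, np.split(ranks, splits))}
            rows.append(ParameterComparison(
                parameter=param, route="kruskal-wallis",
                homogeneity_p=hom_p, statistic=kw.h, df=(kw.df,),
                p=kw.p, significant=kw.p < alpha,
                group_means=means, group_sds=sds, mean_ranks=mean_ranks))
        else:
            an = anova_oneway(groups)
            pw = lsd_pairwise(groups, labels=labels)
            rows.append(ParameterComparison(
                parameter=param, route="anova",
                homogeneity_p=hom_p, statistic=an.f,
                df=(an.df_between, an.df_within),
                p=an.p, significant=an.p < alpha,
                group_means=means, group_sds=sds, pairwise=pw))
    return ComparisonReport(rows=rows, alpha=alpha, group_labels=tuple(labels))
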