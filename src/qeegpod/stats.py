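"""Two-group statistics for qEEG biomarker tables.

The statistical layer of a delirium-biomarker study: Welch's unequal-
variance t-test (from raw samples or from published mean ± SEM
summaries), one-way ANOVA, 2×2 proportion comparison (Fisher exact by
full hypergeometric enumeration, plus chi-square with and without
continuity correction), incidence, two-proportion sample-size formulas,
and the mean ± SEM comparison table that mirrors how such studies print
their qEEG results.

The model-style entry point is :class:`GroupComparison`:

>>> model = GroupComparison.from_dataframe(df, group_col="group")
>>> res = model.fit()
>>> print(res.summary())
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_NAMES


# ---------------------------------------------------------------------------
# Welch's t
# ---------------------------------------------------------------------------

def welch_t_from_summary(
    mean1: float, sem1: float, n1: int, mean2: float, sem2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's two-sided t-test from group summaries (mean, SEM, n).

    Published tables report mean ± SEM, which is exactly what the Welch
    statistic needs: ``t = (m1 - m2) / sqrt(sem1² + sem2²)`` with
    Welch–Satterthwaite degrees of freedom.  Returns ``(t, df, p)``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("Welch's t-test needs at least 2 observations per group")
    if sem1 <= 0 or sem2 <= 0:
        raise ValueError("SEMs must be positive")
    v1, v2 = sem1**2, sem2**2
    t = (mean1 - mean2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return t, df, p


def welch_t_test(samples1, samples2) -> tuple[float, float, float]:
    """Welch's t-test on raw samples.

    Defined as :func:`welch_t_from_summary` applied to the computed
    summaries, so the two routes agree exactly.
    """
    x = np.asarray(samples1, dtype=float)
    y = np.asarray(samples2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("zero variance in both groups; t is undefined")
    return welch_t_from_summary(
        float(np.mean(x)), float(np.std(x, ddof=1) / np.sqrt(x.size)), x.size,
        float(np.mean(y)), float(np.std(y, ddof=1) / np.sqrt(y.size)), y.size,
    )


# ---------------------------------------------------------------------------
# one-way ANOVA
# ---------------------------------------------------------------------------

def anova_oneway(*groups) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA; returns ``(F, df_between, df_within, p)``.

    Standard between/within sum-of-squares decomposition.  With exactly
    two groups, F equals the square of the pooled-variance t statistic.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise ValueError("ANOVA needs at least 2 groups with at least 2 values each")
    n_total = sum(a.size for a in arrs)
    grand = sum(a.sum() for a in arrs) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df1 = len(arrs) - 1
    df2 = n_total - len(arrs)
    if ss_within == 0:
        raise ValueError("zero within-group variance; F is undefined")
    f = (ss_between / df1) / (ss_within / df2)
    p = sps.f.sf(f, df1, df2)
    return f, df1, df2, p


# ---------------------------------------------------------------------------
# proportions
# ---------------------------------------------------------------------------

def fisher_exact_2x2(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Conditions on both margins and sums the point probabilities of
    every table at least as extreme as the observed one under the
    standard "small-p" rule (probability ≤ observed, with a 1+1e-7
    relative guard against floating-point ties).
    """
    total = n1 + n2
    successes = k1 + k2
    support = np.arange(max(0, successes - n2), min(n1, successes) + 1)
    pmf = sps.hypergeom.pmf(support, total, successes, n1)
    observed = sps.hypergeom.pmf(k1, total, successes, n1)
    return float(pmf[pmf <= observed * (1 + 1e-7)].sum())


def proportion_compare(k1: int, n1: int, k2: int, n2: int) -> dict:
    """Compare two proportions from a 2×2 table.

    Returns the odds ratio, the enumerated Fisher exact two-sided p,
    and the chi-square p both with and without Yates continuity
    correction (published papers rarely say which variant they used, so
    both are always reported).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("group sizes must be positive")
        if not 0 <= k <= n:
            raise ValueError("event counts must satisfy 0 <= k <= n")
    a, b = k1, n1 - k1
    c, d = k2, n2 - k2
    odds_ratio = math.inf if b * c == 0 and a * d > 0 else (
        math.nan if b * c == 0 else (a * d) / (b * c)
    )

    def chi2_p(correction: bool) -> float:
        table = np.array([[a, b], [c, d]], dtype=float)
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        expected = row @ col / table.sum()
        if np.any(expected == 0):
            return math.nan
        diff = np.abs(table - expected)
        if correction:
            diff = np.clip(diff - 0.5, 0.0, None)
        stat = float((diff**2 / expected).sum())
        return float(sps.chi2.sf(stat, 1))

    return {
        "odds_ratio": odds_ratio,
        "p_fisher": fisher_exact_2x2(k1, n1, k2, n2),
        "p_chi2": chi2_p(False),
        "p_chi2_yates": chi2_p(True),
    }


def incidence(k: int, n: int) -> dict:
    """Event incidence as a percentage.

    Returns both the full-precision value and the one-decimal display
    rounding used in clinical tables (``41.7`` for 10/24).
    """
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= k <= n:
        raise ValueError("event count must satisfy 0 <= k <= n")
    value = 100.0 * k / n
    return {"percent": value, "display": round(value, 1)}


def sample_size_two_proportions(
    p1: float,
    p2: float,
    alpha: float = 0.05,
    power: float = 0.80,
    method: str = "unpooled-normal",
) -> dict:
    """Per-group n to detect a difference between two proportions.

    Methods:

    ``unpooled-normal``
        ``n = (z_{1-a/2} + z_pow)² (p1 q1 + p2 q2) / (p1 - p2)²``
    ``pooled-normal``
        pooled variance under H0 in the alpha term (Fleiss-style,
        without continuity correction)
    ``arcsine``
        Cohen's effect size ``h = 2 asin√p1 - 2 asin√p2`` with
        ``n = (z_{1-a/2} + z_pow)² / h²``

    Returns the ceiling integer n along with the method, since
    different planning tools disagree by design.
    """
    if not (0 < p2 < 1 and 0 < p1 < 1):
        raise ValueError("proportions must be in (0, 1)")
    if p1 == p2:
        raise ValueError("equal proportions imply an infinite sample size")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    z_a = sps.norm.ppf(1 - alpha / 2)
    z_b = sps.norm.ppf(power)
    if method == "unpooled-normal":
        n = (z_a + z_b) ** 2 * (p1 * (1 - p1) + p2 * (1 - p2)) / (p1 - p2) ** 2
    elif method == "pooled-normal":
        pbar = (p1 + p2) / 2
        n = (
            z_a * math.sqrt(2 * pbar * (1 - pbar))
            + z_b * math.sqrt(p1 * (1 - p1) + p2 * (1 - p2))
        ) ** 2 / (p1 - p2) ** 2
    elif method == "arcsine":
        h = 2 * math.asin(math.sqrt(p1)) - 2 * math.asin(math.sqrt(p2))
        n = (z_a + z_b) ** 2 / h**2
    else:
        raise ValueError(
            f"unknown method {method!r}; expected 'unpooled-normal', "
            "'pooled-normal' or 'arcsine'"
        )
    return {"n_per_group": math.ceil(n - 1e-12), "exact": n, "method": method}


# ---------------------------------------------------------------------------
# group summaries and the comparison model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSummary:
    """Per-feature mean / SD / SEM for one group of subjects."""

    label: str
    n: int
    means: pd.Series
    sds: pd.Series

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be at least 1")

    @property
    def sems(self) -> pd.Series:
        return self.sds / math.sqrt(self.n)


#: Fixed row order of the comparison table, matching clinical reporting.
TABLE_ROW_ORDER: tuple[str, ...] = FEATURE_NAMES


class GroupComparison:
    """Model: per-subject qEEG features with group labels.

    Built from a tidy DataFrame (one row per subject, one column per
    feature, plus a group column); :meth:`fit` produces a
    :class:`GroupComparisonResults` with mean ± SEM per group and a
    Welch test (two groups) or one-way ANOVA (three or more) per
    feature row.
    """

    def __init__(self, data: pd.DataFrame, group_col: str = "group",
                 feature_cols: "list[str] | None" = None) -> None:
        if group_col not in data.columns:
            raise KeyError(f"group column {group_col!r} not in data")
        if feature_cols is None:
            feature_cols = [
                c for c in TABLE_ROW_ORDER if c in data.columns
            ] or [c for c in data.columns if c != group_col]
        self.data = data
        self.group_col = group_col
        self.feature_cols = list(feature_cols)
        self.group_labels = list(pd.unique(data[group_col]))
        if len(self.group_labels) < 2:
            raise ValueError("need at least 2 groups to compare")
        sizes = data[group_col].value_counts()
        if (sizes < 2).any():
            small = sizes[sizes < 2].index.tolist()
            raise ValueError(f"groups of size 1 have undefined SEM: {small}")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, group_col: str = "group",
                       feature_cols: "list[str] | None" = None) -> "GroupComparison":
        return cls(data, group_col=group_col, feature_cols=feature_cols)

    @classmethod
    def from_features(cls, features) -> "GroupComparison":
        """Build from a list of :class:`~qeegpod.features.QEEGFeatures`."""
        rows = []
        for f in features:
            row = f.mean.to_dict()
            row["group"] = f.group_label
            row["subject_id"] = f.subject_id
            rows.append(row)
        df = pd.DataFrame(rows).set_index("subject_id")
        return cls(df, group_col="group")

    def fit(self) -> "GroupComparisonResults":
        summaries = []
        for label in self.group_labels:
            sub = self.data.loc[self.data[self.group_col] == label, self.feature_cols]
            summaries.append(
                GroupSummary(
                    label=str(label),
                    n=int(sub.shape[0]),
                    means=sub.mean(),
                    sds=sub.std(ddof=1),
                )
            )
        rows = []
        for feat in self.feature_cols:
            groups = [
                self.data.loc[self.data[self.group_col] == lb, feat].to_numpy()
                for lb in self.group_labels
            ]
            row: dict = {"feature": feat}
            for s in summaries:
                row[f"mean_{s.label}"] = float(s.means[feat])
                row[f"sem_{s.label}"] = float(s.sems[feat])
                row[f"n_{s.label}"] = s.n
            if len(groups) == 2:
                t, df, p = welch_t_test(groups[0], groups[1])
                row.update(test="welch", statistic=t, df=df, p_value=p)
            else:
                f_stat, df1, df2, p = anova_oneway(*groups)
                row.update(test="anova", statistic=f_stat, df=(df1, df2), p_value=p)
            rows.append(row)
        table = pd.DataFrame(rows).set_index("feature")
        return GroupComparisonResults(self, summaries, table)


@dataclass
class GroupComparisonResults:
    """Fitted group comparison: summaries, test statistics, display table."""

    model: GroupComparison
    group_summaries: list[GroupSummary]
    table: pd.DataFrame

    @property
    def p_values(self) -> pd.Series:
        return self.table["p_value"]

    def holm_adjusted(self) -> pd.Series:
        """Holm step-down adjusted p-values (off by default in displays;
        provided because the feature rows are a family of 9 tests)."""
        p = self.table["p_value"].to_numpy()
        order = np.argsort(p)
        m = p.size
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(1.0, running)
        return pd.Series(adj, index=self.table.index, name="p_holm")

    def display_table(self) -> pd.DataFrame:
        """Rounded table in the journal style: mean ± SEM per group, p.

        Means/SEMs to two decimals, p to four; full precision stays in
        ``.table``.
        """
        out = pd.DataFrame(index=self.table.index)
        for s in self.group_summaries:
            out[f"{s.label} (n={s.n})"] = [
                f"{self.table.loc[f, f'mean_{s.label}']:.2f} ± "
                f"{self.table.loc[f, f'sem_{s.label}']:.2f}"
                for f in self.table.index
            ]
        out["p value"] = [f"{p:.4f}" for p in self.table["p_value"]]
        return out

    def summary(self) -> str:
        labels = " vs ".join(s.label for s in self.group_summaries)
        lines = [
            "qEEG group comparison",
            f"  groups: {labels}",
            f"  test:   {'Welch t (two-sided)' if len(self.group_summaries) == 2 else 'one-way ANOVA'}",
            "",
            self.display_table().to_string(),
        ]
        return "\n".join(lines)


def summarize_groups(features, group_col: str = "group") -> GroupComparisonResults:
    """One-call comparison table from per-subject features.

    ``features`` is either a list of
    :class:`~qeegpod.features.QEEGFeatures` or a tidy DataFrame with a
    group column.
    """
    if isinstance(features, pd.DataFrame):
        model = GroupComparison.from_dataframe(features, group_col=group_col)
    else:
        model = GroupComparison.from_features(features)
    return model.fit()
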