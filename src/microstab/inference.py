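"""Inferential statistics for treatment comparisons of stability metrics.

The experimental design reduces each microcosm to a single derived value
(e.g. its CV), so the inferential layer is a one-way fixed-effects layout:
5 treatments x 8 replicates, 40 observations, F on (4, 35) degrees of
freedom.  Because variance heterogeneity across treatment arms is the rule
rather than the exception for CVs, the omnibus test is a Wald F built on a
heteroscedasticity-consistent (sandwich) covariance estimate — HC3 by
default, the standard small-sample recommendation.  Post-hoc pairwise
comparisons use Tukey's HSD on the classical pooled-variance scale,
summarised as a compact letter display; a robust alternative (pairwise HC3
Wald tests with Holm adjustment) is available.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "PairwiseResult",
    "hc_anova",
    "tukey_hsd",
    "robust_pairwise",
    "compact_letter_display",
    "pearson_correlation",
]

HC_TYPES = ("HC0", "HC1", "HC2", "HC3")


@dataclass
class AnovaResult:
    """One-way ANOVA summary (robust Wald F plus the classical F)."""

    F: float
    df_num: int
    df_den: int
    p_value: float
    robust: bool
    hc_type: str | None
    group_means: dict[str, float]
    f_classical: float
    p_classical: float
    degenerate: bool = False
    letters: dict[str, str] | None = None

    def to_dict(self) -> dict:
        return {
            "F": self.F,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "p_value": self.p_value,
            "robust": self.robust,
            "hc_type": self.hc_type,
            "group_means": self.group_means,
            "F_classical": self.f_classical,
            "p_classical": self.p_classical,
            "degenerate": self.degenerate,
            "letters": self.letters,
        }


@dataclass
class PairwiseResult:
    """All pairwise comparisons plus the compact letter display."""

    table: pd.DataFrame  # columns: group1, group2, meandiff, p_adj, reject
    letters: dict[str, str]
    alpha: float
    method: str


def _check_groups(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape or values.ndim != 1:
        raise ValueError("values and groups must be 1-d arrays of equal length")
    if not np.all(np.isfinite(values)):
        raise ValueError("values contain non-finite entries")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    small = labels[counts < 2]
    if small.size:
        raise ValueError(f"groups with fewer than 2 observations: {list(small)}")
    return values, groups, [str(l) for l in labels]


def hc_anova(values, groups, hc_type: str = "HC3") -> AnovaResult:
    """Wald F test of equal group means with sandwich (HC) covariance.

    Fits the one-way linear model y ~ treatment and tests the joint null
    that all group means are equal, using the requested
    heteroscedasticity-consistent covariance for the Wald statistic.  The
    p-value is taken from F(k-1, n-k).  The classical (pooled-variance)
    F is computed alongside for reference.

    If all residual variance is zero (every observation in every group
    identical to its group mean, and all group means equal) the test is
    degenerate: F = 0, p = 1, ``degenerate=True``.
    """
    if hc_type not in HC_TYPES:
        raise ValueError(f"hc_type must be one of {HC_TYPES}, got {hc_type!r}")
    values, groups, labels = _check_groups(values, groups)
    k = len(labels)
    n = len(values)
    df_num, df_den = k - 1, n - k

    means = {lab: float(values[groups == lab].mean()) for lab in labels}

    # treatment-coded design: intercept + k-1 dummies
    dummies = np.column_stack([(groups == lab).astype(float) for lab in labels[1:]])
    X = sm.add_constant(dummies)
    model = sm.OLS(values, X)

    resid_ss = float(((values - np.array([means[str(g)] for g in groups])) ** 2).sum())
    if resid_ss == 0.0:
        if len(set(means.values())) == 1:
            return AnovaResult(
                F=0.0, df_num=df_num, df_den=df_den, p_value=1.0, robust=True,
                hc_type=hc_type, group_means=means, f_classical=0.0, p_classical=1.0,
                degenerate=True,
            )
        # group means differ but zero within-group variance: infinite evidence
        return AnovaResult(
            F=np.inf, df_num=df_num, df_den=df_den, p_value=0.0, robust=True,
            hc_type=hc_type, group_means=means, f_classical=np.inf, p_classical=0.0,
            degenerate=True,
        )

    res_robust = model.fit(cov_type=hc_type)
    R = np.zeros((k - 1, k))
    R[:, 1:] = np.eye(k - 1)
    ft = res_robust.f_test(R)
    F = float(np.squeeze(ft.fvalue))
    p = float(scipy.stats.f.sf(F, df_num, df_den))

    f_cls, p_cls = scipy.stats.f_oneway(*[values[groups == lab] for lab in labels])

    return AnovaResult(
        F=F, df_num=df_num, df_den=df_den, p_value=p, robust=True, hc_type=hc_type,
        group_means=means, f_classical=float(f_cls), p_classical=float(p_cls),
    )


def compact_letter_display(
    labels: list[str],
    means: dict[str, float],
    significant_pairs: set[tuple[str, str]],
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Two treatments share a letter iff they are NOT significantly different.
    Columns (letter groups) start as one all-inclusive set; each significant
    pair splits every column containing both members; columns that become
    subsets of another column are absorbed.  Letters are assigned in
    ascending order of group mean, so 'a' marks the lowest-mean group.
    """
    sig = {tuple(sorted(p)) for p in significant_pairs}
    columns: list[set[str]] = [set(labels)]
    for a, b in sorted(sig):
        new_columns: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb: drop empty columns, duplicates, and proper subsets of another column
        columns = []
        for c in new_columns:
            if not c or c in columns:
                continue
            if any(c < d for d in new_columns):
                continue
            columns.append(c)
    # order columns by the mean of their lowest-mean member for stable lettering
    columns.sort(key=lambda c: min(means[m] for m in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for letter, col in zip(alphabet, columns):
        for lab in sorted(col, key=lambda m: (means[m], m)):
            out[lab] += letter
    return {lab: "".join(sorted(s)) for lab, s in out.items()}


def tukey_hsd(values, groups, alpha: float = 0.05) -> PairwiseResult:
    """All-pairwise Tukey HSD comparisons with compact letter display.

    Adjusted p-values come from the studentized-range distribution on the
    classical pooled-MSE scale.  If the pooled within-group variance is
    zero the comparisons are degenerate: all pairs with equal means are
    non-significant and pairs with different means are significant.
    """
    values, groups, labels = _check_groups(values, groups)
    means = {lab: float(values[groups == lab].mean()) for lab in labels}

    within_ss = sum(float(((values[groups == lab] - means[lab]) ** 2).sum()) for lab in labels)
    if within_ss == 0.0:
        rows = []
        sig_pairs = set()
        for a, b in itertools.combinations(labels, 2):
            diff = means[b] - means[a]
            reject = diff != 0.0
            rows.append((a, b, diff, 0.0 if reject else 1.0, reject))
            if reject:
                sig_pairs.add((a, b))
        table = pd.DataFrame(rows, columns=["group1", "group2", "meandiff", "p_adj", "reject"])
        letters = compact_letter_display(labels, means, sig_pairs)
        return PairwiseResult(table=table, letters=letters, alpha=alpha, method="tukey-hsd")

    res = pairwise_tukeyhsd(values, groups, alpha=alpha)
    summ = res.summary()
    df = pd.DataFrame(summ.data[1:], columns=summ.data[0])
    table = pd.DataFrame(
        {
            "group1": df["group1"].astype(str),
            "group2": df["group2"].astype(str),
            "meandiff": df["meandiff"].astype(float),
            "p_adj": np.asarray(res.pvalues, dtype=float),
            "reject": np.asarray(res.reject, dtype=bool),
        }
    )
    sig_pairs = {
        (r.group1, r.group2) for r in table.itertuples() if r.reject
    }
    letters = compact_letter_display(labels, means, sig_pairs)
    return PairwiseResult(table=table, letters=letters, alpha=alpha, method="tukey-hsd")


def robust_pairwise(values, groups, alpha: float = 0.05, hc_type: str = "HC3") -> PairwiseResult:
    """Pairwise Wald tests with HC variance of group means, Holm-adjusted.

    The HC3 variance of a group mean with n_g observations is
    ``sum(e_i^2 / (1 - 1/n_g)^2) / n_g^2``; pairs are compared with a
    Welch–Satterthwaite t.  Family-wise error is controlled by Holm's
    step-down procedure instead of the studentized range.
    """
    if hc_type not in HC_TYPES:
        raise ValueError(f"hc_type must be one of {HC_TYPES}, got {hc_type!r}")
    values, groups, labels = _check_groups(values, groups)
    means = {lab: float(values[groups == lab].mean()) for lab in labels}

    def hc_var_of_mean(x: np.ndarray) -> float:
        n_g = len(x)
        e2 = (x - x.mean()) ** 2
        h = 1.0 / n_g
        if hc_type == "HC0":
            s = e2.sum()
        elif hc_type == "HC1":
            s = e2.sum() * n_g / (n_g - 1)
        elif hc_type == "HC2":
            s = (e2 / (1 - h)).sum()
        else:
            s = (e2 / (1 - h) ** 2).sum()
        return float(s) / n_g**2

    rows = []
    pvals = []
    for a, b in itertools.combinations(labels, 2):
        xa, xb = values[groups == a], values[groups == b]
        va, vb = hc_var_of_mean(xa), hc_var_of_mean(xb)
        diff = float(xb.mean() - xa.mean())
        se = np.sqrt(va + vb)
        if se == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            df_ws = (va + vb) ** 2 / (
                va**2 / (len(xa) - 1) + vb**2 / (len(xb) - 1)
            )
            t = diff / se
            p = 2 * scipy.stats.t.sf(abs(t), df_ws)
        rows.append([a, b, diff])
        pvals.append(p)

    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    table = pd.DataFrame(rows, columns=["group1", "group2", "meandiff"])
    table["p_adj"] = p_adj
    table["reject"] = reject
    sig_pairs = {(r.group1, r.group2) for r in table.itertuples() if r.reject}
    letters = compact_letter_display(labels, means, sig_pairs)
    return PairwiseResult(table=table, letters=letters, alpha=alpha, method=f"{hc_type.lower()}-holm")


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided t-based p-value.

    Requires >= 3 paired finite observations and nonzero variance in both
    variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs contain non-finite values")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined: zero variance in x or y")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)
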