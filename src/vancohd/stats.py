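"""Outcome statistics: 2x2 tables, stepwise logistic regression, ROC, and
group/correlation comparisons.

Crude odds ratios use the Woolf logit interval
exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)); p-values come from the
Pearson chi-square without continuity correction, switching to the
two-sided Fisher exact test when any expected cell count is below 5.
Candidate factors passing a univariate screen (p < 0.2) enter a
forward-backward stepwise logistic model selected by likelihood-ratio
p-values; ROC cut-offs maximise the Youden index J = sens + spec - 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

SEPARATION_COEF_LIMIT = 15.0


# ---------------------------------------------------------------------------
# 2x2 tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable:
    """Counts: a = exposed responders, b = exposed non-responders,
    c = unexposed responders, d = unexposed non-responders."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError("counts must be nonnegative integers")

    @property
    def or_defined(self) -> bool:
        return self.b * self.c > 0

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class OrResult:
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    test_used: str
    defined: bool = True


def _association_p(table: ContingencyTable) -> tuple[float, str]:
    arr = table.as_array()
    n = arr.sum()
    if n == 0:
        return float("nan"), "none"
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / n
    if (expected < 5).any():
        _, p = sps.fisher_exact(arr, alternative="two-sided")
        return float(p), "fisher"
    chi2, p, _, _ = sps.chi2_contingency(arr, correction=False)
    return float(p), "chi2"


def crude_or(table: ContingencyTable, alpha: float = 0.05) -> OrResult:
    """Crude odds ratio with a Woolf (log-normal) confidence interval.

    A zero in b or c leaves the OR undefined (flagged; no continuity
    correction is applied).
    """
    p, test = _association_p(table)
    if not table.or_defined or table.a * table.d == 0:
        point = float("inf") if table.a * table.d > 0 else float("nan")
        return OrResult(point, float("nan"), float("nan"), p, test, defined=False)
    a, b, c, d = table.a, table.b, table.c, table.d
    point = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    # the conventional two-decimal quantile at the 95% level, matching how
    # clinical factor tables are typically computed and printed
    z = 1.96 if abs(alpha - 0.05) < 1e-12 else sps.norm.ppf(1 - alpha / 2)
    log_or = np.log(point)
    return OrResult(
        or_point=float(point),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        p_value=p,
        test_used=test,
    )


def proportion(numerator: int, denominator: int) -> float:
    """Response-rate arithmetic as a percentage rounded to 1 decimal."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    return round(100.0 * numerator / denominator, 1)


# ---------------------------------------------------------------------------
# stepwise logistic regression
# ---------------------------------------------------------------------------


@dataclass
class RetainedFactor:
    name: str
    adjusted_or: float
    ci_low: float
    ci_high: float
    p_value: float
    separation: bool = False


@dataclass
class StepwiseResult:
    retained: list[RetainedFactor]
    screened_in: list[str]
    univariate_p: dict[str, float]
    warnings: list[str] = field(default_factory=list)

    @property
    def retained_names(self) -> list[str]:
        return [f.name for f in self.retained]


def _univariate_p(y: np.ndarray, x: np.ndarray) -> float:
    vals = np.unique(x)
    if len(vals) <= 1:
        return 1.0
    if len(vals) == 2:  # binary factor: 2x2 association test
        t = ContingencyTable(
            a=int(((x == vals[1]) & (y == 1)).sum()),
            b=int(((x == vals[1]) & (y == 0)).sum()),
            c=int(((x == vals[0]) & (y == 1)).sum()),
            d=int(((x == vals[0]) & (y == 0)).sum()),
        )
        p, _ = _association_p(t)
        return p
    return _lrt_p(y, np.empty((len(y), 0)), x)


def _fit_logit(y: np.ndarray, X: np.ndarray):
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        except Exception:
            return None


def _lrt_p(y: np.ndarray, X_base: np.ndarray, x_new: np.ndarray) -> float:
    full = _fit_logit(y, np.column_stack([X_base, x_new]))
    base = _fit_logit(y, X_base) if X_base.shape[1] else _fit_logit(y, np.empty((len(y), 0)))
    if full is None or base is None or not np.isfinite(full.llf) or not np.isfinite(base.llf):
        return float("nan")
    lr = 2.0 * (full.llf - base.llf)
    if lr < -1e-6:
        return float("nan")
    return float(sps.chi2.sf(max(lr, 0.0), df=1))


def stepwise_logistic(
    records: pd.DataFrame,
    outcome: str,
    candidates: Sequence[str],
    entry_p: float = 0.2,
    enter_p: float = 0.05,
    stay_p: float = 0.05,
    alpha: float = 0.05,
) -> StepwiseResult:
    """Univariate screen (p < entry_p) followed by forward-backward stepwise
    selection on likelihood-ratio p-values; retained factors are reported
    with adjusted ORs and Wald confidence intervals.

    Quasi-complete separation is flagged (huge coefficients produce the
    unstable, extremely wide intervals typical of small samples); perfectly
    collinear duplicates simply fail to improve the likelihood and are
    never entered alongside their twin.
    """
    y = records[outcome].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    notes: list[str] = []

    uni = {c: _univariate_p(y, records[c].to_numpy(dtype=float)) for c in candidates}
    screened = [c for c in candidates if np.isfinite(uni[c]) and uni[c] < entry_p]

    model: list[str] = []
    changed = True
    while changed:
        changed = False
        # forward
        best_c, best_p = None, enter_p
        X_base = records[model].to_numpy(dtype=float) if model else np.empty((len(y), 0))
        for c in screened:
            if c in model:
                continue
            p = _lrt_p(y, X_base, records[c].to_numpy(dtype=float))
            if np.isfinite(p) and p < best_p:
                best_c, best_p = c, p
        if best_c is not None:
            model.append(best_c)
            changed = True
        # backward
        if len(model) > 1:
            worst_c, worst_p = None, stay_p
            for c in model:
                others = [m for m in model if m != c]
                X_base = records[others].to_numpy(dtype=float) if others else np.empty((len(y), 0))
                p = _lrt_p(y, X_base, records[c].to_numpy(dtype=float))
                if not np.isfinite(p) or p > worst_p:
                    worst_c, worst_p = c, p
            if worst_c is not None:
                model.remove(worst_c)
                changed = True

    retained: list[RetainedFactor] = []
    if model:
        fit = _fit_logit(y, records[model].to_numpy(dtype=float))
        if fit is not None:
            z = sps.norm.ppf(1 - alpha / 2)
            params = np.asarray(fit.params)
            ses = np.asarray(fit.bse)
            pvals = np.asarray(fit.pvalues)
            for j, name in enumerate(model, start=1):
                coef, se = params[j], ses[j]
                sep = abs(coef) > SEPARATION_COEF_LIMIT or not np.isfinite(se)
                if sep:
                    notes.append(
                        f"{name}: separation suspected; confidence interval unstable"
                    )
                retained.append(
                    RetainedFactor(
                        name=name,
                        adjusted_or=float(np.exp(coef)),
                        ci_low=float(np.exp(coef - z * se)),
                        ci_high=float(np.exp(coef + z * se)),
                        p_value=float(pvals[j]),
                        separation=sep,
                    )
                )
        else:
            notes.append("final model fit failed")
    return StepwiseResult(retained=retained, screened_in=screened,
                         univariate_p=uni, warnings=notes)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RocResult:
    auc_roc: float
    cutoff: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float


def roc_analysis(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """Empirical ROC by rank.

    AUC equals the Mann-Whitney concordance U/(n1*n0) with mid-rank tie
    handling; the cut-off is the observed score value that maximises the
    Youden index for the rule "positive if score >= cut-off", ties broken
    toward the higher cut-off (higher specificity).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")

    ranks = sps.rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    best = None
    for c in np.unique(s):
        pred = s >= c
        sens = float((pred & (y == 1)).sum()) / n1
        spec = float((~pred & (y == 0)).sum()) / n0
        j = sens + spec - 1.0
        # strict > plus ascending c scan => ties resolve to the larger
        # cut-off, i.e. toward higher specificity
        if best is None or j > best[0] - 1e-12:
            if best is None or j > best[0] + 1e-12 or c > best[1]:
                best = (j, float(c), sens, spec)
    return RocResult(auc_roc=float(auc), cutoff=best[1],
                     sensitivity_at_cutoff=best[2], specificity_at_cutoff=best[3])


# ---------------------------------------------------------------------------
# correlation and group comparisons
# ---------------------------------------------------------------------------


def correlation_compare(x1, y1, x2, y2) -> tuple[float, float, float]:
    """Two-sided test for a difference between two independent Pearson
    correlations via Fisher's z-transform; returns (r1, r2, p)."""
    x1, y1, x2, y2 = (np.asarray(v, dtype=float) for v in (x1, y1, x2, y2))
    if len(x1) < 4 or len(x2) < 4:
        raise ValueError("each sample must have n >= 4")
    r1 = float(np.corrcoef(x1, y1)[0, 1])
    r2 = float(np.corrcoef(x2, y2)[0, 1])
    if abs(r1) >= 1.0 - 1e-12 or abs(r2) >= 1.0 - 1e-12:
        warnings.warn("|r| = 1: Fisher z is infinite")
        return r1, r2, 0.0 if r1 != r2 else 1.0
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    se = np.sqrt(1.0 / (len(x1) - 3) + 1.0 / (len(x2) - 3))
    z = (z1 - z2) / se
    return r1, r2, float(2.0 * sps.norm.sf(abs(z)))


@dataclass(frozen=True)
class GroupCompareResult:
    statistic: float
    p_value: float
    test_used: str


def group_compare(values_a, values_b, paired: bool = False,
                  normality_alpha: float = 0.05) -> GroupCompareResult:
    """Normality-gated two-group comparison.

    Unpaired: Student's t-test when both groups pass a Shapiro-Wilk screen,
    otherwise the Mann-Whitney U-test (mid-rank ties).  Paired: Wilcoxon
    signed-rank (used for within-patient term comparisons).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")

    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison needs equal-length groups")
        diffs = a - b
        if np.all(diffs == 0):
            return GroupCompareResult(0.0, 1.0, "wilcoxon")
        stat, p = sps.wilcoxon(a, b, zero_method="wilcox")
        return GroupCompareResult(float(stat), float(p), "wilcoxon")

    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return GroupCompareResult(float(len(a) * len(b) / 2.0), 1.0, "mannwhitney")
    normal = True
    for g in (a, b):
        if np.ptp(g) == 0:
            normal = False
            break
        if sps.shapiro(g).pvalue <= normality_alpha:
            normal = False
            break
    if normal:
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        return GroupCompareResult(float(stat), float(p), "t")
    stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return GroupCompareResult(float(stat), float(p), "mannwhitney")


# ---------------------------------------------------------------------------
# factor-table report
# ---------------------------------------------------------------------------


def factor_table(
    records: pd.DataFrame,
    outcome: str,
    factors: Sequence[str],
    stepwise: StepwiseResult | None = None,
) -> pd.DataFrame:
    """One row per binary factor: counts, crude OR, CI, p, adjusted OR when
    retained by the stepwise model — a machine-readable univariate/
    multivariate factor table."""
    rows = []
    y = records[outcome].to_numpy(dtype=int)
    adj = {f.name: f for f in (stepwise.retained if stepwise else [])}
    for f in factors:
        x = records[f].to_numpy(dtype=int)
        t = ContingencyTable(
            a=int(((x == 1) & (y == 1)).sum()),
            b=int(((x == 1) & (y == 0)).sum()),
            c=int(((x == 0) & (y == 1)).sum()),
            d=int(((x == 0) & (y == 0)).sum()),
        )
        res = crude_or(t)
        row = {
            "factor": f, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "crude_or": res.or_point, "ci_low": res.ci_low, "ci_high": res.ci_high,
            "p_value": res.p_value, "test_used": res.test_used,
            "adjusted_or": np.nan, "adjusted_ci_low": np.nan,
            "adjusted_ci_high": np.nan, "adjusted_p": np.nan,
        }
        if f in adj:
            row.update(
                adjusted_or=adj[f].adjusted_or, adjusted_ci_low=adj[f].ci_low,
                adjusted_ci_high=adj[f].ci_high, adjusted_p=adj[f].p_value,
            )
        rows.append(row)
    return pd.DataFrame(rows)
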