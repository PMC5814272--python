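"""Association statistics: proportion tests, mean comparisons, correlation,
Benjamini-Hochberg FDR, Kaplan-Meier / log-rank survival.

The two-proportion z test, BH step-up and product-limit/log-rank routines
are implemented directly (they are part of the analysis contract and are
cross-checked against independent library implementations in the test
suite); t tests and Pearson correlation delegate to scipy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError
from .io_formats import ClinicalRecord


def significance_stars(p: float) -> str:
    """Presentation column: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# Proportions
# ---------------------------------------------------------------------------

def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z test, two-sided.

    Returns ``(z, p)``.  A pooled proportion of exactly 0 or 1 is a
    degenerate comparison: z is defined as 0 with p = 1 (warned).
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1 or not (0 <= x <= n):
            raise ValueError(f"invalid counts x={x}, n={n}")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn("degenerate pooled proportion; z = 0, p = 1")
        return 0.0, 1.0
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    p = 2 * sps.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# Mean comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    statistic: float
    p: float
    test_name: str

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


def mean_test(a: Sequence[float], b: Sequence[float],
              variant: Literal["student", "welch"] = "welch",
              label_a: str = "a", label_b: str = "b") -> GroupComparison:
    """Unpaired two-tailed Student's or Welch's t test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("each group needs n >= 2 for a t test")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = np.inf if a.mean() > b.mean() else -np.inf, 0.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    sem = lambda x: float(x.std(ddof=1) / np.sqrt(x.size))
    return GroupComparison(
        label_a=label_a, label_b=label_b, n_a=a.size, n_b=b.size,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sem_a=sem(a), sem_b=sem(b), statistic=float(t), p=float(p),
        test_name="student_t" if variant == "student" else "welch_t",
    )


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    gene: str
    r: float
    p: float
    n: int

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


def pearson(x: Sequence[float], y: Sequence[float],
            gene: str = "") -> CorrelationResult:
    """Pearson correlation with two-sided p (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise DataError("Pearson correlation needs n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DataError("Pearson correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(gene=gene, r=float(r), p=float(p), n=int(x.size))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate for one group."""

    group: str
    times: np.ndarray        # distinct event/censor times, ascending
    survival: np.ndarray     # S(t) just after each time
    at_risk: np.ndarray      # number at risk just before each time
    n_events: np.ndarray     # deaths at each time
    n_censored: np.ndarray   # censored at each time


def kaplan_meier(records: Sequence[ClinicalRecord], group: str = "") -> SurvivalCurve:
    t = np.array([r.os_months for r in records], dtype=float)
    e = np.array([r.os_event for r in records], dtype=bool)
    if t.size == 0:
        raise DataError("empty survival group")
    times = np.unique(t)
    at_risk, deaths, censored, surv = [], [], [], []
    s = 1.0
    for ti in times:
        n_i = int(np.sum(t >= ti))
        d_i = int(np.sum((t == ti) & e))
        c_i = int(np.sum((t == ti) & ~e))
        if d_i:
            s *= 1 - d_i / n_i
        at_risk.append(n_i)
        deaths.append(d_i)
        censored.append(c_i)
        surv.append(s)
    return SurvivalCurve(group=group, times=times,
                         survival=np.array(surv), at_risk=np.array(at_risk),
                         n_events=np.array(deaths), n_censored=np.array(censored))


def km_logrank(groups: Mapping[str, Sequence[ClinicalRecord]]
               ) -> tuple[dict[str, SurvivalCurve], float, float]:
    """Kaplan-Meier curves per group plus the standard log-rank test.

    Returns ``(curves, chi_square, p)`` with ``len(groups) - 1`` degrees
    of freedom.  Raises if fewer than two groups or no events at all.
    """
    if len(groups) < 2:
        raise DataError("log-rank test needs >= 2 groups")
    labels = list(groups)
    times = {g: np.array([r.os_months for r in groups[g]], dtype=float)
             for g in labels}
    events = {g: np.array([r.os_event for r in groups[g]], dtype=bool)
              for g in labels}
    if not any(events[g].any() for g in labels):
        raise DataError("log-rank test undefined with no observed events")

    all_event_times = np.unique(np.concatenate(
        [times[g][events[g]] for g in labels if events[g].any()]))
    k = len(labels)
    observed = np.zeros(k)
    expected = np.zeros(k)
    # variance of the (k-1)-vector of O-E; use groups 0..k-2
    var = np.zeros((k - 1, k - 1))
    for ti in all_event_times:
        n_g = np.array([np.sum(times[g] >= ti) for g in labels], dtype=float)
        d_g = np.array([np.sum((times[g] == ti) & events[g]) for g in labels],
                       dtype=float)
        n_tot, d_tot = n_g.sum(), d_g.sum()
        if n_tot <= 1 or d_tot == 0:
            continue
        observed += d_g
        expected += d_tot * n_g / n_tot
        factor = d_tot * (n_tot - d_tot) / (n_tot - 1) / n_tot
        for i in range(k - 1):
            for j in range(k - 1):
                if i == j:
                    var[i, j] += factor * n_g[i] * (n_tot - n_g[i]) / n_tot
                else:
                    var[i, j] -= factor * n_g[i] * n_g[j] / n_tot
    diff = (observed - expected)[: k - 1]
    try:
        chi2 = float(diff @ np.linalg.solve(var, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(var) @ diff)
    p = float(sps.chi2.sf(chi2, df=k - 1))
    curves = {g: kaplan_meier(groups[g], group=g) for g in labels}
    return curves, chi2, p


# ---------------------------------------------------------------------------
# Infiltration fold changes between sample groups
# ---------------------------------------------------------------------------

def infiltration_fold_change(calls, groups: Mapping[str, str],
                             group_a: str, group_b: str,
                             min_samples: int = 10) -> pd.DataFrame:
    """Per-cell-type infiltration percent in two sample groups.

    ``calls`` is a boolean samples-by-cell-types frame (or an object with
    a ``.calls`` attribute).  Cell types with fewer than ``min_samples``
    positive calls overall are excluded.  Fold change is
    ``percent_a / percent_b`` (inf when percent_b is 0); ``log2_fold``
    carries the logarithmic-scale view.  p comes from the pooled
    two-proportion z test.
    """
    calls = getattr(calls, "calls", calls)
    sample_group = pd.Series(groups)
    in_a = sample_group[sample_group == group_a].index
    in_b = sample_group[sample_group == group_b].index
    if len(in_a) == 0 or len(in_b) == 0:
        raise DataError("both groups must be nonempty")
    rows = []
    for ct in calls.columns:
        col = calls[ct]
        if int(col.sum()) < min_samples:
            continue
        x1, n1 = int(col.loc[col.index.intersection(in_a)].sum()), len(in_a)
        x2, n2 = int(col.loc[col.index.intersection(in_b)].sum()), len(in_b)
        pct_a, pct_b = 100.0 * x1 / n1, 100.0 * x2 / n2
        fold = np.inf if pct_b == 0 else pct_a / pct_b
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z, p = two_proportion_z(x1, n1, x2, n2)
        rows.append({
            "cell_type": ct, "percent_a": pct_a, "percent_b": pct_b,
            "fold_change": fold,
            "log2_fold": np.log2(fold) if np.isfinite(fold) and fold > 0
                         else (np.inf if fold == np.inf else -np.inf),
            "z": z, "p": p, "stars": significance_stars(p),
        })
    return pd.DataFrame(
        rows, columns=["cell_type", "percent_a", "percent_b", "fold_change",
                       "log2_fold", "z", "p", "stars"])
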