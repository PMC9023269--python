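"""Contingency-table and replicate-summary statistics.

Two tests back the group comparisons in this pipeline: the Pearson
chi-square test of independence on large-deletion count tables (deletion vs
no deletion, by treatment) and the unpaired two-sample t-test reconstructed
from replicate summaries (mean, SEM, n), as published tables report.

The p-value machinery -- the regularized incomplete gamma function for the
chi-square survival function and the regularized incomplete beta function
for the t distribution -- is implemented here directly (series and
continued-fraction expansions), so the module has no runtime dependency on
a statistics library; accuracy is verified against independent
high-precision oracles in the test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GroupSummary",
    "chi_square_independence",
    "t_test_from_summary",
    "profile_summary",
    "regularized_gamma_q",
    "regularized_beta",
]

_EPS = 3e-16
_MAX_ITER = 500


@dataclass(frozen=True)
class GroupSummary:
    """Replicate summary: mean, standard error of the mean, replicate count."""

    mean: float
    sem: float
    n: int

    def __post_init__(self):
        if self.sem < 0:
            raise ValueError("sem must be >= 0")
        if self.n < 2:
            raise ValueError("need n >= 2 replicates")


# --- special functions -------------------------------------------------------

def _gamma_p_series(a: float, x: float) -> float:
    """Lower regularized incomplete gamma P(a, x) by series, for x < a + 1."""
    if x == 0.0:
        return 0.0
    ap = a
    term = 1.0 / a
    total = term
    for _ in range(_MAX_ITER):
        ap += 1.0
        term *= x / ap
        total += term
        if abs(term) < abs(total) * _EPS:
            break
    return total * math.exp(-x + a * math.log(x) - math.lgamma(a))

def _gamma_q_contfrac(a: float, x: float) -> float:
    """Upper regularized incomplete gamma Q(a, x) by continued fraction, x >= a + 1."""
    tiny = 1e-300
    b = x + 1.0 - a
    c = 1.0 / tiny
    d = 1.0 / b
    h = d
    for i in range(1, _MAX_ITER + 1):
        an = -i * (i - a)
        b += 2.0
        d = an * d + b
        if abs(d) < tiny:
            d = tiny
        c = b + an / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < _EPS:
            break
    return h * math.exp(-x + a * math.log(x) - math.lgamma(a))

def regularized_gamma_q(a: float, x: float) -> float:
    """Q(a, x) = Gamma(a, x)/Gamma(a): chi-square survival is Q(df/2, stat/2)."""
    if a <= 0 or x < 0:
        raise ValueError("require a > 0 and x >= 0")
    if x < a + 1.0:
        return 1.0 - _gamma_p_series(a, x)
    return _gamma_q_contfrac(a, x)

def _beta_contfrac(a: float, b: float, x: float) -> float:
    tiny = 1e-300
    qab, qap, qam = a + b, a + 1.0, a - 1.0
    c = 1.0
    d = 1.0 - qab * x / qap
    if abs(d) < tiny:
        d = tiny
    d = 1.0 / d
    h = d
    for m in range(1, _MAX_ITER + 1):
        m2 = 2 * m
        aa = m * (b - m) * x / ((qam + m2) * (a + m2))
        d = 1.0 + aa * d
        if abs(d) < tiny:
            d = tiny
        c = 1.0 + aa / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        h *= d * c
        aa = -(a + m) * (qab + m) * x / ((a + m2) * (qap + m2))
        d = 1.0 + aa * d
        if abs(d) < tiny:
            d = tiny
        c = 1.0 + aa / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < _EPS:
            break
    return h

def regularized_beta(a: float, b: float, x: float) -> float:
    """I_x(a, b), the regularized incomplete beta function."""
    if not 0.0 <= x <= 1.0:
        raise ValueError("x must be in [0, 1]")
    if x == 0.0 or x == 1.0:
        return x
    ln_front = (
        math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
        + a * math.log(x) + b * math.log1p(-x)
    )
    front = math.exp(ln_front)
    if x < (a + 1.0) / (a + b + 2.0):
        return front * _beta_contfrac(a, b, x) / a
    return 1.0 - front * _beta_contfrac(b, a, 1.0 - x) / b


# --- tests -------------------------------------------------------------------

def chi_square_independence(table, yates: bool = False) -> dict:
    """Pearson chi-square test of independence on an r x c count table.

    ``table`` is any 2-D array-like of non-negative integers with at least
    two rows and columns.  ``yates`` applies the continuity correction
    (|O - E| reduced by 0.5, floored at 0; meaningful for 2x2 tables).
    Raises ``ValueError`` on degenerate tables (a zero marginal).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    total = obs.sum()
    if total == 0:
        raise ValueError("degenerate table: grand total is 0")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("degenerate table: zero marginal")
    expected = row * col / total
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = regularized_gamma_q(df / 2.0, stat / 2.0)
    return {"statistic": stat, "df": df, "p": p}


def t_test_from_summary(a: GroupSummary, b: GroupSummary) -> dict:
    """Unpaired pooled-variance t-test from (mean, SEM, n) summaries.

    Group variances are recovered from the SEMs (s^2 = n * sem^2); the
    two-tailed p-value comes from the t distribution with n_a + n_b - 2
    degrees of freedom via the regularized incomplete beta function.
    """
    df = a.n + b.n - 2
    var_a = a.n * a.sem**2
    var_b = b.n * b.sem**2
    pooled = ((a.n - 1) * var_a + (b.n - 1) * var_b) / df
    se = math.sqrt(pooled * (1.0 / a.n + 1.0 / b.n))
    if se == 0.0:
        if a.mean == b.mean:
            return {"t": 0.0, "df": df, "p": 1.0}
        warnings.warn("zero variance with unequal means: p = 0", stacklevel=2)
        return {"t": math.inf if a.mean > b.mean else -math.inf, "df": df, "p": 0.0}
    t = (a.mean - b.mean) / se
    # two-tailed: P(|T| > |t|) = I_{df/(df+t^2)}(df/2, 1/2)
    p = regularized_beta(df / 2.0, 0.5, df / (df + t * t))
    return {"t": t, "df": df, "p": min(1.0, p)}


def summarize_metrics(values_by_metric: dict) -> dict:
    """Per-metric (mean, SEM, n) from metric name -> list of replicate values.

    ``None`` entries are dropped; raises ``ValueError`` with fewer than two
    usable replicates for a metric.
    """
    out = {}
    for metric, values in values_by_metric.items():
        vals = [v for v in values if v is not None]
        if len(vals) < 2:
            raise ValueError(f"insufficient replicates for metric {metric!r}")
        arr = np.asarray(vals, dtype=float)
        n = arr.size
        sem = float(arr.std(ddof=1) / math.sqrt(n))
        out[metric] = GroupSummary(mean=float(arr.mean()), sem=sem, n=n)
    return out


def profile_summary(profiles) -> dict:
    """(mean, SEM, n) for the standard metrics over replicate MutationProfiles.

    Requires at least two profiles; metric percentages that are missing
    (``None``, e.g. no insertions observed) are dropped per metric.
    """
    if len(profiles) < 2:
        raise ValueError("insufficient replicates: need >= 2 profiles")
    metrics = [
        "indel_rate",
        "pct_del_1bp",
        "pct_del_gt1bp",
        "pct_insertion",
        "pct_mixed",
        "pct_TIS_1bp_of_insertions",
    ]
    return summarize_metrics(
        {m: [getattr(p, m) for p in profiles] for m in metrics}
    )
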