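"""Contingency-table statistics for enrichment of splice-altering calls.

Two classical tests back the downstream application analyses:

* :func:`chisq_trend` — the chi-squared test for trend in proportions
  (Cochran-Armitage), used to ask whether the proportion of predicted
  splice-altering variants rises with recurrence (how often a somatic
  variant was observed across tumor samples).  Group scores default to
  1..k and no continuity correction is applied; the p-value is invariant
  to affine transformations of the scores.
* :func:`pearson_chisq` — Pearson's chi-squared test on a 2x2 table, used
  to compare the splice-altering proportion between cancer-census genes and
  all other genes.  Yates continuity correction is off by default (matching
  the uncorrected statistic's name) but available via a flag.

p-values below double precision's representable floor are displayed as
"< 2.2e-16" alongside the raw float, the conventional display cutoff.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: Conventional display floor for vanishing p-values.
P_DISPLAY_FLOOR = 2.2e-16


def format_p(p: float) -> str:
    return f"< {P_DISPLAY_FLOOR:g}" if p < P_DISPLAY_FLOOR else f"{p:.4g}"


@dataclass
class TrendTable:
    """k ordered groups of (total, event) counts with numeric group scores."""

    n_total: np.ndarray
    n_event: np.ndarray
    scores: np.ndarray | None = None
    labels: list | None = None

    def __post_init__(self):
        self.n_total = np.asarray(self.n_total, dtype=float)
        self.n_event = np.asarray(self.n_event, dtype=float)
        if self.n_total.size < 2:
            raise ValueError("need at least two groups")
        if self.n_total.shape != self.n_event.shape:
            raise ValueError("totals and events must align")
        if (self.n_event < 0).any() or (self.n_event > self.n_total).any():
            raise ValueError("events must satisfy 0 <= event <= total")
        if self.scores is None:
            self.scores = np.arange(1.0, self.n_total.size + 1.0)
        else:
            self.scores = np.asarray(self.scores, dtype=float)

    @property
    def proportions(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.n_event / self.n_total


@dataclass
class TwoByTwo:
    """event/non-event x group1/group2 counts: [[a, b], [c, d]]."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class TestResult:
    chi2: float
    df: int
    p: float
    p_display: str = field(init=False)

    def __post_init__(self):
        self.p_display = format_p(self.p)


def chisq_trend(table: TrendTable) -> TestResult:
    """Chi-squared test for trend in proportions, df = 1, no correction.

    Statistic: with pooled proportion pbar, scores s_i, totals n_i and
    events x_i,

        chi2 = [sum s_i (x_i - n_i pbar)]^2
               / [pbar (1 - pbar) (sum n_i s_i^2 - (sum n_i s_i)^2 / N)]
    """
    x, n, s = table.n_event, table.n_total, table.scores
    active = n > 0
    if active.sum() < 2:
        raise ValueError("need at least two groups with observations")
    x, n, s = x[active], n[active], s[active]
    N = n.sum()
    pbar = x.sum() / N
    if pbar == 0.0 or pbar == 1.0:
        warnings.warn("degenerate trend table: all events zero or saturated")
        return TestResult(0.0, 1, 1.0)
    num = float((s * (x - n * pbar)).sum()) ** 2
    den = pbar * (1 - pbar) * float((n * s * s).sum() - (n * s).sum() ** 2 / N)
    if den == 0:
        warnings.warn("degenerate scores: zero trend variance")
        return TestResult(0.0, 1, 1.0)
    chi2 = num / den
    return TestResult(float(chi2), 1, float(stats.chi2.sf(chi2, 1)))


def pearson_chisq(t: TwoByTwo, yates: bool = False) -> TestResult:
    """Pearson's chi-squared test on a 2x2 table (df = 1)."""
    m = t.matrix
    if (m.sum(axis=0) == 0).any() or (m.sum(axis=1) == 0).any():
        raise ValueError("a zero marginal makes the chi-squared test undefined")
    chi2, p, dof, _ = stats.chi2_contingency(m, correction=yates)
    return TestResult(float(chi2), int(dof), float(p))


#: Recurrence bins used in the somatic-variant trend analysis.
DEFAULT_RECURRENCE_BINS = ((1, 2), (3, 4), (5, math.inf))


def recurrence_table(calls, bins=DEFAULT_RECURRENCE_BINS) -> TrendTable:
    """Bin (recurrence_count, is_positive) calls into a TrendTable.

    Bins are inclusive (lo, hi) ranges; empty bins are omitted (with their
    scores), so the trend test runs on observed groups only.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("no calls supplied")
    totals = np.zeros(len(bins))
    events = np.zeros(len(bins))
    for rec, pos in calls:
        if rec < 1:
            raise ValueError(f"recurrence must be >= 1, got {rec}")
        for i, (lo, hi) in enumerate(bins):
            if lo <= rec <= hi:
                totals[i] += 1
                events[i] += bool(pos)
                break
        else:
            raise ValueError(f"recurrence {rec} falls in no bin")
    keep = totals > 0
    labels = [f"{lo}-{hi}" for (lo, hi) in bins]
    return TrendTable(
        n_total=totals[keep],
        n_event=events[keep],
        scores=np.arange(1.0, len(bins) + 1.0)[keep],
        labels=[l for l, k in zip(labels, keep) if k],
    )
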