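"""Contingency-table and rank statistics for cohort comparisons.

Covers the suture-material comparison (relative risk with the Katz
log-normal interval, two-sided Fisher exact test) and the nonparametric
group comparisons (Mann-Whitney U with midrank ties, Kruskal-Wallis),
plus simple rate arithmetic with display rounding kept separate from
the value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .cohort import PregnancyRecord, Suture, assign_risk_group, is_preterm

#: 97.5th normal percentile at full precision (1.96 rounded is not enough
#: to reproduce 2-dp interval bounds stably).
Z95 = 1.959964


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 counts; rows are exposure groups, columns outcome / non-outcome.

    Row 1 = (a, b), row 2 = (c, d); risk ratio compares row 1 to row 2.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total == 0:
            raise ValueError("table total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def swap_rows(self) -> "TwoByTwo":
        return TwoByTwo(self.c, self.d, self.a, self.b)

    def swap_columns(self) -> "TwoByTwo":
        return TwoByTwo(self.b, self.a, self.d, self.c)


@dataclass(frozen=True)
class RelativeRiskResult:
    rr: float
    ci_low: float
    ci_high: float
    confidence: float = 0.95
    continuity_corrected: bool = False


def relative_risk(table: TwoByTwo, confidence: float = 0.95,
                  continuity: bool = False) -> RelativeRiskResult:
    """Risk ratio of row 1 vs row 2 with the Katz log-method interval:
    exp(ln rr +/- z * sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))).

    A zero event cell leaves the interval undefined (NaN) unless
    ``continuity`` adds 0.5 to every cell (flagged in the result).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + b == 0 or c + d == 0:
        raise ValueError("both row totals must be positive")
    corrected = False
    if (a == 0 or c == 0) and continuity:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    if c == 0:
        rr = math.inf
        return RelativeRiskResult(rr, math.nan, math.nan, confidence, corrected)
    rr = (a / (a + b)) / (c / (c + d))
    if a == 0:
        return RelativeRiskResult(rr, math.nan, math.nan, confidence, corrected)
    z = Z95 if confidence == 0.95 else float(sps.norm.ppf(0.5 + confidence / 2.0))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return RelativeRiskResult(
        rr,
        math.exp(math.log(rr) - z * se),
        math.exp(math.log(rr) + z * se),
        confidence,
        corrected,
    )


def fisher_exact_two_sided(table: TwoByTwo) -> float:
    """Two-sided Fisher exact p: with margins fixed, the sum of
    hypergeometric probabilities of all tables no more probable than the
    observed one, accumulated in ascending order.
    """
    if table.total > 10_000:
        raise ValueError("table total exceeds the enumeration bound (10000)")
    n = table.total
    r1 = table.a + table.b  # row-1 margin
    c1 = table.a + table.c  # column-1 margin
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, c1, r1)
    p_obs = float(sps.hypergeom.pmf(table.a, n, c1, r1))
    eligible = pmf <= p_obs * (1.0 + 1e-9)  # guard float noise at ties
    return float(min(1.0, np.sort(pmf[eligible]).sum()))


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float        # min(U_x, U_y) convention
    u_x: float
    u_y: float
    p: float
    method: str     # "exact" or "asymptotic"


def mann_whitney(x: Sequence[float], y: Sequence[float],
                 continuity: bool = True) -> MannWhitneyResult:
    """Two-sided Mann-Whitney with midrank ties.

    Exact p by full enumeration of rank assignments when both samples have
    at most 8 observations (two-sided as the probability of a U at least as
    far from its null mean n1*n2/2 as observed); otherwise the normal
    approximation with tie correction (optionally continuity-corrected).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r_x = float(ranks[:n1].sum())
    u_x = r_x - n1 * (n1 + 1) / 2.0
    u_y = n1 * n2 - u_x
    mu = n1 * n2 / 2.0

    if n1 <= 8 and n2 <= 8:
        obs_dev = abs(u_x - mu)
        count = 0
        total = 0
        rank_sum_base = n1 * (n1 + 1) / 2.0
        for combo in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(combo)].sum() - rank_sum_base
            if abs(u - mu) >= obs_dev - 1e-9:
                count += 1
            total += 1
        return MannWhitneyResult(min(u_x, u_y), u_x, u_y, count / total, "exact")

    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return MannWhitneyResult(min(u_x, u_y), u_x, u_y, 1.0, "asymptotic")
    dev = abs(u_x - mu)
    if continuity:
        dev = max(dev - 0.5, 0.0)
    z = dev / math.sqrt(var)
    p = min(1.0, 2.0 * float(sps.norm.sf(z)))
    return MannWhitneyResult(min(u_x, u_y), u_x, u_y, p, "asymptotic")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with the chi-square reference
    (k-1 degrees of freedom).  All-equal observations give H = 0, p = 1."""
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need at least 3 observations in total")
    if all(np.all(g == groups[0][0]) for g in groups):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def rate(numerator: int, denominator: int) -> float:
    """Percentage 100*num/den; rounding is a display concern (format_rate)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    return 100.0 * numerator / denominator


def format_rate(value: float, decimals: int = 1) -> str:
    return f"{value:.{decimals}f}%"


# --- cohort-level convenience ----------------------------------------------


def suture_preterm_table(records: Sequence[PregnancyRecord],
                         outcome: str = "preterm") -> TwoByTwo:
    """Suture-material 2x2 among cerclage recipients.

    Row 1 = monofilament, row 2 = braided; ``outcome="preterm"`` counts
    births <37+0 in column 1, ``outcome="term"`` the complement (the
    direction whose risk ratio matches the published interval is the term
    direction with rows swapped; see ``docs/methods.md``).
    """
    if outcome not in ("preterm", "term"):
        raise ValueError("outcome must be 'preterm' or 'term'")
    counts = {Suture.MONOFILAMENT: [0, 0], Suture.BRAIDED: [0, 0]}
    for rec in records:
        if rec.cerclage is None:
            continue
        event = is_preterm(rec.ga_at_birth)
        if outcome == "term":
            event = not event
        counts[rec.cerclage.suture][0 if event else 1] += 1
    (a, b), (c, d) = counts[Suture.MONOFILAMENT], counts[Suture.BRAIDED]
    return TwoByTwo(a, b, c, d)


def group_comparison(records: Sequence[PregnancyRecord],
                     field: str) -> Optional[tuple[float, float]]:
    """Mann-Whitney comparison of a numeric record field between the
    low-risk and high-risk outcome strata; None when a stratum is empty."""
    g1, g2 = [], []
    for rec in records:
        v = getattr(rec, field)
        if v is None:
            continue
        from .cohort import RiskLabel  # local to avoid cycle at import time

        if assign_risk_group(rec).label is RiskLabel.GROUP1:
            g1.append(v)
        else:
            g2.append(v)
    if not g1 or not g2:
        return None
    res = mann_whitney(g1, g2)
    return res.u, res.p
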