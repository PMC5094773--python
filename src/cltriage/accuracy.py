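"""Diagnostic-accuracy machinery for CL and %ΔCL screening thresholds.

The positive class throughout is the high-risk outcome stratum (preterm
birth and/or cerclage).  Test-positive predicates are "CL <= t" for
single-measurement sweeps and "%ΔCL >= d" for interval-shortening
sweeps.  Each sweep row uses only the records with the required
measurement(s) observed; metrics are computed from unrounded counts, and
a separate formatter applies report rounding (integer percents, LR to
one decimal) plus the conventional rendering of undefined cells (an
empty test-negative set with no missed positives shows NPV 100%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cohort import PregnancyRecord, cohort_to_frame

#: Default threshold sets (mm) per timepoint and (%) per interval.
DEFAULT_CL_THRESHOLDS = {"A": (20, 25, 30, 35, 40, 50),
                         "B": (20, 25, 30, 35, 40, 50),
                         "C": (20, 25, 30, 35, 37)}
DEFAULT_DELTA_THRESHOLDS = (5, 10, 20, 30, 40)

_TP_COLUMN = {"A": "cl_a", "B": "cl_b", "C": "cl_c"}
_INTERVAL_COLUMN = {"A-B": "d_ab", "B-C": "d_bc", "A-C": "d_ac"}


@dataclass(frozen=True)
class AccuracyResult:
    """Confusion counts with derived Se/Sp/PPV/NPV/LR+.

    Metrics whose denominator is empty are NaN and listed in ``undefined``;
    LR+ is ``inf`` when specificity is 1 with nonzero sensitivity.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    undefined: frozenset[str] = field(default_factory=frozenset, compare=False)

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int) -> "AccuracyResult":
        undef = set()
        if tp + fn == 0:
            undef.add("sensitivity")
        if tn + fp == 0:
            undef.add("specificity")
        if tp + fp == 0:
            undef.add("ppv")
        if tn + fn == 0:
            undef.add("npv")
        return cls(tp, fp, tn, fn, frozenset(undef))

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else math.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else math.nan

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else math.nan

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else math.nan

    @property
    def lr_pos(self) -> float:
        se, sp = self.sensitivity, self.specificity
        if math.isnan(se) or math.isnan(sp):
            return math.nan
        if sp == 1.0:
            return math.inf if se > 0 else math.nan
        return se / (1.0 - sp)


def confusion(values: Sequence[float], labels: Sequence[bool],
              predicate: Callable[[np.ndarray], np.ndarray]) -> AccuracyResult:
    """Confusion counts of ``predicate(values)`` against binary labels.

    Records with a missing (NaN/None) measurement are excluded from the
    denominator.
    """
    v = np.asarray([np.nan if x is None else x for x in values], dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.shape != y.shape:
        raise ValueError("values and labels must have equal length")
    obs = ~np.isnan(v)
    v, y = v[obs], y[obs]
    pos = np.asarray(predicate(v), dtype=bool)
    tp = int((pos & y).sum())
    fp = int((pos & ~y).sum())
    fn = int((~pos & y).sum())
    tn = int((~pos & ~y).sum())
    return AccuracyResult.from_counts(tp, fp, tn, fn)


def _as_frame(cohort) -> pd.DataFrame:
    if isinstance(cohort, pd.DataFrame):
        return cohort
    return cohort_to_frame(cohort)


def sweep_cl(cohort: Union[Sequence[PregnancyRecord], pd.DataFrame],
             timepoint: str,
             thresholds: Optional[Sequence[float]] = None) -> pd.DataFrame:
    """One row per CL threshold t with predicate "CL <= t" at a timepoint."""
    timepoint = str(timepoint).upper().strip()
    if timepoint not in _TP_COLUMN:
        raise ValueError(f"timepoint must be A, B or C, got {timepoint!r}")
    if thresholds is None:
        thresholds = DEFAULT_CL_THRESHOLDS[timepoint]
    df = _as_frame(cohort)
    values = df[_TP_COLUMN[timepoint]].to_numpy(float)
    labels = df["group2"].to_numpy(bool)
    rows = []
    for t in thresholds:
        res = confusion(values, labels, lambda v, t=t: v <= t)
        rows.append(_sweep_row(f"CL_{timepoint}", "<=", t, res))
    return pd.DataFrame(rows)


def sweep_delta(cohort: Union[Sequence[PregnancyRecord], pd.DataFrame],
                interval: str,
                thresholds: Optional[Sequence[float]] = None) -> pd.DataFrame:
    """One row per %ΔCL threshold d with predicate "ΔCL >= d" over an interval.

    Per-record ΔCL comes from pre-cerclage measurements only and requires
    both endpoints observed.
    """
    interval = str(interval).upper().replace("–", "-").strip()
    if interval not in _INTERVAL_COLUMN:
        raise ValueError(f"interval must be one of {sorted(_INTERVAL_COLUMN)}")
    if thresholds is None:
        thresholds = DEFAULT_DELTA_THRESHOLDS
    df = _as_frame(cohort)
    values = df[_INTERVAL_COLUMN[interval]].to_numpy(float)
    labels = df["group2"].to_numpy(bool)
    rows = []
    for d in thresholds:
        res = confusion(values, labels, lambda v, d=d: v >= d)
        rows.append(_sweep_row(f"dCL_{interval}", ">=", d, res))
    return pd.DataFrame(rows)


def _sweep_row(block: str, direction: str, threshold: float,
               res: AccuracyResult) -> dict:
    return {
        "block": block,
        "direction": direction,
        "threshold": threshold,
        "tp": res.tp, "fp": res.fp, "tn": res.tn, "fn": res.fn,
        "n": res.n,
        "sensitivity": res.sensitivity,
        "specificity": res.specificity,
        "ppv": res.ppv,
        "npv": res.npv,
        "lr_pos": res.lr_pos,
        "undefined": ";".join(sorted(res.undefined)),
    }


def full_sweep(cohort) -> pd.DataFrame:
    """All default CL and %ΔCL sweep blocks stacked into one table."""
    df = _as_frame(cohort)
    parts = [sweep_cl(df, tp) for tp in ("A", "B", "C")]
    parts += [sweep_delta(df, iv) for iv in ("A-B", "B-C", "A-C")]
    return pd.concat(parts, ignore_index=True)


def _fmt_pct(x: float, *, small_1dp: bool = True) -> str:
    """Integer percent, keeping one decimal below 10% (report style)."""
    if math.isnan(x):
        return ""
    pct = 100.0 * x
    if small_1dp and pct < 10.0 and round(pct) != pct:
        return f"{pct:.1f}"
    return f"{pct:.0f}"


def format_sweep(sweep: pd.DataFrame) -> pd.DataFrame:
    """Report-style rendering of a sweep table.

    Percentages to the nearest integer (one decimal below 10), LR+ to one
    decimal; an undefined NPV with no missed positives renders as 100 (no
    positive was called test-negative), other undefined cells render empty.
    """
    out = []
    for _, r in sweep.iterrows():
        undef = set(r["undefined"].split(";")) if r["undefined"] else set()
        npv = r["npv"]
        if "npv" in undef and r["fn"] == 0:
            npv_s = "100"
        else:
            npv_s = _fmt_pct(npv)
        ppv_s = "" if "ppv" in undef else _fmt_pct(r["ppv"])
        lr = r["lr_pos"]
        lr_s = "inf" if math.isinf(lr) else ("" if math.isnan(lr) else f"{lr:.1f}")
        out.append(
            {
                "block": r["block"],
                "threshold": f"{r['direction']} {r['threshold']:g}",
                "S": _fmt_pct(r["sensitivity"]),
                "Sp": _fmt_pct(r["specificity"]),
                "PPV": ppv_s,
                "NPV": npv_s,
                "LR": lr_s,
                "n": r["n"],
            }
        )
    return pd.DataFrame(out)


def roc(values: Sequence[float], labels: Sequence[bool],
        direction: str = "<=") -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points over all distinct observed thresholds, plus trapezoid AUC.

    ``direction="<="`` treats small measurements as test-positive (the CL
    convention); ``">="`` the reverse (the %ΔCL convention).  Requires at
    least one positive and one negative among observed records.
    """
    v = np.asarray([np.nan if x is None else x for x in values], dtype=float)
    y = np.asarray(labels, dtype=bool)
    obs = ~np.isnan(v)
    v, y = v[obs], y[obs]
    if not y.any() or y.all():
        raise ValueError("ROC needs at least one positive and one negative label")
    if direction not in ("<=", ">="):
        raise ValueError("direction must be '<=' or '>='")
    score = -v if direction == "<=" else v
    thresholds = np.unique(score)[::-1]
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        flag = score >= t
        tpr.append(float((flag & y).sum()) / n_pos)
        fpr.append(float((flag & ~y).sum()) / n_neg)
    fpr_arr, tpr_arr = np.array(fpr), np.array(tpr)
    auc = float(np.trapezoid(tpr_arr, fpr_arr))
    return fpr_arr, tpr_arr, auc
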