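"""Scan-utilisation bookkeeping under a triage policy.

Each woman is scheduled for a fixed number of surveillance scans
(default 3).  A triage exit after scan 1 or 2 — whether a discharge or a
high-risk call that ends CL surveillance — avoids the remaining
scheduled scans.  Follow-up scans are the scheduled scans beyond the
first visit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Union

from .triage import TriageOutcome


@dataclass(frozen=True)
class ScanAccounting:
    n_total: int
    scheduled_per_woman: int
    n_exit_after_1: int
    n_exit_after_2: int
    n_complete_3: int

    def __post_init__(self) -> None:
        if self.n_exit_after_1 + self.n_exit_after_2 + self.n_complete_3 != self.n_total:
            raise ValueError("exit counts must sum to n_total")

    @property
    def scans_performed(self) -> int:
        # the surveillance protocol has three visits; completers attend all 3
        return (self.n_exit_after_1 * 1 + self.n_exit_after_2 * 2
                + self.n_complete_3 * 3)

    @property
    def scans_avoided(self) -> int:
        return self.n_total * self.scheduled_per_woman - self.scans_performed

    @property
    def scheduled_followups(self) -> int:
        return self.n_total * (self.scheduled_per_woman - 1)

    @property
    def pct_exit_after_1(self) -> float:
        return 100.0 * self.n_exit_after_1 / self.n_total if self.n_total else 0.0

    @property
    def pct_exit_after_2(self) -> float:
        return 100.0 * self.n_exit_after_2 / self.n_total if self.n_total else 0.0

    @property
    def pct_complete_3(self) -> float:
        return 100.0 * self.n_complete_3 / self.n_total if self.n_total else 0.0

    @property
    def pct_followups_avoided(self) -> float:
        """Avoided scans as a share of scheduled follow-up scans."""
        return (100.0 * self.scans_avoided / self.scheduled_followups
                if self.scheduled_followups else 0.0)


def scan_savings(
    outcomes: Iterable[Union[TriageOutcome, int]],
    n_total: Optional[int] = None,
    scheduled_per_woman: int = 3,
) -> ScanAccounting:
    """Tabulate scans used/avoided from triage outcomes (or raw scan counts).

    All exits before the final scheduled scan count as surveillance exits:
    discharged women leave as low risk and high-risk women leave for
    cerclage intervention, so neither returns for further CL scans.
    """
    if scheduled_per_woman < 3:
        raise ValueError("the surveillance protocol schedules at least 3 scans")
    counts = {1: 0, 2: 0, 3: 0}
    n_seen = 0
    for out in outcomes:
        used = out.scans_used if isinstance(out, TriageOutcome) else int(out)
        if not 1 <= used <= scheduled_per_woman:
            raise ValueError(
                f"scans_used={used} outside 1..{scheduled_per_woman}"
            )
        counts[min(used, 3)] += 1
        n_seen += 1
    if n_total is None:
        n_total = n_seen
    elif n_total != n_seen:
        raise ValueError(f"n_total={n_total} but {n_seen} outcomes supplied")
    return ScanAccounting(
        n_total=n_total,
        scheduled_per_woman=scheduled_per_woman,
        n_exit_after_1=counts[1],
        n_exit_after_2=counts[2],
        n_complete_3=counts[3],
    )
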