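"""Gestational-age arithmetic in clinical ``W+D`` notation.

Obstetric gestational age is written as completed weeks plus days,
e.g. ``16+0``; internally everything reduces to a total-day count so
that comparisons and window tests are integer arithmetic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import total_ordering

_GA_TOKEN = re.compile(r"^(\d+)\+(\d)$")


@total_ordering
@dataclass(frozen=True)
class GestationalAge:
    """Completed weeks plus days (0-6), e.g. ``GestationalAge(16, 0)``."""

    weeks: int
    days: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.days <= 6):
            raise ValueError(f"days must be in 0..6, got {self.days}")
        if self.weeks < 0:
            raise ValueError(f"weeks must be >= 0, got {self.weeks}")

    @property
    def total_days(self) -> int:
        return 7 * self.weeks + self.days

    @classmethod
    def from_days(cls, total_days: int) -> "GestationalAge":
        if total_days < 0:
            raise ValueError("total_days must be >= 0")
        return cls(total_days // 7, total_days % 7)

    @classmethod
    def parse(cls, token: str) -> "GestationalAge":
        """Parse a ``"W+D"`` token such as ``"16+0"``.

        Raises ValueError for anything not matching the notation
        (including day parts outside 0-6, e.g. ``"36+7"``).
        """
        m = _GA_TOKEN.match(token.strip())
        if m is None:
            raise ValueError(f"malformed gestational-age token {token!r}; expected 'W+D'")
        return cls(int(m.group(1)), int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.weeks}+{self.days}"

    def __lt__(self, other: "GestationalAge") -> bool:
        if not isinstance(other, GestationalAge):
            return NotImplemented
        return self.total_days < other.total_days


#: First day of term: deliveries strictly before 37+0 (259 days) are preterm.
TERM_CUTOFF = GestationalAge(37, 0)
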