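"""Domain model for a post-conization pregnancy cohort.

One row per pregnancy after excisional cervical treatment (cone biopsy,
LLETZ/LEEP), with cervical length (CL, mm) measured at up to three
second-trimester surveillance windows:

* A: 13+0 - 15+6 weeks
* B: 16+0 - 18+6 weeks
* C: 20+0 - 22+6 weeks

The protocol offers ultrasound-indicated cerclage when CL < 25 mm before
24 weeks.  Outcome strata follow the surveillance-study convention:
Group 1 ("low risk") delivered at term with no cerclage; Group 2 ("high
risk") delivered preterm (<37+0) and/or received a cerclage, and splits
into three subgroups by the cross of those two events.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

from .gestage import GestationalAge, TERM_CUTOFF


class Timepoint(str, Enum):
    A = "A"
    B = "B"
    C = "C"


#: Inclusive gestational windows for each screening timepoint.
TIMEPOINT_WINDOWS: dict[Timepoint, tuple[GestationalAge, GestationalAge]] = {
    Timepoint.A: (GestationalAge(13, 0), GestationalAge(15, 6)),
    Timepoint.B: (GestationalAge(16, 0), GestationalAge(18, 6)),
    Timepoint.C: (GestationalAge(20, 0), GestationalAge(22, 6)),
}

#: Protocol cerclage threshold: offered when CL < 25 mm before 24+0.
CERCLAGE_CL_THRESHOLD_MM = 25.0
CERCLAGE_GA_LIMIT = GestationalAge(24, 0)


class Suture(str, Enum):
    MONOFILAMENT = "monofilament"
    BRAIDED = "braided"


class RiskLabel(str, Enum):
    GROUP1 = "GROUP1"
    GROUP2 = "GROUP2"


class Subgroup(str, Enum):
    TERM_NO_CERCLAGE = "term_no_cerclage"
    PTB_NO_CERCLAGE = "ptb_no_cerclage"
    PTB_WITH_CERCLAGE = "ptb_with_cerclage"
    TERM_WITH_CERCLAGE = "term_with_cerclage"


#: Exclusion criteria: risk factors other than prior conization.
EXCLUSION_FLAGS = frozenset(
    {
        "prior_preterm",
        "mid_trimester_loss",
        "uterine_anomaly",
        "multifetal",
        "history_indicated_cerclage",
    }
)


@dataclass(frozen=True)
class RiskGroup:
    label: RiskLabel
    subgroup: Subgroup


@dataclass(frozen=True)
class CerclageEvent:
    """Ultrasound-indicated cerclage: CL and gestation at insertion, suture."""

    cl_at_insertion: float
    ga_at_insertion: GestationalAge
    suture: Suture

    def __post_init__(self) -> None:
        if not self.ga_at_insertion < CERCLAGE_GA_LIMIT:
            raise ValueError(
                f"cerclage must be inserted before {CERCLAGE_GA_LIMIT}, "
                f"got {self.ga_at_insertion}"
            )
        if not 0 < self.cl_at_insertion <= 70:
            raise ValueError(f"implausible CL at insertion: {self.cl_at_insertion}")


@dataclass
class PregnancyRecord:
    """One pregnancy post-conization.

    CL fields hold pre-cerclage measurements only; values after cerclage
    insertion are censored at generation/ingest time.
    """

    id: str
    hospital: str
    ga_at_birth: GestationalAge
    cl_a: Optional[float] = None
    cl_b: Optional[float] = None
    cl_c: Optional[float] = None
    cerclage: Optional[CerclageEvent] = None
    declined_cerclage: bool = False
    birthweight: Optional[float] = None
    apgar1: Optional[int] = None
    apgar10: Optional[int] = None
    nicu_admission: Optional[bool] = None
    age: Optional[float] = None
    bmi: Optional[float] = None
    parity: int = 0
    smoker: bool = False
    ethnicity: str = ""
    exclusion_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name in ("cl_a", "cl_b", "cl_c"):
            v = getattr(self, name)
            if v is not None and not (0 < v <= 70):
                raise ValueError(f"{name}={v} outside plausible range (0, 70] mm")
        if not (GestationalAge(20, 0) <= self.ga_at_birth <= GestationalAge(43, 0)):
            raise ValueError(f"ga_at_birth {self.ga_at_birth} outside 20+0..43+0")
        unknown = set(self.exclusion_flags) - EXCLUSION_FLAGS
        if unknown:
            raise ValueError(f"unknown exclusion flags: {sorted(unknown)}")

    def cl(self, tp: Timepoint) -> Optional[float]:
        return {Timepoint.A: self.cl_a, Timepoint.B: self.cl_b, Timepoint.C: self.cl_c}[tp]

    @property
    def has_any_cl(self) -> bool:
        return any(v is not None for v in (self.cl_a, self.cl_b, self.cl_c))


def is_preterm(ga: GestationalAge) -> bool:
    """Preterm birth: strictly before 37+0 (i.e. total days < 259)."""
    return ga.total_days < TERM_CUTOFF.total_days


def pct_delta_cl(cl_early: float, cl_late: float) -> float:
    """Percentage change in CL between two timepoints, relative to the
    earlier measurement.  Positive values denote shortening.
    """
    if cl_early <= 0:
        raise ValueError(f"cl_early must be > 0, got {cl_early}")
    return 100.0 * (cl_early - cl_late) / cl_early


def record_delta(record: PregnancyRecord, early: Timepoint, late: Timepoint) -> Optional[float]:
    """%ΔCL for one record over an interval, or None if either endpoint is
    unobserved (stored CLs are pre-cerclage by construction)."""
    a, b = record.cl(early), record.cl(late)
    if a is None or b is None:
        return None
    return pct_delta_cl(a, b)


def assign_risk_group(record: PregnancyRecord) -> RiskGroup:
    """Outcome stratum: GROUP2 iff preterm birth and/or cerclage inserted.

    A declined cerclage does not count as an insertion, so a woman who
    declined and delivered at term remains GROUP1.
    """
    if record.ga_at_birth is None:
        raise ValueError("record has no ga_at_birth; cannot assign risk group")
    preterm = is_preterm(record.ga_at_birth)
    cerclage = record.cerclage is not None
    if not preterm and not cerclage:
        return RiskGroup(RiskLabel.GROUP1, Subgroup.TERM_NO_CERCLAGE)
    if preterm and not cerclage:
        sub = Subgroup.PTB_NO_CERCLAGE
    elif preterm and cerclage:
        sub = Subgroup.PTB_WITH_CERCLAGE
    else:
        sub = Subgroup.TERM_WITH_CERCLAGE
    return RiskGroup(RiskLabel.GROUP2, sub)


def apply_eligibility(
    records: Iterable[PregnancyRecord],
) -> tuple[list[PregnancyRecord], list[tuple[PregnancyRecord, tuple[str, ...]]]]:
    """Split a cohort into eligible records and excluded records with reasons.

    Exclusion reasons are the record's exclusion flags (other preterm-birth
    risk factors / history-indicated cerclage) plus ``no_screening`` when no
    CL was measured at any timepoint.
    """
    eligible: list[PregnancyRecord] = []
    excluded: list[tuple[PregnancyRecord, tuple[str, ...]]] = []
    for rec in records:
        reasons = tuple(sorted(rec.exclusion_flags))
        if not rec.has_any_cl:
            reasons = reasons + ("no_screening",)
        if reasons:
            excluded.append((rec, reasons))
        else:
            eligible.append(rec)
    return eligible, excluded


# ---------------------------------------------------------------------------
# Cohort file I/O: comma-separated UTF-8, fixed header, one row per pregnancy.
# Missing values are empty fields; gestational ages are "W+D" tokens;
# booleans are 0/1; exclusion flags are semicolon-joined.
# ---------------------------------------------------------------------------

COHORT_HEADER = [
    "id", "hospital", "cl_a", "cl_b", "cl_c",
    "cerclage_cl", "cerclage_ga", "suture", "declined_cerclage",
    "ga_birth", "birthweight", "apgar1", "apgar10", "nicu",
    "age", "bmi", "parity", "smoker", "ethnicity", "exclusion_flags",
]


class CohortParseError(ValueError):
    """Malformed cohort file; message names the offending row."""


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(float(value))  # plain-float repr round-trips exactly
    return str(value)


def _record_to_row(rec: PregnancyRecord) -> list[str]:
    cer = rec.cerclage
    return [
        rec.id,
        rec.hospital,
        _fmt(rec.cl_a), _fmt(rec.cl_b), _fmt(rec.cl_c),
        _fmt(cer.cl_at_insertion if cer else None),
        str(cer.ga_at_insertion) if cer else "",
        cer.suture.value if cer else "",
        _fmt(rec.declined_cerclage),
        str(rec.ga_at_birth),
        _fmt(rec.birthweight),
        _fmt(rec.apgar1), _fmt(rec.apgar10),
        _fmt(rec.nicu_admission),
        _fmt(rec.age), _fmt(rec.bmi),
        str(rec.parity),
        _fmt(rec.smoker),
        rec.ethnicity,
        ";".join(sorted(rec.exclusion_flags)),
    ]


def write_cohort(records: Sequence[PregnancyRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(COHORT_HEADER)
        for rec in records:
            w.writerow(_record_to_row(rec))


def _opt_float(s: str) -> Optional[float]:
    return float(s) if s != "" else None


def _opt_int(s: str) -> Optional[int]:
    return int(s) if s != "" else None


def _opt_bool(s: str) -> Optional[bool]:
    return bool(int(s)) if s != "" else None


def read_cohort(path) -> list[PregnancyRecord]:
    records: list[PregnancyRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != COHORT_HEADER:
            raise CohortParseError(
                f"unexpected header {reader.fieldnames}; expected {COHORT_HEADER}"
            )
        for i, row in enumerate(reader, start=2):  # header is line 1
            try:
                cerclage = None
                if row["cerclage_cl"] != "":
                    cerclage = CerclageEvent(
                        cl_at_insertion=float(row["cerclage_cl"]),
                        ga_at_insertion=GestationalAge.parse(row["cerclage_ga"]),
                        suture=Suture(row["suture"]),
                    )
                flags = frozenset(f for f in row["exclusion_flags"].split(";") if f)
                records.append(
                    PregnancyRecord(
                        id=row["id"],
                        hospital=row["hospital"],
                        cl_a=_opt_float(row["cl_a"]),
                        cl_b=_opt_float(row["cl_b"]),
                        cl_c=_opt_float(row["cl_c"]),
                        cerclage=cerclage,
                        declined_cerclage=bool(int(row["declined_cerclage"])),
                        ga_at_birth=GestationalAge.parse(row["ga_birth"]),
                        birthweight=_opt_float(row["birthweight"]),
                        apgar1=_opt_int(row["apgar1"]),
                        apgar10=_opt_int(row["apgar10"]),
                        nicu_admission=_opt_bool(row["nicu"]),
                        age=_opt_float(row["age"]),
                        bmi=_opt_float(row["bmi"]),
                        parity=int(row["parity"]),
                        smoker=bool(int(row["smoker"])),
                        ethnicity=row["ethnicity"],
                        exclusion_flags=flags,
                    )
                )
            except (ValueError, KeyError) as exc:
                raise CohortParseError(f"row {i} (id={row.get('id', '?')}): {exc}") from exc
    return records


def cohort_to_frame(records: Sequence[PregnancyRecord]) -> pd.DataFrame:
    """Analysis frame: CLs, interval %ΔCL, outcome labels, one row per record.

    ``group2`` is the binary high-risk indicator (preterm and/or cerclage);
    deltas are None->NaN when an endpoint is unobserved.
    """
    rows = []
    for rec in records:
        rg = assign_risk_group(rec)
        rows.append(
            {
                "id": rec.id,
                "hospital": rec.hospital,
                "cl_a": rec.cl_a,
                "cl_b": rec.cl_b,
                "cl_c": rec.cl_c,
                "d_ab": record_delta(rec, Timepoint.A, Timepoint.B),
                "d_bc": record_delta(rec, Timepoint.B, Timepoint.C),
                "d_ac": record_delta(rec, Timepoint.A, Timepoint.C),
                "group2": rg.label is RiskLabel.GROUP2,
                "subgroup": rg.subgroup.value,
                "preterm": is_preterm(rec.ga_at_birth),
                "cerclage": rec.cerclage is not None,
                "suture": rec.cerclage.suture.value if rec.cerclage else None,
                "ga_birth_days": rec.ga_at_birth.total_days,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(
            columns=["id", "hospital", "cl_a", "cl_b", "cl_c", "d_ab", "d_bc",
                     "d_ac", "group2", "subgroup", "preterm", "cerclage",
                     "suture", "ga_birth_days"]
        )
    for col in ("cl_a", "cl_b", "cl_c", "d_ab", "d_bc", "d_ac"):
        df[col] = pd.to_numeric(df[col])
    return df


def clone_record(rec: PregnancyRecord, **changes) -> PregnancyRecord:
    return replace(rec, **changes)
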