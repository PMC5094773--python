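"""Synthetic post-conization surveillance cohorts.

The generator emulates the statistical structure of a multi-site
cervical-length surveillance cohort: four outcome subgroups
(term/no-cerclage, preterm/no-cerclage, preterm/with-cerclage,
term/with-cerclage) with subgroup-specific CL trajectories.  CL at
timepoint A is drawn from a truncated normal; longitudinal dependence is
induced multiplicatively through per-individual interval shortening
fractions (also truncated normal), so the configured %ΔCL moments are
the direct calibration targets and the downstream CL_B/CL_C means are
emergent.  Cerclage subgroups receive a cerclage at the first observed
timepoint with CL below the 25 mm protocol threshold (trajectories are
resampled until one exists) and later CLs are censored, mirroring a
protocol in which only pre-cerclage measurements are analysed.

All randomness flows from one integer seed through a single
``numpy.random.Generator``; truncated normals are sampled by inverse CDF
on the truncated interval, so the output is a deterministic function of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from .cohort import (
    CERCLAGE_CL_THRESHOLD_MM,
    CerclageEvent,
    PregnancyRecord,
    RiskLabel,
    Subgroup,
    Suture,
    TIMEPOINT_WINDOWS,
    Timepoint,
    assign_risk_group,
    record_delta,
)
from .gestage import GestationalAge


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SubgroupTrajectoryParams:
    """Distribution parameters for one outcome subgroup.

    ``mu_cl_a``/``sd_cl_a`` are the CL mm moments at timepoint A;
    ``mu_pct_*``/``sd_pct_*`` the interval shortening-percentage moments
    (positive = shortening); ``p_missing_*`` the per-timepoint missed-visit
    probabilities; ``ga_birth_*`` the gestation-at-birth moments in weeks
    with hard truncation ``ga_birth_range`` (preterm subgroups capped
    below 37.0 weeks by construction).
    """

    name: Subgroup
    n: int
    mu_cl_a: float
    sd_cl_a: float
    mu_pct_ab: float
    sd_pct_ab: float
    mu_pct_bc: float
    sd_pct_bc: float
    p_missing_a: float
    p_missing_b: float
    p_missing_c: float
    ga_birth_mu: float
    ga_birth_sd: float
    ga_birth_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigError(f"{self.name}: n must be >= 0")
        for nm in ("sd_cl_a", "sd_pct_ab", "sd_pct_bc", "ga_birth_sd"):
            if getattr(self, nm) <= 0:
                raise ConfigError(f"{self.name}: {nm} must be > 0")
        for nm in ("p_missing_a", "p_missing_b", "p_missing_c"):
            p = getattr(self, nm)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{self.name}: {nm}={p} not a probability")
        lo, hi = self.ga_birth_range
        if not lo < hi:
            raise ConfigError(f"{self.name}: empty ga_birth_range {self.ga_birth_range}")
        preterm = self.name in (Subgroup.PTB_NO_CERCLAGE, Subgroup.PTB_WITH_CERCLAGE)
        if preterm and hi > 37.0:
            raise ConfigError(f"{self.name}: preterm subgroup must cap ga below 37.0")
        if not preterm and lo < 37.0:
            raise ConfigError(f"{self.name}: term subgroup must start ga at >= 37.0")


#: Shortening fractions are truncated to (-50, 95): a cervix may lengthen
#: by up to half its prior measurement but cannot shorten past ~zero.
PCT_TRUNCATION = (-50.0, 95.0)

_CERCLAGE_SUBGROUPS = (Subgroup.PTB_WITH_CERCLAGE, Subgroup.TERM_WITH_CERCLAGE)


def default_subgroups() -> list[SubgroupTrajectoryParams]:
    """Default subgroup parameters: sizes 581/46/24/74 with subgroup CL-at-A
    and interval-%ΔCL moments matching a large three-site surveillance
    cohort; missingness rates from the observed per-cell denominators at
    timepoint A (B/C missingness in cerclage subgroups is dominated by
    post-cerclage censoring, so only modest visit-level rates are set)."""
    return [
        SubgroupTrajectoryParams(
            name=Subgroup.TERM_NO_CERCLAGE, n=581,
            mu_cl_a=33.6, sd_cl_a=4.2,
            mu_pct_ab=3.0, sd_pct_ab=8.0, mu_pct_bc=2.0, sd_pct_bc=9.0,
            p_missing_a=0.172, p_missing_b=0.151, p_missing_c=0.153,
            ga_birth_mu=39.1, ga_birth_sd=1.8, ga_birth_range=(37.0, 43.0),
        ),
        SubgroupTrajectoryParams(
            name=Subgroup.PTB_NO_CERCLAGE, n=46,
            mu_cl_a=32.3, sd_cl_a=6.0,
            mu_pct_ab=4.0, sd_pct_ab=8.0, mu_pct_bc=6.0, sd_pct_bc=11.0,
            p_missing_a=0.152, p_missing_b=0.239, p_missing_c=0.239,
            ga_birth_mu=35.5, ga_birth_sd=2.0, ga_birth_range=(24.0, 37.0),
        ),
        SubgroupTrajectoryParams(
            name=Subgroup.PTB_WITH_CERCLAGE, n=24,
            mu_cl_a=26.8, sd_cl_a=5.4,
            mu_pct_ab=18.0, sd_pct_ab=12.0, mu_pct_bc=39.0, sd_pct_bc=23.0,
            p_missing_a=0.083, p_missing_b=0.10, p_missing_c=0.10,
            ga_birth_mu=38.0, ga_birth_sd=3.1, ga_birth_range=(24.0, 37.0),
        ),
        SubgroupTrajectoryParams(
            name=Subgroup.TERM_WITH_CERCLAGE, n=74,
            mu_cl_a=25.8, sd_cl_a=5.4,
            mu_pct_ab=12.0, sd_pct_ab=15.0, mu_pct_bc=30.0, sd_pct_bc=15.0,
            p_missing_a=0.081, p_missing_b=0.10, p_missing_c=0.10,
            ga_birth_mu=38.0, ga_birth_sd=3.1, ga_birth_range=(37.0, 42.0),
        ),
    ]


@dataclass(frozen=True)
class SyntheticCohortConfig:
    subgroups: tuple[SubgroupTrajectoryParams, ...] = field(
        default_factory=lambda: tuple(default_subgroups())
    )
    hospital_labels: tuple[str, ...] = ("QCH", "SMH", "CWH")
    hospital_weights: tuple[float, ...] = (0.40, 0.35, 0.25)
    #: counts (monofilament, braided) among cerclage recipients
    suture_split: tuple[int, int] = (60, 38)
    smoker_rate_g1: float = 0.07
    smoker_rate_g2: float = 0.23
    cl_bounds: tuple[float, float] = (5.0, 60.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hospital_labels) != len(self.hospital_weights):
            raise ConfigError("hospital labels/weights length mismatch")
        if abs(sum(self.hospital_weights) - 1.0) > 1e-9:
            raise ConfigError("hospital_weights must sum to 1")
        n_cerclage = sum(p.n for p in self.subgroups if p.name in _CERCLAGE_SUBGROUPS)
        if sum(self.suture_split) <= 0:
            raise ConfigError("suture_split must have positive total")
        lo, hi = self.cl_bounds
        if not 0 < lo < hi:
            raise ConfigError(f"bad cl_bounds {self.cl_bounds}")
        del n_cerclage  # proportions of the split are used, not its total


def _trunc_normal(rng: np.random.Generator, mu: float, sd: float,
                  lo: float, hi: float, size: int) -> np.ndarray:
    """Inverse-CDF sampling of N(mu, sd) truncated to [lo, hi]."""
    if mu < lo - 6 * sd or mu > hi + 6 * sd:
        raise ConfigError(
            f"infeasible truncation: mu={mu} is >6 sd outside [{lo}, {hi}]"
        )
    a, b = ndtr((lo - mu) / sd), ndtr((hi - mu) / sd)
    u = rng.uniform(a, b, size=size)
    return mu + sd * ndtri(u)


def truncated_normal_mean(mu: float, sd: float, lo: float, hi: float) -> float:
    """Closed-form mean of the truncated normal (used for calibration checks)."""
    a, b = (lo - mu) / sd, (hi - mu) / sd
    z = norm.cdf(b) - norm.cdf(a)
    return mu + sd * (norm.pdf(a) - norm.pdf(b)) / z


def _draw_ga_window(rng: np.random.Generator, tp: Timepoint) -> GestationalAge:
    lo, hi = TIMEPOINT_WINDOWS[tp]
    return GestationalAge.from_days(int(rng.integers(lo.total_days, hi.total_days + 1)))


def _ga_from_weeks(weeks: float, preterm: bool) -> GestationalAge:
    days = int(np.floor(weeks * 7))
    if preterm:
        days = min(days, 258)  # strictly before 37+0
    else:
        days = max(days, 259)
    return GestationalAge.from_days(days)


def _sample_trajectory(rng, params: SubgroupTrajectoryParams, bounds):
    lo, hi = bounds
    cl_a = float(_trunc_normal(rng, params.mu_cl_a, params.sd_cl_a, lo, hi, 1)[0])
    f_ab = float(_trunc_normal(rng, params.mu_pct_ab, params.sd_pct_ab, *PCT_TRUNCATION, size=1)[0])
    f_bc = float(_trunc_normal(rng, params.mu_pct_bc, params.sd_pct_bc, *PCT_TRUNCATION, size=1)[0])
    cl_b = float(np.clip(cl_a * (1 - f_ab / 100.0), lo, hi))
    cl_c = float(np.clip(cl_b * (1 - f_bc / 100.0), lo, hi))
    miss = (
        rng.random() < params.p_missing_a,
        rng.random() < params.p_missing_b,
        rng.random() < params.p_missing_c,
    )
    values = [cl_a, cl_b, cl_c]
    observed = [None if m else v for v, m in zip(values, miss)]
    return observed


def generate_cohort(config: SyntheticCohortConfig) -> list[PregnancyRecord]:
    """Draw a fully synthetic cohort; deterministic given (config, seed)."""
    rng = np.random.default_rng(config.seed)
    bounds = config.cl_bounds
    records: list[PregnancyRecord] = []
    cerclage_indices: list[int] = []
    seq = 0

    for params in config.subgroups:
        needs_cerclage = params.name in _CERCLAGE_SUBGROUPS
        preterm = params.name in (Subgroup.PTB_NO_CERCLAGE, Subgroup.PTB_WITH_CERCLAGE)
        for _ in range(params.n):
            seq += 1
            cerclage_tp: Optional[Timepoint] = None
            for attempt in range(1000):
                cls = _sample_trajectory(rng, params, bounds)
                if not needs_cerclage:
                    # eligibility contract: at least one observed timepoint
                    if any(v is not None for v in cls):
                        break
                    continue
                for tp, v in zip(Timepoint, cls):
                    if v is not None and v < CERCLAGE_CL_THRESHOLD_MM:
                        cerclage_tp = tp
                        break
                if cerclage_tp is not None:
                    break
            else:  # pragma: no cover - defensive
                raise ConfigError(
                    f"{params.name}: could not realise CL<25 mm trajectory"
                )

            cerclage = None
            if needs_cerclage:
                order = list(Timepoint)
                k = order.index(cerclage_tp)
                cl_at = cls[k]
                for later in range(k + 1, 3):
                    cls[later] = None  # censor post-cerclage measurements
                cerclage = CerclageEvent(
                    cl_at_insertion=cl_at,
                    ga_at_insertion=_draw_ga_window(rng, cerclage_tp),
                    suture=Suture.MONOFILAMENT,  # reassigned by split below
                )

            ga_weeks = float(
                _trunc_normal(rng, params.ga_birth_mu, params.ga_birth_sd,
                              *params.ga_birth_range, size=1)[0]
            )
            ga_birth = _ga_from_weeks(ga_weeks, preterm)

            smoker_rate = (
                config.smoker_rate_g1
                if params.name is Subgroup.TERM_NO_CERCLAGE
                else config.smoker_rate_g2
            )
            hw = np.cumsum(config.hospital_weights)
            hospital = str(
                config.hospital_labels[int(np.searchsorted(hw, rng.random()))]
            )
            # crude birthweight model: term mean ~3350 g, ~170 g per week early
            bw = float(np.clip(rng.normal(3350 - 170 * (40.0 - ga_weeks), 450), 500, 5100))
            apgar1 = int(np.clip(round(rng.normal(8.6 if ga_weeks >= 34 else 7, 1.4)), 0, 10))
            apgar10 = int(np.clip(round(rng.normal(9.7 if ga_weeks >= 34 else 8.5, 0.9)), 0, 10))
            nicu = bool(rng.random() < (0.5 if ga_weeks < 34 else 0.02))
            observed = [v for v in cls if v is not None]
            declined = (
                cerclage is None
                and bool(observed)
                and min(observed) < CERCLAGE_CL_THRESHOLD_MM
            )

            rec = PregnancyRecord(
                id=f"S{seq:05d}",
                hospital=hospital,
                ga_at_birth=ga_birth,
                cl_a=cls[0], cl_b=cls[1], cl_c=cls[2],
                cerclage=cerclage,
                declined_cerclage=declined,
                birthweight=round(bw),
                apgar1=apgar1, apgar10=apgar10,
                nicu_admission=nicu,
                age=float(np.round(_trunc_normal(rng, 33.8, 4.1, 18, 50, 1)[0], 1)),
                bmi=float(np.round(_trunc_normal(rng, 24.1, 3.9, 16, 45, 1)[0], 1)),
                parity=0 if rng.random() < 0.78 else int(rng.integers(1, 4)),
                smoker=bool(rng.random() < smoker_rate),
                ethnicity=("caucasian", "asian", "black")[
                    int(np.searchsorted((0.66, 0.82, 1.0), rng.random()))
                ],
            )
            if cerclage is not None:
                cerclage_indices.append(len(records))
            records.append(rec)

    # Suture material by configured split across all cerclage recipients.
    n_cer = len(cerclage_indices)
    if n_cer:
        mono_n, braided_n = config.suture_split
        k_mono = round(n_cer * mono_n / (mono_n + braided_n))
        perm = rng.permutation(n_cer)
        mono_set = {cerclage_indices[i] for i in perm[:k_mono]}
        for idx in cerclage_indices:
            rec = records[idx]
            suture = Suture.MONOFILAMENT if idx in mono_set else Suture.BRAIDED
            records[idx] = replace(
                rec, cerclage=replace(rec.cerclage, suture=suture)
            )
    return records


_CELLS = ("cl_a", "cl_b", "cl_c", "pct_ab", "pct_bc", "pct_ac")
_INTERVALS = {
    "pct_ab": (Timepoint.A, Timepoint.B),
    "pct_bc": (Timepoint.B, Timepoint.C),
    "pct_ac": (Timepoint.A, Timepoint.C),
}


def summarize_cohort(records: Sequence[PregnancyRecord]) -> pd.DataFrame:
    """Per-stratum mean (SD) [n] cells for CL at A/B/C and interval %ΔCL.

    Strata: GROUP1, GROUP2, each GROUP2 subgroup, and TOTAL; %ΔCL cells
    average over individuals with both (pre-cerclage) endpoints observed.
    Empty cells carry n=0 and NaN moments.
    """
    per_record: dict[str, list[tuple[str, float]]] = {c: [] for c in _CELLS}
    strata_of: list[list[str]] = []
    for rec in records:
        rg = assign_risk_group(rec)
        strata = ["TOTAL", rg.label.value]
        if rg.label is RiskLabel.GROUP2:
            strata.append(rg.subgroup.value)
        else:
            strata.append(rg.subgroup.value)
        strata_of.append(strata)
        for cell in ("cl_a", "cl_b", "cl_c"):
            v = getattr(rec, cell)
            if v is not None:
                for s in strata:
                    per_record[cell].append((s, v))
        for cell, (e, l) in _INTERVALS.items():
            d = record_delta(rec, e, l)
            if d is not None:
                for s in strata:
                    per_record[cell].append((s, d))

    all_strata = ["GROUP1", "GROUP2",
                  Subgroup.TERM_NO_CERCLAGE.value, Subgroup.PTB_NO_CERCLAGE.value,
                  Subgroup.PTB_WITH_CERCLAGE.value, Subgroup.TERM_WITH_CERCLAGE.value,
                  "TOTAL"]
    rows = []
    for stratum in all_strata:
        for cell in _CELLS:
            vals = np.array([v for s, v in per_record[cell] if s == stratum], dtype=float)
            rows.append(
                {
                    "stratum": stratum,
                    "cell": cell,
                    "mean": float(vals.mean()) if vals.size else np.nan,
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                    "n": int(vals.size),
                }
            )
    return pd.DataFrame(rows)


def generate_planted_cohort(
    n: int = 2000,
    seed: int = 0,
    gap: tuple[float, float] = (20.0, 36.0),
    group2_fraction: float = 0.2,
    hospitals: Sequence[str] = ("QCH", "SMH", "CWH"),
) -> list[PregnancyRecord]:
    """Separation benchmark for threshold derivation.

    High-risk records get CL-at-A strictly below ``gap[0]`` and low-risk
    records at or above ``gap[1]``, so a derivation procedure should recover
    step-1 thresholds at the gap edges.  High-risk women deliver preterm
    (no cerclage is simulated); low-risk women deliver at term with mild
    cervical shortening.  Deterministic given the seed.
    """
    lo_edge, hi_edge = gap
    if not 5.0 < lo_edge < hi_edge < 55.0:
        raise ConfigError(f"bad gap {gap}")
    rng = np.random.default_rng(seed)
    records = []
    n2 = int(round(n * group2_fraction))
    for i in range(n):
        high_risk = i < n2
        if high_risk:
            cl_a = float(rng.uniform(8.0, lo_edge - 1e-6))
            ga = GestationalAge.from_days(int(rng.integers(28 * 7, 259)))
        else:
            cl_a = float(rng.uniform(hi_edge, 52.0))
            ga = GestationalAge.from_days(int(rng.integers(259, 42 * 7)))
        shorten = rng.uniform(0.0, 0.06, size=2)
        cl_b = min(cl_a * (1 - shorten[0]), 60.0)
        cl_c = min(cl_b * (1 - shorten[1]), 60.0)
        records.append(
            PregnancyRecord(
                id=f"P{i:05d}",
                hospital=str(hospitals[int(rng.integers(len(hospitals)))]),
                ga_at_birth=ga,
                cl_a=cl_a, cl_b=cl_b, cl_c=cl_c,
            )
        )
    return records


# --- config (de)serialisation -----------------------------------------------

def config_to_dict(config: SyntheticCohortConfig) -> dict:
    d = asdict(config)
    d["subgroups"] = [
        {**asdict(p), "name": p.name.value, "ga_birth_range": list(p.ga_birth_range)}
        for p in config.subgroups
    ]
    for key in ("hospital_labels", "hospital_weights", "suture_split", "cl_bounds"):
        d[key] = list(d[key])
    return d


def config_from_dict(d: dict) -> SyntheticCohortConfig:
    d = dict(d)
    subgroups = []
    for p in d.pop("subgroups", []):
        p = dict(p)
        p["name"] = Subgroup(p["name"])
        p["ga_birth_range"] = tuple(p["ga_birth_range"])
        subgroups.append(SubgroupTrajectoryParams(**p))
    kwargs = {}
    for key in ("hospital_labels", "hospital_weights", "suture_split", "cl_bounds"):
        if key in d:
            kwargs[key] = tuple(d.pop(key))
    kwargs.update(d)
    if subgroups:
        kwargs["subgroups"] = tuple(subgroups)
    return SyntheticCohortConfig(**kwargs)
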