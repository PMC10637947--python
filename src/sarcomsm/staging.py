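"""AWGS-2019 sarcopenia staging from raw anthropometric and performance data.

The 2019 Asian Working Group for Sarcopenia (AWGS) algorithm combines three
component assessments:

* **muscle mass** — appendicular skeletal muscle mass (ASM) estimated from an
  anthropometric linear equation validated for Chinese adults, adjusted for
  height (ASM/Ht², kg/m²) and compared with sex-specific cutoffs;
* **muscle strength** — maximum handgrip strength over up to four trials,
  compared with sex-specific cutoffs (28 kg men / 18 kg women);
* **physical performance** — the Short Physical Performance Battery (SPPB),
  the sum of a 2.5 m walk test, a 5-repetition chair-stand test and a
  standing-balance test, each scored 0–4; a total of 9 or less is low.

States: 1 = no sarcopenia, 2 = possible sarcopenia (normal mass, low strength
or low performance), 3 = sarcopenia (low mass plus low strength and/or low
performance; severe sarcopenia — all three low — is merged into this state),
4 = death.  Low mass alone carries no AWGS label and stays in state 1 with a
``low_mass_only`` flag recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MeasurementRecord",
    "SPPBScore",
    "CutoffSet",
    "StagingResult",
    "StagingError",
    "estimate_asm",
    "grip_strength",
    "score_walk",
    "score_chair",
    "score_balance",
    "sppb_score",
    "classify_state",
    "derive_mass_cutoffs",
    "grip_qc_bounds",
    "stage_panel",
    "prevalence",
    "STATE_LABELS",
]

STATE_LABELS = {1: "no sarcopenia", 2: "possible sarcopenia", 3: "sarcopenia", 4: "death"}

WALK_COURSE_M = 2.5


class StagingError(ValueError):
    """Raised when a record violates a staging precondition."""


@dataclass
class MeasurementRecord:
    """Raw measurements for one subject-visit.

    ``sex_code`` follows the anthropometric-equation convention: 1 = male,
    2 = female.  ``grip_full_effort`` marks whether the handgrip trials were
    performed with full effort; trials without it are treated as missing.
    Unable-flags encode a participant who attempted but could not complete a
    performance test (scored 0), as distinct from a missing measurement.
    """

    subject_id: str
    visit_time: float
    weight: Optional[float] = None          # kg
    height: Optional[float] = None          # cm
    sex_code: Optional[int] = None          # 1 male, 2 female
    age: Optional[float] = None             # years
    grip_measurements: Sequence[float] = ()  # kg, up to 4
    grip_full_effort: bool = True
    walk_times: Sequence[float] = ()        # s over 2.5 m, up to 2
    walk_unable: bool = False
    chair_stand_time: Optional[float] = None  # s for 5 stands
    chair_unable: bool = False
    balance_side_by_side: Optional[float] = None  # hold seconds
    balance_semi_tandem: Optional[float] = None
    balance_full_tandem: Optional[float] = None
    balance_unable: bool = False

    def __post_init__(self) -> None:
        if self.visit_time < 0:
            raise StagingError(f"{self.subject_id}: visit_time must be >= 0")
        if self.sex_code is not None and self.sex_code not in (1, 2):
            raise StagingError(f"{self.subject_id}: sex_code must be 1 or 2")
        for g in self.grip_measurements:
            if g < 0:
                raise StagingError(f"{self.subject_id}: grip measurements must be >= 0")


@dataclass(frozen=True)
class SPPBScore:
    walk_points: int
    chair_points: int
    balance_points: int

    @property
    def total(self) -> int:
        return self.walk_points + self.chair_points + self.balance_points


@dataclass(frozen=True)
class CutoffSet:
    """Staging cutoffs. Defaults are the published Chinese-cohort values."""

    mass_cutoff_male: float = 6.79    # kg/m², ASM/Ht² below is low
    mass_cutoff_female: float = 4.93
    grip_cutoff_male: float = 28.0    # kg, grip below is low
    grip_cutoff_female: float = 18.0
    sppb_cutoff: int = 9              # SPPB at or below is low

    def __post_init__(self) -> None:
        for name in ("mass_cutoff_male", "mass_cutoff_female",
                     "grip_cutoff_male", "grip_cutoff_female", "sppb_cutoff"):
            if getattr(self, name) <= 0:
                raise StagingError(f"cutoff {name} must be positive")


@dataclass
class StagingResult:
    """Outcome of classifying one subject-visit."""

    subject_id: str
    visit_time: float
    state: Optional[int]                 # 1/2/3, None if excluded
    pre_merge_severe: bool = False       # True when all three components low
    low_mass: Optional[bool] = None
    low_strength: Optional[bool] = None
    low_performance: Optional[bool] = None
    low_mass_only: bool = False
    asm_over_ht2: Optional[float] = None
    grip_max: Optional[float] = None
    sppb_total: Optional[int] = None
    exclusion_reason: Optional[str] = None


def estimate_asm(record: MeasurementRecord) -> tuple[float, float]:
    """Estimate appendicular skeletal muscle mass and its height-adjusted form.

    Uses the anthropometric equation
    ``ASM = 0.193·weight + 0.107·height − 4.157·sex − 0.037·age − 2.631``
    with weight in kg, height in cm, sex coded 1 (male) / 2 (female) and age
    in years.  Returns ``(asm_kg, asm_over_height_squared)`` with the second
    value in kg/m² (height converted to metres).
    """
    for name in ("weight", "height", "sex_code", "age"):
        if getattr(record, name) is None:
            raise StagingError(f"{record.subject_id}: missing {name} for ASM estimation")
    if record.weight <= 0 or record.height <= 0:
        raise StagingError(f"{record.subject_id}: weight and height must be positive")
    asm = (0.193 * record.weight + 0.107 * record.height
           - 4.157 * record.sex_code - 0.037 * record.age - 2.631)
    height_m = record.height / 100.0
    return asm, asm / height_m ** 2


def grip_strength(record: MeasurementRecord,
                  qc_bounds: Optional[tuple[float, float]] = None) -> Optional[float]:
    """Maximum handgrip strength in kg, or None when missing.

    The maximum of the available trials is used.  A record flagged as not
    performed with full effort, or whose maximum falls outside the cohort
    [1st, 99th] percentile bounds (``qc_bounds``), is treated as missing.
    """
    if not record.grip_measurements:
        return None
    if not record.grip_full_effort:
        return None
    gmax = max(record.grip_measurements)
    if qc_bounds is not None:
        lo, hi = qc_bounds
        if gmax < lo or gmax > hi:
            return None
    return gmax


def grip_qc_bounds(grips: Iterable[float],
                   lower_pct: float = 1.0, upper_pct: float = 99.0) -> tuple[float, float]:
    """Cohort [1st, 99th] percentile bounds for grip quality control.

    Linear-interpolation (type-7) percentiles on the baseline cohort maxima.
    """
    arr = np.asarray([g for g in grips if g is not None and np.isfinite(g)], dtype=float)
    if arr.size == 0:
        raise StagingError("no grip values to compute QC percentiles from")
    lo, hi = np.percentile(arr, [lower_pct, upper_pct])
    return float(lo), float(hi)


def score_walk(times_s: Sequence[float], unable: bool = False) -> int:
    """Score the 2.5 m walk test (0–4 points).

    The faster of the two recorded times gives the speed; speeds are rounded
    to 2 decimals so the published bands (≤0.43 / 0.44–0.60 / 0.61–0.77 /
    ≥0.78 m/s) tile the line without gaps.
    """
    if unable:
        return 0
    if not times_s:
        raise StagingError("no walk times and not flagged unable")
    t = min(times_s)
    if t <= 0:
        raise StagingError(f"invalid walk time {t}")
    speed = round(WALK_COURSE_M / t, 2)
    if speed <= 0.43:
        return 1
    if speed <= 0.60:
        return 2
    if speed <= 0.77:
        return 3
    return 4


def score_chair(time_s: Optional[float], unable: bool = False) -> int:
    """Score the 5-repetition chair-stand test (0–4 points).

    Total seconds for 5 stands, rounded to 1 decimal for the published bands
    (≥16.7 / 13.7–16.6 / 11.2–13.6 / ≤11.1 s).
    """
    if unable:
        return 0
    if time_s is None:
        raise StagingError("no chair-stand time and not flagged unable")
    if time_s <= 0:
        raise StagingError(f"invalid chair-stand time {time_s}")
    t = round(time_s, 1)
    if t >= 16.7:
        return 1
    if t >= 13.7:
        return 2
    if t >= 11.2:
        return 3
    return 4


def score_balance(side_by_side_s: Optional[float] = None,
                  semi_tandem_s: Optional[float] = None,
                  full_tandem_s: Optional[float] = None,
                  unable: bool = False) -> int:
    """Score the standing-balance test (0–4 points).

    Hierarchical protocol: semi-tandem first; those unable to hold 10 s do
    side-by-side, those who hold it progress to full-tandem.  Points: unable
    0; side-by-side 10 s with semi-tandem <10 s → 1; semi-tandem 10 s with
    full-tandem 0–2 s → 2; full-tandem 3–9 s → 3; full-tandem ≥10 s → 4.
    Only the recorded hold duration matters.
    """
    if unable:
        return 0
    for v in (side_by_side_s, semi_tandem_s, full_tandem_s):
        if v is not None and v < 0:
            raise StagingError(f"negative balance hold time {v}")
    if side_by_side_s is None and semi_tandem_s is None and full_tandem_s is None:
        raise StagingError("no balance measurements and not flagged unable")
    if full_tandem_s is not None:
        if full_tandem_s >= 10:
            return 4
        if full_tandem_s >= 3:
            return 3
        # 0–2 s full-tandem implies the semi-tandem stage was completed
        if semi_tandem_s is None or semi_tandem_s >= 10:
            return 2
    if semi_tandem_s is not None and semi_tandem_s >= 10:
        return 2
    if side_by_side_s is not None and side_by_side_s >= 10:
        return 1
    return 0


def sppb_score(record: MeasurementRecord) -> SPPBScore:
    """Full SPPB from one record's walk, chair-stand and balance measurements."""
    return SPPBScore(
        walk_points=score_walk(record.walk_times, record.walk_unable),
        chair_points=score_chair(record.chair_stand_time, record.chair_unable),
        balance_points=score_balance(record.balance_side_by_side,
                                     record.balance_semi_tandem,
                                     record.balance_full_tandem,
                                     record.balance_unable),
    )


def derive_mass_cutoffs(asm_ht2_male: Sequence[float],
                        asm_ht2_female: Sequence[float],
                        percentile: float = 20.0,
                        base: CutoffSet = CutoffSet()) -> CutoffSet:
    """Sex-specific low-mass cutoffs as the lowest 20 % of cohort ASM/Ht².

    Linear-interpolation (type-7) percentiles. Requires at least 25 values per
    sex; grip and SPPB cutoffs are carried over from ``base``.
    """
    for name, vals in (("male", asm_ht2_male), ("female", asm_ht2_female)):
        if len(vals) == 0:
            raise StagingError(f"empty {name} stratum for cutoff derivation")
        if len(vals) < 25:
            raise StagingError(f"need >= 25 {name} values to derive a cutoff, got {len(vals)}")
    return CutoffSet(
        mass_cutoff_male=float(np.percentile(np.asarray(asm_ht2_male, float), percentile)),
        mass_cutoff_female=float(np.percentile(np.asarray(asm_ht2_female, float), percentile)),
        grip_cutoff_male=base.grip_cutoff_male,
        grip_cutoff_female=base.grip_cutoff_female,
        sppb_cutoff=base.sppb_cutoff,
    )


def classify_state(record: MeasurementRecord,
                   cutoffs: CutoffSet = CutoffSet(),
                   grip_qc: Optional[tuple[float, float]] = None) -> StagingResult:
    """Classify one subject-visit into an AWGS-2019 state.

    Component flags (strict inequalities for mass and strength, ``<=`` for
    SPPB): low mass = ASM/Ht² below the sex cutoff, low strength = grip below
    the sex cutoff, low performance = SPPB total at or below the cutoff.
    A visit missing any component is excluded with a logged reason.
    """
    res = StagingResult(subject_id=record.subject_id, visit_time=record.visit_time, state=None)

    try:
        _, asm_ht2 = estimate_asm(record)
        res.asm_over_ht2 = asm_ht2
    except StagingError as e:
        res.exclusion_reason = f"missing muscle mass: {e}"
        return res

    grip = grip_strength(record, qc_bounds=grip_qc)
    if grip is None:
        res.exclusion_reason = "missing grip strength"
        return res
    res.grip_max = grip

    try:
        sppb = sppb_score(record)
        res.sppb_total = sppb.total
    except StagingError as e:
        res.exclusion_reason = f"missing physical performance: {e}"
        return res

    male = record.sex_code == 1
    mass_cut = cutoffs.mass_cutoff_male if male else cutoffs.mass_cutoff_female
    grip_cut = cutoffs.grip_cutoff_male if male else cutoffs.grip_cutoff_female
    res.low_mass = asm_ht2 < mass_cut
    res.low_strength = grip < grip_cut
    res.low_performance = sppb.total <= cutoffs.sppb_cutoff

    func_low = res.low_strength or res.low_performance
    if res.low_mass and func_low:
        res.state = 3
        res.pre_merge_severe = res.low_strength and res.low_performance
    elif func_low:
        res.state = 2
    else:
        res.state = 1
        res.low_mass_only = bool(res.low_mass)
    return res


def stage_panel(records: Iterable[MeasurementRecord],
                cutoffs: CutoffSet = CutoffSet(),
                grip_qc: Optional[tuple[float, float]] = None,
                compute_grip_qc: bool = False) -> pd.DataFrame:
    """Stage a panel of records; one output row per input record.

    When ``compute_grip_qc`` is set, grip QC bounds are first derived from the
    baseline (time 0) visits of the cohort itself.  Columns: subject_id, time,
    state (1–3 or NA), component flags, exclusion_reason.
    """
    records = list(records)
    if compute_grip_qc and grip_qc is None:
        base_grips = [grip_strength(r) for r in records if r.visit_time == 0]
        grip_qc = grip_qc_bounds([g for g in base_grips if g is not None])
    rows = []
    for rec in records:
        r = classify_state(rec, cutoffs, grip_qc)
        rows.append({
            "subject_id": r.subject_id,
            "time": r.visit_time,
            "state": r.state,
            "pre_merge_severe": r.pre_merge_severe,
            "low_mass": r.low_mass,
            "low_strength": r.low_strength,
            "low_performance": r.low_performance,
            "low_mass_only": r.low_mass_only,
            "asm_over_ht2": r.asm_over_ht2,
            "grip_max": r.grip_max,
            "sppb_total": r.sppb_total,
            "exclusion_reason": r.exclusion_reason,
        })
    return pd.DataFrame(rows)


def prevalence(staged: pd.DataFrame, state: int, time: float = 0.0) -> tuple[float, int, int]:
    """State prevalence (percent) among staged visits at one time point.

    Returns ``(percent, count, n)`` with percent rounded to 1 decimal, the
    convention used for reporting cross-sectional staging results.
    """
    at_t = staged[(staged["time"] == time) & staged["state"].notna()]
    n = len(at_t)
    if n == 0:
        raise StagingError(f"no staged visits at time {time}")
    count = int((at_t["state"] == state).sum())
    return round(100.0 * count / n, 1), count, n
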