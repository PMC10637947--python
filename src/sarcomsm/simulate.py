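"""Synthetic cohorts with the statistical structure of the sarcopenia panel.

Trajectories follow a continuous-time Markov chain simulated by competing
exponential clocks (Gillespie), observed only at biennial waves, with death
recorded at its exact event time — the observation scheme of a longitudinal
ageing survey with death registrations.  Covariates modify intensities
multiplicatively, mirroring the proportional-intensity fitting model, so
parameter-recovery studies compare like with like.

A separate generator fabricates raw staging measurements (anthropometrics,
grip, walk/chair/balance) whose AWGS-2019 classification is known by
construction, for end-to-end staging tests without survey microdata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .msm import (DEFAULT_STRUCTURE, PanelDataset, TransitionStructure,
                  validate_intensity_matrix)
from .reference import (BASELINE_STATE_MIX, REFERENCE_COVARIATES,
                        REFERENCE_WAVES, reference_intensity_matrix)
from .staging import WALK_COURSE_M, CutoffSet, MeasurementRecord

__all__ = ["SimulationScenario", "simulate_cohort", "covariate_generator",
           "generate_staging_fixture"]


@dataclass
class SimulationScenario:
    """Complete description of one synthetic-cohort draw.

    Defaults emulate the study conditions: the published generator matrix as
    truth, 2856 subjects, waves at 0/2/4 years, the published baseline state
    mix, no covariate effects and no dropout.  ``seed`` is mandatory.
    """

    seed: int
    Q: np.ndarray = field(default_factory=reference_intensity_matrix)
    structure: TransitionStructure = DEFAULT_STRUCTURE
    n_subjects: int = 2856
    waves: tuple[float, ...] = REFERENCE_WAVES
    initial_distribution: tuple[float, ...] = BASELINE_STATE_MIX
    covariate_spec: Mapping[str, tuple] = field(default_factory=dict)
    # covariate name -> {transition (r, s): beta}
    covariate_effects: Mapping[str, Mapping[tuple[int, int], float]] = field(default_factory=dict)
    dropout_prob: float = 0.0

    def __post_init__(self) -> None:
        validate_intensity_matrix(self.Q, self.structure)
        if self.n_subjects < 1:
            raise ValueError("cohort size must be >= 1")
        if any(b <= a for a, b in zip(self.waves, self.waves[1:])):
            raise ValueError("wave schedule must be strictly increasing")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must be in [0, 1)")


def covariate_generator(spec: Mapping[str, tuple], n: int, seed: int) -> pd.DataFrame:
    """Draw a covariate table from named marginal distributions.

    ``spec`` maps a covariate name to ``("bernoulli", p)`` or
    ``("normal", mean, sd)``.  Reproducible given the seed.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    for name, dist in spec.items():
        kind = dist[0]
        if kind == "bernoulli":
            cols[name] = rng.binomial(1, dist[1], size=n).astype(float)
        elif kind == "normal":
            cols[name] = rng.normal(dist[1], dist[2], size=n)
        else:
            raise ValueError(f"unknown distribution {kind!r} for covariate {name!r}")
    return pd.DataFrame(cols)


def _subject_Q(scenario: SimulationScenario, x: Mapping[str, float]) -> np.ndarray:
    """Generator for one subject: intensities scaled by exp(beta * covariate)."""
    Q = scenario.Q.copy()
    for name, effects in scenario.covariate_effects.items():
        for (r, s), beta in effects.items():
            Q[r - 1, s - 1] *= np.exp(beta * float(x.get(name, 0.0)))
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def simulate_cohort(scenario: SimulationScenario,
                    return_latent: bool = False):
    """Simulate a panel-observed cohort from the scenario.

    Each subject's latent path evolves by competing exponential clocks under
    their covariate-specific generator; the state is recorded at each wave,
    death at its exact event time, and (optional) dropout truncates follow-up
    from a wave onward.  Returns a :class:`PanelDataset`; with
    ``return_latent`` also the list of latent ``(time, state)`` paths.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_subjects
    covs = covariate_generator(scenario.covariate_spec, n,
                               seed=rng.integers(2**31 - 1)) \
        if scenario.covariate_spec else pd.DataFrame(index=range(n))
    pi0 = np.asarray(scenario.initial_distribution, dtype=float)
    pi0 = pi0 / pi0.sum()
    transient = scenario.structure.transient
    absorbing = scenario.structure.absorbing
    horizon = scenario.waves[-1]

    rows = []
    latent_paths = []
    for i in range(n):
        x = covs.iloc[i].to_dict() if len(covs.columns) else {}
        Q = _subject_Q(scenario, x)
        state = transient[rng.choice(len(pi0), p=pi0)]
        t = 0.0
        path = [(0.0, state)]
        # competing exponential clocks until absorption or horizon
        while state not in absorbing:
            rates = Q[state - 1].copy()
            rates[state - 1] = 0.0
            total = rates.sum()
            if total <= 0:
                break
            t += rng.exponential(1.0 / total)
            if t > horizon:
                break
            state = int(rng.choice(len(rates), p=rates / total)) + 1
            path.append((t, state))
        latent_paths.append(path)

        # wave observations of the latent path; death kept at exact time
        death_time = next((tt for tt, ss in path if ss in absorbing), None)
        n_waves = len(scenario.waves)
        observed_until = n_waves
        if scenario.dropout_prob > 0:
            for w in range(1, n_waves):
                if rng.random() < scenario.dropout_prob:
                    observed_until = w
                    break
        for w, tw in enumerate(scenario.waves[:observed_until]):
            if death_time is not None and tw >= death_time:
                break
            s_at = _state_at(path, tw)
            rows.append({"subject_id": f"S{i:05d}", "time": tw, "state": s_at,
                         "death_exact": False, **x})
        if death_time is not None and death_time <= scenario.waves[observed_until - 1]:
            dstate = next(ss for tt, ss in path if ss in absorbing)
            rows.append({"subject_id": f"S{i:05d}", "time": death_time,
                         "state": dstate, "death_exact": True, **x})

    df = pd.DataFrame(rows)
    ds = PanelDataset.from_frame(df, covariates=tuple(covs.columns),
                                 structure=scenario.structure)
    if return_latent:
        return ds, latent_paths
    return ds


def _state_at(path: list[tuple[float, int]], t: float) -> int:
    s = path[0][1]
    for tt, ss in path:
        if tt <= t:
            s = ss
        else:
            break
    return s


# ---------------------------------------------------------------------------
# staging fixture with planted truth


def _sppb_components(total: int, rng: np.random.Generator) -> tuple[int, int, int]:
    """Random (walk, chair, balance) points summing to ``total``."""
    while True:
        w = rng.integers(max(0, total - 8), min(4, total) + 1)
        c = rng.integers(max(0, total - w - 4), min(4, total - w) + 1)
        b = total - w - c
        if 0 <= b <= 4:
            return int(w), int(c), int(b)


_WALK_SPEED_BANDS = {1: (0.15, 0.42), 2: (0.45, 0.59), 3: (0.62, 0.76), 4: (0.79, 1.20)}
_CHAIR_TIME_BANDS = {1: (16.8, 25.0), 2: (13.8, 16.5), 3: (11.3, 13.5), 4: (6.0, 11.0)}


def _walk_measurements(points: int, rng) -> tuple[tuple[float, ...], bool]:
    if points == 0:
        return (), True
    lo, hi = _WALK_SPEED_BANDS[points]
    speed = rng.uniform(lo, hi)
    t = WALK_COURSE_M / speed
    return (round(t, 2), round(t * rng.uniform(1.0, 1.3), 2)), False


def _chair_measurement(points: int, rng) -> tuple[Optional[float], bool]:
    if points == 0:
        return None, True
    lo, hi = _CHAIR_TIME_BANDS[points]
    return round(rng.uniform(lo, hi), 1), False


def _balance_measurements(points: int, rng):
    """(side_by_side, semi_tandem, full_tandem, unable) achieving the points."""
    if points == 0:
        return None, None, None, True
    if points == 1:
        return 10.0, round(rng.uniform(0, 9.0), 1), None, False
    if points == 2:
        return 10.0, 10.0, round(rng.uniform(0, 2.0), 1), False
    if points == 3:
        return 10.0, 10.0, round(rng.uniform(3.0, 9.0), 1), False
    return 10.0, 10.0, round(rng.uniform(10.0, 30.0), 1), False


def _weight_for_asm_ratio(ratio: float, height_cm: float, sex: int, age: float) -> float:
    """Invert the anthropometric ASM equation for weight at a target ASM/Ht²."""
    h_m = height_cm / 100.0
    asm = ratio * h_m ** 2
    return (asm + 4.157 * sex + 0.037 * age + 2.631 - 0.107 * height_cm) / 0.193


def generate_staging_fixture(n: int, seed: int,
                             target_state_mix: Sequence[float] = BASELINE_STATE_MIX,
                             missing_fraction: float = 0.0,
                             cutoffs: CutoffSet = CutoffSet(),
                             ) -> tuple[list[MeasurementRecord], pd.DataFrame]:
    """Measurement records whose AWGS-2019 classification is known a priori.

    Draws sex/age/height, then solves weight, grip and SPPB component
    measurements so each record lands in its target state (1, 2 or 3) by
    construction; margins around every cutoff keep band rounding harmless.
    A ``missing_fraction`` of records get their grip measurements removed and
    are expected to be excluded at staging.  Returns the records and a truth
    table (subject_id, true_state, missing flag).
    """
    mix = np.asarray(target_state_mix, dtype=float)
    if mix.min() < 0 or abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("target state mix must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    records, truth = [], []
    labels = rng.choice([1, 2, 3], size=n, p=mix)
    missing = rng.random(n) < missing_fraction
    for i in range(n):
        label = int(labels[i])
        sex = 1 if rng.random() > 0.484 else 2
        age = rng.uniform(60, 85)
        height = rng.normal(166 if sex == 1 else 154, 5.5)
        mass_cut = cutoffs.mass_cutoff_male if sex == 1 else cutoffs.mass_cutoff_female
        grip_cut = cutoffs.grip_cutoff_male if sex == 1 else cutoffs.grip_cutoff_female

        low_mass = label == 3
        if label == 1:
            low_strength = low_perf = False
        else:
            kind = rng.integers(3)          # strength only / performance only / both
            low_strength = kind in (0, 2)
            low_perf = kind in (1, 2)

        ratio = mass_cut + (-rng.uniform(0.3, 1.5) if low_mass else rng.uniform(0.3, 2.0))
        weight = _weight_for_asm_ratio(ratio, height, sex, age)
        grip = grip_cut + (-rng.uniform(1.0, 8.0) if low_strength else rng.uniform(1.0, 12.0))
        grip = max(grip, 1.0)
        trials = tuple(round(v, 1) for v in
                       sorted(rng.uniform(max(grip - 6, 0.5), grip, size=3)) ) + (round(grip, 1),)
        total = int(rng.integers(2, 10)) if low_perf else int(rng.integers(10, 13))
        w_pts, c_pts, b_pts = _sppb_components(total, rng)
        walk_times, walk_unable = _walk_measurements(w_pts, rng)
        chair_time, chair_unable = _chair_measurement(c_pts, rng)
        side, semi, full, bal_unable = _balance_measurements(b_pts, rng)

        rec = MeasurementRecord(
            subject_id=f"F{i:05d}", visit_time=0.0,
            weight=round(weight, 2), height=round(height, 1), sex_code=sex,
            age=round(age, 1),
            grip_measurements=() if missing[i] else trials,
            walk_times=walk_times, walk_unable=walk_unable,
            chair_stand_time=chair_time, chair_unable=chair_unable,
            balance_side_by_side=side, balance_semi_tandem=semi,
            balance_full_tandem=full, balance_unable=bal_unable,
        )
        records.append(rec)
        truth.append({"subject_id": rec.subject_id, "true_state": label,
                      "missing": bool(missing[i])})
    return records, pd.DataFrame(truth)
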