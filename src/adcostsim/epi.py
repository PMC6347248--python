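"""Cohort simulation: prevalence, incidence calibration, yearly state update.

The total population is split into healthy persons (including people with
mild cognitive impairment, who share the healthy death rate) and patients in
the Mild/Moderate/Severe stages.  Age-specific prevalence follows
``r(x) = 0.0142 * exp(0.1161 * x)`` with ``x`` measured as years past the
onset age (default 60) and clamped to a cap (default 0.95).

A first *reference* run calibrates two tables that every scenario then reuses
verbatim:

* the incidence schedule - for each year and age, the probability that a
  healthy person converts to a new Mild patient, chosen so that post-update
  patient counts track the prevalence curve on the projected population; and
* the healthy-mortality table - cohort deaths left over after stage-specific
  patient deaths, as a rate on the healthy pool.

Each yearly update applies, in order: (1) patient deaths by stage-specific
probability; (2) stage transitions among survivors (transition matrix
conditioned on survival); (3) healthy deaths; (4) ageing by one year, with
the top age leaving the grid and the youngest age refilled from the
projection; (5) new Mild entrants drawn from the healthy pool by the
incidence schedule.  Counts propagate as deterministic expected values
(fractional persons); :func:`micro_oracle` is the stochastic individual-level
counterpart used for validation.

Drug scenarios switch the transition law, and MCI scenarios scale the
incidence schedule, for updates from the drug year (default 2023) onward, so
the first affected counts appear in the following calendar year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .population import PopulationProjection, cohort_mortality
from .stage_markov import (
    STAGES,
    StageTransitionModel,
    build_baseline_model,
    build_scenario_model,
    fundamental_matrix,
    scenario_incidence_multiplier,
)

__all__ = [
    "PrevalenceModel",
    "IncidenceSchedule",
    "ScenarioSpec",
    "Trajectory",
    "CalibrationResult",
    "prevalence",
    "initial_patient_state",
    "calibrate",
    "simulate",
    "micro_oracle",
    "make_scenario_spec",
]

logger = logging.getLogger(__name__)

DEFAULT_DRUG_YEAR = 2023


@dataclass(frozen=True)
class PrevalenceModel:
    """Exponential age-prevalence curve, zero below onset and clamped at ``cap``."""

    a: float = 0.0142      # prevalence at the onset age
    b: float = 0.1161      # exponential slope per year of age
    onset_age: float = 60.0
    cap: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 <= self.cap < 1.0:
            raise ValueError("cap must lie in [0, 1)")


def prevalence(age, model: PrevalenceModel | None = None) -> np.ndarray | float:
    """Disease prevalence at ``age`` (scalar or array)."""
    m = model or PrevalenceModel()
    age_arr = np.asarray(age, dtype=float)
    raw = m.a * np.exp(m.b * (age_arr - m.onset_age))
    out = np.where(age_arr >= m.onset_age, np.minimum(raw, m.cap), 0.0)
    return float(out) if np.isscalar(age) else out


@dataclass(frozen=True)
class IncidenceSchedule:
    """Frozen per-age, per-year probability of healthy -> new Mild conversion."""

    ages: np.ndarray
    years: np.ndarray
    rate: np.ndarray  # shape (n_ages, n_years)

    def __post_init__(self) -> None:
        if self.rate.shape != (self.ages.size, self.years.size):
            raise ValueError("rate shape must be (n_ages, n_years)")
        if (self.rate < 0).any() or (self.rate > 1).any():
            raise ValueError("incidence rates must lie in [0, 1]")
        for arr in (self.ages, self.years, self.rate):
            arr.setflags(write=False)


@dataclass(frozen=True)
class ScenarioSpec:
    """A named scenario: transition law after the drug year plus incidence multiplier."""

    name: str
    model: StageTransitionModel
    drug_year: int = DEFAULT_DRUG_YEAR
    incidence_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.incidence_multiplier <= 1.0:
            raise ValueError("incidence multiplier must lie in [0, 1]")


def make_scenario_spec(name: str, drug_year: int = DEFAULT_DRUG_YEAR) -> ScenarioSpec:
    """Build the spec for one of the canonical scenario ids."""
    return ScenarioSpec(
        name=name,
        model=build_scenario_model(name),
        drug_year=drug_year,
        incidence_multiplier=scenario_incidence_multiplier(name),
    )


@dataclass(frozen=True)
class Trajectory:
    """Simulated compartment counts by age and year, with yearly death tallies.

    ``ad_deaths``/``healthy_deaths`` include persons leaving the top of the
    age grid, so that population totals are conserved year over year.
    """

    ages: np.ndarray
    years: np.ndarray
    healthy: np.ndarray        # (n_ages, n_years)
    patients: np.ndarray       # (3, n_ages, n_years)
    ad_deaths: np.ndarray      # (n_years,)
    healthy_deaths: np.ndarray  # (n_years,)

    def __post_init__(self) -> None:
        for arr in (self.ages, self.years, self.healthy, self.patients,
                    self.ad_deaths, self.healthy_deaths):
            arr.setflags(write=False)

    def patient_totals(self) -> np.ndarray:
        """Total patients per stage and year, summed over ages: shape (3, n_years)."""
        return self.patients.sum(axis=1)

    def to_frame(self):
        """Tidy long-format DataFrame (year, age, compartment, count)."""
        import pandas as pd

        frames = []
        grid_age, grid_year = np.meshgrid(self.ages, self.years, indexing="ij")
        for label, block in [("Healthy", self.healthy)] + [
            (stage, self.patients[s]) for s, stage in enumerate(STAGES)
        ]:
            frames.append(
                pd.DataFrame(
                    {
                        "year": grid_year.ravel(),
                        "age": grid_age.ravel(),
                        "compartment": label,
                        "count": block.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class CalibrationResult:
    """Frozen incidence schedule and healthy-mortality table from the reference run."""

    schedule: IncidenceSchedule
    healthy_mortality: np.ndarray  # (n_ages, n_years), rate applied during year t
    trajectory: Trajectory         # the reference trajectory itself
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.healthy_mortality.setflags(write=False)


def initial_patient_state(
    projection: PopulationProjection,
    prev_model: PrevalenceModel,
    mix: np.ndarray,
) -> np.ndarray:
    """Stage-resolved patient counts in the first projection year.

    Prevalent patients are split across stages by ``mix`` (normally the
    limit stage distribution of the baseline chain): shape (3, n_ages).
    """
    mix = np.asarray(mix, dtype=float)
    if mix.shape != (3,) or abs(mix.sum() - 1.0) > 1e-9 or (mix < 0).any():
        raise ValueError("mix must be a length-3 simplex vector")
    p = prevalence(projection.ages, prev_model)
    return mix[:, None] * (p * projection.counts[:, 0])[None, :]


# ---------------------------------------------------------------------------
# The yearly update, shared by calibration and scenario simulation
# ---------------------------------------------------------------------------


def _run(
    projection: PopulationProjection,
    prev_model: PrevalenceModel,
    baseline: StageTransitionModel,
    spec: ScenarioSpec | None,
    schedule: IncidenceSchedule | None,
    healthy_mortality: np.ndarray | None,
) -> CalibrationResult | Trajectory:
    """One pass of the cohort engine.

    With ``schedule is None`` the pass calibrates: incidence and healthy
    mortality are solved on the fly and recorded (reference model, no drug).
    Otherwise the frozen tables are replayed under ``spec``.  Both modes
    execute identical floating-point operations, so replaying the reference
    scenario reproduces the calibration trajectory bit for bit.
    """
    calib = schedule is None
    ages, years = projection.ages, projection.years
    n_ages, n_years = ages.size, years.size
    counts = projection.counts
    total_mort = cohort_mortality(projection)

    mix = fundamental_matrix(baseline).limit_mix
    healthy = np.zeros((n_ages, n_years))
    patients = np.zeros((3, n_ages, n_years))
    ad_deaths = np.zeros(n_years)
    healthy_deaths = np.zeros(n_years)

    patients[:, :, 0] = initial_patient_state(projection, prev_model, mix)
    healthy[:, 0] = counts[:, 0] - patients[:, :, 0].sum(axis=0)
    if (healthy[:, 0] < 0).any():
        raise ValueError("initial prevalence exceeds population counts")

    if calib:
        rate = np.zeros((n_ages, n_years))
        hm = np.zeros((n_ages, n_years))
        diags = {"negative_healthy_mortality_cells": 0, "truncated_entrant_cells": 0,
                 "floored_entrant_cells": 0}
        target_prev = prevalence(ages, prev_model)
    else:
        rate = schedule.rate
        hm = healthy_mortality

    base_cond = baseline.conditional_q()
    if spec is not None:
        scen_cond = spec.model.conditional_q()

    P = patients[:, :, 0].copy()
    H = healthy[:, 0].copy()
    for k in range(n_years - 1):
        year = int(years[k])
        if spec is not None and year >= spec.drug_year:
            model, cond, mult = spec.model, scen_cond, spec.incidence_multiplier
        else:
            model, cond, mult = baseline, base_cond, 1.0

        # (1) patient deaths by stage-specific probability
        stage_deaths = P * model.death[:, None]
        ad_dead_by_age = stage_deaths.sum(axis=0)
        P1 = P - stage_deaths

        # (2) stage transitions among survivors
        P2 = cond.T @ P1

        # (3) healthy deaths
        if calib:
            resid = total_mort[:, k] * counts[:, k] - ad_dead_by_age
            neg = resid < -1e-9
            if neg.any():
                diags["negative_healthy_mortality_cells"] += int(neg.sum())
            hm_k = np.where(H > 0, np.clip(resid / np.where(H > 0, H, 1.0), 0.0, 1.0), 0.0)
            hm[:, k] = hm_k
        else:
            hm_k = hm[:, k]
        h_dead = H * hm_k
        H1 = H - h_dead

        # (4) ageing; the top age leaves the grid, the youngest refills healthy
        aged_out_p = P2[:, -1].sum()
        aged_out_h = H1[-1]
        P3 = np.zeros_like(P2)
        P3[:, 1:] = P2[:, :-1]
        H2 = np.zeros_like(H1)
        H2[1:] = H1[:-1]
        H2[0] = counts[0, k + 1]

        # (5) new Mild entrants by incidence
        if calib:
            target = target_prev * counts[:, k + 1]
            need = target - P3.sum(axis=0)
            floored = need < -1e-9 * np.maximum(target, 1.0)
            truncated = need > H2
            if floored.any():
                diags["floored_entrant_cells"] += int(floored.sum())
            if truncated.any():
                diags["truncated_entrant_cells"] += int(truncated.sum())
                logger.debug(
                    "calibration gap in %d: healthy pool short at ages %s",
                    int(years[k + 1]), ages[truncated].tolist(),
                )
            need = np.clip(need, 0.0, H2)
            rate[:, k + 1] = np.where(H2 > 0, need / np.where(H2 > 0, H2, 1.0), 0.0)
        entrants = rate[:, k + 1] * H2 * mult
        entrants = np.minimum(entrants, H2)
        P3[0] += entrants
        H = H2 - entrants
        P = P3

        patients[:, :, k + 1] = P
        healthy[:, k + 1] = H
        ad_deaths[k + 1] = stage_deaths.sum() + aged_out_p
        healthy_deaths[k + 1] = h_dead.sum() + aged_out_h

    traj = Trajectory(
        ages=ages.copy(), years=years.copy(), healthy=healthy, patients=patients,
        ad_deaths=ad_deaths, healthy_deaths=healthy_deaths,
    )
    if calib:
        hm[:, -1] = hm[:, -2]  # final year never drives an update; keep the table full
        sched = IncidenceSchedule(ages=ages.copy(), years=years.copy(), rate=rate)
        return CalibrationResult(
            schedule=sched, healthy_mortality=hm, trajectory=traj, diagnostics=diags
        )
    return traj


def calibrate(
    projection: PopulationProjection,
    prev_model: PrevalenceModel | None = None,
    baseline: StageTransitionModel | None = None,
) -> CalibrationResult:
    """Reference run: solve the incidence schedule and healthy-mortality table.

    Both tables are frozen afterwards and reused verbatim by every scenario,
    making incidence independent of the treatment choice.
    """
    return _run(
        projection,
        prev_model or PrevalenceModel(),
        baseline or build_baseline_model(),
        spec=None,
        schedule=None,
        healthy_mortality=None,
    )


def simulate(
    projection: PopulationProjection,
    spec: ScenarioSpec,
    schedule: IncidenceSchedule,
    healthy_mortality: np.ndarray,
    prev_model: PrevalenceModel | None = None,
    baseline: StageTransitionModel | None = None,
) -> Trajectory:
    """Run a scenario with the frozen calibration tables.

    The reference scenario reproduces the calibration trajectory exactly.
    """
    if healthy_mortality.shape != schedule.rate.shape:
        raise ValueError("healthy-mortality table and schedule grids differ")
    return _run(
        projection,
        prev_model or PrevalenceModel(),
        baseline or build_baseline_model(),
        spec=spec,
        schedule=schedule,
        healthy_mortality=healthy_mortality,
    )


# ---------------------------------------------------------------------------
# Individual-based stochastic oracle
# ---------------------------------------------------------------------------


def micro_oracle(
    projection: PopulationProjection,
    spec: ScenarioSpec,
    schedule: IncidenceSchedule,
    healthy_mortality: np.ndarray,
    seed: int,
    prev_model: PrevalenceModel | None = None,
    baseline: StageTransitionModel | None = None,
    max_persons: float = 1e5,
) -> Trajectory:
    """Stochastic individual-level counterpart of :func:`simulate`.

    Every death, stage transition and disease onset is sampled as a
    Bernoulli/multinomial event with the same ordered probabilities the
    deterministic engine applies to expectations.  Intended for small
    populations; reproducible given ``seed``.
    """
    if projection.counts[:, 0].sum() > max_persons:
        raise ValueError(f"micro oracle is for populations <= {max_persons:g} persons")
    rng = np.random.default_rng(seed)
    prev_model = prev_model or PrevalenceModel()
    baseline = baseline or build_baseline_model()
    ages, years = projection.ages, projection.years
    n_ages, n_years = ages.size, years.size

    mix = fundamental_matrix(baseline).limit_mix
    p_age = prevalence(ages, prev_model)
    n0 = np.round(projection.counts[:, 0]).astype(np.int64)
    P = np.zeros((3, n_ages), dtype=np.int64)
    for a in range(n_ages):
        draw = rng.multinomial(n0[a], np.append(p_age[a] * mix, 1.0 - p_age[a]))
        P[:, a] = draw[:3]
    H = n0 - P.sum(axis=0)

    healthy = np.zeros((n_ages, n_years))
    patients = np.zeros((3, n_ages, n_years))
    ad_deaths = np.zeros(n_years)
    healthy_deaths = np.zeros(n_years)
    healthy[:, 0] = H
    patients[:, :, 0] = P

    base_cond = baseline.conditional_q()
    scen_cond = spec.model.conditional_q()
    for k in range(n_years - 1):
        year = int(years[k])
        if year >= spec.drug_year:
            model, cond, mult = spec.model, scen_cond, spec.incidence_multiplier
        else:
            model, cond, mult = baseline, base_cond, 1.0

        dead = rng.binomial(P, model.death[:, None])
        surv = P - dead
        P2 = np.zeros_like(P)
        for s in range(3):
            for a in range(n_ages):
                if surv[s, a]:
                    P2[:, a] += rng.multinomial(surv[s, a], cond[s])
        h_dead = rng.binomial(H, healthy_mortality[:, k])
        H1 = H - h_dead

        aged_out_p = int(P2[:, -1].sum())
        aged_out_h = int(H1[-1])
        P3 = np.zeros_like(P2)
        P3[:, 1:] = P2[:, :-1]
        H2 = np.zeros_like(H1)
        H2[1:] = H1[:-1]
        H2[0] = int(round(projection.counts[0, k + 1]))

        p_onset = np.minimum(schedule.rate[:, k + 1] * mult, 1.0)
        entrants = rng.binomial(H2, p_onset)
        P3[0] += entrants
        H = H2 - entrants
        P = P3

        patients[:, :, k + 1] = P
        healthy[:, k + 1] = H
        ad_deaths[k + 1] = dead.sum() + aged_out_p
        healthy_deaths[k + 1] = h_dead.sum() + aged_out_h

    return Trajectory(
        ages=ages.copy(), years=years.copy(), healthy=healthy, patients=patients,
        ad_deaths=ad_deaths, healthy_deaths=healthy_deaths,
    )
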