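"""Disease-stage Markov algebra.

Alzheimer's disease progression is modelled as a four-state absorbing Markov
chain with yearly steps: the transient clinical stages Mild, Moderate and
Severe, and the absorbing state Death.  A model consists of the 3x3 transient
block ``q`` (one-year transition probabilities among stages) and a length-3
vector of stage-specific one-year death probabilities; each row of the full
chain is stochastic, ``q[i].sum() + death[i] == 1``.

The fundamental matrix ``N = (I - Q)^-1`` of the absorbing chain gives, in
entry ``(i, j)``, the expected number of years spent in stage ``j`` before
death for a patient entering in stage ``i``.  Because every new patient enters
in the Mild stage, the Mild row of ``N`` is the scenario-comparison metric
throughout the package, and its normalisation (the long-run stage mix of
patient-years under a steady entrant stream) is used both to split prevalent
patients across stages at simulation start and for steady-state per-patient
cost summaries.

Drug scenarios prolong the expected stay in one stage.  The built-in solver
scales the worsening probabilities out of the target stage by a common factor
(death held fixed, the freed mass absorbed into staying) and bisects that
factor until the fundamental-matrix sojourn gain hits the requested number of
years; for the Severe stage, which has no onward worsening, the death
probability is lowered instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "STAGES",
    "DEATH",
    "SCENARIO_IDS",
    "StageTransitionModel",
    "FundamentalSummary",
    "build_baseline_model",
    "build_scenario_model",
    "scenario_incidence_multiplier",
    "fundamental_matrix",
    "expected_stage_years",
    "solve_prolongation",
    "mc_stage_walk",
]

#: Transient stage labels, in severity order.  Index 3 is the absorbing state.
STAGES: tuple[str, str, str] = ("Mild", "Moderate", "Severe")
DEATH: str = "Death"

_ROW_TOL = 1e-12


def _stage_index(stage: int | str) -> int:
    if isinstance(stage, str):
        label = stage.capitalize()
        if label == DEATH:
            raise ValueError("Death is absorbing; no transient operation applies to it")
        try:
            return STAGES.index(label)
        except ValueError:
            raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}") from None
    idx = int(stage)
    if not 0 <= idx <= 2:
        raise ValueError(f"stage index {idx} out of range 0..2 (3 = Death is absorbing)")
    return idx


@dataclass(frozen=True)
class StageTransitionModel:
    """One-year disease-stage transition law.

    ``q[i, j]`` is the probability of moving from stage ``i`` to stage ``j``
    within a year; ``death[i]`` the probability of dying from stage ``i``.
    Rows of the implied 4-state chain are stochastic to 1e-12.
    """

    q: np.ndarray
    death: np.ndarray
    name: str = "unnamed"

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        death = np.asarray(self.death, dtype=float)
        if q.shape != (3, 3) or death.shape != (3,):
            raise ValueError("q must be 3x3 and death length 3")
        if (q < -_ROW_TOL).any() or (q > 1 + _ROW_TOL).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        if (death < -_ROW_TOL).any() or (death > 1 + _ROW_TOL).any():
            raise ValueError("death probabilities must lie in [0, 1]")
        rows = q.sum(axis=1) + death
        if np.abs(rows - 1.0).max() > _ROW_TOL:
            raise ValueError(f"rows must sum to 1 within {_ROW_TOL}; got {rows}")
        if q[2, 0] != 0.0:
            raise ValueError("Severe -> Mild (two-stage improvement) is not modelled")
        q.setflags(write=False)
        death.setflags(write=False)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "death", death)

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict[str, float | str]:
        """Flat key/value form (named stage-row probabilities)."""
        out: dict[str, float | str] = {"name": self.name}
        for i, frm in enumerate(STAGES):
            for j, to in enumerate(STAGES):
                if (i, j) != (2, 0):
                    out[f"{frm.lower()}_to_{to.lower()}"] = float(self.q[i, j])
            out[f"{frm.lower()}_death"] = float(self.death[i])
        return out

    @classmethod
    def from_dict(cls, data: dict[str, float | str]) -> "StageTransitionModel":
        q = np.zeros((3, 3))
        death = np.zeros(3)
        for i, frm in enumerate(STAGES):
            for j, to in enumerate(STAGES):
                if (i, j) != (2, 0):
                    q[i, j] = float(data[f"{frm.lower()}_to_{to.lower()}"])
            death[i] = float(data[f"{frm.lower()}_death"])
        return cls(q=q, death=death, name=str(data.get("name", "unnamed")))

    def conditional_q(self) -> np.ndarray:
        """Stage-transition matrix conditioned on surviving the year."""
        return self.q / (1.0 - self.death)[:, None]


@dataclass(frozen=True)
class FundamentalSummary:
    """Fundamental matrix of the absorbing chain and derived sojourn summaries."""

    n: np.ndarray                 #: expected years in column-stage given row-stage entry
    years_from_mild: np.ndarray   #: Mild-entry row of ``n``
    limit_mix: np.ndarray         #: ``years_from_mild`` normalised to a simplex vector

    def __post_init__(self) -> None:
        for arr in (self.n, self.years_from_mild, self.limit_mix):
            arr.setflags(write=False)


# ---------------------------------------------------------------------------
# Model construction: baseline probabilities and the published drug scenarios
# ---------------------------------------------------------------------------

# Baseline one-year law: National Alzheimer's Coordinating Centre transition
# probabilities with stage death probabilities 5.5% / 21.5% / 48.0%.
_BASELINE_Q = np.array(
    [
        [0.774, 0.158, 0.013],
        [0.070, 0.501, 0.214],
        [0.000, 0.028, 0.492],
    ]
)
_BASELINE_DEATH = np.array([0.055, 0.215, 0.480])

# Published scenario matrices.  Probabilities not quoted for a scenario stay
# at baseline; the residual needed for a unit row sum goes to the death
# probability (Moderate scenarios) or the stay probability (Severe scenario).
_SCENARIO_ROWS: dict[str, tuple[int, np.ndarray, float]] = {
    #                row  q-row                        death
    "mild+1": (0, np.array([0.814, 0.121, 0.010]), 0.055),
    "mild+2": (0, np.array([0.844, 0.092, 0.009]), 0.055),
    "moderate+1": (1, np.array([0.050, 0.700, 0.040]), 0.210),
    "moderate+2": (1, np.array([0.040, 0.770, 0.004]), 0.186),
    "severe+1": (2, np.array([0.000, 0.028, 0.772]), 0.200),
}

#: Incidence multipliers for the MCI (prevention) scenarios: lowering the
#: MCI->Mild conversion rate by 10/30/50% from the drug year onward.
_MCI_MULTIPLIERS = {"mci-10": 0.9, "mci-30": 0.7, "mci-50": 0.5}

SCENARIO_IDS: tuple[str, ...] = (
    "reference",
    *_SCENARIO_ROWS,
    *_MCI_MULTIPLIERS,
)


def build_baseline_model() -> StageTransitionModel:
    """The reference (no new treatment) transition law."""
    return StageTransitionModel(q=_BASELINE_Q.copy(), death=_BASELINE_DEATH.copy(), name="reference")


def build_scenario_model(name: str) -> StageTransitionModel:
    """Transition law for a named scenario.

    Treatment scenarios (``mild+1`` .. ``severe+1``) carry the published
    adjusted matrices; the reference and MCI scenarios carry the baseline
    matrix (MCI scenarios act through the incidence multiplier instead).
    """
    if name not in SCENARIO_IDS:
        raise ValueError(f"unknown scenario {name!r}; valid ids: {', '.join(SCENARIO_IDS)}")
    if name in _SCENARIO_ROWS:
        row, qrow, drow = _SCENARIO_ROWS[name]
        q = _BASELINE_Q.copy()
        death = _BASELINE_DEATH.copy()
        q[row] = qrow
        death[row] = drow
        return StageTransitionModel(q=q, death=death, name=name)
    return StageTransitionModel(q=_BASELINE_Q.copy(), death=_BASELINE_DEATH.copy(), name=name)


def scenario_incidence_multiplier(name: str) -> float:
    """Incidence multiplier applied from the drug year (1.0 except MCI scenarios)."""
    if name not in SCENARIO_IDS:
        raise ValueError(f"unknown scenario {name!r}; valid ids: {', '.join(SCENARIO_IDS)}")
    return _MCI_MULTIPLIERS.get(name, 1.0)


# ---------------------------------------------------------------------------
# Fundamental-matrix algebra
# ---------------------------------------------------------------------------


def fundamental_matrix(model: StageTransitionModel) -> FundamentalSummary:
    """Fundamental matrix ``N = (I - Q)^-1`` with Mild-entry summaries.

    Raises if ``I - Q`` is singular (a transient stage with no exit route),
    which also covers a spectral radius >= 1.
    """
    a = np.eye(3) - model.q
    try:
        n = np.linalg.solve(a, np.eye(3))
    except np.linalg.LinAlgError:
        raise ValueError(
            f"model {model.name!r} has no absorbing solution: I - Q is singular"
        ) from None
    if (n < -1e-9).any():
        raise ValueError(f"model {model.name!r}: fundamental matrix has negative entries")
    years = n[0].copy()
    return FundamentalSummary(n=n, years_from_mild=years, limit_mix=years / years.sum())


def expected_stage_years(model: StageTransitionModel, entry: int | str = "Mild") -> np.ndarray:
    """Expected total years per stage before death, for a given entry stage.

    The scenario-comparison metric is always ``entry="Mild"`` because every
    new patient enters in the Mild stage.
    """
    i = _stage_index(entry)
    return fundamental_matrix(model).n[i].copy()


def limit_mix_mortality(model: StageTransitionModel) -> float:
    """Mean one-year death probability of a patient population at the limit mix.

    This is the cohort-level mortality a fully prevalent (cap-saturated)
    patient population exhibits under a steady Mild entrant stream; the
    synthetic demography uses it as its extreme-age mortality plateau so that
    incidence calibration stays well-posed (see population module).
    """
    return float(fundamental_matrix(model).limit_mix @ model.death)


# ---------------------------------------------------------------------------
# Sojourn-prolongation solver
# ---------------------------------------------------------------------------


def _scaled_model(model: StageTransitionModel, stage: int, alpha: float) -> StageTransitionModel:
    """Scale worsening probabilities out of ``stage`` by ``alpha``, stay absorbing."""
    q = model.q.copy()
    worsen = [j for j in range(3) if j > stage]
    freed = 0.0
    for j in worsen:
        freed += q[stage, j] * (1.0 - alpha)
        q[stage, j] *= alpha
    q[stage, stage] += freed
    return StageTransitionModel(q=q, death=model.death.copy(), name=f"{model.name}+prolonged")


def _lowered_death_model(model: StageTransitionModel, stage: int, new_death: float) -> StageTransitionModel:
    q = model.q.copy()
    death = model.death.copy()
    q[stage, stage] += death[stage] - new_death
    death[stage] = new_death
    return StageTransitionModel(q=q, death=death, name=f"{model.name}+prolonged")


def solve_prolongation(
    model: StageTransitionModel,
    stage: int | str,
    delta: float,
    policy: str = "proportional-worsening",
    tol: float = 1e-9,
) -> StageTransitionModel:
    """Adjust the transition law so the expected stay in ``stage`` grows by ``delta`` years.

    The sojourn metric is the expected total years in ``stage`` for a Mild
    entrant (fundamental-matrix Mild row).  Under the only built-in policy the
    worsening probabilities out of the stage are scaled by a common factor in
    (0, 1], the stage's death probability is held fixed and the freed mass is
    absorbed into staying.  The Severe stage has no onward worsening, so there
    the death probability is lowered and staying absorbs the mass.

    Raises ``ValueError`` when ``delta`` exceeds what the policy can reach,
    reporting the attainable maximum.
    """
    if policy != "proportional-worsening":
        raise ValueError(f"unknown policy {policy!r}; only 'proportional-worsening' is built in")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    s = _stage_index(stage)
    if delta == 0:
        return model
    base_years = float(fundamental_matrix(model).n[0, s])
    target = base_years + delta

    if s == 2:
        # no onward worsening: lower the death probability, stay absorbs
        floor = 1e-12

        def gap_death(d: float) -> float:
            m = _lowered_death_model(model, s, d)
            return float(fundamental_matrix(m).n[0, s]) - target

        shortfall = gap_death(floor)
        if shortfall < 0:
            raise ValueError(
                f"delta={delta} years unreachable by lowering Severe death; "
                f"attainable maximum is {shortfall + delta:.6f} years gain"
            )
        d_star = brentq(gap_death, floor, float(model.death[s]), xtol=1e-14)
        return _lowered_death_model(model, s, float(d_star))

    def gap(alpha: float) -> float:
        m = _scaled_model(model, s, alpha)
        return float(fundamental_matrix(m).n[0, s]) - target

    lo = 1e-12
    if gap(lo) < 0:
        max_gain = gap(lo) + delta
        raise ValueError(
            f"delta={delta} years unreachable with alpha in (0, 1]; "
            f"attainable maximum is {max_gain:.6f} years gain"
        )
    alpha_star = brentq(gap, lo, 1.0, xtol=1e-14)
    solved = _scaled_model(model, s, float(alpha_star))
    # guard the contract rather than trust the bracketing tolerance
    achieved = float(fundamental_matrix(solved).n[0, s])
    if abs(achieved - target) > max(tol, 1e-9):
        raise RuntimeError(f"solver did not converge: |{achieved} - {target}| > {tol}")
    return solved


# ---------------------------------------------------------------------------
# Monte-Carlo oracle
# ---------------------------------------------------------------------------


def mc_stage_walk(model: StageTransitionModel, walkers: int, seed: int) -> np.ndarray:
    """Empirical mean years per stage from Mild entry, by simulating chains.

    Each walker starts in Mild and takes yearly steps under the full 4-state
    law until absorbed in Death.  Returns the per-stage mean occupation time;
    reproducible for a fixed seed.  Serves as an independent stochastic check
    on :func:`fundamental_matrix`.
    """
    if walkers < 1:
        raise ValueError("walkers must be >= 1")
    rng = np.random.default_rng(seed)
    # full transition matrix rows: q | death
    p = np.hstack([model.q, model.death[:, None]])
    cum = np.cumsum(p, axis=1)
    cum[:, -1] = 1.0
    state = np.zeros(walkers, dtype=np.int64)  # all start Mild
    time_in = np.zeros((walkers, 3), dtype=np.int64)
    alive = np.arange(walkers)
    while alive.size:
        s = state[alive]
        time_in[alive, s] += 1
        u = rng.random(alive.size)
        nxt = (u[:, None] > cum[s]).sum(axis=1)
        state[alive] = nxt
        alive = alive[nxt < 3]
    return time_in.mean(axis=0)
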