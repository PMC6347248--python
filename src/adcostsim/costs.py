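"""Stage-wise cost accounting and scenario comparison reports.

Care costs are attached per patient-year by disease stage, split into the
Drummond classes: informal care (surveillance, activities of daily living),
nonmedical care (day care, home help, alarm services) and medical care
(visits, hospitalisation, medication).  The built-in table is in monthly EUR
per patient; annual stage cost is twelve times the row sum.  Costs are
linear in patient counts, at constant prices with no discounting.

Comparison reports mirror the published layout: for each stage and selected
year, the scenario-minus-reference delta in billions of EUR (one decimal)
and the scenario as a percentage of reference (two decimals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epi import Trajectory
from .stage_markov import STAGES, StageTransitionModel, fundamental_matrix

__all__ = [
    "COST_CLASSES",
    "StageCostTable",
    "CostTrajectory",
    "ComparisonReport",
    "annual_stage_cost",
    "cost_trajectory",
    "per_patient_average",
    "steady_state_average_cost",
    "compare",
]

COST_CLASSES = ("informal", "nonmedical", "medical")

_DEFAULT_MONTHLY = np.array(
    [
        # informal, nonmedical, medical  (EUR per patient per month)
        [1027.00, 619.00, 280.00],    # Mild
        [1676.64, 1432.20, 234.36],   # Moderate
        [2315.36, 1977.80, 323.64],   # Severe
    ]
)


@dataclass(frozen=True)
class StageCostTable:
    """Monthly EUR per patient by stage (rows) and cost class (columns)."""

    monthly: np.ndarray = None

    def __post_init__(self) -> None:
        monthly = self.monthly if self.monthly is not None else _DEFAULT_MONTHLY.copy()
        monthly = np.asarray(monthly, dtype=float)
        if monthly.shape != (3, 3):
            raise ValueError("monthly must be 3 stages x 3 cost classes")
        if (monthly < 0).any():
            raise ValueError("costs must be nonnegative")
        monthly.setflags(write=False)
        object.__setattr__(self, "monthly", monthly)

    def annual(self) -> np.ndarray:
        """Annual EUR per patient-year by stage: 12 x row sum."""
        return 12.0 * self.monthly.sum(axis=1)


def annual_stage_cost(stage: int | str, table: StageCostTable | None = None) -> float:
    """EUR per patient-year in one stage."""
    table = table or StageCostTable()
    if isinstance(stage, str):
        stage = STAGES.index(stage.capitalize())
    return float(table.annual()[stage])


@dataclass(frozen=True)
class CostTrajectory:
    """Annual EUR by stage and year; ``overall`` is the stage sum."""

    years: np.ndarray
    by_stage: np.ndarray  # (3, n_years), EUR

    def __post_init__(self) -> None:
        self.years.setflags(write=False)
        self.by_stage.setflags(write=False)

    @property
    def overall(self) -> np.ndarray:
        return self.by_stage.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.by_stage, index=pd.Index(STAGES, name="stage"), columns=self.years)
        df.loc["Overall"] = self.overall
        return df


def cost_trajectory(traj: Trajectory, table: StageCostTable | None = None) -> CostTrajectory:
    """Annual cost per stage: annual stage cost times patients in the stage."""
    table = table or StageCostTable()
    totals = traj.patient_totals()  # (3, n_years)
    return CostTrajectory(years=traj.years.copy(), by_stage=table.annual()[:, None] * totals)


def per_patient_average(
    costs: CostTrajectory, traj: Trajectory, year: int
) -> float:
    """Overall cost divided by total patients in ``year`` (EUR per patient-year)."""
    k = int(np.searchsorted(traj.years, year))
    if k >= traj.years.size or traj.years[k] != year:
        raise ValueError(f"year {year} not on the trajectory grid")
    total_patients = traj.patient_totals()[:, k].sum()
    if total_patients <= 0:
        raise ZeroDivisionError(f"no patients in {year}; per-patient average undefined")
    return float(costs.overall[k] / total_patients)


def steady_state_average_cost(
    model: StageTransitionModel, table: StageCostTable | None = None
) -> float:
    """Long-run average annual cost per patient under a transition law.

    The limit stage mix (normalised expected stage-years from Mild entry)
    weights the annual stage costs.  Approximates the per-patient average a
    scenario settles to once its drug is in steady use.
    """
    table = table or StageCostTable()
    mix = fundamental_matrix(model).limit_mix
    return float(mix @ table.annual())


@dataclass(frozen=True)
class ComparisonReport:
    """Scenario-vs-reference deltas (EUR billions) and percentages by stage and year."""

    years: np.ndarray
    delta_billions: pd.DataFrame  # rows Mild/Moderate/Severe/Overall, 1 decimal
    percent: pd.DataFrame         # same layout, 2 decimals

    def to_frame(self) -> pd.DataFrame:
        """Interleaved layout: per stage a delta row and a percentage row."""
        rows, idx = [], []
        for stage in list(STAGES) + ["Overall"]:
            rows.append(self.delta_billions.loc[stage])
            idx.append((stage, "delta_billion_eur"))
            rows.append(self.percent.loc[stage])
            idx.append((stage, "percent_of_reference"))
        out = pd.DataFrame(rows)
        out.index = pd.MultiIndex.from_tuples(idx, names=["stage", "quantity"])
        return out


def compare(
    reference: CostTrajectory, scenario: CostTrajectory, years: list[int] | np.ndarray
) -> ComparisonReport:
    """Scenario-vs-reference report over selected years.

    Deltas are ``scenario - reference`` in billions of EUR rounded to one
    decimal; percentages are ``100 * scenario / reference`` rounded to two.
    """
    if reference.years.size != scenario.years.size or (reference.years != scenario.years).any():
        raise ValueError("reference and scenario year grids differ")
    years = np.asarray(list(years), dtype=int)
    missing = np.setdiff1d(years, reference.years)
    if missing.size:
        raise ValueError(f"years {missing.tolist()} not on the cost grid")
    cols = np.searchsorted(reference.years, years)

    ref = np.vstack([reference.by_stage[:, cols], reference.overall[cols]])
    scen = np.vstack([scenario.by_stage[:, cols], scenario.overall[cols]])
    index = pd.Index(list(STAGES) + ["Overall"], name="stage")
    delta = pd.DataFrame(np.round((scen - ref) / 1e9, 1), index=index, columns=years)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(ref > 0, 100.0 * scen / np.where(ref > 0, ref, 1.0), np.nan)
    percent = pd.DataFrame(np.round(pct, 2), index=index, columns=years)
    return ComparisonReport(years=years, delta_billions=delta, percent=percent)
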