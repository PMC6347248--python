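"""End-to-end scenario runner, configuration and report/fixture generation.

``run_all`` is the one-stop pipeline: build (or read) the demographic
projection, calibrate incidence and healthy mortality once on the reference
scenario, replay every requested scenario with those frozen tables, attach
costs and write trajectory CSVs, cost CSVs, comparison reports and a run
manifest.  Single calibration shared across scenarios is enforced here, not
left to callers, so incidence is independent of the treatment choice by
construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .costs import ComparisonReport, StageCostTable, compare, cost_trajectory
from .epi import (
    DEFAULT_DRUG_YEAR,
    CalibrationResult,
    PrevalenceModel,
    Trajectory,
    calibrate,
    make_scenario_spec,
    simulate,
)
from .population import (
    PopulationProjection,
    eu_preset,
    generate_projection,
    read_eurostat_tsv,
    toy_projection,
)
from .stage_markov import SCENARIO_IDS, build_baseline_model

__all__ = ["RunConfig", "RunResult", "run_all", "make_fixtures", "REPORT_YEARS"]

logger = logging.getLogger(__name__)

#: Years shown in the published comparison tables.
REPORT_YEARS = (2030, 2040, 2050, 2060, 2070, 2080)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    projection_source: str = "synthetic"   # "synthetic" or a Eurostat TSV path
    scenarios: tuple[str, ...] = SCENARIO_IDS
    drug_year: int = DEFAULT_DRUG_YEAR
    prevalence: PrevalenceModel = field(default_factory=PrevalenceModel)
    report_years: tuple[int, ...] = REPORT_YEARS
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.scenarios) - set(SCENARIO_IDS)
        if unknown:
            raise ValueError(f"unknown scenarios {sorted(unknown)}; valid: {SCENARIO_IDS}")


@dataclass(frozen=True)
class RunResult:
    projection: PopulationProjection
    calibration: CalibrationResult
    trajectories: dict[str, Trajectory]
    costs: dict[str, "np.ndarray"]
    reports: dict[str, ComparisonReport]


def _load_projection(config: RunConfig) -> PopulationProjection:
    if config.projection_source == "synthetic":
        return generate_projection(eu_preset(seed=config.seed))
    return read_eurostat_tsv(
        config.projection_source, years=range(2015, 2081), ages=range(0, 101)
    )


def run_all(config: RunConfig | None = None, cost_table: StageCostTable | None = None) -> RunResult:
    """Calibrate once, simulate every scenario, build reports, optionally write CSVs."""
    config = config or RunConfig()
    cost_table = cost_table or StageCostTable()
    projection = _load_projection(config)
    baseline = build_baseline_model()

    calibration = calibrate(projection, config.prevalence, baseline)
    if any(calibration.diagnostics.values()):
        logger.info("calibration diagnostics: %s", calibration.diagnostics)

    trajectories: dict[str, Trajectory] = {}
    costs = {}
    for name in config.scenarios:
        spec = make_scenario_spec(name, drug_year=config.drug_year)
        if name == "reference":
            traj = calibration.trajectory
        else:
            traj = simulate(
                projection, spec, calibration.schedule, calibration.healthy_mortality,
                config.prevalence, baseline,
            )
        trajectories[name] = traj
        costs[name] = cost_trajectory(traj, cost_table)

    reports: dict[str, ComparisonReport] = {}
    if "reference" in costs:
        for name in config.scenarios:
            if name != "reference":
                reports[name] = compare(costs["reference"], costs[name], list(config.report_years))

    if config.output_dir is not None:
        _write_outputs(config, projection, calibration, trajectories, costs, reports)
    return RunResult(projection, calibration, trajectories, costs, reports)


def _write_outputs(config, projection, calibration, trajectories, costs, reports) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    projection.to_frame().to_csv(out / "projection_counts.csv")
    np.savetxt(out / "incidence_schedule.csv", calibration.schedule.rate, delimiter=",")
    np.savetxt(out / "healthy_mortality.csv", calibration.healthy_mortality, delimiter=",")
    for name, traj in trajectories.items():
        safe = name.replace("+", "plus")
        traj.to_frame().to_csv(out / f"trajectory_{safe}.csv", index=False)
        costs[name].to_frame().to_csv(out / f"costs_{safe}.csv")
    for name, report in reports.items():
        safe = name.replace("+", "plus")
        report.to_frame().to_csv(out / f"comparison_{safe}.csv")
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "projection_source": config.projection_source,
        "scenarios": list(config.scenarios),
        "drug_year": config.drug_year,
        "prevalence": {
            "a": config.prevalence.a, "b": config.prevalence.b,
            "onset_age": config.prevalence.onset_age, "cap": config.prevalence.cap,
        },
        "report_years": list(config.report_years),
        "calibration_diagnostics": calibration.diagnostics,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def make_fixtures(seed: int, output_dir: str | None = None):
    """Emit a tiny projection plus matching reference trajectory for tests.

    A 20-age x 10-year toy population (100k persons) runs through the full
    calibrate-and-replay pipeline in well under a second.
    """
    projection = toy_projection(1e5)
    calibration = calibrate(projection)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        projection.to_frame().to_csv(out / "toy_projection.csv")
        calibration.trajectory.to_frame().to_csv(out / "toy_reference_trajectory.csv", index=False)
        np.savetxt(out / "toy_incidence.csv", calibration.schedule.rate, delimiter=",")
    return projection, calibration
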