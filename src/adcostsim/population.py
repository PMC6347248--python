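"""Synthetic EU-28-like demographic projection and Eurostat TSV ingestion.

The disease simulation consumes a population projection: person counts by
single year of age (0..100, top age closed) and calendar year (2015..2080),
with cohort deaths derivable by cohort differencing.  This module provides

* a deterministic cohort-component generator whose EU-like preset reproduces
  the broad features of the EU-28 baseline projection (~5.08e8 persons in
  2015, an ageing pyramid with a late-working-age bulge, smooth cohort
  survival under a Gompertz-Makeham mortality law), and
* a reader for the Eurostat bulk-download TSV dialect, so a real extract can
  be substituted for the synthetic stand-in.

Old-age mortality in the preset plateaus at the disease chain's limit-mix
patient mortality (~0.1365/yr).  At extreme ages the prevalence curve is cap-
saturated, so nearly the whole cohort consists of patients whose death rates
are stage-determined and age-constant; total cohort mortality must then match
the stage-implied patient mortality or the incidence calibration has no
solution (healthy-pool exhaustion on one side, negative incidence on the
other).  This is a deliberate departure from real extreme-age life tables,
made once for model consistency; see docs/methods.md.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .stage_markov import build_baseline_model, limit_mix_mortality

__all__ = [
    "ProjectionConfig",
    "PopulationProjection",
    "eu_preset",
    "generate_projection",
    "toy_projection",
    "cohort_mortality",
    "read_eurostat_tsv",
    "write_eurostat_tsv",
]

TOP_AGE = 100
DEFAULT_YEARS = (2015, 2080)


@dataclass(frozen=True)
class ProjectionConfig:
    """Parameters of the synthetic cohort-component generator.

    Mortality follows a Gompertz-Makeham law ``m(a) = c + A * exp(b * a)``
    capped at ``plateau``; the closed top age dies fully within the year.
    The 2015 pyramid combines the survival curve implied by that law with a
    Gaussian cohort-size bulge (a baby-boom echo) centred at ``modal_age``,
    rescaled to ``total_2015``.  Births are constant at ``annual_births``
    (persons/year) and net migration is zero, keeping cohorts closed so that
    healthy-population mortality can be derived exactly.  ``noise_sd`` adds
    optional lognormal jitter to the 2015 pyramid behind ``seed``; the
    default 0 makes the generator fully deterministic.
    """

    total_2015: float = 5.08e8
    modal_age: float = 50.0
    bulge_amplitude: float = 0.35
    bulge_width: float = 12.0
    makeham_c: float = 5.0e-4
    gompertz_a: float = 6.3e-6
    gompertz_b: float = 0.11
    mortality_plateau: float | None = None  # default: limit-mix patient mortality
    annual_births: float | None = None      # default: 2015 age-0 cohort size
    net_migration: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    year_start: int = DEFAULT_YEARS[0]
    year_end: int = DEFAULT_YEARS[1]

    def mortality(self) -> np.ndarray:
        """One-year death probability by age, 0..TOP_AGE."""
        ages = np.arange(TOP_AGE + 1, dtype=float)
        plateau = self.mortality_plateau
        if plateau is None:
            plateau = limit_mix_mortality(build_baseline_model())
        m = np.minimum(self.makeham_c + self.gompertz_a * np.exp(self.gompertz_b * ages), plateau)
        m[TOP_AGE] = 1.0  # closed top age: nobody ages past the grid
        if (m < 0).any() or (m > 1).any():
            raise ValueError("mortality law leaves [0, 1]")
        return m


@dataclass(frozen=True)
class PopulationProjection:
    """Person counts and cohort deaths on an age x calendar-year grid."""

    ages: np.ndarray          #: consecutive integer ages
    years: np.ndarray         #: consecutive calendar years
    counts: np.ndarray        #: persons, shape (n_ages, n_years)
    cohort_deaths: np.ndarray  #: persons dying during year t at age a, same shape

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        years = np.asarray(self.years, dtype=int)
        counts = np.asarray(self.counts, dtype=float)
        deaths = np.asarray(self.cohort_deaths, dtype=float)
        if np.any(np.diff(ages) != 1) or np.any(np.diff(years) != 1):
            raise ValueError("ages and years must be consecutive")
        if counts.shape != (ages.size, years.size) or deaths.shape != counts.shape:
            raise ValueError("counts/cohort_deaths shape must be (n_ages, n_years)")
        if (counts < 0).any():
            raise ValueError("population counts must be nonnegative")
        for arr in (ages, years, counts, deaths):
            arr.setflags(write=False)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "cohort_deaths", deaths)

    def year_index(self, year: int) -> int:
        if not self.years[0] <= year <= self.years[-1]:
            raise ValueError(f"year {year} outside projection coverage {self.years[0]}..{self.years[-1]}")
        return int(year - self.years[0])

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame (age rows x year columns)."""
        return pd.DataFrame(self.counts, index=pd.Index(self.ages, name="age"), columns=self.years)


def eu_preset(**overrides) -> ProjectionConfig:
    """The documented EU-28-like configuration (see module docstring)."""
    return replace(ProjectionConfig(), **overrides)


def generate_projection(config: ProjectionConfig | None = None) -> PopulationProjection:
    """Run the cohort-component generator.

    Deterministic given ``config`` (randomness only through ``noise_sd`` /
    ``seed``).  The bookkeeping identity
    ``counts[a+1, t+1] = counts[a, t] - cohort_deaths[a, t]`` holds exactly
    for every age below the top; the top age dies fully within its year.
    """
    cfg = config or eu_preset()
    m = cfg.mortality()
    ages = np.arange(TOP_AGE + 1)
    years = np.arange(cfg.year_start, cfg.year_end + 1)
    n_years = years.size

    survival = np.concatenate([[1.0], np.cumprod(1.0 - m[:-1])])
    bulge = 1.0 + cfg.bulge_amplitude * np.exp(
        -0.5 * ((ages - cfg.modal_age) / cfg.bulge_width) ** 2
    )
    pyramid = survival * bulge
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        pyramid = pyramid * np.exp(rng.normal(0.0, cfg.noise_sd, pyramid.size))
    pyramid = pyramid * (cfg.total_2015 / pyramid.sum())

    births = cfg.annual_births if cfg.annual_births is not None else float(pyramid[0])
    counts = np.zeros((ages.size, n_years))
    deaths = np.zeros_like(counts)
    counts[:, 0] = pyramid
    for k in range(n_years - 1):
        deaths[:, k] = counts[:, k] * m
        counts[1:, k + 1] = counts[:-1, k] - deaths[:-1, k] + cfg.net_migration
        counts[0, k + 1] = births
    deaths[:, -1] = counts[:, -1] * m
    if (counts < 0).any():
        raise ValueError("configuration yields negative cohort counts (check migration)")
    return PopulationProjection(ages=ages, years=years, counts=counts, cohort_deaths=deaths)


def toy_projection(
    n_persons: float,
    ages: tuple[int, int] = (60, 79),
    years: tuple[int, int] = (2015, 2024),
    mortality: float | np.ndarray = 0.02,
) -> PopulationProjection:
    """A small flat-pyramid projection for tests and the micro oracle.

    ``n_persons`` is the total 2015 population, spread uniformly over the age
    range; ``mortality`` is a scalar or per-age vector of one-year death
    probabilities (the top age of the range still dies fully).
    """
    age_grid = np.arange(ages[0], ages[1] + 1)
    year_grid = np.arange(years[0], years[1] + 1)
    m = np.broadcast_to(np.asarray(mortality, dtype=float), age_grid.shape).copy()
    m[-1] = 1.0
    counts = np.zeros((age_grid.size, year_grid.size))
    deaths = np.zeros_like(counts)
    counts[:, 0] = n_persons / age_grid.size
    entrants = counts[0, 0]
    for k in range(year_grid.size - 1):
        deaths[:, k] = counts[:, k] * m
        counts[1:, k + 1] = counts[:-1, k] - deaths[:-1, k]
        counts[0, k + 1] = entrants
    deaths[:, -1] = counts[:, -1] * m
    return PopulationProjection(ages=age_grid, years=year_grid, counts=counts, cohort_deaths=deaths)


def cohort_mortality(projection: PopulationProjection) -> np.ndarray:
    """Per-age, per-year death probability ``deaths / counts``, clipped to [0, 1].

    Zero-count cohorts get mortality 0.
    """
    counts = projection.counts
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(counts > 0, projection.cohort_deaths / np.where(counts > 0, counts, 1.0), 0.0)
    return np.clip(m, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Eurostat bulk-download TSV dialect
# ---------------------------------------------------------------------------

_AGE_TOKEN = re.compile(r"^Y(\d+)$")
_OPEN_TOKENS = {"Y_GE100", "Y_OPEN", "Y_GE99"}
_FLAG_CHARS = "bcdefinprsuz:"


def _parse_cell(cell: str, row: int, col: int) -> float | None:
    """Strip Eurostat flags ('1234.5 e'); ':' marks a missing value."""
    text = cell.strip()
    if not text:
        return None
    value = text.split()[0].rstrip(_FLAG_CHARS)
    if not value or text.startswith(":"):
        return None
    try:
        return float(value)
    except ValueError:
        raise ValueError(f"malformed numeric cell {cell!r} at row {row}, column {col}") from None


def read_eurostat_tsv(
    path,
    years: range | list[int] | None = None,
    ages: range | list[int] | None = None,
) -> PopulationProjection:
    """Read a Eurostat bulk-download TSV population extract.

    The dialect has a comma-joined dimension header in the first column
    (e.g. ``unit,age,sex,geo\\time``) and one tab-separated column per year;
    numeric cells may carry flag letters.  Ages ``Y0..Y99`` are parsed and an
    open-ended top group (``Y_GE100``/``Y_OPEN``) is folded into age 100.
    The result is restricted to 2015-2080.

    When ``years`` or ``ages`` is given, the file must cover the full
    requested grid; a gap is rejected naming the missing year or age.
    Cohort deaths are derived by cohort differencing (closed cohorts, no
    migration assumed); the final year reuses the previous year's rates.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty TSV")
    header = lines[0].split("\t")
    dims = header[0].split(",")
    try:
        age_pos = next(i for i, d in enumerate(dims) if d.split("\\")[0].strip() == "age")
    except StopIteration:
        raise ValueError(f"{path}: no 'age' dimension in header {header[0]!r}") from None
    file_years = [int(col.strip()) for col in header[1:]]

    rows: dict[int, dict[int, float]] = {}
    for r, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        key = cells[0].split(",")
        token = key[age_pos].strip()
        match = _AGE_TOKEN.match(token)
        if match:
            age = int(match.group(1))
            if age > TOP_AGE:
                age = TOP_AGE
        elif token in _OPEN_TOKENS:
            age = TOP_AGE
        else:
            continue  # TOTAL, Y_LT1 aggregates handled elsewhere; skip unknown tokens
        for c, cell in enumerate(cells[1:], start=1):
            if c - 1 >= len(file_years):
                break
            year = file_years[c - 1]
            if not DEFAULT_YEARS[0] <= year <= DEFAULT_YEARS[1]:
                continue
            value = _parse_cell(cell, r, c)
            if value is None:
                continue
            rows.setdefault(age, {})
            rows[age][year] = rows[age].get(year, 0.0) + value

    if not rows:
        raise ValueError(f"{path}: no age rows found")
    avail_ages = sorted(rows)
    avail_years = sorted({y for by_year in rows.values() for y in by_year})

    want_ages = list(ages) if ages is not None else avail_ages
    want_years = list(years) if years is not None else avail_years
    for a in want_ages:
        if a not in rows:
            raise ValueError(f"{path}: missing age {a}")
    for y in want_years:
        if any(y not in rows[a] for a in want_ages):
            raise ValueError(f"{path}: missing year {y}")

    age_grid = np.arange(min(want_ages), max(want_ages) + 1)
    year_grid = np.arange(min(want_years), max(want_years) + 1)
    counts = np.zeros((age_grid.size, year_grid.size))
    for i, a in enumerate(age_grid):
        if a not in rows:
            raise ValueError(f"{path}: missing age {a}")
        for j, y in enumerate(year_grid):
            if y not in rows[a]:
                raise ValueError(f"{path}: missing year {y}")
            counts[i, j] = rows[a][y]

    deaths = np.zeros_like(counts)
    if counts.shape[0] > 1 and counts.shape[1] > 1:
        deaths[:-1, :-1] = counts[:-1, :-1] - counts[1:, 1:]
        deaths[-1, :-1] = counts[-1, :-1]  # top age closed
        deaths[:, -1] = deaths[:, -2] if counts.shape[1] > 1 else 0.0
    deaths = np.clip(deaths, 0.0, None)
    return PopulationProjection(ages=age_grid, years=year_grid, counts=counts, cohort_deaths=deaths)


def write_eurostat_tsv(projection: PopulationProjection, path) -> None:
    """Write counts in the Eurostat bulk TSV dialect (round-trips with the reader)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("unit,age,geo\\time\t" + "\t".join(str(y) for y in projection.years) + "\n")
        for i, age in enumerate(projection.ages):
            token = f"Y{age}" if age < TOP_AGE else "Y_GE100"
            cells = "\t".join(repr(float(v)) for v in projection.counts[i])
            fh.write(f"PER,{token},EU28\t{cells}\n")
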