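"""Synthetic breeding-colony generator with known social ground truth.

The simulator emulates the study system the analysis modules were built for: a
colony of long-lived birds breeding in spatially discrete patches that are
annually ephemeral (mean occupation expectancy of a patch ~1.5 breeding
seasons), so that persistent co-breeding between two individuals cannot be
explained by patch fidelity. Individuals belong to latent social groups whose
members preferentially co-settle; a perturbation regime can either drive
individuals to emigrate permanently or scramble group membership, eroding
social cohesion. Detection of breeders is imperfect and missing at random.

Every downstream stage (association, persistence tests, network regression,
permutation null) is exercised against datasets from this module, for which
the generating group structure, tie strength and detection rate are known.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cobreed.errors import ConfigError

RESIGHTING_COLUMNS = ("individual_id", "year", "colony", "patch_id")

_PERTURBATION_MODES = ("emigrate", "scramble")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic colony.

    Parameters
    ----------
    n_individuals
        Number of marked individuals followed from the first year.
    years
        Inclusive (first, last) breeding seasons to simulate.
    n_groups
        Number of latent social groups; individuals are assigned round-robin
        so group sizes differ by at most one.
    patch_survival
        Probability a breeding patch persists to the next season. Patch
        lifetime is geometric with mean ``1/(1 - patch_survival)``; the
        default 1/3 gives the ~1.5-year occupation expectancy typical of
        ephemeral gull sub-colonies.
    mean_patches
        Expected number of patches available per season (stationary target).
    tie_strength
        Probability that a breeding individual settles on its group's target
        patch for the year rather than on an independently drawn patch.
        0 = no social attraction; 1 = deterministic co-settlement.
    annual_survival
        Per-year survival probability of each individual.
    p_breed
        Probability an alive, non-emigrated individual breeds in a year.
    p_detect
        Probability that a breeding individual is resighted that year
        (missing at random).
    perturbation_start
        First year of the perturbation regime, or None for none.
    perturbation_mode
        "emigrate": from ``perturbation_start`` onward each individual leaves
        the study site permanently with probability ``dispersal_rate`` per
        year (records stop). "scramble": group membership is re-drawn at
        random each year from ``perturbation_start``, destroying long-term
        ties without removing individuals; ``dispersal_rate`` still applies.
    dispersal_rate
        Per-year emigration probability under the perturbation regime.
    seed
        Seed for the default generator used by :func:`simulate_colony`.
    """

    n_individuals: int = 300
    years: tuple[int, int] = (2002, 2017)
    n_groups: int = 30
    patch_survival: float = 1.0 / 3.0
    mean_patches: float = 30.0
    tie_strength: float = 0.9
    annual_survival: float = 0.9
    p_breed: float = 0.85
    p_detect: float = 0.5
    perturbation_start: int | None = None
    perturbation_mode: str = "emigrate"
    dispersal_rate: float = 0.0
    colony: str = "SIM"
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "patch_survival": self.patch_survival,
            "tie_strength": self.tie_strength,
            "annual_survival": self.annual_survival,
            "p_breed": self.p_breed,
            "p_detect": self.p_detect,
            "dispersal_rate": self.dispersal_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if self.n_individuals < 2:
            raise ConfigError("n_individuals must be >= 2")
        if self.n_groups < 1:
            raise ConfigError("n_groups must be >= 1")
        if self.years[1] < self.years[0]:
            raise ConfigError(f"empty year range {self.years}")
        if self.mean_patches < 1:
            raise ConfigError("mean_patches must be >= 1")
        if self.perturbation_mode not in _PERTURBATION_MODES:
            raise ConfigError(
                f"perturbation_mode must be one of {_PERTURBATION_MODES}"
            )

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    @property
    def mean_patch_lifetime(self) -> float:
        """Expected patch occupation time, 1/(1 - patch_survival) years."""
        if self.patch_survival >= 1.0:
            return float("inf")
        return 1.0 / (1.0 - self.patch_survival)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "years" in d:
            d["years"] = tuple(d["years"])
        return cls(**d)


@dataclass
class TrueColonyState:
    """Ground truth of a simulated colony (for recovery tests only).

    ``group_by_year`` equals the initial assignment every year unless the
    "scramble" perturbation re-draws memberships; under the default regime
    group labels are constant over an individual's lifetime.
    """

    individuals: list[str]
    years: list[int]
    group_of: dict[str, int]
    group_by_year: dict[int, dict[str, int]]
    breeding_patch: dict[tuple[str, int], str]
    alive: dict[tuple[str, int], bool]
    emigrated: dict[tuple[str, int], bool]
    patches_by_year: dict[int, list[str]] = field(default_factory=dict)

    def n_breeding_events(self) -> int:
        return len(self.breeding_patch)

    def truth_frame(self) -> pd.DataFrame:
        """One row per individual: group and (first) emigration year."""
        rows = []
        for ind in self.individuals:
            emig = [y for y in self.years if self.emigrated.get((ind, y))]
            rows.append(
                {
                    "individual_id": ind,
                    "group": self.group_of[ind],
                    "emigration_year": emig[0] if emig else pd.NA,
                }
            )
        return pd.DataFrame(rows)


def simulate_patch_dynamics(
    config: SimulationConfig, rng: np.random.Generator
) -> list[list[str]]:
    """Simulate annual patch extinction/colonization.

    Each patch persists to the next season with probability
    ``config.patch_survival`` (geometric lifetime); extinct patches are
    replaced by Poisson-many newly labelled patches so the expected per-year
    patch count stays near ``config.mean_patches``. Patch ids are never
    reused.

    Returns one list of patch ids per simulated year.
    """
    counter = 0

    def new_patches(k: int) -> list[str]:
        nonlocal counter
        out = [f"P{counter + i:05d}" for i in range(k)]
        counter += k
        return out

    n0 = max(1, int(rng.poisson(config.mean_patches)))
    current = new_patches(n0)
    per_year = [list(current)]
    turnover = config.mean_patches * (1.0 - config.patch_survival)
    for _ in config.year_list[1:]:
        survives = rng.random(len(current)) < config.patch_survival
        survivors = [p for p, s in zip(current, survives) if s]
        n_new = int(rng.poisson(turnover))
        if len(survivors) + n_new == 0:
            n_new = 1
        current = survivors + new_patches(n_new)
        per_year.append(list(current))
    return per_year


def simulate_individuals(
    config: SimulationConfig,
    patches: list[list[str]],
    rng: np.random.Generator,
) -> TrueColonyState:
    """Simulate group-mediated settlement, survival and perturbation.

    Each year every group draws one target patch uniformly from that year's
    patches; each alive, non-emigrated individual breeds with probability
    ``p_breed`` and settles on its group's target with probability
    ``tie_strength``, otherwise on an independent uniform patch. Survival and
    (under perturbation) permanent emigration are applied at the end of each
    season, so a year-``Y`` perturbation with ``dispersal_rate=1`` removes all
    records from year ``Y+1`` onward.
    """
    if any(len(p) == 0 for p in patches):
        raise ConfigError("every year needs at least one patch")
    years = config.year_list
    if len(patches) != len(years):
        raise ConfigError("patches must have one entry per simulated year")

    n = config.n_individuals
    individuals = [f"I{i:05d}" for i in range(n)]
    base_groups = np.arange(n) % config.n_groups  # balanced round-robin
    group_of = {ind: int(g) for ind, g in zip(individuals, base_groups)}

    alive = np.ones(n, dtype=bool)
    emigrated = np.zeros(n, dtype=bool)
    groups = base_groups.copy()

    state = TrueColonyState(
        individuals=individuals,
        years=years,
        group_of=group_of,
        group_by_year={},
        breeding_patch={},
        alive={},
        emigrated={},
        patches_by_year={y: list(p) for y, p in zip(years, patches)},
    )

    perturbed = (
        lambda y: config.perturbation_start is not None
        and y >= config.perturbation_start
    )

    for year, year_patches in zip(years, patches):
        if config.perturbation_mode == "scramble" and perturbed(year):
            groups = rng.integers(config.n_groups, size=n)
        state.group_by_year[year] = {
            ind: int(g) for ind, g in zip(individuals, groups)
        }

        targets = rng.integers(len(year_patches), size=config.n_groups)
        can_breed = alive & ~emigrated
        breeds = can_breed & (rng.random(n) < config.p_breed)
        follows = rng.random(n) < config.tie_strength
        independent = rng.integers(len(year_patches), size=n)
        patch_idx = np.where(follows, targets[groups], independent)

        for i in np.flatnonzero(breeds):
            ind = individuals[i]
            state.breeding_patch[(ind, year)] = year_patches[patch_idx[i]]
        for i in range(n):
            state.alive[(individuals[i], year)] = bool(alive[i])
            state.emigrated[(individuals[i], year)] = bool(emigrated[i])

        # end-of-season transitions
        if perturbed(year) and config.dispersal_rate > 0:
            leaves = alive & ~emigrated & (
                rng.random(n) < config.dispersal_rate
            )
            emigrated |= leaves
        alive &= rng.random(n) < config.annual_survival

    return state


def apply_detection(
    state: TrueColonyState,
    p_detect: float,
    rng: np.random.Generator,
    colony: str = "SIM",
) -> pd.DataFrame:
    """Thin true breeding events into a resighting table.

    Each (individual, year) breeding event is independently emitted with
    probability ``p_detect`` (missing at random); emitted rows carry the true
    patch. Returns a table with columns individual_id, year, colony, patch_id.
    """
    if not 0.0 <= p_detect <= 1.0:
        raise ConfigError(f"p_detect must be in [0, 1], got {p_detect}")
    events = sorted(state.breeding_patch.items())
    keep = rng.random(len(events)) < p_detect
    rows = [
        (ind, year, colony, state.breeding_patch[(ind, year)])
        for ((ind, year), _), k in zip(events, keep)
        if k
    ]
    return pd.DataFrame(rows, columns=list(RESIGHTING_COLUMNS))


def simulate_colony(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, TrueColonyState]:
    """Run the full generator: patches, individuals, detection.

    Returns the observed resighting table and the ground-truth state.
    Identical config and seed give byte-identical tables after serialization.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    patches = simulate_patch_dynamics(config, rng)
    state = simulate_individuals(config, patches, rng)
    records = apply_detection(state, config.p_detect, rng, colony=config.colony)
    return records, state


def write_resightings(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def write_truth(state: TrueColonyState, path: str | Path) -> None:
    """Ground-truth CSV (group, emigration year) for test use only."""
    state.truth_frame().to_csv(path, index=False)
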