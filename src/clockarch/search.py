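"""Two-phase search (TPS) for circadian parameter sets.

TPS harvests *all* parameter sets (up to a requested archive size) whose
simulated clock output shows a sustained oscillation with period in the
circadian window (default 23-25 h) and peak-to-trough amplitude in the
target window (default 2-6 nM).  Phase one samples kinetic parameters
log-uniformly within the global bounds (0.1-10 fold around the reference
values); the best candidates seed phase two, a genetic algorithm run in
log-parameter space, and every individual that reaches fitness zero is
archived (subject to a distinctness threshold) until the archive is full.

Constrained searches:

* dual / redundant architectures: each Y-loop parameter is confined to the
  kinetic-symmetry band ``[x/(1+rho), x*(1+rho)]`` around its X-loop
  counterpart (rho=0 forces identical loops; rho>=99 is unconstrained).
* semi-dual architecture: the mean total Y protein level (free Y plus the
  X:Y complex in cytoplasm and nucleus) may be confined to a stratum such
  as <10 nM, 10-200 nM, or >200 nM.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import dynamics
from .models import (
    Architecture,
    ParameterSet,
    RHO_UNCONSTRAINED,
    build_model,
    parameter_names,
    reference_parameters,
    y_loop_pairs,
)

__all__ = [
    "SearchConfig",
    "ArchiveEntry",
    "SolutionArchive",
    "SearchError",
    "fitness",
    "random_phase",
    "ga_phase",
    "run_tps",
]

logger = logging.getLogger(__name__)

#: Fitness tier assigned to every candidate without sustained oscillation.
NONOSCILLATORY_PENALTY = 1e6


class SearchError(RuntimeError):
    """The search could not proceed (e.g. random phase exhausted)."""


@dataclass(frozen=True)
class SearchConfig:
    """Study conditions and budget of one TPS run."""

    architecture: Architecture
    fold_range: tuple[float, float] = (0.1, 10.0)   # around reference values
    rho: Optional[float] = None                     # dual/redundant symmetry
    y_level_constraint: Optional[tuple[float, float]] = None  # nM, semi-dual
    period_window: tuple[float, float] = (23.0, 25.0)     # h
    amplitude_window: tuple[float, float] = (2.0, 6.0)    # nM
    n_solutions: int = 100
    random_phase_trials: int = 5000
    population_size: int = 100
    max_generations: int = 200
    crossover_rate: float = 0.9
    blx_alpha: float = 0.5
    mutation_rate: float = 0.1        # per-gene probability
    mutation_sigma: float = 0.1       # log10 units
    elite_count: int = 1
    min_distance: float = 0.01        # log10 distinctness threshold
    seed: int = 0
    horizon: float = dynamics.DEFAULT_HORIZON
    transient: float = dynamics.DEFAULT_TRANSIENT

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "architecture", Architecture.from_name(self.architecture)
        )
        lo, hi = self.fold_range
        if not (0 < lo < hi):
            raise ValueError(f"invalid fold_range {self.fold_range}")
        if self.rho is not None and self.rho < 0:
            raise ValueError("rho must be non-negative")
        if (
            self.rho is not None
            and self.architecture
            in (Architecture.SINGLE, Architecture.SEMI_DUAL)
        ):
            raise ValueError(
                f"rho does not apply to the {self.architecture.value} model"
            )
        if (
            self.y_level_constraint is not None
            and self.architecture is not Architecture.SEMI_DUAL
        ):
            raise ValueError(
                "y_level_constraint applies to the semi_dual model only"
            )

    @property
    def log_bounds(self) -> tuple[float, float]:
        return (math.log10(self.fold_range[0]), math.log10(self.fold_range[1]))

    @property
    def symmetry_halfwidth(self) -> Optional[float]:
        """Half-width of the Y-loop band in log10 units (None = no band)."""
        if self.rho is None or self.rho >= RHO_UNCONSTRAINED:
            return None
        return math.log10(1.0 + self.rho)


@dataclass(frozen=True)
class ArchiveEntry:
    params: ParameterSet
    features: dynamics.OscillationFeatures
    gamma: Optional[float]         # loop balance; redundant model only
    total_y: Optional[float]       # mean total Y protein, nM; m=6 models
    provenance: dict


@dataclass
class SolutionArchive:
    """Accepted parameter sets with their features and search provenance."""

    config: SearchConfig
    entries: list[ArchiveEntry] = field(default_factory=list)
    n_evaluations: int = 0
    complete: bool = True

    def __len__(self) -> int:
        return len(self.entries)

    def parameter_sets(self) -> list[ParameterSet]:
        return [e.params for e in self.entries]


# ---------------------------------------------------------------------------
# Genome helpers: a genome is the vector of log10 multipliers of the
# reference parameter values, in the canonical parameter order.
# ---------------------------------------------------------------------------


def _loop_indices(arch: Architecture) -> tuple[np.ndarray, np.ndarray]:
    """(y_indices, x_indices) of paired Y/X-loop parameters."""
    names = parameter_names(arch)
    pairs = y_loop_pairs(arch)
    y_idx = np.array([names.index(y) for y in pairs], dtype=int)
    x_idx = np.array([names.index(x) for x in pairs.values()], dtype=int)
    return y_idx, x_idx


def _repair(genome: np.ndarray, config: SearchConfig,
            y_idx: np.ndarray, x_idx: np.ndarray) -> np.ndarray:
    """Clip into global bounds and the rho symmetry band (in log10 space).

    Reference values of paired X/Y parameters are equal, so the
    multiplicative band is an additive band on log10 multipliers.
    """
    lo, hi = config.log_bounds
    genome = np.clip(genome, lo, hi)
    w = config.symmetry_halfwidth
    if w is not None and len(y_idx):
        gx = genome[x_idx]
        genome[y_idx] = np.clip(genome[y_idx], gx - w, gx + w)
    return genome


def _genome_to_params(genome: np.ndarray, ref_array: np.ndarray,
                      arch: Architecture) -> ParameterSet:
    return ParameterSet.from_array(arch, ref_array * 10.0 ** genome)


def _is_duplicate(genome: np.ndarray, archive_genomes: list[np.ndarray],
                  min_distance: float) -> bool:
    return any(
        np.max(np.abs(genome - g)) < min_distance for g in archive_genomes
    )


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------


def _window_penalty(value: float, window: tuple[float, float]) -> float:
    """Relative distance of ``value`` to the window (0 inside)."""
    lo, hi = window
    if lo <= value <= hi:
        return 0.0
    mid = 0.5 * (lo + hi)
    return min(abs(value - lo), abs(value - hi)) / mid


def _stratum_penalty(total_y: float, stratum: tuple[float, float]) -> float:
    """Scale-free (log10) distance of total Y to its stratum."""
    lo, hi = stratum
    if lo <= total_y <= hi:
        return 0.0
    target = lo if total_y < lo else hi
    return abs(math.log10(max(total_y, 1e-12) / target))


def fitness(
    features: dynamics.OscillationFeatures,
    config: SearchConfig,
    total_y: Optional[float] = None,
) -> float:
    """Distance-to-target fitness; zero exactly on acceptable solutions.

    Zero iff the oscillation is sustained, the period and amplitude fall in
    their target windows and (semi-dual) the total Y level lies in its
    stratum.  Non-oscillatory candidates receive the maximal penalty tier.
    """
    if features is None or not features.sustained:
        return NONOSCILLATORY_PENALTY
    pen = _window_penalty(features.period, config.period_window)
    pen += _window_penalty(features.amplitude, config.amplitude_window)
    if config.y_level_constraint is not None:
        if total_y is None:
            return NONOSCILLATORY_PENALTY
        pen += _stratum_penalty(total_y, config.y_level_constraint)
    return pen


# ---------------------------------------------------------------------------
# Candidate evaluation
# ---------------------------------------------------------------------------

_TOTAL_Y_SPECIES = ("Y", "X:Y", "X:Y(nuc)")


def _evaluate(genome: np.ndarray, config: SearchConfig,
              ref_array: np.ndarray):
    """Simulate one genome; returns (fitness, features, gamma, total_y)."""
    arch = config.architecture
    params = _genome_to_params(genome, ref_array, arch)
    model = build_model(arch, params)
    traj = dynamics.integrate(
        model, horizon=config.horizon, transient=config.transient
    )
    feats = dynamics.oscillation_features(traj)
    gamma = None
    total_y = None
    if traj is not None:
        if arch is Architecture.REDUNDANT:
            gamma = dynamics.loop_balance(traj)
        levels = feats.mean_levels
        if arch in (Architecture.SEMI_DUAL, Architecture.DUAL):
            total_y = sum(levels.get(s, 0.0) for s in _TOTAL_Y_SPECIES)
    return fitness(feats, config, total_y), feats, gamma, total_y


@dataclass
class _Pool:
    """GA seed population: genomes with their evaluation results."""

    genomes: np.ndarray                 # (n, n_params)
    fitnesses: np.ndarray               # (n,)
    results: list                       # per-genome (feats, gamma, total_y)


# ---------------------------------------------------------------------------
# Phase 1: random search
# ---------------------------------------------------------------------------


def _sample_genomes(n: int, config: SearchConfig, rng: np.random.Generator,
                    y_idx: np.ndarray, x_idx: np.ndarray) -> np.ndarray:
    lo, hi = config.log_bounds
    n_params = len(parameter_names(config.architecture))
    g = rng.uniform(lo, hi, size=(n, n_params))
    w = config.symmetry_halfwidth
    if w is not None and len(y_idx):
        gx = g[:, x_idx]
        g[:, y_idx] = rng.uniform(
            np.maximum(lo, gx - w), np.minimum(hi, gx + w)
        )
    return g


def random_phase(
    config: SearchConfig, rng: Optional[np.random.Generator] = None
) -> _Pool:
    """Log-uniform sampling phase; returns the GA seed population.

    Raises :class:`SearchError` if no sampled candidate scores below the
    non-oscillatory tier within the trial budget.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    y_idx, x_idx = _loop_indices(config.architecture)
    ref_array = reference_parameters(config.architecture).as_array()
    genomes = _sample_genomes(
        config.random_phase_trials, config, rng, y_idx, x_idx
    )
    fits = np.empty(len(genomes))
    results = []
    for i, g in enumerate(genomes):
        f, feats, gamma, ty = _evaluate(g, config, ref_array)
        fits[i] = f
        results.append((feats, gamma, ty))
    if not np.any(fits < NONOSCILLATORY_PENALTY):
        raise SearchError(
            f"random phase exhausted: no oscillatory candidate in "
            f"{config.random_phase_trials} trials "
            f"({config.architecture.value})"
        )
    order = np.argsort(fits, kind="stable")[: config.population_size]
    logger.info(
        "random phase (%s): %d trials, best fitness %.4g, %d oscillatory",
        config.architecture.value, len(genomes), fits[order[0]],
        int(np.sum(fits < NONOSCILLATORY_PENALTY)),
    )
    return _Pool(
        genomes[order].copy(),
        fits[order].copy(),
        [results[i] for i in order],
    )


# ---------------------------------------------------------------------------
# Phase 2: genetic algorithm
# ---------------------------------------------------------------------------


def _try_archive(
    archive: SolutionArchive,
    genome: np.ndarray,
    result,
    fit: float,
    provenance: dict,
    genomes_seen: list[np.ndarray],
    config: SearchConfig,
) -> None:
    if fit != 0.0 or len(archive) >= config.n_solutions:
        return
    if _is_duplicate(genome, genomes_seen, config.min_distance):
        return
    feats, gamma, total_y = result
    ref_array = reference_parameters(config.architecture).as_array()
    archive.entries.append(
        ArchiveEntry(
            params=_genome_to_params(genome, ref_array, config.architecture),
            features=feats,
            gamma=gamma,
            total_y=total_y,
            provenance=dict(provenance, seed=config.seed),
        )
    )
    genomes_seen.append(genome.copy())


def ga_phase(
    pool: _Pool,
    config: SearchConfig,
    rng: Optional[np.random.Generator] = None,
) -> SolutionArchive:
    """Evolve the seed pool, archiving every distinct fitness-zero
    individual until ``n_solutions`` are collected or the generation budget
    is spent (then a partial archive is returned with a warning)."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    if len(pool.genomes) == 0:
        raise SearchError("empty seed pool")
    y_idx, x_idx = _loop_indices(config.architecture)
    ref_array = reference_parameters(config.architecture).as_array()
    archive = SolutionArchive(config=config)
    genomes_seen: list[np.ndarray] = []

    pop = pool.genomes.copy()
    fits = pool.fitnesses.copy()
    results = list(pool.results)
    for g, f, r in zip(pop, fits, results):
        _try_archive(
            archive, g, r, f, {"phase": "random", "generation": 0},
            genomes_seen, config,
        )

    n = len(pop)
    gen = 0
    while len(archive) < config.n_solutions and gen < config.max_generations:
        gen += 1
        order = np.argsort(fits, kind="stable")
        elites = order[: config.elite_count]
        children = np.empty_like(pop)
        children[: len(elites)] = pop[elites]
        for k in range(len(elites), n):
            # tournament selection, size 2
            i, j = rng.integers(0, n, 2)
            a = pop[i] if fits[i] <= fits[j] else pop[j]
            i, j = rng.integers(0, n, 2)
            b = pop[i] if fits[i] <= fits[j] else pop[j]
            if rng.random() < config.crossover_rate:
                lo = np.minimum(a, b)
                hi = np.maximum(a, b)
                d = hi - lo
                child = rng.uniform(
                    lo - config.blx_alpha * d, hi + config.blx_alpha * d
                )
            else:
                child = a.copy()
            mask = rng.random(child.shape) < config.mutation_rate
            child = child + mask * rng.normal(
                0.0, config.mutation_sigma, child.shape
            )
            children[k] = _repair(child, config, y_idx, x_idx)
        new_fits = np.empty(n)
        new_results = []
        for k in range(n):
            if k < len(elites):
                src = elites[k]
                new_fits[k] = fits[src]
                new_results.append(results[src])
                continue
            f, feats, gamma, ty = _evaluate(children[k], config, ref_array)
            archive.n_evaluations += 1
            new_fits[k] = f
            new_results.append((feats, gamma, ty))
            _try_archive(
                archive, children[k], (feats, gamma, ty), f,
                {"phase": "ga", "generation": gen}, genomes_seen, config,
            )
        pop, fits, results = children, new_fits, new_results
        logger.debug(
            "generation %d: best %.4g, archived %d/%d",
            gen, fits.min(), len(archive), config.n_solutions,
        )
    if len(archive) < config.n_solutions:
        archive.complete = False
        warnings.warn(
            f"TPS collected only {len(archive)}/{config.n_solutions} "
            f"solutions in {gen} generations "
            f"({config.architecture.value})",
            stacklevel=2,
        )
    return archive


def run_tps(config: SearchConfig) -> SolutionArchive:
    """Full two-phase search: random seeding then GA harvest.

    Deterministic given ``config.seed``: the global seed is split into
    independent child streams for the random and the evolutionary phase.
    """
    ss_random, ss_ga = np.random.SeedSequence(config.seed).spawn(2)
    pool = random_phase(config, np.random.default_rng(ss_random))
    archive = ga_phase(pool, config, np.random.default_rng(ss_ga))
    archive.n_evaluations += config.random_phase_trials
    logger.info(
        "TPS (%s): archived %d solutions after %d evaluations",
        config.architecture.value, len(archive), archive.n_evaluations,
    )
    return archive
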