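"""Light-dark forcing and entrainment probability maps.

Light acts on the clock by accelerating degradation of the clock protein
X: during the light phase the maximum degradation rate D2 (and, where the
X:Y complex exists, the complex degradation rate D5) is multiplied by the
light factor delta; during darkness the rates take their free-running
values.  The neutral point is delta = NEUTRAL_LIGHT_FACTOR = 1 (no
modulation).  In the redundant model only the X loop is light-perturbed;
its Y loop runs free.

The light-dark (LD) cycle has total period zeta with light and dark
phases of equal length (duty 0.5) and lights-on at t = 0.  The square
wave is handled by integrating phase-by-phase with restarts at every
switch, so the integrator never steps across a discontinuity.

A parameter set is *entrained* at (zeta, delta) when, on the
post-transient forced trajectory, the cycle-to-cycle period deviation is
below 1%, the cycle amplitude deviation below 10%, and the mean period
matches the forcing period within 1%.  The entrainment probability at a
grid point is the exact fraction of archive parameter sets that entrain
there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import dynamics
from .models import (
    ClockModel,
    ConfigurationError,
    build_model,
    light_modulated_parameters,
)
from .search import SolutionArchive

__all__ = [
    "NEUTRAL_LIGHT_FACTOR",
    "LightSchedule",
    "EntrainmentMap",
    "forced_model",
    "integrate_forced",
    "is_entrained",
    "entrainment_map",
]

logger = logging.getLogger(__name__)

#: delta value at which light leaves the degradation rates unchanged.
NEUTRAL_LIGHT_FACTOR = 1.0

# Forced-run policy: number of forcing cycles integrated / discarded.
DEFAULT_FORCING_CYCLES = 80
DEFAULT_DISCARD_CYCLES = 40

PERIOD_DEV_MAX = 0.01       # cycle-to-cycle and lock tolerance (1%)
AMPLITUDE_DEV_MAX = 0.10    # cycle-to-cycle amplitude tolerance (10%)
#: nM; a forced response below this is a driven ripple of a quenched
#: (non-oscillatory) system, not an entrained circadian oscillation.
ENTRAINED_AMPLITUDE_MIN = 0.1


@dataclass(frozen=True)
class LightSchedule:
    """Square-wave LD cycle: period zeta (h), light factor delta,
    equal-length light and dark phases, lights-on at t = 0."""

    zeta: float
    delta: float
    duty: float = 0.5

    def __post_init__(self) -> None:
        if self.zeta <= 0:
            raise ConfigurationError("forcing period zeta must be positive")
        if self.delta <= 0:
            raise ConfigurationError(
                "light factor delta must be positive (degradation rates "
                "must stay positive)"
            )
        if self.duty != 0.5:
            raise ConfigurationError(
                "light and dark phases have equal length (duty = 0.5)"
            )


def forced_model(model: ClockModel, schedule: LightSchedule) -> ClockModel:
    """The light-phase variant of a model: light-modulated maximum
    degradation rates multiplied by delta.

    The dark-phase model is the free-running model itself; the forced
    system alternates the two parameterisations on the LD square wave.
    """
    updates = {
        name: model.params.values[name] * schedule.delta
        for name in light_modulated_parameters(model.architecture)
    }
    return model.with_params(model.params.replace(**updates))


def integrate_forced(
    model: ClockModel,
    schedule: LightSchedule,
    n_cycles: int = DEFAULT_FORCING_CYCLES,
    discard_cycles: int = DEFAULT_DISCARD_CYCLES,
    initial=None,
    dt: float = dynamics.DEFAULT_DT,
) -> Optional[dynamics.Trajectory]:
    """Integrate under the LD schedule, phase-by-phase.

    Returns a trajectory whose post-transient window starts after
    ``discard_cycles`` forcing cycles, or ``None`` on integration failure.
    """
    light = forced_model(model, schedule)
    kernel = model.rhs_kernel()
    p_dark = model.param_array()
    p_light = light.param_array()
    h = model.params.hill_coefficient
    half = 0.5 * schedule.zeta

    y = (
        dynamics.initial_state(model)
        if initial is None
        else np.asarray(initial, dtype=np.float64)
    )
    times = [np.array([0.0])]
    states = [y.reshape(-1, 1)]
    t0 = 0.0
    n_per_half = max(2, int(round(half / dt)))
    for seg in range(2 * n_cycles):
        p = p_light if seg % 2 == 0 else p_dark  # lights-on first
        t1 = t0 + half
        t_eval = np.linspace(t0, t1, n_per_half + 1)
        out = dynamics._odeint_lsoda(kernel, y, t_eval, (p, h))
        if out is None:
            return None
        times.append(t_eval[1:])
        states.append(out[:, 1:])
        y = out[:, -1].copy()
        t0 = t1
    t = np.concatenate(times)
    x = np.concatenate(states, axis=1)
    start = int(np.searchsorted(t, discard_cycles * schedule.zeta))
    return dynamics.Trajectory(t, x, start, model)


def is_entrained(
    model: ClockModel,
    schedule: LightSchedule,
    n_cycles: int = DEFAULT_FORCING_CYCLES,
    discard_cycles: int = DEFAULT_DISCARD_CYCLES,
) -> bool:
    """En: does this parameter set lock to the LD cycle?

    True iff the forced post-transient output has constant cycles (period
    deviation < 1%, amplitude deviation < 10%) whose mean period matches
    the forcing period zeta within 1%, and whose amplitude exceeds
    ``ENTRAINED_AMPLITUDE_MIN`` (excluding the driven ripple of systems
    whose own oscillation is quenched or absent).  Integration failure
    counts as not entrained.
    """
    traj = integrate_forced(
        model, schedule, n_cycles=n_cycles, discard_cycles=discard_cycles
    )
    feats = dynamics.oscillation_features(traj)
    if not feats.sustained:
        # `sustained` already enforces period CV < 1%; re-check amplitude
        # deviation at the entrainment threshold (10%) explicitly below.
        if (
            feats.period is None
            or feats.period_cv is None
            or feats.period_cv >= PERIOD_DEV_MAX
            or feats.amplitude_cv is None
            or feats.amplitude_cv >= AMPLITUDE_DEV_MAX
        ):
            return False
    if feats.period is None or feats.amplitude is None:
        return False
    if feats.amplitude < ENTRAINED_AMPLITUDE_MIN:
        return False
    return abs(feats.period - schedule.zeta) / schedule.zeta < PERIOD_DEV_MAX


@dataclass
class EntrainmentMap:
    """Entrainment probability on a zeta x delta grid.

    ``probability[i, j]`` is the exact fraction of the N archive sets that
    entrain at (zeta_grid[i], delta_grid[j]); ``entrained[k, i, j]`` keeps
    the per-set booleans for audit.
    """

    zeta_grid: np.ndarray
    delta_grid: np.ndarray
    probability: np.ndarray          # (n_zeta, n_delta)
    entrained: np.ndarray            # (N, n_zeta, n_delta) booleans
    n_sets: int

    def total_area(self) -> float:
        """Sum of probabilities over the grid (entrained-region size in
        grid-cell units)."""
        return float(self.probability.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: zeta, delta, probability, n_entrained, N."""
        rows = []
        for i, z in enumerate(self.zeta_grid):
            for j, d in enumerate(self.delta_grid):
                n_ent = int(self.entrained[:, i, j].sum())
                rows.append(
                    {
                        "zeta": float(z),
                        "delta": float(d),
                        "probability": float(self.probability[i, j]),
                        "n_entrained": n_ent,
                        "N": self.n_sets,
                    }
                )
        return pd.DataFrame(rows)


def entrainment_map(
    archive: SolutionArchive,
    zeta_grid,
    delta_grid,
    n_cycles: int = DEFAULT_FORCING_CYCLES,
    discard_cycles: int = DEFAULT_DISCARD_CYCLES,
) -> EntrainmentMap:
    """Entrainment probability of an archive on a zeta x delta grid."""
    if len(archive) == 0:
        raise ValueError("entrainment_map of an empty archive")
    zeta_grid = np.asarray(zeta_grid, dtype=float)
    delta_grid = np.asarray(delta_grid, dtype=float)
    n = len(archive)
    ent = np.zeros((n, zeta_grid.size, delta_grid.size), dtype=bool)
    for k, entry in enumerate(archive.entries):
        model = build_model(entry.params.architecture, entry.params)
        for i, z in enumerate(zeta_grid):
            for j, d in enumerate(delta_grid):
                ent[k, i, j] = is_entrained(
                    model,
                    LightSchedule(float(z), float(d)),
                    n_cycles=n_cycles,
                    discard_cycles=discard_cycles,
                )
        logger.debug("entrainment: set %d/%d classified", k + 1, n)
    prob = ent.sum(axis=0) / n
    return EntrainmentMap(zeta_grid, delta_grid, prob, ent, n)
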