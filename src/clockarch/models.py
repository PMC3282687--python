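"""Competing circadian feedback-loop architectures as ODE systems.

Four transcriptional-translational oscillator architectures are defined over
named species and named kinetic parameters:

* ``single`` -- one gene *X*; nuclear protein X(nuc) represses its own
  transcription (the classic single negative feedback loop, m=3 equations).
* ``semi_dual`` -- two genes; the X:Y heterodimer represses *X* while *Y* is
  transcribed constitutively (an open second loop, m=6).
* ``dual`` -- as ``semi_dual`` but X:Y(nuc) also represses *Y*, closing both
  loops through a shared protein complex (m=6).
* ``redundant`` -- two structurally identical, fully independent single
  loops whose nuclear proteins are summed at the output (m=6).

Every rate law is composed from four primitives: Hill-repressed (or
constitutive) transcription, first-order translation, mass-action complex
association/dissociation, Michaelis-Menten nuclear import/export, and
Michaelis-Menten plus first-order degradation.  Units are nM and hours
throughout.

Parameter symbols follow the field's conventional families with loop
suffixes: S (transcription maximum rates and translation rate constants,
alternating: S1=X transcription, S2=X translation, S3/S4 the Y
counterparts), K (transcription affinities), A/B (complex association /
dissociation), T/U (nuclear import / export: odd index = maximum rate,
even index = affinity), D (degradation: low indices = Michaelis-Menten
maximum rates per species in state order, high indices = first-order rate
constants per species), L (degradation affinities).  The Hill coefficient
``h`` is fixed at 4 and never searched.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from numba import njit

__all__ = [
    "HILL_COEFFICIENT",
    "Architecture",
    "ParameterSet",
    "ClockModel",
    "ConfigurationError",
    "build_model",
    "reference_parameters",
    "parameter_names",
    "y_loop_pairs",
    "y_loop_bounds",
]

#: Cooperativity exponent of transcriptional repression (dimensionless, fixed).
HILL_COEFFICIENT = 4.0


class ConfigurationError(ValueError):
    """A model or parameter-set was mis-specified (missing/invalid field)."""


class Architecture(enum.Enum):
    """Feedback-loop coupling logic of the clock network."""

    SINGLE = "single"
    SEMI_DUAL = "semi_dual"
    DUAL = "dual"
    REDUNDANT = "redundant"

    @property
    def n_equations(self) -> int:
        """Number of ODEs (state species), m."""
        return 3 if self is Architecture.SINGLE else 6

    @classmethod
    def from_name(cls, name: "str | Architecture") -> "Architecture":
        if isinstance(name, Architecture):
            return name
        try:
            return cls(str(name).lower().replace("-", "_"))
        except ValueError:
            raise ConfigurationError(
                f"unknown architecture {name!r}; expected one of "
                f"{[a.value for a in cls]}"
            ) from None


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------
# Canonical parameter order per architecture.  X-loop parameters come first
# within each family, then the Y-loop counterparts, so the Y-loop symmetry
# constraint is a pure index renaming:
#   dual       Y loop: S3,S4; K2; D3,D4 (MM), D9,D10 (linear); L3,L4
#   redundant  Y loop: S3,S4; K2; T3,T4; U3,U4; D4,D5,D6 (MM),
#              D10,D11,D12 (linear); L4,L5,L6
# D-family layout: D1..Dm are Michaelis-Menten maximum degradation rates for
# the species in state order; D(m+1)..D(2m) are the first-order degradation
# rate constants for the same species (reference 0.01 / h).

_PARAM_NAMES: dict[Architecture, tuple[str, ...]] = {
    Architecture.SINGLE: (
        "S1", "S2", "K1", "T1", "T2", "U1", "U2",
        "D1", "D2", "D3", "D4", "D5", "D6",
        "L1", "L2", "L3",
    ),
    Architecture.SEMI_DUAL: (
        # constitutive Y transcription: no K2
        "S1", "S2", "S3", "S4", "K1", "A", "B", "T1", "T2", "U1", "U2",
        "D1", "D2", "D3", "D4", "D5", "D6",
        "D7", "D8", "D9", "D10", "D11", "D12",
        "L1", "L2", "L3", "L4", "L5", "L6",
    ),
    Architecture.DUAL: (
        "S1", "S2", "S3", "S4", "K1", "K2", "A", "B", "T1", "T2", "U1", "U2",
        "D1", "D2", "D3", "D4", "D5", "D6",
        "D7", "D8", "D9", "D10", "D11", "D12",
        "L1", "L2", "L3", "L4", "L5", "L6",
    ),
    Architecture.REDUNDANT: (
        "S1", "S2", "S3", "S4", "K1", "K2",
        "T1", "T2", "T3", "T4", "U1", "U2", "U3", "U4",
        "D1", "D2", "D3", "D4", "D5", "D6",
        "D7", "D8", "D9", "D10", "D11", "D12",
        "L1", "L2", "L3", "L4", "L5", "L6",
    ),
}

_LINEAR_DEGRADATION: dict[Architecture, frozenset[str]] = {
    Architecture.SINGLE: frozenset({"D4", "D5", "D6"}),
    Architecture.SEMI_DUAL: frozenset({f"D{i}" for i in range(7, 13)}),
    Architecture.DUAL: frozenset({f"D{i}" for i in range(7, 13)}),
    Architecture.REDUNDANT: frozenset({f"D{i}" for i in range(7, 13)}),
}

#: Reference value of every first-order degradation rate constant (1/h).
LINEAR_DEGRADATION_REFERENCE = 0.01

_SPECIES_NAMES: dict[Architecture, tuple[str, ...]] = {
    Architecture.SINGLE: ("mRNA(X)", "X", "X(nuc)"),
    Architecture.SEMI_DUAL: ("mRNA(X)", "X", "mRNA(Y)", "Y", "X:Y", "X:Y(nuc)"),
    Architecture.DUAL: ("mRNA(X)", "X", "mRNA(Y)", "Y", "X:Y", "X:Y(nuc)"),
    Architecture.REDUNDANT: ("mRNA(X)", "X", "X(nuc)", "mRNA(Y)", "Y", "Y(nuc)"),
}

# Clock output: nuclear repressor abundance (a sum of species indices).
_OUTPUT_INDICES: dict[Architecture, tuple[int, ...]] = {
    Architecture.SINGLE: (2,),          # X(nuc)
    Architecture.SEMI_DUAL: (5,),       # X:Y(nuc)
    Architecture.DUAL: (5,),            # X:Y(nuc)
    Architecture.REDUNDANT: (2, 5),     # X(nuc) + Y(nuc)
}

# Y-loop parameter -> X-loop counterpart, for the kinetic-symmetry (rho)
# constraint of the two symmetric architectures.
_Y_LOOP_PAIRS: dict[Architecture, dict[str, str]] = {
    Architecture.DUAL: {
        "S3": "S1", "S4": "S2", "K2": "K1",
        "D3": "D1", "D4": "D2", "D9": "D7", "D10": "D8",
        "L3": "L1", "L4": "L2",
    },
    Architecture.REDUNDANT: {
        "S3": "S1", "S4": "S2", "K2": "K1",
        "T3": "T1", "T4": "T2", "U3": "U1", "U4": "U2",
        "D4": "D1", "D5": "D2", "D6": "D3",
        "D10": "D7", "D11": "D8", "D12": "D9",
        "L4": "L1", "L5": "L2", "L6": "L3",
    },
}

# Index of the light-modulated maximum degradation rates within each
# architecture's canonical parameter order: D2 (clock protein X) always, plus
# D5 (the cytoplasmic X:Y complex) where the complex exists.  The Y loop of
# the redundant model is never light-perturbed.
_LIGHT_MODULATED: dict[Architecture, tuple[str, ...]] = {
    Architecture.SINGLE: ("D2",),
    Architecture.SEMI_DUAL: ("D2", "D5"),
    Architecture.DUAL: ("D2", "D5"),
    Architecture.REDUNDANT: ("D2",),
}


def parameter_names(architecture: "str | Architecture") -> tuple[str, ...]:
    """Canonical ordered tuple of searched kinetic-parameter names."""
    return _PARAM_NAMES[Architecture.from_name(architecture)]


def y_loop_pairs(architecture: "str | Architecture") -> dict[str, str]:
    """Mapping Y-loop parameter -> X-loop counterpart (empty if no rho)."""
    return dict(_Y_LOOP_PAIRS.get(Architecture.from_name(architecture), {}))


def light_modulated_parameters(architecture: "str | Architecture") -> tuple[str, ...]:
    """Degradation maximum rates multiplied by the light factor delta."""
    return _LIGHT_MODULATED[Architecture.from_name(architecture)]


# ---------------------------------------------------------------------------
# ParameterSet
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterSet:
    """Named kinetic parameters of one architecture.

    ``values`` maps every searched parameter symbol to a strictly positive
    float; the Hill coefficient is carried separately and is never part of
    the searched set.
    """

    architecture: Architecture
    values: Mapping[str, float]
    hill_coefficient: float = HILL_COEFFICIENT

    def __post_init__(self) -> None:
        names = _PARAM_NAMES[self.architecture]
        missing = [n for n in names if n not in self.values]
        if missing:
            raise ConfigurationError(
                f"{self.architecture.value} parameter set is missing "
                f"field(s): {', '.join(missing)}"
            )
        extra = set(self.values) - set(names)
        if extra:
            raise ConfigurationError(
                f"unknown parameter field(s) for {self.architecture.value}: "
                f"{', '.join(sorted(extra))}"
            )
        for n in names:
            v = float(self.values[n])
            if not np.isfinite(v) or v <= 0.0:
                raise ConfigurationError(
                    f"parameter {n} must be strictly positive, got {v!r}"
                )

    @property
    def names(self) -> tuple[str, ...]:
        return _PARAM_NAMES[self.architecture]

    def as_array(self) -> np.ndarray:
        """Values in canonical order, as a contiguous float64 vector."""
        return np.array([self.values[n] for n in self.names], dtype=np.float64)

    @classmethod
    def from_array(
        cls, architecture: "str | Architecture", vector: Sequence[float]
    ) -> "ParameterSet":
        arch = Architecture.from_name(architecture)
        names = _PARAM_NAMES[arch]
        vector = np.asarray(vector, dtype=np.float64)
        if vector.shape != (len(names),):
            raise ConfigurationError(
                f"{arch.value} expects {len(names)} parameters, "
                f"got shape {vector.shape}"
            )
        return cls(arch, dict(zip(names, vector.tolist())))

    def replace(self, **updates: float) -> "ParameterSet":
        vals = dict(self.values)
        vals.update(updates)
        return ParameterSet(self.architecture, vals, self.hill_coefficient)

    def to_dict(self) -> dict[str, float]:
        """Flat key=value mapping (including the fixed ``h``)."""
        out = {n: float(self.values[n]) for n in self.names}
        out["h"] = float(self.hill_coefficient)
        return out


def reference_parameters(architecture: "str | Architecture") -> ParameterSet:
    """Reference parameter set: every rate/affinity constant 1.0 in its
    stated unit, first-order degradation rate constants 0.01 /h, h = 4."""
    arch = Architecture.from_name(architecture)
    linear = _LINEAR_DEGRADATION[arch]
    values = {
        n: (LINEAR_DEGRADATION_REFERENCE if n in linear else 1.0)
        for n in _PARAM_NAMES[arch]
    }
    return ParameterSet(arch, values)


# ---------------------------------------------------------------------------
# Rate-law primitives (shared by all architectures; inlined by numba)
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _hill_repression(vmax, K, repressor, h):
    """Transcription rate repressed by ``repressor`` with cooperativity h."""
    Kh = K ** h
    return vmax * Kh / (Kh + repressor ** h)


@njit(cache=True, inline="always")
def _michaelis(vmax, Km, s):
    """Saturable (Michaelis-Menten) rate; vanishes at zero substrate."""
    return vmax * s / (Km + s)


@njit(cache=True, inline="always")
def _degradation(vmax, Km, k_lin, s):
    """Michaelis-Menten plus first-order removal of species ``s``."""
    return vmax * s / (Km + s) + k_lin * s


# ---------------------------------------------------------------------------
# Right-hand sides.  Parameter vectors are in the canonical order above.
# ---------------------------------------------------------------------------


@njit(cache=True)
def _rhs_single(t, x, p, h):
    # p: S1,S2,K1,T1,T2,U1,U2,D1,D2,D3,D4,D5,D6,L1,L2,L3
    M, C, N = x[0], x[1], x[2]
    imp = _michaelis(p[3], p[4], C)
    exp_ = _michaelis(p[5], p[6], N)
    d = np.empty(3)
    d[0] = _hill_repression(p[0], p[2], N, h) - _degradation(p[7], p[13], p[10], M)
    d[1] = p[1] * M - imp + exp_ - _degradation(p[8], p[14], p[11], C)
    d[2] = imp - exp_ - _degradation(p[9], p[15], p[12], N)
    return d


@njit(cache=True)
def _rhs_semi_dual(t, x, p, h):
    # p: S1,S2,S3,S4,K1,A,B,T1,T2,U1,U2,D1..D6,D7..D12,L1..L6
    Mx, Cx, My, Cy, Z, Zn = x[0], x[1], x[2], x[3], x[4], x[5]
    assoc = p[5] * Cx * Cy
    dissoc = p[6] * Z
    imp = _michaelis(p[7], p[8], Z)
    exp_ = _michaelis(p[9], p[10], Zn)
    d = np.empty(6)
    d[0] = _hill_repression(p[0], p[4], Zn, h) - _degradation(p[11], p[23], p[17], Mx)
    d[1] = p[1] * Mx - assoc + dissoc - _degradation(p[12], p[24], p[18], Cx)
    d[2] = p[2] - _degradation(p[13], p[25], p[19], My)  # constitutive Y
    d[3] = p[3] * My - assoc + dissoc - _degradation(p[14], p[26], p[20], Cy)
    d[4] = assoc - dissoc - imp + exp_ - _degradation(p[15], p[27], p[21], Z)
    d[5] = imp - exp_ - _degradation(p[16], p[28], p[22], Zn)
    return d


@njit(cache=True)
def _rhs_dual(t, x, p, h):
    # p: S1,S2,S3,S4,K1,K2,A,B,T1,T2,U1,U2,D1..D6,D7..D12,L1..L6
    # Differs from semi_dual only in equation 3: Y transcription is
    # Hill-repressed by X:Y(nuc) instead of constitutive.
    Mx, Cx, My, Cy, Z, Zn = x[0], x[1], x[2], x[3], x[4], x[5]
    assoc = p[6] * Cx * Cy
    dissoc = p[7] * Z
    imp = _michaelis(p[8], p[9], Z)
    exp_ = _michaelis(p[10], p[11], Zn)
    d = np.empty(6)
    d[0] = _hill_repression(p[0], p[4], Zn, h) - _degradation(p[12], p[24], p[18], Mx)
    d[1] = p[1] * Mx - assoc + dissoc - _degradation(p[13], p[25], p[19], Cx)
    d[2] = _hill_repression(p[2], p[5], Zn, h) - _degradation(p[14], p[26], p[20], My)
    d[3] = p[3] * My - assoc + dissoc - _degradation(p[15], p[27], p[21], Cy)
    d[4] = assoc - dissoc - imp + exp_ - _degradation(p[16], p[28], p[22], Z)
    d[5] = imp - exp_ - _degradation(p[17], p[29], p[23], Zn)
    return d


@njit(cache=True)
def _rhs_redundant(t, x, p, h):
    # p: S1,S2,S3,S4,K1,K2,T1,T2,T3,T4,U1,U2,U3,U4,D1..D6,D7..D12,L1..L6
    # Two fully independent single loops; coupling exists only at the output.
    Mx, Cx, Nx, My, Cy, Ny = x[0], x[1], x[2], x[3], x[4], x[5]
    imp_x = _michaelis(p[6], p[7], Cx)
    exp_x = _michaelis(p[10], p[11], Nx)
    imp_y = _michaelis(p[8], p[9], Cy)
    exp_y = _michaelis(p[12], p[13], Ny)
    d = np.empty(6)
    d[0] = _hill_repression(p[0], p[4], Nx, h) - _degradation(p[14], p[26], p[20], Mx)
    d[1] = p[1] * Mx - imp_x + exp_x - _degradation(p[15], p[27], p[21], Cx)
    d[2] = imp_x - exp_x - _degradation(p[16], p[28], p[22], Nx)
    d[3] = _hill_repression(p[2], p[5], Ny, h) - _degradation(p[17], p[29], p[23], My)
    d[4] = p[3] * My - imp_y + exp_y - _degradation(p[18], p[30], p[24], Cy)
    d[5] = imp_y - exp_y - _degradation(p[19], p[31], p[25], Ny)
    return d


_RHS: dict[Architecture, Callable] = {
    Architecture.SINGLE: _rhs_single,
    Architecture.SEMI_DUAL: _rhs_semi_dual,
    Architecture.DUAL: _rhs_dual,
    Architecture.REDUNDANT: _rhs_redundant,
}


# ---------------------------------------------------------------------------
# ClockModel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClockModel:
    """An architecture bound to a concrete parameter vector.

    ``rhs(t, x)`` evaluates the state derivative; the clock output is the
    sum of the species at ``output_indices``.
    """

    architecture: Architecture
    params: ParameterSet
    species_names: tuple[str, ...] = field(init=False)
    output_indices: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "species_names", _SPECIES_NAMES[self.architecture]
        )
        object.__setattr__(
            self, "output_indices", _OUTPUT_INDICES[self.architecture]
        )

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    def param_array(self) -> np.ndarray:
        return self.params.as_array()

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        return _RHS[self.architecture](t, x, self.param_array(), self.params.hill_coefficient)

    def rhs_kernel(self) -> Callable:
        """The compiled ``f(t, x, p, h)`` kernel (for integrators)."""
        return _RHS[self.architecture]

    def output(self, states: np.ndarray) -> np.ndarray:
        """Clock output signal from a (n_species, n_times) state array."""
        return np.asarray(states)[list(self.output_indices), :].sum(axis=0)

    def with_params(self, params: ParameterSet) -> "ClockModel":
        return ClockModel(self.architecture, params)


def build_model(
    architecture: "str | Architecture", params: ParameterSet
) -> ClockModel:
    """Bind an architecture to a parameter set, validating the fields."""
    arch = Architecture.from_name(architecture)
    if params.architecture is not arch:
        raise ConfigurationError(
            f"parameter set is for {params.architecture.value!r}, "
            f"not {arch.value!r}"
        )
    return ClockModel(arch, params)


# ---------------------------------------------------------------------------
# Kinetic-symmetry (rho) constrained search intervals
# ---------------------------------------------------------------------------

#: rho at or above this value leaves the Y loop unconstrained.
RHO_UNCONSTRAINED = 99.0


def y_loop_bounds(
    x_value: float,
    rho: float,
    global_bounds: tuple[float, float],
) -> tuple[float, float]:
    """Search interval for a Y-loop parameter given its X-loop counterpart.

    The interval is the multiplicative band
    ``[x/(1+rho), x*(1+rho)]`` intersected with ``global_bounds``: it
    collapses to the point ``{x}`` at rho=0 (perfect kinetic symmetry),
    widens monotonically with rho, and equals the global bounds for
    rho >= 99 (independent loops).
    """
    lo, hi = float(global_bounds[0]), float(global_bounds[1])
    x = float(x_value)
    if rho < 0:
        raise ConfigurationError(f"rho must be non-negative, got {rho}")
    if not (lo <= x <= hi):
        raise ConfigurationError(
            f"x_value {x} outside global bounds [{lo}, {hi}]"
        )
    if rho >= RHO_UNCONSTRAINED:
        return (lo, hi)
    band = 1.0 + float(rho)
    return (max(lo, x / band), min(hi, x * band))
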