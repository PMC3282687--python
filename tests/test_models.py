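"""Architecture definitions, reference parameters and symmetry bounds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import clockarch as ca
from clockarch.models import (
    LINEAR_DEGRADATION_REFERENCE,
    _LINEAR_DEGRADATION,
    Architecture,
    ConfigurationError,
)

ARCHES = ["single", "semi_dual", "dual", "redundant"]


@pytest.mark.parametrize(
    "arch,m", [("single", 3), ("semi_dual", 6), ("dual", 6), ("redundant", 6)]
)
def test_equation_counts(arch, m):
    a = Architecture.from_name(arch)
    assert a.n_equations == m
    model = ca.build_model(a, ca.reference_parameters(a))
    assert model.n_species == m
    assert len(model.rhs(0.0, np.full(m, 0.5))) == m


@pytest.mark.parametrize("arch", ARCHES)
def test_reference_values(arch):
    ref = ca.reference_parameters(arch)
    linear = _LINEAR_DEGRADATION[Architecture.from_name(arch)]
    for name, value in ref.values.items():
        expected = LINEAR_DEGRADATION_REFERENCE if name in linear else 1.0
        assert value == expected
    assert ref.hill_coefficient == 4.0


def test_transcription_rate_at_zero_state():
    """With no repressor and no substrate, only transcription fires:
    d[mRNA(X)]/dt equals the maximum transcription rate S1 = 1 nM/h."""
    model = ca.build_model("single", ca.reference_parameters("single"))
    d = model.rhs(0.0, np.zeros(3))
    assert d[0] == pytest.approx(1.0)
    assert d[1] == 0.0 and d[2] == 0.0


def test_missing_parameter_named_in_error():
    ref = ca.reference_parameters("dual")
    values = dict(ref.values)
    values.pop("K2")
    with pytest.raises(ConfigurationError, match="K2"):
        ca.ParameterSet(Architecture.DUAL, values)


def test_unknown_architecture_rejected():
    with pytest.raises(ConfigurationError, match="unknown architecture"):
        Architecture.from_name("triple")


def test_nonpositive_parameter_rejected():
    ref = ca.reference_parameters("single")
    with pytest.raises(ConfigurationError, match="S1"):
        ref.replace(S1=0.0)


def test_semi_dual_and_dual_differ_only_in_y_transcription():
    """All equations except the Y-mRNA equation (no. 3) coincide."""
    semi = ca.reference_parameters("semi_dual")
    dual_vals = dict(semi.values)
    dual_vals["K2"] = 1.0
    dual = ca.ParameterSet(Architecture.DUAL, dual_vals)
    m_semi = ca.build_model("semi_dual", semi)
    m_dual = ca.build_model("dual", dual)
    rng = np.random.default_rng(0)
    for _ in range(20):
        x = rng.uniform(0.0, 5.0, 6)
        ds = m_semi.rhs(0.0, x)
        dd = m_dual.rhs(0.0, x)
        same = np.delete(np.arange(6), 2)
        np.testing.assert_allclose(ds[same], dd[same], rtol=1e-12)
        # constitutive vs Hill-repressed Y transcription differ whenever
        # the nuclear complex is present
        if x[5] > 0:
            assert ds[2] != dd[2]


def test_dual_rho0_structural_symmetry():
    """With identical X/Y-loop parameters, swapping the loop states swaps
    the derivative vector."""
    dual = ca.reference_parameters("dual")
    model = ca.build_model("dual", dual)
    rng = np.random.default_rng(1)
    swap = [2, 3, 0, 1, 4, 5]  # (mRNA(X),X) <-> (mRNA(Y),Y)
    for _ in range(20):
        x = rng.uniform(0.0, 5.0, 6)
        np.testing.assert_allclose(
            model.rhs(0.0, x)[swap], model.rhs(0.0, x[swap]), rtol=1e-12
        )


@pytest.mark.parametrize("arch", ARCHES)
def test_derivatives_finite_for_positive_states(arch):
    model = ca.build_model(arch, ca.reference_parameters(arch))
    rng = np.random.default_rng(2)
    for _ in range(50):
        x = 10.0 ** rng.uniform(-6, 3, model.n_species)
        assert np.all(np.isfinite(model.rhs(0.0, x)))


@pytest.mark.parametrize("arch", ARCHES)
def test_state_nonnegativity(arch):
    """All removal terms vanish at zero substrate, so trajectories stay
    non-negative (up to integrator tolerance) from non-negative starts."""
    model = ca.build_model(arch, ca.reference_parameters(arch))
    traj = ca.integrate(model, horizon=300.0, transient=0.0)
    assert traj is not None
    assert traj.states.min() > -1e-7


def test_dual_symmetric_trajectories_coincide(study_archives):
    """rho=0 dual solutions: X-loop and Y-loop trajectories identical."""
    entry = study_archives["dual_rho0"].entries[0]
    model = ca.build_model("dual", entry.params)
    traj = ca.integrate(model)
    # symmetric initial state: mRNA(X)=mRNA(Y), X=Y holds for the default
    np.testing.assert_allclose(
        traj.states[0], traj.states[2], atol=1e-6
    )
    np.testing.assert_allclose(
        traj.states[1], traj.states[3], atol=1e-6
    )


def test_degenerate_redundant_matches_single():
    """Silencing the Y loop turns the redundant model into a virtual
    single feedback model: the X-loop trajectory matches the single
    model's pointwise."""
    rng = np.random.default_rng(3)
    single_ref = ca.reference_parameters("single")
    sp = {
        n: v * 10.0 ** rng.uniform(-0.3, 0.3)
        for n, v in single_ref.values.items()
    }
    single = ca.ParameterSet(Architecture.SINGLE, sp)
    red_vals = dict(ca.reference_parameters("redundant").values)
    # X loop of the redundant model <- single-model parameters
    mapping = {
        "S1": "S1", "S2": "S2", "K1": "K1", "T1": "T1", "T2": "T2",
        "U1": "U1", "U2": "U2", "D1": "D1", "D2": "D2", "D3": "D3",
        "D7": "D4", "D8": "D5", "D9": "D6", "L1": "L1", "L2": "L2",
        "L3": "L3",
    }
    for red_key, single_key in mapping.items():
        red_vals[red_key] = sp[single_key]
    red_vals["S3"] = 1e-9  # Y transcription silenced
    red = ca.ParameterSet(Architecture.REDUNDANT, red_vals)
    t_single = ca.integrate(
        ca.build_model("single", single), horizon=400.0, transient=200.0
    )
    t_red = ca.integrate(
        ca.build_model("redundant", red), horizon=400.0, transient=200.0
    )
    np.testing.assert_allclose(
        t_red.states[:3], t_single.states, atol=1e-5
    )
    # Y species decay from the initial 0.1 nM to effectively nothing
    assert t_red.post_states[3:].max() < 2e-3


# ---------------------------------------------------------------------------
# Kinetic-symmetry search intervals
# ---------------------------------------------------------------------------


def test_y_loop_bounds_examples():
    assert ca.y_loop_bounds(2.0, 0.0, (0.1, 10.0)) == (2.0, 2.0)
    assert ca.y_loop_bounds(2.0, 99.0, (0.1, 10.0)) == (0.1, 10.0)
    lo, hi = ca.y_loop_bounds(2.0, 1.0, (0.1, 10.0))
    assert (lo, hi) == (1.0, 4.0)  # multiplicative band x/(1+rho)..x(1+rho)
    assert lo < 2.0 < hi


def test_y_loop_bounds_rejects_x_outside_global():
    with pytest.raises(ConfigurationError):
        ca.y_loop_bounds(20.0, 1.0, (0.1, 10.0))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    x=st.floats(0.1, 10.0),
    rho1=st.floats(0.0, 200.0),
    rho2=st.floats(0.0, 200.0),
)
def test_y_loop_bounds_properties(x, rho1, rho2):
    """Interval contains x, sits inside the global bounds, and its width
    is non-decreasing in rho."""
    g = (0.1, 10.0)
    lo, hi = ca.y_loop_bounds(x, rho1, g)
    assert g[0] <= lo <= x <= hi <= g[1]
    r_small, r_big = sorted((rho1, rho2))
    w_small = np.subtract(*ca.y_loop_bounds(x, r_small, g)[::-1])
    w_big = np.subtract(*ca.y_loop_bounds(x, r_big, g)[::-1])
    assert w_big >= w_small - 1e-12


def test_parameter_roundtrip_array():
    ref = ca.reference_parameters("redundant")
    again = ca.ParameterSet.from_array("redundant", ref.as_array())
    assert again.values == dict(ref.values)
    d = ref.to_dict()
    assert d["h"] == 4.0 and "h" not in ref.names
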