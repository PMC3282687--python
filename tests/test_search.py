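"""Two-phase search: fitness contract, constraints, reproducibility."""

import numpy as np
import pytest

import clockarch as ca
from clockarch.dynamics import OscillationFeatures
from clockarch.search import (
    NONOSCILLATORY_PENALTY,
    SearchError,
    _loop_indices,
    _sample_genomes,
    random_phase,
)
from clockarch.models import y_loop_pairs


def _feats(period, amplitude, sustained=True):
    return OscillationFeatures(
        sustained=sustained, period=period, amplitude=amplitude,
        period_cv=0.001, amplitude_cv=0.01, n_peaks=20,
    )


def _cfg(**kw):
    return ca.SearchConfig(architecture=kw.pop("architecture", "single"), **kw)


class TestFitness:
    def test_zero_iff_inside_windows(self):
        cfg = _cfg()
        assert ca.fitness(_feats(24.0, 4.0), cfg) == 0.0
        assert ca.fitness(_feats(23.0, 2.0), cfg) == 0.0
        assert ca.fitness(_feats(25.0, 6.0), cfg) == 0.0
        assert ca.fitness(_feats(22.9, 4.0), cfg) > 0.0
        assert ca.fitness(_feats(24.0, 6.1), cfg) > 0.0

    def test_non_oscillatory_maximal_tier(self):
        cfg = _cfg()
        assert (
            ca.fitness(_feats(None, None, sustained=False), cfg)
            == NONOSCILLATORY_PENALTY
        )

    def test_monotone_in_distance_to_window(self):
        cfg = _cfg()
        assert ca.fitness(_feats(26.0, 4.0), cfg) < ca.fitness(
            _feats(30.0, 4.0), cfg
        )
        assert ca.fitness(_feats(24.0, 1.5), cfg) < ca.fitness(
            _feats(24.0, 0.5), cfg
        )

    def test_stratum_term(self):
        cfg = _cfg(
            architecture="semi_dual", y_level_constraint=(200.0, np.inf)
        )
        f_in = ca.fitness(_feats(24.0, 4.0), cfg, total_y=300.0)
        f_out = ca.fitness(_feats(24.0, 4.0), cfg, total_y=50.0)
        f_far = ca.fitness(_feats(24.0, 4.0), cfg, total_y=5.0)
        assert f_in == 0.0
        assert 0.0 < f_out < f_far


class TestConfigValidation:
    def test_rho_only_for_symmetric_models(self):
        with pytest.raises(ValueError):
            _cfg(rho=1.0)  # single
        with pytest.raises(ValueError):
            ca.SearchConfig(architecture="semi_dual", rho=0.0)

    def test_stratum_only_for_semi_dual(self):
        with pytest.raises(ValueError):
            _cfg(y_level_constraint=(0.0, 10.0))

    def test_default_bounds_are_tenfold(self):
        assert _cfg().fold_range == (0.1, 10.0)


class TestSampling:
    def test_rho0_samples_have_equal_loops(self):
        cfg = ca.SearchConfig(architecture="dual", rho=0.0, seed=3)
        y_idx, x_idx = _loop_indices(cfg.architecture)
        g = _sample_genomes(200, cfg, np.random.default_rng(0), y_idx, x_idx)
        np.testing.assert_allclose(g[:, y_idx], g[:, x_idx], atol=1e-12)

    def test_rho_band_respected(self):
        rho = 0.5
        cfg = ca.SearchConfig(architecture="redundant", rho=rho, seed=3)
        y_idx, x_idx = _loop_indices(cfg.architecture)
        g = _sample_genomes(500, cfg, np.random.default_rng(0), y_idx, x_idx)
        w = np.log10(1.0 + rho)
        assert np.all(np.abs(g[:, y_idx] - g[:, x_idx]) <= w + 1e-12)
        assert np.all((g >= -1.0) & (g <= 1.0))

    def test_random_phase_reproducible(self):
        cfg = ca.SearchConfig(
            architecture="single", random_phase_trials=200,
            population_size=10, seed=7,
        )
        p1 = random_phase(cfg)
        p2 = random_phase(cfg)
        np.testing.assert_array_equal(p1.genomes, p2.genomes)
        np.testing.assert_array_equal(p1.fitnesses, p2.fitnesses)

    def test_different_seeds_sample_different_candidates(self):
        cfg = ca.SearchConfig(architecture="single", seed=0)
        y_idx, x_idx = _loop_indices(cfg.architecture)
        g1 = _sample_genomes(50, cfg, np.random.default_rng(7), y_idx, x_idx)
        g2 = _sample_genomes(50, cfg, np.random.default_rng(8), y_idx, x_idx)
        assert np.abs(g1 - g2).max() > 0.1

    def test_random_phase_exhaustion_is_explicit(self):
        # a 2-trial budget cannot find an oscillator
        cfg = ca.SearchConfig(
            architecture="single", random_phase_trials=2, seed=0
        )
        with pytest.raises(SearchError, match="exhausted"):
            random_phase(cfg)


class TestArchives:
    def test_all_entries_satisfy_windows(self, study_archives):
        for label, arc in study_archives.items():
            lo, hi = arc.config.period_window
            alo, ahi = arc.config.amplitude_window
            for e in arc.entries:
                assert e.features.sustained, label
                assert lo <= e.features.period <= hi, label
                assert alo <= e.features.amplitude <= ahi, label

    def test_entries_pairwise_distinct(self, study_archives):
        arc = study_archives["single"]
        genomes = [
            np.log10(e.params.as_array()) for e in arc.entries
        ]
        for i in range(len(genomes)):
            for j in range(i + 1, len(genomes)):
                assert (
                    np.max(np.abs(genomes[i] - genomes[j]))
                    >= arc.config.min_distance - 1e-12
                )

    def test_y_loop_constraint_closure(self, study_archives):
        """Archived Y-loop values lie in the rho band of their X-loop
        counterparts."""
        for label in ("dual_rho0.1", "redundant_rho0.1", "dual_rho0"):
            arc = study_archives[label]
            rho = arc.config.rho
            pairs = y_loop_pairs(arc.config.architecture)
            for e in arc.entries:
                for y_name, x_name in pairs.items():
                    ratio = e.params.values[y_name] / e.params.values[x_name]
                    assert (
                        1.0 / (1.0 + rho) - 1e-9
                        <= ratio
                        <= (1.0 + rho) + 1e-9
                    ), (label, y_name)

    def test_semi_dual_stratum_enforced(self, study_archives):
        assert all(
            e.total_y > 200.0
            for e in study_archives["semi_dual_hi"].entries
        )
        assert all(
            e.total_y < 10.0
            for e in study_archives["semi_dual_lo"].entries
        )
        assert all(
            10.0 <= e.total_y <= 200.0
            for e in study_archives["semi_dual_mid"].entries
        )

    def test_entries_reproduce_on_resimulation(self, study_archives):
        """Round trip: stored parameters re-simulated from scratch yield
        sustained oscillation inside the windows."""
        for label in ("single", "dual_rho0"):
            arc = study_archives[label]
            for e in arc.entries[:3]:
                model = ca.build_model(arc.config.architecture, e.params)
                f = ca.oscillation_features(ca.integrate(model))
                assert f.sustained
                assert f.period == pytest.approx(e.features.period, rel=1e-6)
                assert f.amplitude == pytest.approx(
                    e.features.amplitude, rel=1e-6
                )

    def test_rho0_dual_archives_have_symmetric_parameters(
        self, study_archives
    ):
        pairs = y_loop_pairs("dual")
        for e in study_archives["dual_rho0"].entries:
            for y_name, x_name in pairs.items():
                assert e.params.values[y_name] == pytest.approx(
                    e.params.values[x_name], rel=1e-12
                )
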