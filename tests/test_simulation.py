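"""Integrator contracts: closed forms, protocols, observables, conservation."""

import numpy as np
import pytest

from aktnfkb.network import compile_network, conserved_pools
from aktnfkb.simulate import (
    InputProtocol,
    SolverSettings,
    constant_protocol,
    default_grid,
    observable,
    simulate,
    washout_protocol,
)
from aktnfkb.synth import toy_networks


class TestProtocols:
    def test_washout_segments(self):
        p = washout_protocol(10.0, 5.0, 10.0)
        assert p.segments == ((0.0, 5.0, 10.0), (5.0, 10.0, 0.0))
        assert p.washout_time() == 5.0

    def test_all_zero_protocol_is_valid(self):
        p = washout_protocol(0.0, 1.0, 2.0)
        assert p.level_at(0.5) == 0.0
        assert p.washout_time() is None

    @pytest.mark.parametrize("t_off, t_end", [(2.0, 2.0), (3.0, 2.0), (0.0, 2.0)])
    def test_bad_washout_ordering_rejected(self, t_off, t_end):
        with pytest.raises(ValueError):
            washout_protocol(10.0, t_off, t_end)

    def test_non_contiguous_segments_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            InputProtocol(segments=((0.0, 1.0, 5.0), (2.0, 3.0, 0.0)))

    def test_default_grid_minute_resolution(self):
        grid = default_grid(constant_protocol(10.0, 10.0))
        assert grid.size == 601
        assert grid[1] - grid[0] == pytest.approx(1.0 / 60.0)


class TestClosedForms:
    def test_exponential_decay(self):
        toy = toy_networks()["decay"]
        m = compile_network(toy.network)
        grid = np.array([0.0, 0.5, 1.0, 2.0, 10.0])
        traj = simulate(m, constant_protocol(0.0, 10.0), t_grid=grid)
        np.testing.assert_allclose(traj.col("A"), toy.analytic(grid)["A"], atol=1e-6)

    def test_isomerization_equilibrium_and_transient(self):
        toy = toy_networks()["iso"]
        m = compile_network(toy.network)
        grid = np.linspace(0, 10, 51)
        traj = simulate(m, constant_protocol(0.0, 10.0), t_grid=grid)
        sol = toy.analytic(grid)
        np.testing.assert_allclose(traj.col("A"), sol["A"], atol=1e-6)
        np.testing.assert_allclose(traj.col("B"), sol["B"], atol=1e-6)
        # equilibrium ratio B/A = kf/kb = 2
        assert traj.col("B")[-1] / traj.col("A")[-1] == pytest.approx(2.0, rel=1e-4)

    def test_mm_substrate_depletion_implicit_relation(self):
        toy = toy_networks()["mm_depletion"]
        m = compile_network(toy.network)
        grid = np.array([0.0, 0.5, 1.0, 2.0])
        tight = SolverSettings(rel_tol=1e-10, abs_tol=1e-12)
        traj = simulate(m, constant_protocol(0.0, 2.0), tight, grid)
        np.testing.assert_allclose(traj.col("S"), toy.analytic(grid)["S"], atol=1e-6)


class TestSolverProperties:
    def test_segment_restart_equals_single_segment(self, baseline_model):
        # run both at tight tolerance so that the restart itself, not the
        # integration error, dominates the comparison
        grid = np.linspace(0, 10, 201)
        split = InputProtocol(segments=((0.0, 5.0, 10.0), (5.0, 10.0, 10.0)))
        tight = SolverSettings(rel_tol=1e-11, abs_tol=1e-13)
        one = simulate(baseline_model, constant_protocol(10.0, 10.0), tight, grid)
        two = simulate(baseline_model, split, tight, grid)
        scale = np.abs(one.states).max()
        np.testing.assert_allclose(two.states, one.states, atol=1e-8 * scale)

    def test_tolerance_refinement_self_consistency(self, baseline_model):
        grid = np.linspace(0, 2, 41)
        prot = constant_protocol(10.0, 2.0)
        coarse = simulate(baseline_model, prot, SolverSettings(rel_tol=1e-6), grid)
        fine = simulate(baseline_model, prot, SolverSettings(rel_tol=5e-7), grid)
        scale = np.abs(fine.states).max()
        rel = np.abs(coarse.states - fine.states).max() / scale
        assert rel < 10 * 1e-6

    def test_stiff_vs_explicit_cross_method(self, baseline_model):
        grid = np.linspace(0, 2, 41)
        prot = constant_protocol(10.0, 2.0)
        tight = SolverSettings(rel_tol=1e-9, abs_tol=1e-12)
        stiff = simulate(baseline_model, prot, SolverSettings(rel_tol=1e-8, abs_tol=1e-11,
                                                             method="stiff_multistep"), grid)
        rk = simulate(baseline_model, prot,
                      SolverSettings(rel_tol=tight.rel_tol, abs_tol=tight.abs_tol,
                                     method="explicit_rk"), grid)
        scale = np.abs(rk.states).max()
        assert np.abs(stiff.states - rk.states).max() / scale < 1e-4

    def test_conservation_along_full_model_trajectory(self, baseline, stimulated_trajectory):
        pools = conserved_pools(baseline)
        assert pools
        traj = stimulated_trajectory
        for pool in pools:
            series = sum(c * traj.col(sid) for sid, c in pool.items())
            total = series[0]
            assert total > 0
            assert np.abs(series - total).max() / total < 1e-6

    def test_deterministic_repeat(self, baseline_model):
        prot = constant_protocol(10.0, 1.0)
        a = simulate(baseline_model, prot)
        b = simulate(baseline_model, prot)
        assert np.array_equal(a.states, b.states)

    def test_grid_outside_protocol_rejected(self, baseline_model):
        with pytest.raises(ValueError, match="span"):
            simulate(baseline_model, constant_protocol(10.0, 1.0), t_grid=np.linspace(0, 2, 10))


class TestObservables:
    def test_unknown_observable_id(self, stimulated_trajectory, catalog):
        with pytest.raises(KeyError, match="nonsense"):
            observable(stimulated_trajectory, catalog, "nonsense")

    def test_all_cytoplasmic_gives_zero_nuclear_series(self, baseline, catalog):
        # zero out the nuclear species so the nuclear readout must vanish
        from aktnfkb.network import ReactionNetwork, Species

        species = []
        for s in baseline.species:
            x0 = 0.0 if s.compartment == "nucleus" else s.initial_nM
            species.append(Species(s.id, s.name, s.compartment, x0, s.is_input))
        net = ReactionNetwork(species=species, reactions=list(baseline.reactions), metadata={})
        m = compile_network(net)
        traj_states = np.tile(m.x0, (3, 1))
        from aktnfkb.simulate import Trajectory

        traj = Trajectory(times=np.array([0.0, 1.0, 2.0]), states=traj_states,
                          species_index=dict(m.species_index),
                          protocol=constant_protocol(0.0, 2.0))
        assert observable(traj, catalog, "nuclear_NFkB") == pytest.approx([0.0, 0.0, 0.0])

    def test_normalized_series_peaks_at_one(self, stimulated_trajectory, catalog):
        y = observable(stimulated_trajectory, catalog, "nuclear_NFkB", normalize=True)
        assert y.max() == pytest.approx(1.0)

    def test_pakt_rises_then_partially_declines(self, stimulated_trajectory, catalog):
        y = observable(stimulated_trajectory, catalog, "pAkt_S473")
        i_peak = int(np.argmax(y))
        assert 0 < i_peak < len(y) - 1  # peak strictly inside the 10 h window
        assert y[-1] < y[i_peak]
        assert y[-1] > 0.2 * y[i_peak]  # declines only partially
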