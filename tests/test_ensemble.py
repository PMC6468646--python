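"""Coupling-rate sampling, ensemble runs, clustering, calibration."""

import numpy as np
import pytest

from aktnfkb.ensemble import (
    NULL_LABEL,
    CalibrationConstraints,
    EnsembleResult,
    SamplingSpec,
    classify_clusters,
    cluster_responses,
    describe_centroid,
    sample_rates,
    select_calibrated,
    run_ensemble,
)
from aktnfkb.network import compile_network
from aktnfkb.pathway import with_coupling_rate
from aktnfkb.simulate import constant_protocol, observable, simulate
from aktnfkb.synth import TrajectoryFamilySpec, generate_mixed_families


@pytest.fixture(scope="module")
def small_ensemble(baseline):
    return run_ensemble(
        baseline,
        SamplingSpec(n_draws=50, seed=17),
        constant_protocol(10.0, 10.0),
        t_grid=np.linspace(0, 10, 241),
    )


def _families_ensemble(noise_sd=0.05, n=20, seed=3):
    """Flat + transient + sustained families wrapped as an EnsembleResult."""
    fam = generate_mixed_families(
        [
            TrajectoryFamilySpec("flat", n=n, noise_sd=noise_sd, seed=seed),
            TrajectoryFamilySpec("transient", n=n, noise_sd=noise_sd, seed=seed + 1),
            TrajectoryFamilySpec("sustained", n=n, noise_sd=noise_sd, seed=seed + 2),
        ]
    )
    ens = EnsembleResult(
        draws=np.ones(3 * n),
        times=fam.times,
        trajectories=fam.values,
        failed=[],
        observable_id="synthetic",
    )
    return ens, fam.labels


class TestSampling:
    def test_draws_within_bounds_and_count(self):
        spec = SamplingSpec(low=1e-3, high=1e2, n_draws=7000, seed=1)
        draws = sample_rates(spec)
        assert draws.shape == (7000,)
        assert draws.min() >= 1e-3 and draws.max() <= 1e2

    def test_degenerate_interval(self):
        draws = sample_rates(SamplingSpec(low=1.0, high=1.0 + 1e-9, n_draws=100, seed=0))
        np.testing.assert_allclose(draws, 1.0, rtol=1e-8)

    def test_seed_determinism(self):
        spec = SamplingSpec(n_draws=200, seed=42)
        np.testing.assert_array_equal(sample_rates(spec), sample_rates(spec))

    def test_log_uniform_decade_occupancy(self):
        # each decade of a 5-decade log-uniform range holds ~1/5 of the draws
        draws = sample_rates(SamplingSpec(low=1e-3, high=1e2, n_draws=5000, seed=7))
        counts, _ = np.histogram(np.log10(draws), bins=5, range=(-3, 2))
        np.testing.assert_allclose(counts / 5000, 0.2, atol=0.03)


class TestRunEnsemble:
    def test_shapes_and_no_failures(self, small_ensemble):
        assert small_ensemble.trajectories.shape == (50, 241)
        assert small_ensemble.failed == []
        assert small_ensemble.n_total == 50

    def test_single_draw_matches_direct_simulation(self, baseline, catalog):
        spec = SamplingSpec(low=1.0, high=1.0 + 1e-12, n_draws=1, seed=0)
        grid = np.linspace(0, 10, 61)
        ens = run_ensemble(baseline, spec, constant_protocol(10.0, 10.0), t_grid=grid)
        direct = simulate(
            compile_network(with_coupling_rate(baseline, ens.draws[0])),
            constant_protocol(10.0, 10.0),
            t_grid=grid,
        )
        np.testing.assert_allclose(
            ens.trajectories[0], observable(direct, catalog, "nuclear_NFkB"), rtol=1e-10
        )

    def test_peak_is_nondecreasing_in_coupling_rate(self, baseline, catalog):
        peaks = []
        grid = np.linspace(0, 10, 121)
        for k in [0.003, 0.03, 0.3, 3.0, 30.0]:
            tr = simulate(
                compile_network(with_coupling_rate(baseline, k)),
                constant_protocol(10.0, 10.0),
                t_grid=grid,
            )
            peaks.append(observable(tr, catalog, "nuclear_NFkB").max())
        assert all(b >= a for a, b in zip(peaks, peaks[1:]))

    def test_mm_target_reaction_rejected(self, baseline):
        from aktnfkb.errors import EnsembleError

        with pytest.raises(EnsembleError, match="mass action"):
            run_ensemble(
                baseline,
                SamplingSpec(target_reaction="receptor_autophos", n_draws=1),
                constant_protocol(10.0, 1.0),
            )


class TestClustering:
    def test_three_family_recovery_ari(self):
        from sklearn.metrics import adjusted_rand_score

        ens, truth = _families_ensemble()
        classes = cluster_responses(ens, k=3, seed=0)
        ari = adjusted_rand_score(truth, classes.labels)
        assert ari >= 0.95

    def test_auto_selects_three_families(self):
        ens, _ = _families_ensemble()
        classes = cluster_responses(ens, k="auto", seed=0)
        assert classes.chosen_k == 3

    def test_flat_zero_goes_to_reserved_null_class(self):
        ens, truth = _families_ensemble(noise_sd=0.0)
        classes = cluster_responses(ens, k=3, seed=0)
        flat = truth == "flat"
        assert np.all(classes.labels[flat] == NULL_LABEL)
        assert np.all(classes.labels[~flat] >= 0)

    def test_identical_trajectories_single_cluster(self):
        y = np.tile(np.linspace(0, 1, 60), (8, 1))
        ens = EnsembleResult(
            draws=np.ones(8), times=np.linspace(0, 10, 60), trajectories=y,
            failed=[], observable_id="x",
        )
        classes = cluster_responses(ens, k=1, seed=0)
        assert set(classes.labels) == {0}
        assert np.var(classes.centroids[0] - y[0] / y[0].max()) < 1e-20

    def test_k_exceeding_trajectories_rejected(self):
        y = np.tile(np.linspace(0, 1, 60), (3, 1))
        ens = EnsembleResult(
            draws=np.ones(3), times=np.linspace(0, 10, 60), trajectories=y,
            failed=[], observable_id="x",
        )
        with pytest.raises(ValueError, match="exceeds"):
            cluster_responses(ens, k=5, seed=0)

    def test_seed_determinism_end_to_end(self, small_ensemble):
        a = cluster_responses(small_ensemble, k=3, seed=11)
        b = cluster_responses(small_ensemble, k=3, seed=11)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.centroids, b.centroids)

    def test_model_ensemble_has_flat_and_sustained_categories(self, small_ensemble):
        classes = cluster_responses(small_ensemble, k="auto", seed=0)
        shapes = set(classify_clusters(small_ensemble, classes).values())
        assert "flat" in shapes
        assert "sustained" in shapes

    def test_describe_centroid_shapes(self):
        t = np.linspace(0, 10, 60)
        assert describe_centroid(np.full(60, 0.9)) == "flat"
        assert describe_centroid(1 - np.exp(-t / 0.5)) == "sustained"
        assert describe_centroid((1 - np.exp(-t / 0.3)) * np.exp(-t / 1.0)) == "transient"
        osc = (1 - np.exp(-t / 0.3)) * np.exp(-t / 4) * 0.5 * (1 - np.cos(2 * np.pi * t / 2))
        assert describe_centroid(osc / osc.max()) == "oscillatory"


class TestCalibration:
    def _mk(self, times, ys):
        ys = np.atleast_2d(np.asarray(ys, dtype=float))
        return EnsembleResult(
            draws=np.full(ys.shape[0], 2.0), times=times, trajectories=ys,
            failed=[], observable_id="x",
        )

    def test_fast_sustained_trajectory_kept(self):
        t = np.linspace(0, 10, 601)
        y = 100 * (1 - np.exp(-t / 0.05))  # half-max near 2 min, sustained
        res = select_calibrated(self._mk(t, y))
        assert list(res.kept) == [0]
        assert res.nominal_rate == pytest.approx(2.0)

    def test_flat_zero_trajectory_rejected(self):
        t = np.linspace(0, 10, 601)
        res = select_calibrated(self._mk(t, np.zeros_like(t)))
        assert res.kept.size == 0
        assert res.nominal_rate is None

    def test_flat_resting_trajectory_rejected_by_fold_induction(self):
        t = np.linspace(0, 10, 601)
        y = np.full_like(t, 5.0)  # constant non-zero: no induction
        res = select_calibrated(self._mk(t, y))
        assert res.kept.size == 0

    def test_late_riser_rejected(self):
        t = np.linspace(0, 10, 601)
        y = 100 * (1 - np.exp(-np.maximum(t - 1.0, 0) / 0.1))  # rises after 1 h
        res = select_calibrated(self._mk(t, y))
        assert res.kept.size == 0

    def test_transient_rejected(self):
        t = np.linspace(0, 10, 601)
        y = 100 * (1 - np.exp(-t / 0.05)) * np.exp(-t / 1.5)  # collapses before 6 h
        res = select_calibrated(self._mk(t, y))
        assert res.kept.size == 0

    def test_selection_monotone_in_constraints(self, small_ensemble):
        strict = select_calibrated(small_ensemble, CalibrationConstraints())
        loose_rise = select_calibrated(
            small_ensemble, CalibrationConstraints(rise_deadline=0.5)
        )
        loose_sustain = select_calibrated(
            small_ensemble, CalibrationConstraints(sustain_horizon=3.0)
        )
        assert set(strict.kept) <= set(loose_rise.kept)
        assert set(strict.kept) <= set(loose_sustain.kept)

    def test_kept_fraction_discriminative_on_model_ensemble(self, small_ensemble):
        res = select_calibrated(small_ensemble)
        assert 0 < res.kept.size < small_ensemble.n_total
        assert res.nominal_rate is not None
        # nominal summarizes the kept draws: it lies within their range
        kept_rates = small_ensemble.draws[res.kept]
        assert kept_rates.min() <= res.nominal_rate <= kept_rates.max()
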