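"""Network data model, compiler, rate evaluation and conserved pools."""

import json

import numpy as np
import pytest

from aktnfkb.errors import ModelSchemaError, ModelValidationError
from aktnfkb.network import (
    RateLaw,
    Reaction,
    ReactionNetwork,
    Species,
    compile_network,
    conserved_pools,
    evaluate_rhs,
    evaluate_rhs_loop,
    mass_action_rates,
    mm_rates,
    network_from_dict,
    parse_network,
    rhs_jacobian,
    serialize_network,
)

from .conftest import random_toy_network


def _net(species, reactions):
    return ReactionNetwork(species=species, reactions=reactions, metadata={})


def _sp(sid, x0=1.0, **kw):
    return Species(sid, sid, "cytoplasm", x0, **kw)


class TestValidation:
    def test_minimal_network_one_species_no_reactions(self):
        net = _net([_sp("A")], [])
        assert net.species_ids == ["A"]
        assert net.reactions == []

    def test_unresolved_species_id_names_the_reaction(self):
        with pytest.raises(ModelSchemaError, match="rx1.*AKTX"):
            _net(
                [_sp("A")],
                [Reaction("rx1", (("AKTX", 1),), (), RateLaw("mass_action", k=1.0), "receptor")],
            )

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ModelValidationError, match="duplicate species"):
            _net([_sp("A"), _sp("A")], [])

    def test_negative_concentration_rejected(self):
        with pytest.raises(ModelValidationError, match="initial concentration"):
            _sp("A", -1.0)

    def test_nonpositive_rate_constant_rejected(self):
        with pytest.raises(ModelValidationError, match="k > 0"):
            RateLaw("mass_action", k=0.0)

    def test_mass_action_order_capped_at_two(self):
        with pytest.raises(ModelValidationError, match="order"):
            Reaction("r", (("A", 2), ("B", 1)), (), RateLaw("mass_action", k=1.0), "receptor")

    def test_mm_requires_single_substrate(self):
        with pytest.raises(ModelValidationError, match="one substrate"):
            Reaction("r", (("A", 1), ("B", 1)), (("C", 1),),
                     RateLaw("michaelis_menten", vmax=1.0, km=1.0), "receptor")

    def test_at_most_one_input_species(self):
        with pytest.raises(ModelValidationError, match="is_input"):
            _net([_sp("A", is_input=True), _sp("B", is_input=True)], [])

    def test_parse_error_on_malformed_json(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{not json")
        with pytest.raises(ModelSchemaError, match="not valid JSON"):
            parse_network(p)

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        net = random_toy_network(rng)
        p = tmp_path / "net.json"
        serialize_network(net, p)
        assert parse_network(p) == net


class TestCompile:
    def test_bimolecular_stoichiometry_columns(self):
        net = _net(
            [_sp("A"), _sp("B"), _sp("C")],
            [Reaction("r", (("A", 1), ("B", 1)), (("C", 1),),
                      RateLaw("mass_action", k=1.0), "receptor")],
        )
        m = compile_network(net)
        assert m.S_ma_in[:, 0].tolist() == [1, 1, 0]
        assert m.S_ma_out[:, 0].tolist() == [0, 0, 1]

    def test_mm_column_is_net_stoichiometry(self):
        net = _net(
            [_sp("S"), _sp("P")],
            [Reaction("r", (("S", 1),), (("P", 1),),
                      RateLaw("michaelis_menten", vmax=1.0, km=1.0), "receptor")],
        )
        m = compile_network(net)
        assert m.S_mm[:, 0].tolist() == [-1, 1]
        assert m.S_ma_in.shape == (2, 0)

    def test_species_order_is_declaration_order(self):
        net = _net([_sp("Z"), _sp("A")], [])
        m = compile_network(net)
        assert m.species_ids == ["Z", "A"]


class TestRates:
    def test_bimolecular_product_rule(self):
        net = _net(
            [_sp("A", 2.0), _sp("B", 3.0)],
            [Reaction("r", (("A", 1), ("B", 1)), (), RateLaw("mass_action", k=1.0), "receptor")],
        )
        m = compile_network(net)
        assert mass_action_rates(m, [2.0, 3.0]) == pytest.approx([6.0])

    def test_zero_concentration_gives_zero_rate(self):
        net = _net(
            [_sp("A", 0.0)],
            [Reaction("r", (("A", 1),), (), RateLaw("mass_action", k=5.0), "receptor")],
        )
        m = compile_network(net)
        assert mass_action_rates(m, [0.0]) == pytest.approx([0.0])

    def test_input_coupling_factor(self):
        # k=2, c=0.5, u=4 -> 2 * x_A * (1 + 2) = 6 at x_A = 1
        net = _net(
            [_sp("A")],
            [Reaction("r", (("A", 1),), (), RateLaw("mass_action", k=2.0, c=0.5), "receptor")],
        )
        m = compile_network(net)
        assert mass_action_rates(m, [1.0], u=4.0) == pytest.approx([6.0])

    def test_negative_state_is_a_domain_error(self):
        net = _net(
            [_sp("A")],
            [Reaction("r", (("A", 1),), (), RateLaw("mass_action", k=1.0), "receptor")],
        )
        m = compile_network(net)
        with pytest.raises(ValueError, match="negative"):
            mass_action_rates(m, [-0.1])

    @pytest.mark.parametrize(
        "x_s, expected",
        [(2.0, 5.0), (0.0, 0.0)],
    )
    def test_mm_half_saturation_and_zero(self, x_s, expected):
        net = _net(
            [_sp("S", 2.0)],
            [Reaction("r", (("S", 1),), (), RateLaw("michaelis_menten", vmax=10.0, km=2.0), "receptor")],
        )
        m = compile_network(net)
        assert mm_rates(m, [x_s]) == pytest.approx([expected])

    def test_mm_saturation_limit(self):
        net = _net(
            [_sp("S", 1.0)],
            [Reaction("r", (("S", 1),), (), RateLaw("michaelis_menten", vmax=3.0, km=1.0), "receptor")],
        )
        m = compile_network(net)
        assert mm_rates(m, [1e6])[0] == pytest.approx(3.0, abs=1e-5)


class TestRhs:
    def test_unimolecular_conversion(self):
        net = _net(
            [_sp("A", 1.0), _sp("B", 0.0)],
            [Reaction("r", (("A", 1),), (("B", 1),), RateLaw("mass_action", k=1.0), "receptor")],
        )
        m = compile_network(net)
        assert evaluate_rhs(m, [1.0, 0.0]) == pytest.approx([-1.0, 1.0])

    def test_all_rates_zero_gives_zero_vector(self):
        net = _net(
            [_sp("A", 0.0), _sp("B", 0.0)],
            [Reaction("r", (("A", 1), ("B", 1)), (("A", 2),),
                      RateLaw("mass_action", k=3.0), "receptor")],
        )
        m = compile_network(net)
        assert evaluate_rhs(m, [0.0, 0.0]) == pytest.approx([0.0, 0.0])

    def test_matrix_path_matches_loop_oracle_on_random_networks(self):
        rng = np.random.default_rng(1234)
        for _ in range(100):
            net = random_toy_network(rng)
            m = compile_network(net)
            x = rng.uniform(0, 4, len(net.species))
            u = float(rng.uniform(0, 2))
            got = evaluate_rhs(m, x, u)
            want = evaluate_rhs_loop(net, x, u)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-12)

    def test_zero_is_absorbing_without_production(self):
        # species with no producing reaction must have exactly zero derivative at x_i = 0
        rng = np.random.default_rng(99)
        for _ in range(50):
            net = random_toy_network(rng)
            m = compile_network(net)
            produced = set()
            for r in net.reactions:
                produced.update(sid for sid, _ in r.products)
            x = rng.uniform(0, 3, len(net.species))
            for i, s in enumerate(net.species):
                if s.id not in produced:
                    x[i] = 0.0
            dx = evaluate_rhs(m, x)
            for i, s in enumerate(net.species):
                if s.id not in produced and x[i] == 0.0:
                    assert dx[i] == pytest.approx(0.0, abs=1e-14)

    def test_analytic_jacobian_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        net = random_toy_network(rng)
        m = compile_network(net)
        x = rng.uniform(0.5, 3, len(net.species))
        J = rhs_jacobian(m, x, u=0.7)
        eps = 1e-7
        for i in range(len(x)):
            xp = x.copy()
            xp[i] += eps
            col = (evaluate_rhs(m, xp, 0.7) - evaluate_rhs(m, x, 0.7)) / eps
            np.testing.assert_allclose(J[:, i], col, rtol=1e-5, atol=1e-6)


class TestConservedPools:
    def test_isomerization_pool(self):
        net = _net(
            [_sp("A"), _sp("B")],
            [
                Reaction("f", (("A", 1),), (("B", 1),), RateLaw("mass_action", k=1.0), "receptor"),
                Reaction("b", (("B", 1),), (("A", 1),), RateLaw("mass_action", k=2.0), "receptor"),
            ],
        )
        pools = conserved_pools(net)
        assert pools == [{"A": 1, "B": 1}]

    def test_degraded_species_in_no_pool(self):
        net = _net(
            [_sp("A")],
            [Reaction("d", (("A", 1),), (), RateLaw("mass_action", k=1.0), "receptor")],
        )
        assert all("A" not in p for p in conserved_pools(net))

    def test_pools_annihilate_rhs_on_random_states(self, baseline, baseline_model):
        rng = np.random.default_rng(11)
        pools = conserved_pools(baseline)
        assert pools, "baseline should have conserved pools"
        sidx = baseline_model.species_index
        for _ in range(10):
            x = rng.uniform(0, 50, baseline_model.n_species)
            dx = evaluate_rhs(baseline_model, x, u=rng.uniform(0, 10))
            for pool in pools:
                w = np.zeros(baseline_model.n_species)
                for sid, c in pool.items():
                    w[sidx[sid]] = c
                assert abs(w @ dx) < 1e-12 * max(1.0, np.abs(dx).max())
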