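import itertools

import numpy as np
import pytest

from iqgrn.logic import BooleanRule, GrnModel
from iqgrn.simulate import (Perturbation, async_step, derive_initial_states,
                            find_fixed_points, perturb_link,
                            simulate_ensemble, systematic_perturbation_scan)
from iqgrn.synthetic import SyntheticConfig, generate_random_grn

from conftest import make_binarized


def brute_force_fixed_points(model, clamps=None):
    """Independent oracle: pure-python scan over every full state."""
    clamps = clamps or {}
    out = []
    for bits in itertools.product((0, 1), repeat=len(model.genes)):
        state = dict(zip(model.genes, bits))
        if any(state[g] != v for g, v in clamps.items()):
            continue
        if all(model.rules[g].evaluate(state) == state[g]
               for g in model.genes if g not in clamps):
            out.append(state)
    return out


class TestAsyncStep:
    def test_fixed_point_invariant_under_any_choice(self, toggle_model):
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert async_step(toggle_model, {"g1": 1, "g2": 0}, rng) == \
                {"g1": 1, "g2": 0}

    def test_clamped_gene_never_changes(self, cascade_model):
        rng = np.random.default_rng(1)
        pert = Perturbation.knockouts("b")
        state = {"a": 1, "b": 0, "c": 0}
        for _ in range(50):
            state = async_step(cascade_model, state, rng, pert)
            assert state["b"] == 0

    def test_two_gene_hand_example(self):
        # g1 = g1, g2 = g1; from (1,0) updating g2 -> (1,1), g1 -> (1,0)
        model = GrnModel(
            genes=["g1", "g2"],
            rules={"g1": BooleanRule("g1", activators=("g1",)),
                   "g2": BooleanRule("g2", activators=("g1",))})
        seen = set()
        for seed in range(20):
            rng = np.random.default_rng(seed)
            seen.add(tuple(async_step(model, {"g1": 1, "g2": 0}, rng).values()))
        assert seen == {(1, 1), (1, 0)}


class TestInitialStates:
    def _binary(self):
        calls = np.array([[1, 0, 1, 0]] * 6 + [[0, 1, 0, 1]] * 4)
        return make_binarized(calls, gene_ids=["a", "b", "c", "d"])

    @pytest.mark.parametrize("noisy,expected", [([], 1), (["a", "b"], 4),
                                                (["a", "b", "c"], 8)])
    def test_state_counts(self, noisy, expected):
        states = derive_initial_states(self._binary(), ["a", "b", "c", "d"],
                                       n_earliest=6, noisy_genes=noisy)
        assert len(states) == expected
        assert len({tuple(sorted(s.items())) for s in states}) == expected

    def test_majority_over_earliest_cells(self):
        states = derive_initial_states(self._binary(), ["a", "b", "c", "d"],
                                       n_earliest=6)
        assert states[0] == {"a": 1, "b": 0, "c": 1, "d": 0}

    def test_unknown_noisy_gene_fatal(self):
        with pytest.raises(KeyError, match="zz"):
            derive_initial_states(self._binary(), ["a"], noisy_genes=["zz"])


class TestEnsemble:
    def test_self_activator_absorbed_immediately(self):
        model = GrnModel(genes=["g"],
                         rules={"g": BooleanRule("g", activators=("g",))})
        ens = simulate_ensemble(model, [{"g": 1}], n_traj=10, max_steps=5,
                                seed=0)
        assert ens.n_absorbed == 10
        assert all(t.length == 0 for t in ens.trajectories)
        np.testing.assert_allclose(ens.average_exp["g"], 1.0)
        assert ens.asp[(1,)] == 1.0  # attractor scores 1 on absorbed paths

    def test_toggle_absorption_matches_exact_markov_chain(self, toggle_model):
        # from (1,1) the first update flips exactly one gene, landing in a
        # fixed point: exact absorption probabilities are 1/2 and 1/2,
        # and (0,0) is unreachable
        ens = simulate_ensemble(toggle_model, [{"g1": 1, "g2": 1}],
                                n_traj=4000, max_steps=50, seed=2)
        terms = [t.terminal for t in ens.trajectories]
        freq10 = terms.count((1, 0)) / len(terms)
        assert ens.n_absorbed == 4000
        assert (0, 0) not in terms and (1, 1) not in terms
        assert freq10 == pytest.approx(0.5, abs=0.03)

    def test_average_exp_bounded(self, cascade_model):
        ens = simulate_ensemble(cascade_model,
                                [{"a": 1, "b": 0, "c": 0}],
                                n_traj=50, max_steps=30, seed=3)
        assert (ens.average_exp.to_numpy() >= 0).all()
        assert (ens.average_exp.to_numpy() <= 1).all()

    def test_asp_in_unit_interval(self, cascade_model):
        ens = simulate_ensemble(cascade_model, [{"a": 1, "b": 0, "c": 0}],
                                n_traj=50, max_steps=30, seed=4)
        assert all(0 <= v <= 1 for v in ens.asp.values())

    def test_clamp_respected_in_all_states(self, cascade_model):
        pert = Perturbation.overexpressions("c")
        ens = simulate_ensemble(cascade_model, [{"a": 1, "b": 0, "c": 0}],
                                n_traj=20, max_steps=20,
                                perturbation=pert, seed=5)
        ci = cascade_model.genes.index("c")
        assert all(s[ci] == 1 for t in ens.trajectories for s in t.states)


class TestFixedPoints:
    def test_self_activator_two_fixed_points(self):
        model = GrnModel(genes=["g"],
                         rules={"g": BooleanRule("g", activators=("g",))})
        fps = find_fixed_points(model)
        assert fps == [{"g": 0}, {"g": 1}]

    def test_toggle_three_fixed_points(self, toggle_model):
        fps = find_fixed_points(toggle_model)
        assert [tuple(s.values()) for s in fps] == [(0, 0), (0, 1), (1, 0)]

    def test_knockout_restricts_fixed_points(self, toggle_model):
        fps = find_fixed_points(toggle_model, Perturbation.knockouts("g2"))
        assert [tuple(s.values()) for s in fps] == [(0, 0), (1, 0)]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_models(self, seed):
        cfg = SyntheticConfig(n_genes=int(5 + seed % 4), seed=seed)
        model = generate_random_grn(cfg)
        got = find_fixed_points(model)
        expected = brute_force_fixed_points(model)
        assert got == expected

    def test_terminal_states_subset_of_fixed_points(self):
        cfg = SyntheticConfig(n_genes=6, seed=11)
        model = generate_random_grn(cfg)
        fps = {tuple(s.values()) for s in find_fixed_points(model)}
        init = {g: 1 if i == 0 else 0 for i, g in enumerate(model.genes)}
        ens = simulate_ensemble(model, [init], n_traj=300, max_steps=100,
                                seed=6)
        terms = {t.terminal for t in ens.trajectories if t.absorbed}
        assert terms <= fps


class TestPerturbationScan:
    def test_order_one_row_count(self, cascade_model):
        table = systematic_perturbation_scan(cascade_model, order=1)
        assert len(table) == 2 * 3

    def test_order_two_row_count(self, cascade_model):
        table = systematic_perturbation_scan(cascade_model, order=2)
        assert len(table) == 4 * 3  # 4 * C(3,2)

    def test_knockout_rows_respect_clamp(self, cascade_model):
        table = systematic_perturbation_scan(cascade_model, order=1)
        row = table[table.perturbation == "KO:a"].iloc[0]
        ai = cascade_model.genes.index("a")
        for fp in row.fixed_points.split(";"):
            assert fp[ai] == "0"


class TestPerturbLink:
    def test_remove_repressor(self):
        rule = BooleanRule("g", activators=("a1",), repressors=("r1", "r2"))
        model = GrnModel(genes=["g", "a1", "r1", "r2"],
                         rules={"g": rule,
                                **{x: BooleanRule(x, activators=(x,))
                                   for x in ("a1", "r1", "r2")}})
        out = perturb_link(model, "r1", "g")
        assert out.rules["g"].repressors == ("r2",)

    def test_remove_one_of_two_activators(self):
        rule = BooleanRule("g", activators=("a1", "a2"), repressors=("r1",))
        model = GrnModel(genes=["g", "a1", "a2", "r1"],
                         rules={"g": rule,
                                **{x: BooleanRule(x, activators=(x,))
                                   for x in ("a1", "a2", "r1")}})
        out = perturb_link(model, "a1", "g")
        assert out.rules["g"].activators == ("a2",)
        assert out.rules["g"].repressors == ("r1",)

    def test_remove_sole_activator_constant_zero_flagged(self):
        model = GrnModel(genes=["g", "a1"],
                         rules={"g": BooleanRule("g", activators=("a1",)),
                                "a1": BooleanRule("a1", activators=("a1",))})
        out = perturb_link(model, "a1", "g")
        assert out.rules["g"].constant == 0
        assert out.rules["g"].flag == "no-activators-after-link-removal"

    def test_absent_edge_fatal(self, cascade_model):
        with pytest.raises(ValueError, match="not present"):
            perturb_link(cascade_model, "c", "a")
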