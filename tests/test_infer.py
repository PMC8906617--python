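import itertools

import numpy as np
import pytest

from iqgrn.infer import (RuleSearchSpace, enumerate_rules, nrules_closed_form,
                         rule_agreement, select_rules)
from iqgrn.logic import BooleanRule
from iqgrn.network import CandidateNetwork, InteractionCandidate

from conftest import make_binarized


def brute_force_count(n, m, max_act=4, max_rep=2):
    """Independent oracle: explicit subset generation."""
    acts = [s for k in range(1, max_act + 1)
            for s in itertools.combinations(range(n), k)]
    reps = [s for k in range(0, max_rep + 1)
            for s in itertools.combinations(range(m), k)]
    return len(acts) * len(reps)


class TestRuleSemantics:
    @pytest.mark.parametrize("k,m", [(k, m) for k in range(1, 5)
                                     for m in range(0, 3)])
    def test_truth_table_exhaustive(self, k, m):
        acts = tuple(f"a{i}" for i in range(k))
        reps = tuple(f"r{i}" for i in range(m))
        rule = BooleanRule("g", activators=acts, repressors=reps)
        for bits in itertools.product((0, 1), repeat=k + m):
            state = dict(zip(acts + reps, bits))
            expected = int(all(bits[:k]) and not any(bits[k:]))
            assert rule.evaluate(state) == expected

    def test_single_repressor_suffices(self):
        rule = BooleanRule("g", activators=("a",), repressors=("r1", "r2"))
        assert rule.evaluate({"a": 1, "r1": 1, "r2": 0}) == 0

    def test_relaxed_combinators(self):
        rule = BooleanRule("g", activators=("a", "b"), repressors=("r", "s"),
                           act_op="or", rep_op="and")
        assert rule.evaluate({"a": 1, "b": 0, "r": 1, "s": 0}) == 1
        assert rule.evaluate({"a": 1, "b": 0, "r": 1, "s": 1}) == 0


class TestEnumerate:
    @pytest.mark.parametrize("n,m", [(n, m) for n in range(0, 7)
                                     for m in range(0, 5)])
    def test_count_matches_closed_form_and_oracle(self, n, m):
        space = RuleSearchSpace(
            gene="g",
            activators=tuple(f"a{i}" for i in range(n)),
            repressors=tuple(f"r{i}" for i in range(m)))
        rules = enumerate_rules(space)
        assert len(rules) == nrules_closed_form(n, m) if n else len(rules) == 0
        if n:
            assert len(rules) == brute_force_count(n, m)
            assert len(set(rules)) == len(rules)

    def test_specific_counts(self):
        mk = lambda n, m: RuleSearchSpace(
            "g", tuple(f"a{i}" for i in range(n)),
            tuple(f"r{i}" for i in range(m)))
        assert len(enumerate_rules(mk(4, 2))) == 60
        assert len(enumerate_rules(mk(2, 0))) == 3
        # one activator gives a single non-empty activator subset, crossed
        # with the empty and singleton repressor subsets
        assert len(enumerate_rules(mk(1, 1))) == 2

    def test_relaxed_multiplies_multi_literal_groups(self):
        space = RuleSearchSpace("g", ("a1", "a2"), ("r1", "r2"))
        strict = enumerate_rules(space)
        relaxed = enumerate_rules(space, relaxed=True)
        assert len(set(relaxed)) == len(relaxed)
        assert len(relaxed) > len(strict)
        # the one rule with both groups multi-literal appears in 4 variants
        both = [r for r in relaxed
                if len(r.activators) == 2 and len(r.repressors) == 2]
        assert len(both) == 4


class TestAgreement:
    def test_self_consistent_series_is_hundred(self):
        # target g1 follows g0 with lag 1 exactly
        g0 = np.array([0, 0, 1, 1, 1, 0, 0, 1])
        g1 = np.array([9, 0, 0, 1, 1, 1, 0, 0])  # shifted; first entry unused
        g1[0] = 0
        b = make_binarized(np.column_stack([g0, g1]))
        rule = BooleanRule("g1", activators=("g0",))
        assert rule_agreement(rule, b) == pytest.approx(100.0)

    def test_constant_zero_against_half_on(self):
        calls = np.array([0, 1, 0, 1, 0, 1])[:, None]
        b = make_binarized(calls, gene_ids=["g"])
        rule = BooleanRule("g", constant=0)
        # predictions compare to cells 2..6: on in 3 of 5
        assert rule_agreement(rule, b) == pytest.approx(100 * 2 / 5)

    def test_lag_exhausting_cells_fatal(self):
        b = make_binarized(np.zeros((4, 1)), gene_ids=["g"])
        with pytest.raises(ValueError, match="lag"):
            rule_agreement(BooleanRule("g", constant=0), b, lag=4)


def _network_for(gene, activators, repressors, mi):
    genes = sorted({gene, *activators, *repressors})
    net = CandidateNetwork(genes=genes)
    for a in activators:
        net.add(InteractionCandidate(a, gene, mi[a], 0.9, "+",
                                     autoregulation=a == gene))
    for r in repressors:
        net.add(InteractionCandidate(r, gene, mi[r], -0.9, "-"))
    for g in genes:
        if g != gene:
            net.add(InteractionCandidate(g, g, 0.0, 1.0, "+",
                                         autoregulation=True))
    return net


class TestSelectRules:
    def test_highest_average_mi_wins(self):
        # g's observed series is perfectly explained by a AND by b alone
        a = np.array([0, 0, 1, 1, 1, 1])
        g = np.array([0, 0, 0, 1, 1, 1])
        b = make_binarized(np.column_stack([a, a, g]),
                           gene_ids=["a", "b", "g"])
        net = _network_for("g", ["a", "b"], [], {"a": 0.8, "b": 0.5})
        model = select_rules(net, b, agreement_cutoff=80.0)
        assert model.rules["g"].activators == ("a",)
        assert model.rules["g"].avg_mi == pytest.approx(0.8)

    def test_self_activation_penalized_by_zero_mi(self):
        a = np.array([0, 1, 1, 1, 1, 1])
        g = np.array([0, 0, 1, 1, 1, 1])
        b = make_binarized(np.column_stack([a, g]), gene_ids=["a", "g"])
        net = CandidateNetwork(genes=["a", "g"])
        net.add(InteractionCandidate("a", "g", 0.6, 0.9, "+"))
        net.add(InteractionCandidate("g", "g", 0.0, 1.0, "+",
                                     autoregulation=True))
        net.add(InteractionCandidate("a", "a", 0.0, 1.0, "+",
                                     autoregulation=True))
        model = select_rules(net, b, agreement_cutoff=80.0)
        rule = model.rules["g"]
        # {a} (avg 0.6) beats {a, g-self} (avg 0.3)
        assert rule.activators == ("a",)

    def test_no_survivor_falls_back_to_best_agreement(self):
        rng = np.random.default_rng(0)
        a = (rng.random(40) < 0.5).astype(int)
        g = (rng.random(40) < 0.5).astype(int)
        b = make_binarized(np.column_stack([a, g]), gene_ids=["a", "g"])
        net = CandidateNetwork(genes=["a", "g"])
        net.add(InteractionCandidate("a", "g", 0.2, 0.5, "+"))
        net.add(InteractionCandidate("a", "a", 0.0, 1.0, "+",
                                     autoregulation=True))
        model = select_rules(net, b, agreement_cutoff=99.9)
        assert model.rules["g"].flag == "below-cutoff-best-agreement-fallback"

    def test_empty_candidates_constant_majority(self):
        g = np.array([1, 1, 1, 0, 1, 1])
        b = make_binarized(g[:, None], gene_ids=["g"])
        net = CandidateNetwork(genes=["g"])  # no candidates at all
        model = select_rules(net, b)
        rule = model.rules["g"]
        assert rule.constant == 1
        assert rule.flag == "no-candidates-constant-fallback"

    def test_deterministic_given_inputs(self):
        rng = np.random.default_rng(1)
        calls = (rng.random((50, 3)) < 0.5).astype(int)
        b = make_binarized(calls, gene_ids=["a", "b", "g"])
        net = _network_for("g", ["a", "b"], [], {"a": 0.4, "b": 0.4})
        m1 = select_rules(net, b)
        m2 = select_rules(net, b)
        assert m1.rules == m2.rules
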