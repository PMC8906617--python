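"""Boolean rule enumeration, pseudo-time agreement scoring and selection.

Each gene's update rule is drawn from a bounded family — 1..4 activators
combined with AND, 0..2 repressors combined with OR (a *relaxed* mode also
tries the opposite combinator in each group).  With N candidate activators
and M candidate repressors the strict family has

    nRules = [C(N,1)+C(N,2)+C(N,3)+C(N,4)] * [C(M,0)+C(M,1)+C(M,2)]

members.  Every enumerated rule is scored by teacher-forced agreement: the
rule is evaluated on the observed binarized state of cell i and its output
compared to the target's observed call at cell i+lag, over the pseudo-time
ordering.  Rules at or above the agreement cutoff compete on average
mutual information of their edges; self-activation edges carry MI 0, so a
self-loop is selected only when nothing else survives the cutoff.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from math import comb

import numpy as np
import pandas as pd

from .logic import BooleanRule, GrnModel
from .network import CandidateNetwork
from .preprocess import BinarizedDataset

__all__ = [
    "RuleSearchSpace", "nrules_closed_form", "enumerate_rules",
    "rule_agreement", "select_rules", "evaluate_rule",
    "MAX_ACTIVATORS", "MAX_REPRESSORS",
]

MAX_ACTIVATORS = 4
MAX_REPRESSORS = 2


def nrules_closed_form(n_activators: int, n_repressors: int,
                       max_act: int = MAX_ACTIVATORS,
                       max_rep: int = MAX_REPRESSORS) -> int:
    """Size of the strict rule family for N candidate activators, M repressors."""
    act = sum(comb(n_activators, k) for k in range(1, max_act + 1))
    rep = sum(comb(n_repressors, m) for m in range(0, max_rep + 1))
    return act * rep


@dataclass(frozen=True)
class RuleSearchSpace:
    """Candidate regulator pools for one gene."""

    gene: str
    activators: tuple[str, ...]
    repressors: tuple[str, ...]

    @property
    def n_rules(self) -> int:
        return nrules_closed_form(len(self.activators), len(self.repressors))

    @classmethod
    def from_network(cls, network: CandidateNetwork, gene: str) -> "RuleSearchSpace":
        return cls(gene=gene,
                   activators=tuple(network.activators_of(gene)),
                   repressors=tuple(network.repressors_of(gene)))


def evaluate_rule(rule: BooleanRule, state) -> int:
    """Evaluate a rule on a gene -> {0,1} mapping (thin alias)."""
    return rule.evaluate(state)


def _avg_mi(network: CandidateNetwork, rule: BooleanRule) -> float:
    """Mean MI over the rule's edges; a self-activation edge contributes 0."""
    weights = []
    for reg in rule.regulators:
        weights.append(0.0 if reg == rule.target
                       else network.mi_weight(reg, rule.target))
    return float(np.mean(weights)) if weights else 0.0


def enumerate_rules(space: RuleSearchSpace, network: CandidateNetwork | None = None,
                    relaxed: bool = False) -> list[BooleanRule]:
    """All rules in the family for one gene's candidate pools.

    Strict mode crosses activator subsets of size 1..4 with repressor
    subsets of size 0..2 (AND/OR combinators fixed).  Relaxed mode
    additionally tries both combinators in every multi-literal group.
    An empty activator pool yields an empty list (the gene is unresolvable
    within the family).
    """
    gene = space.gene
    if not space.activators:
        return []
    rules: list[BooleanRule] = []
    act_subsets = [s for k in range(1, MAX_ACTIVATORS + 1)
                   for s in itertools.combinations(space.activators, k)]
    rep_subsets = [s for m in range(0, MAX_REPRESSORS + 1)
                   for s in itertools.combinations(space.repressors, m)]
    for acts in act_subsets:
        for reps in rep_subsets:
            act_ops = ("and", "or") if relaxed and len(acts) > 1 else ("and",)
            rep_ops = ("or", "and") if relaxed and len(reps) > 1 else ("or",)
            for aop in act_ops:
                for rop in rep_ops:
                    rule = BooleanRule(target=gene, activators=acts,
                                       repressors=reps, act_op=aop, rep_op=rop)
                    if network is not None:
                        rule = replace(rule, avg_mi=_avg_mi(network, rule))
                    rules.append(rule)
    return rules


def _predict(rule: BooleanRule, calls: np.ndarray, col: dict[str, int],
             rows: slice) -> np.ndarray:
    """Vectorized rule output on the observed states of a block of cells."""
    if rule.constant is not None:
        n = calls[rows].shape[0]
        return np.full(n, rule.constant, dtype=bool)
    A = calls[rows][:, [col[a] for a in rule.activators]].astype(bool)
    active = A.all(axis=1) if rule.act_op == "and" else A.any(axis=1)
    if rule.repressors:
        R = calls[rows][:, [col[r] for r in rule.repressors]].astype(bool)
        repressed = R.any(axis=1) if rule.rep_op == "or" else R.all(axis=1)
        active = active & ~repressed
    return active


def rule_agreement(rule: BooleanRule, binary: BinarizedDataset,
                   lag: int = 1) -> float:
    """Teacher-forced agreement (percent) of a rule with the ordered data.

    The rule, fed the observed binarized state at cell i, predicts the
    target at cell i+lag; agreement is the fraction of matching predictions
    over the n_cells - lag comparable pairs.
    """
    n = binary.n_cells
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if lag >= n:
        raise ValueError(f"lag={lag} leaves no comparable cell pairs (n_cells={n})")
    col = {g: j for j, g in enumerate(binary.gene_ids)}
    pred = _predict(rule, binary.calls, col, slice(0, n - lag))
    obs = binary.calls[lag:, col[rule.target]].astype(bool)
    return float(100.0 * (pred == obs).mean())


def _agreements(rules: list[BooleanRule], binary: BinarizedDataset,
                lag: int) -> list[BooleanRule]:
    """Batch agreement scoring; shares the observed-state slices across rules."""
    n = binary.n_cells
    col = {g: j for j, g in enumerate(binary.gene_ids)}
    out = []
    for rule in rules:
        pred = _predict(rule, binary.calls, col, slice(0, n - lag))
        obs = binary.calls[lag:, col[rule.target]].astype(bool)
        out.append(replace(rule, agreement=float(100.0 * (pred == obs).mean())))
    return out


def select_rules(network: CandidateNetwork, binary: BinarizedDataset,
                 agreement_cutoff: float = 80.0, lag: int = 1,
                 relaxed: bool = False,
                 provenance: dict | None = None) -> GrnModel:
    """Pick one rule per gene: best average MI among rules passing the cutoff.

    Ties prefer fewer regulators, then lexicographic regulator names.  A
    gene with no rule at the cutoff falls back to its single
    highest-agreement rule (flagged); a gene with an empty candidate pool
    gets a constant rule at its majority binarized value (flagged).
    """
    genes = list(network.genes)
    col = {g: j for j, g in enumerate(binary.gene_ids)}
    rules: dict[str, BooleanRule] = {}
    diag_rows = []
    for gene in genes:
        space = RuleSearchSpace.from_network(network, gene)
        candidates = enumerate_rules(space, network, relaxed=relaxed)
        if not candidates:
            majority = int(binary.calls[:, col[gene]].mean() > 0.5)
            chosen = BooleanRule(target=gene, constant=majority,
                                 flag="no-candidates-constant-fallback",
                                 avg_mi=0.0, agreement=float("nan"))
            chosen = replace(chosen,
                             agreement=rule_agreement(chosen, binary, lag))
            n_passing = 0
        else:
            scored = _agreements(candidates, binary, lag)
            passing = [r for r in scored if r.agreement >= agreement_cutoff]
            n_passing = len(passing)
            if passing:
                chosen = min(passing, key=_selection_key)
            else:
                chosen = replace(
                    max(scored, key=lambda r: (r.agreement, -len(r.regulators))),
                    flag="below-cutoff-best-agreement-fallback")
        rules[gene] = chosen
        diag_rows.append({
            "gene": gene, "n_candidate_rules": len(candidates),
            "n_passing": n_passing, "rule": chosen.to_expression(),
            "agreement_pct": chosen.agreement, "avg_mi_bits": chosen.avg_mi,
            "flag": chosen.flag})
    prov = dict(provenance or {})
    prov.update({"agreement_cutoff": agreement_cutoff, "lag": lag,
                 "relaxed": relaxed})
    model = GrnModel(genes=genes, rules=rules, provenance=prov)
    model.provenance["diagnostics"] = diag_rows
    return model


def _selection_key(rule: BooleanRule):
    # max avg MI, then fewest regulators, then lexicographic regulator names
    return (-(rule.avg_mi or 0.0), len(rule.regulators), rule.regulators)


def diagnostics_frame(model: GrnModel) -> pd.DataFrame:
    rows = model.provenance.get("diagnostics", [])
    return pd.DataFrame(rows)
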