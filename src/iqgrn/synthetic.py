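"""Synthetic ground truth: random Boolean GRNs and expression matrices.

The generator draws a random acyclic-ordered model inside the inference
family (AND-combined activators from earlier genes, optional OR-combined
repressors), simulates it asynchronously from a root-on initial state, and
turns sampled trajectory states into a cells x genes matrix: each gene's
value is drawn from an *on* or *off* lognormal according to its Boolean
state, and dropout zeroes entries independently.  Pseudo-time is the
average simulation step (asp) of the sampled state plus small jitter — the
cleanest in-family notion of progression, standing in for a real
pseudo-time algorithm.

Repressors of a target are preferentially drawn from genes downstream of
its activators so repression switches on after activation: the target is
transiently expressed (a visible high->low transition) instead of never
firing, keeping the dynamics learnable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionDataset
from .logic import BooleanRule, GrnModel
from .preprocess import BinarizedDataset
from .simulate import simulate_ensemble

__all__ = [
    "SyntheticConfig", "generate_random_grn", "simulate_to_expression",
    "recovery_metrics",
]


def _activator_sets(pool: list[int], max_size: int,
                    ancestors: dict[int, set[int]]) -> list[frozenset]:
    """All cross-branch (pairwise non-ancestral) activator subsets of a pool."""
    import itertools as it
    out = [frozenset((j,)) for j in pool]
    for size in range(2, max_size + 1):
        for combo in it.combinations(pool, size):
            if all(a not in ancestors[b] and b not in ancestors[a]
                   for a, b in it.combinations(combo, 2)):
                out.append(frozenset(combo))
    return out


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    On/off expression is lognormal around well-separated medians
    (off 0.2, on 3.0, log-sd 0.25, ~15x apart; under 1% of either
    component falls on the wrong side of the midpoint threshold) so the
    data are cleanly
    bimodal; dropout is Bernoulli per entry.
    """

    n_genes: int = 8
    n_roots: int = 1
    max_activators: int = 2   # per generated rule (inference family allows 4)
    max_repressors: int = 1   # per generated rule (inference family allows 2)
    repressor_prob: float = 0.4
    n_cells: int = 2000
    mean_on: float = 3.0      # lognormal median of the on state
    mean_off: float = 0.2     # lognormal median of the off state
    sd_log: float = 0.25      # lognormal shape (log-space sd)
    dropout: float = 0.0
    n_traj: int = 200
    max_steps: int | None = None   # default 4 * n_genes
    jitter_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.max_activators <= 4:
            raise ValueError("max_activators must be in 1..4")
        if not 0 <= self.max_repressors <= 2:
            raise ValueError("max_repressors must be in 0..2")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.mean_off >= self.mean_on:
            raise ValueError("mean_off must be below mean_on")
        if self.n_roots < 1 or self.n_roots > self.n_genes:
            raise ValueError("n_roots must be in 1..n_genes")

    @property
    def gene_names(self) -> list[str]:
        return [f"G{i+1}" for i in range(self.n_genes)]

    @property
    def steps(self) -> int:
        return self.max_steps if self.max_steps is not None else 4 * self.n_genes


def generate_random_grn(config: SyntheticConfig,
                        rng: np.random.Generator | None = None) -> GrnModel:
    """Random model inside the inference family.

    Root genes self-activate: they model a constitutive upstream source
    (held on throughout, like an externally provided signal) and so carry
    no usable variation themselves.  The two genes after the roots are
    *branch seeds*, each driven directly by the roots, which gives the
    network two independent arms; every later gene draws 1..max_activators
    activators from earlier cascade genes and, with probability
    ``repressor_prob``, up to max_repressors repressors from genes
    switching on well after its activators, so repression produces a wide
    transient on-window.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    genes = config.gene_names
    rules: dict[str, BooleanRule] = {}
    # ancestor bookkeeping: in a latching cascade, A1 & A2 with A1 an
    # ancestor of A2 collapses to A2 on every reachable state, so such an
    # edge would be unidentifiable from any data; multi-activator sets are
    # drawn cross-branch (pairwise non-ancestral) to keep the truth
    # identifiable
    ancestors: dict[int, set[int]] = {}
    depth: dict[int, int] = {}
    repressed: set[int] = set()
    from collections import Counter
    used_sets: Counter = Counter()
    for i, g in enumerate(genes):
        if i < config.n_roots:
            rules[g] = BooleanRule(target=g, activators=(g,))
            ancestors[i] = set()
            depth[i] = 0
            continue
        if i == config.n_roots:
            # the first cascade gene hangs directly off the roots
            acts = np.arange(config.n_roots)[
                : 1 + int(rng.integers(min(config.max_activators,
                                           config.n_roots)))]
            rules[g] = BooleanRule(target=g,
                                   activators=tuple(genes[int(j)] for j in acts))
            ancestors[i] = set(int(j) for j in acts)
            depth[i] = 1
            continue
        # pool: earlier non-repressed cascade genes — repressed genes are
        # terminal (a shut-down side program does not drive the main
        # cascade, and feeding it forward would collapse the downstream
        # dynamics into rarely visited states)
        pool = list(range(config.n_roots, i))
        live = [j for j in pool if j not in repressed]
        pool = live if live else pool
        n_act = int(rng.integers(1, min(config.max_activators, len(pool)) + 1))
        # a single-activator set may recur once (a fork, the minimal
        # branching motif); multi-activator sets stay unique — wider
        # fan-out of identically regulated genes would leave the copies
        # mutually indistinguishable from their true regulators
        options = _activator_sets(pool, min(config.max_activators, len(pool)),
                                  ancestors)
        fresh = [s for s in options if used_sets[s] < (2 if len(s) == 1 else 1)]
        sized = [s for s in fresh if len(s) == n_act] or fresh or options
        acts = np.array(sorted(sized[rng.integers(len(sized))]))
        used_sets[frozenset(int(j) for j in acts)] += 1
        reps: tuple[str, ...] = ()
        act_depth = max(depth[int(j)] for j in acts)
        if config.max_repressors and rng.random() < config.repressor_prob:
            # repressors come from genes switching on well after the
            # activators (two cascade levels down), so the target is
            # transiently expressed with a wide on-window rather than
            # barely firing
            anc_of_acts = set().union(*(ancestors[int(j)] | {int(j)}
                                        for j in acts))
            rep_pool = [j for j in range(config.n_roots, i)
                        if j not in anc_of_acts and j not in repressed
                        and depth[j] >= act_depth + 2]
            if rep_pool:
                n_rep = int(rng.integers(1, min(config.max_repressors,
                                                len(rep_pool)) + 1))
                reps = tuple(genes[j] for j in rng.choice(rep_pool, size=n_rep,
                                                          replace=False))
        rules[g] = BooleanRule(target=g,
                               activators=tuple(genes[int(j)] for j in acts),
                               repressors=reps)
        reg_idx = [int(j) for j in acts] + [genes.index(r) for r in reps]
        ancestors[i] = set(reg_idx).union(*(ancestors[j] for j in reg_idx))
        depth[i] = 1 + act_depth
        if reps:
            repressed.add(i)
    return GrnModel(genes=genes, rules=rules,
                    provenance={"generator_seed": config.seed})


def simulate_to_expression(model: GrnModel, config: SyntheticConfig,
                           rng: np.random.Generator | None = None
                           ) -> tuple[ExpressionDataset, BinarizedDataset]:
    """Sample cells from an asynchronous ensemble of the model.

    Returns the noisy expression matrix plus the ground-truth binary calls
    of the sampled states (thresholds are the lognormal-midpoint, for
    reference only).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    genes = model.genes
    init = {g: 1 if i < config.n_roots else 0 for i, g in enumerate(genes)}
    ens = simulate_ensemble(model, [init], n_traj=config.n_traj,
                            max_steps=config.steps,
                            seed=int(rng.integers(2 ** 31)))
    # sample (trajectory, step) uniformly over the padded horizon so the
    # attractor region is as populated as the transient
    horizon = config.steps
    states = np.empty((config.n_cells, len(genes)), dtype=np.int8)
    pseudo = np.empty(config.n_cells)
    for c in range(config.n_cells):
        t = ens.trajectories[rng.integers(len(ens.trajectories))]
        step = int(rng.integers(horizon + 1))
        s = t.states[min(step, len(t.states) - 1)]
        states[c] = s
        pseudo[c] = ens.asp[s] + rng.normal(0.0, config.jitter_sd)
    on = np.exp(rng.normal(np.log(config.mean_on), config.sd_log, states.shape))
    off = np.exp(rng.normal(np.log(config.mean_off), config.sd_log, states.shape))
    values = np.where(states == 1, on, off)
    if config.dropout > 0:
        values = np.where(rng.random(states.shape) < config.dropout, 0.0, values)
    # the dataset contract is log-transformed normalized expression; the
    # lognormal draws play the role of normalized counts
    values = np.log1p(values)
    cell_ids = [f"cell{c+1}" for c in range(config.n_cells)]
    data = ExpressionDataset(cell_ids=cell_ids, gene_ids=list(genes),
                             values=values, pseudotime=pseudo)
    order = np.argsort(pseudo, kind="stable")
    tau = (config.mean_off + config.mean_on) / 2.0
    truth_calls = BinarizedDataset(
        cell_ids=[cell_ids[i] for i in order], gene_ids=list(genes),
        calls=states[order],
        thresholds=np.full(len(genes), tau),
        mu_off=np.full(len(genes), config.mean_off),
        mu_on=np.full(len(genes), config.mean_on),
        method="ground-truth", pseudotime=pseudo[order])
    return data, truth_calls


def recovery_metrics(inferred: GrnModel, truth: GrnModel,
                     signed: bool = False,
                     include_self_loops: bool = True) -> dict[str, float]:
    """Edge precision/recall plus the fraction of exactly recovered rules."""
    shared = set(inferred.genes) & set(truth.genes)
    if not shared:
        raise ValueError("no shared genes between inferred and truth models")

    def edges(m: GrnModel) -> set:
        out = m.edge_set(signed=signed)
        out = {e for e in out if e[0] in shared and e[1] in shared}
        if not include_self_loops:
            out = {e for e in out if e[0] != e[1]}
        return out

    inf_e, tru_e = edges(inferred), edges(truth)
    tp = len(inf_e & tru_e)
    precision = tp / len(inf_e) if inf_e else 0.0
    recall = tp / len(tru_e) if tru_e else 0.0
    exact = sum(int(inferred.rules[g] == truth.rules[g]) for g in shared)
    return {"precision": precision, "recall": recall,
            "rule_exact_fraction": exact / len(shared),
            "n_inferred_edges": float(len(inf_e)),
            "n_truth_edges": float(len(tru_e))}
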