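"""Asynchronous Boolean simulation with clamping perturbations.

At every discrete step one uniformly chosen non-clamped gene is updated
through its rule, giving stochastic trajectories.  Knockout clamps a gene
to 0, overexpression to 1; clamped genes are excluded from the update draw
and never change.  A *fixed point* is a state every non-clamped rule maps
to itself — the model's steady-state attractors.  Ensemble statistics:

* ``average_exp`` — per-step, per-gene mean state over trajectories
  (absorbed trajectories are padded with their fixed point), in [0, 1];
* ``asp`` — the average simulation step of each distinct visited state:
  first-visit step normalized by trajectory length, averaged over the
  trajectories that visit it; an absorbing state scores 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .logic import BooleanRule, GrnModel
from .preprocess import BinarizedDataset

__all__ = [
    "Perturbation", "Trajectory", "SimulationEnsemble",
    "async_step", "derive_initial_states", "simulate_ensemble",
    "find_fixed_points", "systematic_perturbation_scan", "perturb_link",
    "EXHAUSTIVE_LIMIT",
]

EXHAUSTIVE_LIMIT = 24  # genes; beyond this, fixed points come from sampling


@dataclass(frozen=True)
class Perturbation:
    """Gene clamps (KO -> 0, OE -> 1) and deleted regulatory links."""

    clamps: tuple[tuple[str, int], ...] = ()
    removed_edges: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        names = [g for g, _ in self.clamps]
        if len(set(names)) != len(names):
            raise ValueError("a gene may appear at most once in clamps")
        for _, v in self.clamps:
            if v not in (0, 1):
                raise ValueError("clamp values must be 0 (KO) or 1 (OE)")

    @property
    def clamp_map(self) -> dict[str, int]:
        return dict(self.clamps)

    @classmethod
    def knockouts(cls, *genes: str) -> "Perturbation":
        return cls(clamps=tuple((g, 0) for g in genes))

    @classmethod
    def overexpressions(cls, *genes: str) -> "Perturbation":
        return cls(clamps=tuple((g, 1) for g in genes))

    def label(self) -> str:
        parts = [f"{'KO' if v == 0 else 'OE'}:{g}" for g, v in self.clamps]
        parts += [f"del:{r}->{t}" for r, t in self.removed_edges]
        return "+".join(parts) if parts else "wild-type"


@dataclass
class Trajectory:
    states: list[tuple[int, ...]]
    absorbed: bool

    @property
    def length(self) -> int:
        """Steps until absorption (or the step budget)."""
        return len(self.states) - 1

    @property
    def terminal(self) -> tuple[int, ...]:
        return self.states[-1]


@dataclass
class SimulationEnsemble:
    genes: list[str]
    trajectories: list[Trajectory]
    average_exp: pd.DataFrame          # steps x genes, values in [0, 1]
    asp: dict[tuple[int, ...], float]  # distinct state -> average simulation step
    seed: int | None
    perturbation: Perturbation

    @property
    def n_absorbed(self) -> int:
        return sum(t.absorbed for t in self.trajectories)

    def terminal_states(self) -> set[tuple[int, ...]]:
        return {t.terminal for t in self.trajectories}


def _prepare(model: GrnModel, perturbation: Perturbation | None
             ) -> tuple[GrnModel, dict[str, int]]:
    pert = perturbation or Perturbation()
    for g, _ in pert.clamps:
        if g not in model.rules:
            raise KeyError(f"clamped gene {g!r} not in model")
    m = model
    for reg, tgt in pert.removed_edges:
        m = perturb_link(m, reg, tgt)
    return m, pert.clamp_map


def async_step(model: GrnModel, state: dict[str, int], rng: np.random.Generator,
               perturbation: Perturbation | None = None) -> dict[str, int]:
    """Update one uniformly chosen non-clamped gene; clamped genes never move."""
    model, clamps = _prepare(model, perturbation)
    free = [g for g in model.genes if g not in clamps]
    if not free:
        return dict(state)
    gene = free[rng.integers(len(free))]
    new = dict(state)
    new[gene] = model.rules[gene].evaluate(state)
    return new


def derive_initial_states(binary: BinarizedDataset, genes: list[str],
                          n_earliest: int = 20,
                          noisy_genes: list[str] = ()) -> list[dict[str, int]]:
    """Initial simulation states from the earliest cells.

    The base state is the majority binarized call over the ``n_earliest``
    lowest-pseudo-time cells (an exact tie counts as on); each gene marked
    noisy is crossed with both values, giving 2^k distinct states.
    """
    unknown = [g for g in noisy_genes if g not in genes]
    if unknown:
        raise KeyError(f"noisy gene(s) not in model: {unknown}")
    col = {g: j for j, g in enumerate(binary.gene_ids)}
    head = binary.calls[:max(1, min(n_earliest, binary.n_cells))]
    base = {g: int(head[:, col[g]].mean() >= 0.5) for g in genes}
    noisy = sorted(set(noisy_genes))
    states = []
    for combo in itertools.product((0, 1), repeat=len(noisy)):
        s = dict(base)
        s.update(dict(zip(noisy, combo)))
        states.append(s)
    return states


def simulate_ensemble(model: GrnModel, initial_states: list[dict[str, int]],
                      n_traj: int = 100, max_steps: int = 200,
                      perturbation: Perturbation | None = None,
                      seed: int | None = None) -> SimulationEnsemble:
    """Run an ensemble of asynchronous trajectories and summarize it.

    Each trajectory starts from a uniformly chosen initial state (clamps
    applied first) and runs until a fixed point or ``max_steps``.  Absorbed
    trajectories are padded with their fixed point when averaging.
    """
    if n_traj < 1 or max_steps < 1:
        raise ValueError("n_traj and max_steps must be >= 1")
    if not initial_states:
        raise ValueError("at least one initial state is required")
    model, clamps = _prepare(model, perturbation)
    genes = model.genes
    rng = np.random.default_rng(seed)
    free = [g for g in genes if g not in clamps]
    trajectories: list[Trajectory] = []
    for _ in range(n_traj):
        init = dict(initial_states[rng.integers(len(initial_states))])
        init.update(clamps)
        state = init
        states = [tuple(state[g] for g in genes)]
        absorbed = model.is_fixed_point(state, clamps)
        for _ in range(max_steps):
            if absorbed:
                break
            gene = free[rng.integers(len(free))]
            nxt = dict(state)
            nxt[gene] = model.rules[gene].evaluate(state)
            state = nxt
            states.append(tuple(state[g] for g in genes))
            absorbed = model.is_fixed_point(state, clamps)
        trajectories.append(Trajectory(states=states, absorbed=absorbed))

    horizon = max(len(t.states) for t in trajectories)
    acc = np.zeros((horizon, len(genes)))
    for t in trajectories:
        arr = np.asarray(t.states, dtype=float)
        if len(t.states) < horizon:  # pad absorbed trajectories with the fixed point
            pad = np.repeat(arr[-1:], horizon - len(t.states), axis=0)
            arr = np.vstack([arr, pad])
        acc += arr
    average_exp = pd.DataFrame(acc / len(trajectories), columns=genes)
    average_exp.index.name = "step"

    visits: dict[tuple[int, ...], list[float]] = {}
    for t in trajectories:
        L = max(t.length, 1)
        seen: dict[tuple[int, ...], int] = {}
        for step, s in enumerate(t.states):
            if s not in seen:
                seen[s] = step
        for s, step in seen.items():
            x = 1.0 if (t.absorbed and s == t.terminal and t.length == 0) else step / L
            visits.setdefault(s, []).append(x)
    asp = {s: float(np.mean(v)) for s, v in visits.items()}
    return SimulationEnsemble(genes=list(genes), trajectories=trajectories,
                              average_exp=average_exp, asp=asp, seed=seed,
                              perturbation=perturbation or Perturbation())


def find_fixed_points(model: GrnModel,
                      perturbation: Perturbation | None = None,
                      n_traj: int = 1000, max_steps: int = 500,
                      seed: int = 0) -> list[dict[str, int]]:
    """All steady states of the (possibly perturbed) model.

    Exhaustive over the 2^m states of the non-clamped genes for m <=
    EXHAUSTIVE_LIMIT; larger models fall back to collecting terminal states
    of a simulation ensemble (flagged non-exhaustive via a warning).
    """
    model, clamps = _prepare(model, perturbation)
    genes = model.genes
    free = [g for g in genes if g not in clamps]
    if len(free) > EXHAUSTIVE_LIMIT:
        import warnings
        warnings.warn("model too large for exhaustive scan; "
                      "returning terminal states of a simulation ensemble "
                      "(non-exhaustive)")
        init = [{g: clamps.get(g, 0) for g in genes}]
        ens = simulate_ensemble(model, init, n_traj=n_traj, max_steps=max_steps,
                                perturbation=perturbation, seed=seed)
        found = {t.terminal for t in ens.trajectories if t.absorbed}
        return [dict(zip(genes, s)) for s in sorted(found)]

    m = len(free)
    grid = np.zeros((2 ** m, len(genes)), dtype=np.int8)
    if m:
        bits = ((np.arange(2 ** m)[:, None] >> np.arange(m - 1, -1, -1)) & 1)
        for j, g in enumerate(free):
            grid[:, genes.index(g)] = bits[:, j]
    for g, v in clamps.items():
        grid[:, genes.index(g)] = v
    col = {g: j for j, g in enumerate(genes)}
    stable = np.ones(grid.shape[0], dtype=bool)
    for g in free:
        rule = model.rules[g]
        out = _vector_rule(rule, grid, col)
        stable &= out == grid[:, col[g]].astype(bool)
    return [dict(zip(genes, map(int, row))) for row in grid[stable]]


def _vector_rule(rule: BooleanRule, grid: np.ndarray, col: dict[str, int]) -> np.ndarray:
    if rule.constant is not None:
        return np.full(grid.shape[0], bool(rule.constant))
    A = grid[:, [col[a] for a in rule.activators]].astype(bool)
    active = A.all(axis=1) if rule.act_op == "and" else A.any(axis=1)
    if rule.repressors:
        R = grid[:, [col[r] for r in rule.repressors]].astype(bool)
        rep = R.any(axis=1) if rule.rep_op == "or" else R.all(axis=1)
        active &= ~rep
    return active


def systematic_perturbation_scan(model: GrnModel, order: int = 1,
                                 reference=None) -> pd.DataFrame:
    """Fixed points under every KO/OE clamp of the given order.

    Order 1 yields 2n rows; order 2 all gene pairs with the four clamp-sign
    combinations (4*C(n,2) rows).  With a reference profile set, each row
    also reports the best attractor-to-reference similarity per state.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    perts: list[Perturbation] = []
    if order == 1:
        for g in model.genes:
            perts.append(Perturbation(clamps=((g, 0),)))
            perts.append(Perturbation(clamps=((g, 1),)))
    else:
        for a, b in itertools.combinations(model.genes, 2):
            for va, vb in itertools.product((0, 1), repeat=2):
                perts.append(Perturbation(clamps=((a, va), (b, vb))))
    rows = []
    for pert in perts:
        fps = find_fixed_points(model, pert)
        row = {
            "perturbation": pert.label(),
            "n_fixed_points": len(fps),
            "fixed_points": ";".join(
                "".join(str(s[g]) for g in model.genes) for s in fps),
        }
        if reference is not None:
            from .evaluate import state_similarity
            for name in reference.state_names:
                prof = reference.profile(name)
                row[f"best_similarity_{name}"] = max(
                    (state_similarity(fp, prof) for fp in fps), default=float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def perturb_link(model: GrnModel, regulator: str, target: str) -> GrnModel:
    """Delete one regulatory link from the target's rule.

    Removing the last activator collapses the rule to constant 0 (every
    activator is necessary, so nothing can fire it); the rule is flagged.
    """
    if target not in model.rules:
        raise KeyError(f"unknown target gene {target!r}")
    rule = model.rules[target]
    if regulator not in rule.regulators:
        raise ValueError(f"edge {regulator}->{target} not present in the model")
    return model.with_rule(rule.without_edge(regulator))
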