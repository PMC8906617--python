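"""Candidate interaction network: MI scoring, sign assignment, hierarchy filter.

The gene hierarchy orders genes by the pseudo-time position where their
smoothed on/off density first crosses 0.5 (a *transition point*); genes
that are on throughout sit at the top (earliest possible regulators), genes
never on at the bottom.  Only pairs whose regulator transitions no later
than the target are admissible — a causal-ordering filter.

Pair dependence is scored with a conditional-resampled mutual information
on a 2-D histogram: occupied regulator bins are given equal weight so the
estimate is not dominated by the most populated expression regime, and the
score is symmetrized by taking the larger of the two directions.  The sign
of an interaction comes from the Pearson correlation; pairs whose |r| falls
below a permissive threshold are discarded as sign-ambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionDataset
from .preprocess import DensityProfile

__all__ = [
    "TransitionEntry", "GeneHierarchy", "MIEstimate", "InteractionCandidate",
    "CandidateNetwork", "transition_points", "rank_genes", "pairwise_mi",
    "assign_sign", "build_candidate_network",
]


@dataclass(frozen=True)
class TransitionEntry:
    """Density threshold crossings for one gene.

    ``primary`` is the index of the first crossing; -inf for genes whose
    density is >= 0.5 everywhere (always on, top of the hierarchy), +inf for
    genes never reaching 0.5 (bottom).
    """

    gene: str
    transitions: tuple[tuple[int, str], ...]  # (index, "low->high" | "high->low")
    primary: float


@dataclass
class GeneHierarchy:
    """Genes ordered by primary transition point (1 = most regulatory potential)."""

    order: list[str]
    ranks: dict[str, int]
    entries: dict[str, TransitionEntry]

    def primary(self, gene: str) -> float:
        return self.entries[gene].primary

    def admits(self, regulator: str, target: str) -> bool:
        """Hierarchy filter: regulator must transition no later than target."""
        return self.primary(regulator) <= self.primary(target)


@dataclass(frozen=True)
class MIEstimate:
    """Conditional-resampled MI between two genes, in bits."""

    value: float
    grid: int
    h_y: float
    h_y_given_x: float
    n_occupied: int


@dataclass(frozen=True)
class InteractionCandidate:
    regulator: str
    target: str
    mi: float           # bits; symmetric pair score
    correlation: float
    sign: str           # "+" or "-"
    autoregulation: bool = False


@dataclass
class CandidateNetwork:
    """Directed, signed, MI-weighted candidate edges under the hierarchy filter."""

    genes: list[str]
    edges: dict[tuple[str, str], InteractionCandidate] = field(default_factory=dict)

    def add(self, cand: InteractionCandidate) -> None:
        key = (cand.regulator, cand.target)
        if key in self.edges:
            raise ValueError(f"duplicate candidate edge {key}")
        self.edges[key] = cand

    def activators_of(self, gene: str) -> list[str]:
        return sorted(r for (r, t), c in self.edges.items()
                      if t == gene and c.sign == "+")

    def repressors_of(self, gene: str) -> list[str]:
        return sorted(r for (r, t), c in self.edges.items()
                      if t == gene and c.sign == "-")

    def mi_weight(self, regulator: str, target: str) -> float:
        return self.edges[(regulator, target)].mi

    def counts(self, gene: str) -> tuple[int, int]:
        """(n candidate activators, n candidate repressors)."""
        return len(self.activators_of(gene)), len(self.repressors_of(gene))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"regulator": c.regulator, "target": c.target, "sign": c.sign,
             "mi_bits": c.mi, "correlation": c.correlation,
             "autoregulation": c.autoregulation}
            for c in self.edges.values()]
        return pd.DataFrame(rows, columns=["regulator", "target", "sign",
                                           "mi_bits", "correlation",
                                           "autoregulation"])


def transition_points(gene: str, density: np.ndarray) -> TransitionEntry:
    """Threshold a density trace at 0.5 and record the crossings."""
    density = np.asarray(density, dtype=float)
    high = density >= 0.5
    idx = np.flatnonzero(high[1:] != high[:-1]) + 1
    transitions = tuple(
        (int(i), "low->high" if high[i] else "high->low") for i in idx)
    if transitions:
        primary = float(transitions[0][0])
    else:
        primary = -math.inf if high.all() else math.inf
    return TransitionEntry(gene=gene, transitions=transitions, primary=primary)


def rank_genes(entries: list[TransitionEntry]) -> GeneHierarchy:
    """Ascending sort by primary transition point; ties break on gene name."""
    ordered = sorted(entries, key=lambda e: (e.primary, e.gene))
    return GeneHierarchy(
        order=[e.gene for e in ordered],
        ranks={e.gene: i + 1 for i, e in enumerate(ordered)},
        entries={e.gene: e for e in entries})


def hierarchy_from_density(profile: DensityProfile) -> GeneHierarchy:
    return rank_genes([
        transition_points(g, profile.gene_density(g)) for g in profile.gene_ids])


def pairwise_mi(x: np.ndarray, y: np.ndarray, grid: int = 20,
                min_count: int = 3) -> MIEstimate:
    """Symmetric conditional-resampled MI (bits) on a grid x grid histogram.

    Each direction computes I = H(Y) - H(Y|X) on the *resampled* joint that
    puts uniform mass on occupied X columns (columns holding fewer than
    ``min_count`` points are ignored); the pair score is the larger
    direction.  Constant vectors score 0 by convention.
    """
    if grid < 2:
        raise ValueError("grid must be >= 2")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    fwd = _directional_mi(x, y, grid, min_count)
    rev = _directional_mi(y, x, grid, min_count)
    return fwd if fwd.value >= rev.value else rev


def _directional_mi(x: np.ndarray, y: np.ndarray, grid: int,
                    min_count: int) -> MIEstimate:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return MIEstimate(0.0, grid, 0.0, 0.0, 0)
    counts, _, _ = np.histogram2d(x, y, bins=grid,
                                  range=[[x.min(), x.max()], [y.min(), y.max()]])
    col_tot = counts.sum(axis=1)
    occupied = col_tot >= min_count
    if not occupied.any():
        occupied = col_tot > 0
    cond = counts[occupied] / col_tot[occupied, None]   # p(y | x-bin)
    with np.errstate(divide="ignore", invalid="ignore"):
        h_cols = -np.nansum(np.where(cond > 0, cond * np.log2(cond), 0.0), axis=1)
    # Miller-Madow bias correction: a plug-in entropy from n samples over m
    # occupied bins underestimates by ~(m-1)/(2n ln 2); uncorrected, the
    # conditional entropies (each from ~n/grid samples) are biased low much
    # more strongly than H(Y), inflating the MI of independent pairs
    m_cols = (cond > 0).sum(axis=1)
    h_cols = h_cols + (m_cols - 1) / (2 * col_tot[occupied] * np.log(2))
    h_y_given_x = float(h_cols.mean())
    marg = cond.mean(axis=0)                            # resampled p(y)
    nz = marg > 0
    h_y = float(-(marg[nz] * np.log2(marg[nz])).sum()
                + (int(nz.sum()) - 1) / (2 * x.size * np.log(2)))
    return MIEstimate(max(h_y - h_y_given_x, 0.0), grid, h_y, h_y_given_x,
                      int(occupied.sum()))


def assign_sign(x: np.ndarray, y: np.ndarray,
                threshold: float = 0.05) -> str | None:
    """Interaction sign from Pearson correlation.

    Returns '+' (c >= 0), '-' (c < 0), or None when |c| < threshold or a
    vector has zero variance (sign-ambiguous pairs are dropped).
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return None
    c = float(((x * y).mean() - x.mean() * y.mean()) / (sx * sy))
    if abs(c) < threshold:
        return None
    return "+" if c >= 0 else "-"


def build_candidate_network(data: ExpressionDataset, hierarchy: GeneHierarchy,
                            sign_threshold: float = 0.05, grid: int = 20,
                            allow_autoregulation: bool = True) -> CandidateNetwork:
    """All admissible signed pairs plus conditional self-activations.

    An ordered pair (r, t) becomes a candidate when the hierarchy admits it
    and the correlation sign is unambiguous.  With ``allow_autoregulation``,
    genes left with fewer than two candidate activators get a self-activation
    candidate carrying MI weight 0 (so rule selection includes it only when
    necessary).
    """
    genes = list(data.gene_ids)
    net = CandidateNetwork(genes=genes)
    X = data.values
    idx = {g: j for j, g in enumerate(genes)}
    mi_cache: dict[frozenset, float] = {}
    for a in genes:
        for b in genes:
            if a == b or not hierarchy.admits(a, b):
                continue
            sign = assign_sign(X[:, idx[a]], X[:, idx[b]], sign_threshold)
            if sign is None:
                continue
            key = frozenset((a, b))
            if key not in mi_cache:
                mi_cache[key] = pairwise_mi(X[:, idx[a]], X[:, idx[b]], grid).value
            corr = float(np.corrcoef(X[:, idx[a]], X[:, idx[b]])[0, 1])
            net.add(InteractionCandidate(regulator=a, target=b, mi=mi_cache[key],
                                         correlation=corr, sign=sign))
    if allow_autoregulation:
        for g in genes:
            n_act, _ = net.counts(g)
            if n_act < 2:
                net.add(InteractionCandidate(
                    regulator=g, target=g, mi=0.0, correlation=1.0,
                    sign="+", autoregulation=True))
    return net
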