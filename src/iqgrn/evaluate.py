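"""Benchmarking an inferred GRN: attractor-vs-reference similarity,
capture of experimentally reported interactions, and MI-weighted AUPRC.

A known interaction is captured *directly* when the regulator appears in
the target's selected rule, *indirectly* when a directed path through at
most ``max_path`` inferred edges connects them (the number of intermediate
genes on the shortest such path is reported), and *missed* otherwise.
Inferred edges not in the reference set are *proposed-only* — candidate
novel interactions rather than errors, since curated networks are
incomplete.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .io import KnownNetwork, ReferenceProfileSet
from .logic import GrnModel

__all__ = [
    "NetworkComparison", "state_similarity", "attractor_similarity",
    "compare_known_network", "auprc", "rank_model_edges",
]


def state_similarity(state: Mapping[str, int], profile: Mapping[str, int]) -> float:
    """Percent of shared genes with matching on/off values."""
    shared = [g for g in state if g in profile]
    if not shared:
        raise ValueError("state and profile share no genes")
    match = sum(int(bool(state[g]) == bool(profile[g])) for g in shared)
    return 100.0 * match / len(shared)


def attractor_similarity(attractors: list[Mapping[str, int]],
                         reference: ReferenceProfileSet) -> pd.DataFrame:
    """Attractors x reference-states similarity matrix (percent)."""
    rows = []
    for i, att in enumerate(attractors):
        rows.append({name: state_similarity(att, reference.profile(name))
                     for name in reference.state_names})
    out = pd.DataFrame(rows, columns=reference.state_names)
    out.index.name = "attractor"
    return out


@dataclass
class NetworkComparison:
    """Per-edge capture table plus summary fractions."""

    table: pd.DataFrame          # known edges: regulator, target, status, ...
    proposed_only: pd.DataFrame  # inferred edges absent from the known set
    n_known: int
    n_direct: int
    n_indirect: int
    n_missed: int

    @property
    def direct_fraction(self) -> float:
        return self.n_direct / self.n_known if self.n_known else float("nan")

    @property
    def capture_fraction(self) -> float:
        """Direct + indirect over known edges on the shared gene set."""
        if not self.n_known:
            return float("nan")
        return (self.n_direct + self.n_indirect) / self.n_known


def compare_known_network(model: GrnModel, known: KnownNetwork,
                          max_path: int = 3,
                          require_sign: bool = False) -> NetworkComparison:
    """Classify each known interaction as direct / indirect / missed.

    Only known edges whose two genes are both in the model are scored.
    ``require_sign`` additionally demands a matching sign for direct capture
    (unknown reference signs always match).
    """
    if max_path < 1:
        raise ValueError("max_path must be >= 1")
    inferred = model.edge_set(signed=True)
    inferred_pairs = {(r, t) for r, t, _ in inferred}
    graph = model.to_digraph()
    genes = set(model.genes)
    rows = []
    n_direct = n_indirect = n_missed = 0
    for reg, tgt, sign in known.edges:
        if reg not in genes or tgt not in genes:
            continue
        direct = ((reg, tgt) in inferred_pairs if not require_sign or sign == "?"
                  else (reg, tgt, sign) in inferred)
        status, k = "missed", None
        if direct:
            status = "direct"
            n_direct += 1
        else:
            try:
                plen = nx.shortest_path_length(graph, reg, tgt)
            except (nx.NetworkXNoPath, nx.NodeNotFound):
                plen = None
            if plen is not None and 2 <= plen <= max_path + 1:
                status, k = "indirect", plen - 1
                n_indirect += 1
            else:
                n_missed += 1
        rows.append({"regulator": reg, "target": tgt, "sign": sign,
                     "status": status, "n_intermediates": k})
    table = pd.DataFrame(rows, columns=["regulator", "target", "sign",
                                        "status", "n_intermediates"])
    known_pairs = known.pair_set()
    proposed = pd.DataFrame(
        [{"regulator": r, "target": t, "sign": s}
         for r, t, s in sorted(inferred) if (r, t) not in known_pairs],
        columns=["regulator", "target", "sign"])
    return NetworkComparison(table=table, proposed_only=proposed,
                             n_known=len(rows), n_direct=n_direct,
                             n_indirect=n_indirect, n_missed=n_missed)


def rank_model_edges(model: GrnModel) -> list[tuple[str, str, float]]:
    """Inferred edges ranked by their rule's average MI, best rank on ties.

    An edge appearing in several rules takes its highest score.  Ranking is
    descending by score with (regulator, target) lexicographic tie-break.
    """
    scores: dict[tuple[str, str], float] = {}
    for g in model.genes:
        rule = model.rules[g]
        w = rule.avg_mi if rule.avg_mi is not None else 0.0
        for reg in rule.regulators:
            key = (reg, g)
            scores[key] = max(scores.get(key, -np.inf), w)
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(r, t, s) for (r, t), s in ranked]


def auprc(model: GrnModel, truth: KnownNetwork,
          include_self_loops: bool = False) -> float:
    """Area under the precision-recall curve of the ranked inferred edges.

    Truth edges are restricted to the model's genes; every ordered gene
    pair not in the ranking counts as a non-prediction, so recall saturates
    at the fraction of truth the model proposes at all.  Step-wise area:
    sum of precision x recall-increment down the ranking.  Invariant to
    strictly monotone transformations of the scores.
    """
    genes = set(model.genes)
    truth_pairs = {(r, t) for r, t, _ in truth.edges
                   if r in genes and t in genes
                   and (include_self_loops or r != t)}
    if not truth_pairs:
        raise ValueError("no truth edges over the model's genes")
    ranked = [(r, t) for r, t, _ in rank_model_edges(model)
              if include_self_loops or r != t]
    tp = 0
    area = 0.0
    prev_recall = 0.0
    for i, pair in enumerate(ranked, start=1):
        if pair in truth_pairs:
            tp += 1
            recall = tp / len(truth_pairs)
            area += (recall - prev_recall) * (tp / i)
            prev_recall = recall
    return area
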