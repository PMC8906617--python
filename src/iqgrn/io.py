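"""Core data containers and plain-text readers/writers.

Formats: delimited expression matrix (cells as rows by default, header of
gene names, first column cell IDs; tab/comma auto-detected), pseudo-time TSV
(``cell_id``, ``t``), BoolNet-style rules text, JSON edge lists, binary
reference-profile TSVs and known-interaction edge lists.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .logic import BooleanRule, GrnModel, parse_rule_expression

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset", "ReferenceProfileSet", "KnownNetwork",
    "load_expression", "write_expression",
    "write_grn", "read_grn",
    "load_reference_profiles", "write_reference_profiles",
    "load_known_network", "write_known_network",
]


@dataclass
class ExpressionDataset:
    """A pseudo-time-ordered cells x genes expression matrix.

    ``values`` holds non-negative library-normalized, log-transformed
    expression; ``pseudotime`` one scalar per cell in an arbitrary monotone
    unit.  Construction sorts cells by non-decreasing pseudo-time (stable,
    so input order breaks ties); genes are never reordered.
    """

    cell_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    pseudotime: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells or len(self.pseudotime) != n_cells:
            raise ValueError("cell_ids/pseudotime length must match matrix rows")
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length must match matrix columns")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell IDs")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene IDs")
        neg = np.argwhere(self.values < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative expression at cell {self.cell_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}: {self.values[i, j]}")
        order = np.argsort(self.pseudotime, kind="stable")
        if not np.array_equal(order, np.arange(n_cells)):
            self.values = self.values[order]
            self.pseudotime = self.pseudotime[order]
            self.cell_ids = [self.cell_ids[i] for i in order]

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)

    def subset_genes(self, genes: list[str]) -> "ExpressionDataset":
        missing = [g for g in genes if g not in self.gene_ids]
        if missing:
            raise KeyError(f"genes not in dataset: {missing}")
        idx = [self.gene_ids.index(g) for g in genes]
        return ExpressionDataset(
            cell_ids=list(self.cell_ids), gene_ids=list(genes),
            values=self.values[:, idx].copy(), pseudotime=self.pseudotime.copy())

    def with_values(self, values: np.ndarray) -> "ExpressionDataset":
        return ExpressionDataset(
            cell_ids=list(self.cell_ids), gene_ids=list(self.gene_ids),
            values=np.asarray(values, dtype=float), pseudotime=self.pseudotime.copy())


@dataclass
class ReferenceProfileSet:
    """Binary expression profiles of named reference cell states."""

    state_names: list[str]
    gene_ids: list[str]
    profiles: np.ndarray  # states x genes, entries in {0,1}

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=int)
        if self.profiles.shape != (len(self.state_names), len(self.gene_ids)):
            raise ValueError("profile matrix shape mismatch")
        if not np.isin(self.profiles, (0, 1)).all():
            raise ValueError("reference profiles must be binary")

    def profile(self, state: str) -> dict[str, int]:
        i = self.state_names.index(state)
        return dict(zip(self.gene_ids, self.profiles[i]))


@dataclass
class KnownNetwork:
    """Experimentally reported interactions used for benchmarking."""

    edges: list[tuple[str, str, str]]  # (regulator, target, sign in {+,-,?})
    allow_self_loops: bool = False
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for reg, tgt, sign in self.edges:
            if sign not in ("+", "-", "?"):
                raise ValueError(f"sign must be one of + - ?, got {sign!r}")
            if reg == tgt and not self.allow_self_loops:
                raise ValueError(f"self-loop {reg}->{tgt} (set allow_self_loops)")
            if (reg, tgt) in seen:
                raise ValueError(f"duplicate edge {reg}->{tgt}")
            seen.add((reg, tgt))
        universe = {g for e in self.edges for g in e[:2]}
        if self.genes:
            stray = universe - set(self.genes)
            if stray:
                raise ValueError(f"edges reference genes outside the universe: {sorted(stray)}")
        else:
            self.genes = sorted(universe)

    def pair_set(self) -> set[tuple[str, str]]:
        return {(r, t) for r, t, _ in self.edges}


def _read_delimited(path: str | Path, **kw) -> pd.DataFrame:
    """Read a delimited table, auto-detecting tab vs comma from the header."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, **kw)


def load_expression(matrix_path: str | Path, pseudotime_path: str | Path,
                    genes_as_rows: bool = False) -> ExpressionDataset:
    """Load an expression matrix plus a per-cell pseudo-time table.

    Cells present in only one of the two files are dropped with a logged
    warning; an empty intersection is fatal.  The returned dataset is sorted
    by non-decreasing pseudo-time.
    """
    mat = _read_delimited(matrix_path, index_col=0)
    if genes_as_rows:
        mat = mat.T
    pt = _read_delimited(pseudotime_path)
    if not {"cell_id", "t"} <= set(pt.columns):
        raise ValueError("pseudo-time file must have columns cell_id, t")
    pt = pt.set_index("cell_id")["t"]
    mat.index = mat.index.astype(str)
    pt.index = pt.index.astype(str)
    shared = [c for c in mat.index if c in pt.index]
    if not shared:
        raise ValueError("no cell IDs shared between matrix and pseudo-time table")
    dropped = (len(mat) - len(shared)) + (len(pt) - len(shared))
    if dropped:
        logger.warning("dropped %d cell(s) present in only one input file", dropped)
    mat = mat.loc[shared]
    return ExpressionDataset(
        cell_ids=list(mat.index), gene_ids=list(mat.columns.astype(str)),
        values=mat.to_numpy(dtype=float), pseudotime=pt.loc[shared].to_numpy(dtype=float))


def write_expression(data: ExpressionDataset, matrix_path: str | Path,
                     pseudotime_path: str | Path) -> None:
    data.to_frame().to_csv(matrix_path, sep="\t", index_label="cell_id")
    pd.DataFrame({"cell_id": data.cell_ids, "t": data.pseudotime}).to_csv(
        pseudotime_path, sep="\t", index=False)


# --- GRN model serialization -------------------------------------------------

def write_grn(model: GrnModel, path: str | Path,
              format: str = "rules_text") -> None:
    """Write a model as BoolNet-style rules text or a JSON edge list.

    The JSON form carries (regulator, target, sign, mi_weight) edges plus
    enough per-rule metadata (combinators, constants, scores) to round-trip
    exactly.
    """
    path = Path(path)
    if format == "rules_text":
        lines = ["targets, factors"]
        lines += [f"{g}, {model.rules[g].to_expression()}" for g in model.genes]
        path.write_text("\n".join(lines) + "\n")
    elif format == "edge_list_json":
        rules_meta = {}
        edges = []
        for g in model.genes:
            rule = model.rules[g]
            rules_meta[g] = {
                "act_op": rule.act_op, "rep_op": rule.rep_op,
                "constant": rule.constant, "agreement": rule.agreement,
                "avg_mi": rule.avg_mi, "flag": rule.flag,
            }
            for a in rule.activators:
                edges.append({"regulator": a, "target": g, "sign": "+",
                              "mi_weight": rule.avg_mi})
            for r in rule.repressors:
                edges.append({"regulator": r, "target": g, "sign": "-",
                              "mi_weight": rule.avg_mi})
        payload = {"genes": model.genes, "edges": edges,
                   "rules": rules_meta, "provenance": model.provenance}
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_grn(path: str | Path, format: str = "rules_text") -> GrnModel:
    path = Path(path)
    if format == "rules_text":
        lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
        if not lines or lines[0].lower().replace(" ", "") != "targets,factors":
            raise ValueError("rules file must start with a 'targets, factors' header")
        genes, rules = [], {}
        for ln in lines[1:]:
            target, _, expr = ln.partition(",")
            target = target.strip()
            genes.append(target)
            rules[target] = parse_rule_expression(target, expr.strip())
        return GrnModel(genes=genes, rules=rules)
    if format == "edge_list_json":
        payload = json.loads(path.read_text())
        rules: dict[str, BooleanRule] = {}
        acts: dict[str, list[str]] = {g: [] for g in payload["genes"]}
        reps: dict[str, list[str]] = {g: [] for g in payload["genes"]}
        for e in payload["edges"]:
            (acts if e["sign"] == "+" else reps)[e["target"]].append(e["regulator"])
        for g in payload["genes"]:
            meta = payload["rules"][g]
            rules[g] = BooleanRule(
                target=g, activators=tuple(acts[g]), repressors=tuple(reps[g]),
                act_op=meta["act_op"], rep_op=meta["rep_op"],
                constant=meta["constant"], agreement=meta.get("agreement"),
                avg_mi=meta.get("avg_mi"), flag=meta.get("flag"))
        return GrnModel(genes=list(payload["genes"]), rules=rules,
                        provenance=payload.get("provenance", {}))
    raise ValueError(f"unknown format {format!r}")


# --- reference profiles and known networks ----------------------------------

def load_reference_profiles(path: str | Path) -> ReferenceProfileSet:
    df = _read_delimited(path, index_col=0)
    return ReferenceProfileSet(
        state_names=list(df.index.astype(str)),
        gene_ids=list(df.columns.astype(str)),
        profiles=df.to_numpy(dtype=int))


def write_reference_profiles(ref: ReferenceProfileSet, path: str | Path) -> None:
    pd.DataFrame(ref.profiles, index=ref.state_names, columns=ref.gene_ids).to_csv(
        path, sep="\t", index_label="state")


def load_known_network(path: str | Path, allow_self_loops: bool = False) -> KnownNetwork:
    df = _read_delimited(path)
    cols = {c.lower(): c for c in df.columns}
    reg, tgt = cols.get("regulator"), cols.get("target")
    if reg is None or tgt is None:
        raise ValueError("known-network file must have regulator and target columns")
    sign_col = cols.get("sign")
    edges = []
    for _, row in df.iterrows():
        sign = str(row[sign_col]) if sign_col is not None else "?"
        edges.append((str(row[reg]), str(row[tgt]), sign if sign in "+-" else "?"))
    return KnownNetwork(edges=edges, allow_self_loops=allow_self_loops)


def write_known_network(net: KnownNetwork, path: str | Path) -> None:
    pd.DataFrame(net.edges, columns=["regulator", "target", "sign"]).to_csv(
        path, sep="\t", index=False)
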