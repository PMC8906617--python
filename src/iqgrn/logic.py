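"""Boolean update rules and executable GRN models.

A gene's next state is a conjunction of activators gated by a negated
disjunction of repressors::

    g(t+1) = (A1 & A2 & ... ) & !(R1 | R2 | ...)

i.e. every activator is necessary and any single repressor suffices to shut
the gene off.  A *relaxed* variant lets either group use the other
combinator.  Rules serialize to a BoolNet-compatible text dialect
(``targets, factors`` header; operators ``& | !`` and parentheses).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = ["BooleanRule", "GrnModel", "parse_rule_expression", "RuleParseError"]

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.-]*$")
_FORBIDDEN = set("&|!(),\t ")


def _check_gene_name(name: str) -> str:
    if not name or any(ch in _FORBIDDEN for ch in name) or not _NAME_RE.match(name):
        raise ValueError(f"gene name {name!r} contains rule-operator characters or is invalid")
    return name


@dataclass(frozen=True)
class BooleanRule:
    """One executable update rule for a target gene.

    ``constant`` (0 or 1) marks a degenerate rule with no regulators; such
    rules arise as fallbacks for genes with an empty candidate set.
    ``agreement`` (percent) and ``avg_mi`` (bits) are scoring annotations and
    do not take part in equality.
    """

    target: str
    activators: tuple[str, ...] = ()
    repressors: tuple[str, ...] = ()
    act_op: str = "and"   # combinator within the activator group
    rep_op: str = "or"    # combinator within the repressor group
    constant: int | None = None
    agreement: float | None = field(default=None, compare=False)
    avg_mi: float | None = field(default=None, compare=False)
    flag: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "activators", tuple(sorted(self.activators)))
        object.__setattr__(self, "repressors", tuple(sorted(self.repressors)))
        if set(self.activators) & set(self.repressors):
            raise ValueError(f"{self.target}: activators and repressors overlap")
        if self.act_op not in ("and", "or") or self.rep_op not in ("and", "or"):
            raise ValueError("combinators must be 'and' or 'or'")
        if self.constant is not None and (self.activators or self.repressors):
            raise ValueError("constant rule cannot have regulators")
        if self.constant is not None and self.constant not in (0, 1):
            raise ValueError("constant must be 0 or 1")

    @property
    def regulators(self) -> tuple[str, ...]:
        return self.activators + self.repressors

    def evaluate(self, state: Mapping[str, int]) -> int:
        """Evaluate the rule on a gene -> {0,1} state mapping."""
        if self.constant is not None:
            return self.constant
        acts = [bool(state[a]) for a in self.activators]
        if self.act_op == "and":
            active = all(acts)
        else:
            active = any(acts)
        if not active:
            return 0
        reps = [bool(state[r]) for r in self.repressors]
        if reps:
            repressed = any(reps) if self.rep_op == "or" else all(reps)
            if repressed:
                return 0
        return 1

    def without_edge(self, regulator: str) -> "BooleanRule":
        """Drop a regulator literal (link perturbation).

        Removing the last activator leaves nothing able to activate the gene
        (every activator is necessary, so an empty group cannot fire): the
        rule collapses to constant 0 and is flagged.
        """
        if regulator in self.activators:
            acts = tuple(a for a in self.activators if a != regulator)
            if not acts:
                return replace(self, activators=(), repressors=(), constant=0,
                               flag="no-activators-after-link-removal")
            return replace(self, activators=acts)
        if regulator in self.repressors:
            reps = tuple(r for r in self.repressors if r != regulator)
            return replace(self, repressors=reps)
        raise ValueError(f"{regulator} is not a regulator of {self.target}")

    def to_expression(self) -> str:
        """Render the factor side of the BoolNet-style line."""
        if self.constant is not None:
            return str(self.constant)
        op = {"and": " & ", "or": " | "}
        act = op[self.act_op].join(self.activators)
        if not self.repressors:
            return act
        rep = op[self.rep_op].join(self.repressors)
        return f"({act}) & !({rep})"

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return f"{self.target}, {self.to_expression()}"


class RuleParseError(ValueError):
    pass


# --- minimal recursive-descent parser for the emitted dialect ---------------

_TOKEN_RE = re.compile(r"\s*([A-Za-z_][A-Za-z0-9_.-]*|[01]|&|\||!|\(|\))")


def _tokenize(expr: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if not m:
            raise RuleParseError(f"cannot tokenize {expr[pos:]!r}")
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _Parser:
    """Precedence: ``!`` > ``&`` > ``|``.  AST nodes are tuples."""

    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.i = 0

    def peek(self) -> str | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise RuleParseError("unexpected end of expression")
        self.i += 1
        return tok

    def parse(self):
        node = self.parse_or()
        if self.peek() is not None:
            raise RuleParseError(f"trailing tokens at {self.tokens[self.i:]}")
        return node

    def parse_or(self):
        terms = [self.parse_and()]
        while self.peek() == "|":
            self.next()
            terms.append(self.parse_and())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def parse_and(self):
        terms = [self.parse_atom()]
        while self.peek() == "&":
            self.next()
            terms.append(self.parse_atom())
        return terms[0] if len(terms) == 1 else ("and", terms)

    def parse_atom(self):
        tok = self.next()
        if tok == "!":
            return ("not", self.parse_atom())
        if tok == "(":
            node = self.parse_or()
            if self.next() != ")":
                raise RuleParseError("unbalanced parentheses")
            return node
        if tok in ("0", "1"):
            return ("const", int(tok))
        if tok in ("&", "|", ")"):
            raise RuleParseError(f"unexpected token {tok!r}")
        return ("var", tok)


def _flatten(node, op: str) -> list:
    if isinstance(node, tuple) and node[0] == op:
        out = []
        for child in node[1]:
            out.extend(_flatten(child, op))
        return out
    return [node]


def _literal_group(node) -> tuple[tuple[str, ...], str]:
    """Interpret a node as a homogeneous group of plain literals."""
    for op in ("or", "and"):
        if isinstance(node, tuple) and node[0] == op:
            lits = _flatten(node, op)
            if not all(n[0] == "var" for n in lits):
                raise RuleParseError("nested logic beyond the supported rule family")
            return tuple(n[1] for n in lits), op
    if isinstance(node, tuple) and node[0] == "var":
        return (node[1],), "or"
    raise RuleParseError("expected a literal group")


def parse_rule_expression(target: str, expr: str) -> BooleanRule:
    """Parse a factor expression back into a :class:`BooleanRule`.

    Accepts exactly the family the model emits: a constant, an activator
    group, or ``(activators) & !(repressors)``.
    """
    ast = _Parser(_tokenize(expr)).parse()
    if ast[0] == "const":
        return BooleanRule(target=target, constant=ast[1])
    if ast[0] == "not":
        raise RuleParseError(f"{target}: rule with repressors only is outside the family")
    if ast[0] == "var":
        return BooleanRule(target=target, activators=(ast[1],))
    if ast[0] == "or":
        acts, _ = _literal_group(ast)
        return BooleanRule(target=target, activators=acts, act_op="or")
    # top-level AND: split off an optional single NOT group
    parts = _flatten(ast, "and")
    nots = [p for p in parts if isinstance(p, tuple) and p[0] == "not"]
    rest = [p for p in parts if not (isinstance(p, tuple) and p[0] == "not")]
    if len(nots) > 1:
        raise RuleParseError(f"{target}: more than one repressor group")
    if not rest:
        raise RuleParseError(f"{target}: no activators")
    if len(rest) == 1:
        acts, act_op = _literal_group(rest[0])
    else:
        if not all(p[0] == "var" for p in rest):
            raise RuleParseError(f"{target}: mixed activator structure")
        acts, act_op = tuple(p[1] for p in rest), "and"
    if len(acts) == 1:
        act_op = "and"
    if not nots:
        return BooleanRule(target=target, activators=acts, act_op=act_op)
    reps, rep_op = _literal_group(nots[0][1])
    if len(reps) == 1:
        rep_op = "or"
    return BooleanRule(target=target, activators=acts, repressors=reps,
                       act_op=act_op, rep_op=rep_op)


@dataclass
class GrnModel:
    """An executable Boolean GRN: one update rule per gene.

    ``provenance`` records thresholds, seeds and flags so a run can be
    replayed exactly.
    """

    genes: list[str]
    rules: dict[str, BooleanRule]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.genes) != set(self.rules):
            raise ValueError("model must carry exactly one rule per gene")
        for g in self.genes:
            _check_gene_name(g)
            for r in self.rules[g].regulators:
                if r not in self.rules:
                    raise ValueError(f"rule for {g} references unknown gene {r}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def edges(self) -> list[tuple[str, str, str]]:
        """Directed (regulator, target, sign) triples; '+' activator, '-' repressor."""
        out = []
        for g in self.genes:
            rule = self.rules[g]
            out.extend((a, g, "+") for a in rule.activators)
            out.extend((r, g, "-") for r in rule.repressors)
        return out

    def edge_set(self, signed: bool = False) -> set[tuple]:
        if signed:
            return set(self.edges())
        return {(r, t) for r, t, _ in self.edges()}

    def to_digraph(self) -> "nx.DiGraph":
        g = nx.DiGraph()
        g.add_nodes_from(self.genes)
        for r, t, sign in self.edges():
            g.add_edge(r, t, sign=sign)
        return g

    def step(self, state: Mapping[str, int]) -> dict[str, int]:
        """Synchronous full update (used for fixed-point checks, not simulation)."""
        return {g: self.rules[g].evaluate(state) for g in self.genes}

    def is_fixed_point(self, state: Mapping[str, int],
                       clamped: Iterable[str] = ()) -> bool:
        skip = set(clamped)
        return all(self.rules[g].evaluate(state) == state[g]
                   for g in self.genes if g not in skip)

    def with_rule(self, rule: BooleanRule) -> "GrnModel":
        rules = dict(self.rules)
        rules[rule.target] = rule
        return GrnModel(genes=list(self.genes), rules=rules,
                        provenance=dict(self.provenance))
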