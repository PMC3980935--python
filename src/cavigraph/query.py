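"""Boolean residue queries over cavities, and temporal statistics.

Cavities carry residue sets (the amino acids lining them). A query selects
cavities by their residues with a small boolean language::

    140 | 170             # OR  (the unicode '∨' also works)
    171 & 190             # AND
    (120-140) & (180-190) & 173
    !(171 & 190)          # NOT

An integer matches when the cavity's residue set contains it; a range
``lo-hi`` matches when the set contains any residue in [lo, hi]. Precedence
is NOT > AND > OR; parentheses group. Conjuncts are evaluated independently
(no requirement that overlapping ranges be satisfied by distinct residues).

Temporal statistics over a per-frame corpus of cavities: the presence
fraction of a query (fraction of frames with at least one matching cavity)
and the ranking of residues by how many (frame, cavity) pairs they line.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union


# ----------------------------------------------------------------------- AST

@dataclass(frozen=True)
class Term:
    residue: int


@dataclass(frozen=True)
class Range:
    lo: int
    hi: int

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise QuerySyntaxError(f"reversed range {self.lo}-{self.hi}")


@dataclass(frozen=True)
class And:
    operands: tuple["Query", ...]


@dataclass(frozen=True)
class Or:
    operands: tuple["Query", ...]


@dataclass(frozen=True)
class Not:
    operand: "Query"


Query = Union[Term, Range, And, Or, Not]


class QuerySyntaxError(ValueError):
    pass


# -------------------------------------------------------------------- parser

_TOKEN = re.compile(r"\s*(?:(\d+)|(∨|\|)|(&)|(!|¬)|(\()|(\))|(-))")


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            rest = text[pos:].lstrip()
            if not rest:
                break
            raise QuerySyntaxError(
                f"unexpected character {rest[0]!r} at position {pos}"
            )
        kinds = ("INT", "OR", "AND", "NOT", "LPAR", "RPAR", "DASH")
        for kind, group in zip(kinds, m.groups()):
            if group is not None:
                tokens.append((kind, group))
                break
        pos = m.end()
    return tokens


class _Parser:
    """Recursive descent over: expr := and ((∨||) and)* ;
    and := unary (& unary)* ; unary := ! unary | atom ;
    atom := INT (- INT)? | ( expr )"""

    def __init__(self, tokens: list[tuple[str, str]]):
        self.tokens = tokens
        self.i = 0

    def peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def eat(self, kind: str) -> str:
        if self.peek() != kind:
            got = self.tokens[self.i][1] if self.i < len(self.tokens) else "end of query"
            raise QuerySyntaxError(f"expected {kind} at token {self.i}, got {got!r}")
        value = self.tokens[self.i][1]
        self.i += 1
        return value

    def expr(self) -> Query:
        parts = [self.conj()]
        while self.peek() == "OR":
            self.eat("OR")
            parts.append(self.conj())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def conj(self) -> Query:
        parts = [self.unary()]
        while self.peek() == "AND":
            self.eat("AND")
            parts.append(self.unary())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def unary(self) -> Query:
        if self.peek() == "NOT":
            self.eat("NOT")
            return Not(self.unary())
        return self.atom()

    def atom(self) -> Query:
        if self.peek() == "LPAR":
            self.eat("LPAR")
            inner = self.expr()
            self.eat("RPAR")
            return inner
        lo = int(self.eat("INT"))
        if self.peek() == "DASH":
            self.eat("DASH")
            return Range(lo, int(self.eat("INT")))
        return Term(lo)


def parse_query(text: str) -> Query:
    """Parse a residue query; raises :class:`QuerySyntaxError` with the
    offending position on malformed input."""
    if not text or not text.strip():
        raise QuerySyntaxError("empty query")
    parser = _Parser(_tokenize(text))
    q = parser.expr()
    if parser.i != len(parser.tokens):
        raise QuerySyntaxError(
            f"trailing input starting at token {parser.i}: "
            f"{parser.tokens[parser.i][1]!r}"
        )
    return q


# ----------------------------------------------------------------- evaluation

def evaluate(query: Query | str, residues: Iterable[int]) -> bool:
    """Evaluate a query against a cavity's residue set."""
    if isinstance(query, str):
        query = parse_query(query)
    rset = residues if isinstance(residues, (set, frozenset)) else set(residues)
    return _eval(query, rset)


def _eval(q: Query, rset: set[int]) -> bool:
    if isinstance(q, Term):
        return q.residue in rset
    if isinstance(q, Range):
        return any(q.lo <= a <= q.hi for a in rset)
    if isinstance(q, And):
        return all(_eval(op, rset) for op in q.operands)
    if isinstance(q, Or):
        return any(_eval(op, rset) for op in q.operands)
    if isinstance(q, Not):
        return not _eval(q.operand, rset)
    raise TypeError(f"not a query node: {q!r}")


# Corpus: mapping frame_index -> sequence of objects with .graph_id and
# .residues (CavityGraph satisfies this), or -> sequence of (graph_id,
# residue set) pairs.

def _iter_corpus(per_frame_graphs: Mapping[int, Sequence]) -> Iterable[tuple[int, int, set[int]]]:
    for t in sorted(per_frame_graphs):
        for g in per_frame_graphs[t]:
            if isinstance(g, tuple):
                gid, residues = g
            else:
                gid, residues = g.graph_id, g.residues
            yield t, gid, set(residues or ())


def select(query: Query | str, per_frame_graphs: Mapping[int, Sequence]) -> set[tuple[int, int]]:
    """All (frame_index, graph_id) pairs whose residue set matches."""
    if isinstance(query, str):
        query = parse_query(query)
    return {
        (t, gid)
        for t, gid, residues in _iter_corpus(per_frame_graphs)
        if _eval(query, residues)
    }


def presence_fraction(query: Query | str, per_frame_graphs: Mapping[int, Sequence]) -> float:
    """Fraction of frames in which at least one cavity matches the query."""
    n_frames = len(per_frame_graphs)
    if n_frames == 0:
        return 0.0
    matched = {t for t, _ in select(query, per_frame_graphs)}
    return len(matched) / n_frames


def residue_occurrence_ranking(per_frame_graphs: Mapping[int, Sequence]) -> list[tuple[int, int]]:
    """Residues ranked by the number of (frame, cavity) pairs lining them.

    Descending by count; ties ascending by residue id.
    """
    counts: dict[int, int] = {}
    for _, _, residues in _iter_corpus(per_frame_graphs):
        for a in residues:
            counts[a] = counts.get(a, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
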