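"""Domain-architecture normalisation and a declarative rule mini-grammar.

Raw domtblout hits are noisy: envelopes overlap, and sub-threshold matches
abound. :func:`annotate` reduces them to one ordered, non-overlapping
architecture per protein under a fixed dominance order (higher bit score,
then lower i-evalue, then lower start). Family filters are then expressed
as small boolean rules over domain classes::

    has(Ferric_reduct) AND (has(FAD_binding_8) OR has(NAD_binding_6))
    count(Sod_Cu) >= 3
    order(PAS before Ferric_reduct)
    region(Ferric_reduct within [300, 600])

parsed by :func:`parse_rule` and evaluated by :func:`match_rule`, which
returns the verdict together with the indices of the domains that witnessed
it (the per-sequence evidence trail).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .config import PipelineConfig, RuleSet
from .seqio import DomainHit

__all__ = [
    "DomainAnnotation",
    "annotate",
    "count_domains",
    "parse_rule",
    "match_rule",
    "RuleParseError",
]


@dataclass
class DomainAnnotation:
    """Ordered, non-overlapping retained domains of one protein."""

    seq_id: str
    length: int
    # (domain name, accession, start, end, score), sorted by start
    domains: List[Tuple[str, str, int, int, float]] = field(default_factory=list)

    def classes(self, rules: RuleSet) -> List[Optional[str]]:
        return [rules.class_of(acc) for _, acc, _, _, _ in self.domains]

    def __len__(self) -> int:
        return len(self.domains)


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def annotate(
    hits: Sequence[DomainHit],
    seq_lengths: Dict[str, int],
    config: PipelineConfig,
    rules: RuleSet | None = None,
) -> Dict[str, DomainAnnotation]:
    """Normalise hits into one :class:`DomainAnnotation` per sequence.

    Hits with i-evalue above ``config.i_evalue_max`` are dropped. Among the
    survivors, overlaps greater than ``config.overlap_tolerance`` residues
    are resolved by dominance: higher bit score wins, ties broken by lower
    i-evalue then lower envelope start. Retained domains are sorted by
    start. Idempotent: annotating an annotation's own hits returns it.
    """
    per_seq: Dict[str, List[DomainHit]] = {}
    for h in hits:
        if h.seq_id not in seq_lengths:
            raise KeyError(f"hit on unknown sequence {h.seq_id!r}")
        if h.env_end > seq_lengths[h.seq_id]:
            raise ValueError(
                f"{h.seq_id}/{h.domain}: envelope end {h.env_end} exceeds "
                f"sequence length {seq_lengths[h.seq_id]}"
            )
        if h.i_evalue <= config.i_evalue_max:
            per_seq.setdefault(h.seq_id, []).append(h)

    out: Dict[str, DomainAnnotation] = {
        sid: DomainAnnotation(seq_id=sid, length=n) for sid, n in seq_lengths.items()
    }
    for sid, seq_hits in per_seq.items():
        ranked = sorted(seq_hits, key=lambda h: (-h.score, h.i_evalue, h.env_start))
        kept: List[DomainHit] = []
        for h in ranked:
            if all(
                _overlap(h.env_start, h.env_end, k.env_start, k.env_end)
                <= config.overlap_tolerance
                for k in kept
            ):
                kept.append(h)
        out[sid].domains = sorted(
            [(h.domain, h.accession, h.env_start, h.env_end, h.score) for h in kept],
            key=lambda d: (d[2], d[3]),
        )
    return out


def count_domains(ann: DomainAnnotation, cls: str, rules: RuleSet) -> int:
    """Number of retained domains whose accession belongs to class ``cls``."""
    accs = set(rules.accessions(cls))  # raises on unknown class
    return sum(1 for _, acc, _, _, _ in ann.domains if acc in accs)


# ---------------------------------------------------------------------------
# Rule expressions


class RuleParseError(ValueError):
    def __init__(self, message: str, pos: int):
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


@dataclass(frozen=True)
class Has:
    cls: str


@dataclass(frozen=True)
class Count:
    cls: str
    op: str  # '>=', '<=', '=='
    k: int


@dataclass(frozen=True)
class Order:
    first: str
    second: str


@dataclass(frozen=True)
class Region:
    cls: str
    start: int
    end: int


@dataclass(frozen=True)
class Not:
    child: object


@dataclass(frozen=True)
class And:
    children: tuple


@dataclass(frozen=True)
class Or:
    children: tuple


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<lbrack>\[)|(?P<rbrack>\])"
    r"|(?P<comma>,)|(?P<op>>=|<=|==)"
    r"|(?P<word>[A-Za-z_][A-Za-z0-9_]*)|(?P<int>\d+))"
)


def _tokenize(text: str):
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            if text[pos:].strip():
                raise RuleParseError(f"unexpected character {text[pos]!r}", pos)
            break
        kind = m.lastgroup
        tokens.append((kind, m.group(kind), m.start(kind)))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def _peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None, len(self.text))

    def _next(self):
        tok = self._peek()
        self.i += 1
        return tok

    def _expect(self, kind, value=None):
        k, v, p = self._next()
        if k != kind or (value is not None and v != value):
            raise RuleParseError(f"expected {value or kind}, found {v!r}", p)
        return v

    def parse(self):
        node = self._or()
        k, v, p = self._peek()
        if k is not None:
            raise RuleParseError(f"trailing input {v!r}", p)
        return node

    def _or(self):
        children = [self._and()]
        while self._peek()[:2] == ("word", "OR"):
            self._next()
            children.append(self._and())
        return children[0] if len(children) == 1 else Or(tuple(children))

    def _and(self):
        children = [self._not()]
        while self._peek()[:2] == ("word", "AND"):
            self._next()
            children.append(self._not())
        return children[0] if len(children) == 1 else And(tuple(children))

    def _not(self):
        if self._peek()[:2] == ("word", "NOT"):
            self._next()
            return Not(self._not())
        return self._atom()

    def _atom(self):
        k, v, p = self._next()
        if k == "lpar":
            node = self._or()
            self._expect("rpar")
            return node
        if k != "word":
            raise RuleParseError(f"expected predicate, found {v!r}", p)
        if v == "has":
            self._expect("lpar")
            cls = self._expect("word")
            self._expect("rpar")
            return Has(cls)
        if v == "count":
            self._expect("lpar")
            cls = self._expect("word")
            self._expect("rpar")
            op = self._expect("op")
            kk = int(self._expect("int"))
            return Count(cls, op, kk)
        if v == "order":
            self._expect("lpar")
            a = self._expect("word")
            self._expect("word", "before")
            b = self._expect("word")
            self._expect("rpar")
            return Order(a, b)
        if v == "region":
            self._expect("lpar")
            cls = self._expect("word")
            self._expect("word", "within")
            self._expect("lbrack")
            a = int(self._expect("int"))
            self._expect("comma")
            b = int(self._expect("int"))
            self._expect("rbrack")
            self._expect("rpar")
            return Region(cls, a, b)
        raise RuleParseError(f"unknown predicate {v!r}", p)


def parse_rule(text: str):
    """Parse a rule expression into its AST; errors carry a position."""
    return _Parser(text).parse()


def _indices(ann: DomainAnnotation, cls: str, rules: RuleSet) -> List[int]:
    accs = set(rules.accessions(cls))
    return [i for i, (_, acc, _, _, _) in enumerate(ann.domains) if acc in accs]


def _eval(node, ann: DomainAnnotation, rules: RuleSet) -> Tuple[bool, List[int]]:
    if isinstance(node, Has):
        idx = _indices(ann, node.cls, rules)
        return bool(idx), idx
    if isinstance(node, Count):
        idx = _indices(ann, node.cls, rules)
        n = len(idx)
        ok = {">=": n >= node.k, "<=": n <= node.k, "==": n == node.k}[node.op]
        return ok, idx if ok else []
    if isinstance(node, Order):
        ia = _indices(ann, node.first, rules)
        ib = _indices(ann, node.second, rules)
        for a in ia:
            for b in ib:
                if ann.domains[a][3] < ann.domains[b][2]:  # a ends before b starts
                    return True, [a, b]
        return False, []
    if isinstance(node, Region):
        hit = [
            i
            for i in _indices(ann, node.cls, rules)
            if ann.domains[i][2] >= node.start and ann.domains[i][3] <= node.end
        ]
        return bool(hit), hit
    if isinstance(node, Not):
        ok, _ = _eval(node.child, ann, rules)
        return (not ok), []
    if isinstance(node, And):
        witness: List[int] = []
        for ch in node.children:
            ok, w = _eval(ch, ann, rules)
            if not ok:
                return False, []
            witness.extend(w)
        return True, sorted(set(witness))
    if isinstance(node, Or):
        for ch in node.children:
            ok, w = _eval(ch, ann, rules)
            if ok:
                return True, w
        return False, []
    raise TypeError(f"unknown rule node {node!r}")


def match_rule(
    ann: DomainAnnotation, expr, rules: RuleSet | None = None
) -> Tuple[bool, List[int]]:
    """Evaluate a rule (text or AST) against an annotation.

    Returns (verdict, witness domain indices). The witness lists the
    retained-domain indices that satisfied the matched predicates; it is
    empty for a false verdict and for negations.
    """
    rules = rules or RuleSet()
    node = parse_rule(expr) if isinstance(expr, str) else expr
    return _eval(node, ann, rules)
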