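"""Boolean gene-protein-reaction (GPR) associations.

A GPR rule is a Boolean formula over gene identifiers built from AND, OR and
parentheses.  In its disjunctive normal form (DNF) every conjunction is one
*enzyme*: an alternative catalyst whose subunits are the conjoined genes
(isozymes are the OR-joined alternatives, complexes the AND-joined subunit
lists).  The DNF is the bridge between Boolean gene states and the
stoichiometric representation built by :mod:`gprflux.transform`.
"""

from __future__ import annotations

import itertools
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

__all__ = [
    "GPRError",
    "GPRParseError",
    "CapacityError",
    "Enzyme",
    "GPRAssociation",
    "parse_gpr",
    "to_dnf",
    "evaluate_gpr",
    "minimal_knockout_sets",
]

DEFAULT_DNF_CAP = 10_000
DEFAULT_KNOCKOUT_CAP = 100_000


class GPRError(ValueError):
    """Base class for GPR handling errors."""


class GPRParseError(GPRError):
    """Malformed GPR rule; carries the offending character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class CapacityError(GPRError):
    """A combinatorial expansion exceeded its configured cap."""


# ---------------------------------------------------------------------------
# expression tree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Var:
    gene: str

    def evaluate(self, active) -> bool:
        return self.gene in active

    def genes(self):
        yield self.gene

    def __str__(self) -> str:
        return self.gene


@dataclass(frozen=True)
class _And:
    children: tuple

    def evaluate(self, active) -> bool:
        return all(c.evaluate(active) for c in self.children)

    def genes(self):
        for c in self.children:
            yield from c.genes()

    def __str__(self) -> str:
        return "(" + " and ".join(str(c) for c in self.children) + ")"


@dataclass(frozen=True)
class _Or:
    children: tuple

    def evaluate(self, active) -> bool:
        return any(c.evaluate(active) for c in self.children)

    def genes(self):
        for c in self.children:
            yield from c.genes()

    def __str__(self) -> str:
        return "(" + " or ".join(str(c) for c in self.children) + ")"


# ---------------------------------------------------------------------------
# enzymes and associations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Enzyme:
    """One alternative catalyst: a multiset of subunit genes.

    ``subunits`` maps each gene to its copy number (how many times the gene
    product occurs in the complex).  Copy numbers default to 1; a gene written
    twice in one AND-clause yields copy number 2.  Boolean semantics only
    depend on the support :attr:`genes`.
    """

    _items: tuple  # sorted tuple of (gene, copies)

    def __init__(self, subunits):
        if isinstance(subunits, (Counter, dict)):
            items = tuple(sorted(subunits.items()))
        else:
            items = tuple(sorted(Counter(subunits).items()))
        if not items:
            raise GPRError("an enzyme must have at least one subunit")
        if any(c < 1 for _, c in items):
            raise GPRError("subunit copy numbers must be >= 1")
        object.__setattr__(self, "_items", items)

    @property
    def subunits(self) -> dict:
        return dict(self._items)

    @property
    def genes(self) -> frozenset:
        return frozenset(g for g, _ in self._items)

    @property
    def total_copies(self) -> int:
        return sum(c for _, c in self._items)

    def copies(self, gene: str) -> int:
        return dict(self._items).get(gene, 0)

    def is_active(self, deleted) -> bool:
        return not (self.genes & frozenset(deleted))

    def sort_key(self):
        return tuple(sorted(self.genes)), self._items

    def __iter__(self) -> Iterator[str]:
        return iter(g for g, _ in self._items)

    def __str__(self) -> str:
        parts = []
        for g, c in self._items:
            parts.extend([g] * c)
        return " and ".join(parts)

    def __repr__(self) -> str:
        return f"Enzyme({dict(self._items)!r})"


@dataclass(frozen=True)
class GPRAssociation:
    """A parsed GPR rule plus its minimal disjunctive normal form."""

    text: str
    _ast: object = field(repr=False)
    dnf: tuple = ()

    @property
    def genes(self) -> frozenset:
        return frozenset(itertools.chain.from_iterable(e.genes for e in self.dnf))

    def evaluate(self, deleted=()) -> bool:
        return any(e.is_active(deleted) for e in self.dnf)

    def evaluate_expression(self, active) -> bool:
        """Evaluate the original (non-normalized) formula; ``active`` is the
        set of genes that are present/on."""
        return self._ast.evaluate(frozenset(active))

    def __str__(self) -> str:
        return self.text


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str):
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:  # only trailing whitespace remains
            break
        tok = m.group(1)
        tokens.append((tok, m.start(1)))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser for ``expr := term (OR term)*``,
    ``term := factor (AND factor)*``, ``factor := '(' expr ')' | gene``."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, len(self.text))

    def next(self):
        tok = self.peek()
        self.i += 1
        return tok

    def parse(self):
        node = self.expr()
        tok, pos = self.peek()
        if tok is not None:
            raise GPRParseError(f"unexpected token {tok!r}", pos)
        return node

    def expr(self):
        terms = [self.term()]
        while True:
            tok, _ = self.peek()
            if tok is not None and tok.lower() == "or":
                self.next()
                terms.append(self.term())
            else:
                break
        return terms[0] if len(terms) == 1 else _Or(tuple(terms))

    def term(self):
        factors = [self.factor()]
        while True:
            tok, _ = self.peek()
            if tok is not None and tok.lower() == "and":
                self.next()
                factors.append(self.factor())
            else:
                break
        return factors[0] if len(factors) == 1 else _And(tuple(factors))

    def factor(self):
        tok, pos = self.next()
        if tok is None:
            raise GPRParseError("unexpected end of expression", pos)
        if tok == "(":
            node = self.expr()
            close, cpos = self.next()
            if close != ")":
                raise GPRParseError("expected closing parenthesis", cpos)
            return node
        if tok == ")":
            raise GPRParseError("unexpected ')'", pos)
        if tok.lower() in ("and", "or"):
            raise GPRParseError(f"operator {tok!r} without operand", pos)
        return _Var(tok.strip())


def parse_gpr(text: str | None, cap: int = DEFAULT_DNF_CAP) -> GPRAssociation | None:
    """Parse a GPR rule string into a :class:`GPRAssociation`.

    AND/OR are case-insensitive; gene identifiers are case-sensitive after
    whitespace trimming.  Empty (or all-whitespace) input means "no GPR" and
    returns ``None``.

    Raises :class:`GPRParseError` on malformed syntax and
    :class:`CapacityError` if DNF expansion exceeds ``cap`` terms.
    """
    if text is None or not text.strip():
        return None
    ast = _Parser(text).parse()
    dnf = _dnf_of(ast, cap)
    return GPRAssociation(text=text.strip(), _ast=ast, dnf=dnf)


# ---------------------------------------------------------------------------
# DNF expansion with on-the-fly absorption
# ---------------------------------------------------------------------------


def _absorb(enzymes: list, new: Enzyme) -> list:
    """Insert ``new`` into an absorption-free list, keeping it absorption-free."""
    ng = new.genes
    kept = []
    for e in enzymes:
        eg = e.genes
        if eg <= ng:
            if eg == ng and new.total_copies < e.total_copies:
                continue  # replace by the cheaper equal-support enzyme
            return enzymes  # new is absorbed (or duplicated)
        if ng < eg:
            continue  # existing enzyme is absorbed by new
        kept.append(e)
    kept.append(new)
    return kept


def _merge_or(parts: Sequence[list], cap: int) -> list:
    out: list = []
    for part in parts:
        for e in part:
            out = _absorb(out, e)
            if len(out) > cap:
                raise CapacityError(f"DNF expansion exceeded {cap} terms")
    return out


def _merge_and(parts: Sequence[list], cap: int) -> list:
    out = parts[0]
    for part in parts[1:]:
        combined: list = []
        if len(out) * len(part) > 4 * cap:
            raise CapacityError(f"DNF expansion exceeded {cap} terms")
        for a in out:
            ca = Counter(a.subunits)
            for b in part:
                cc = ca.copy()
                cc.update(b.subunits)
                combined = _absorb(combined, Enzyme(cc))
                if len(combined) > cap:
                    raise CapacityError(f"DNF expansion exceeded {cap} terms")
        out = combined
    return out


def _dnf_of(node, cap: int) -> tuple:
    if isinstance(node, _Var):
        return (Enzyme({node.gene: 1}),)
    if isinstance(node, _Or):
        merged = _merge_or([list(_dnf_of(c, cap)) for c in node.children], cap)
    elif isinstance(node, _And):
        merged = _merge_and([list(_dnf_of(c, cap)) for c in node.children], cap)
    else:  # pragma: no cover - parser only emits the three node types
        raise TypeError(f"unexpected node {node!r}")
    return tuple(sorted(merged, key=Enzyme.sort_key))


def to_dnf(assoc: GPRAssociation) -> tuple:
    """Return the minimal DNF of a parsed association as a tuple of enzymes."""
    return assoc.dnf


def evaluate_gpr(assoc: GPRAssociation | None, deleted: Iterable[str] = ()) -> bool:
    """True iff at least one enzyme survives the deletion of ``deleted`` genes.

    Reactions without association (``assoc is None``) are always active:
    there is nothing to knock out.
    """
    if assoc is None:
        return True
    return assoc.evaluate(deleted)


# ---------------------------------------------------------------------------
# minimal knockout (hitting) sets
# ---------------------------------------------------------------------------


def minimal_knockout_sets(
    assoc: GPRAssociation, cap: int = DEFAULT_KNOCKOUT_CAP
) -> list:
    """All inclusion-minimal gene sets whose deletion disables the reaction.

    A knockout set must *hit* every enzyme of the DNF (delete at least one
    subunit of each alternative catalyst); minimality means no proper subset
    does.  For k pairwise-disjoint complexes of sizes n1..nk the count is the
    product of the ni (e.g. two disjoint complexes of 11 and 7 subunits give
    77 combinations).  Results are sorted lexicographically.
    """
    if assoc is None or not assoc.dnf:
        raise GPRError("association has an empty DNF; nothing to disable")
    families = [tuple(sorted(e.genes)) for e in assoc.dnf]
    candidates: set = set()

    def recurse(chosen: frozenset):
        if len(candidates) > cap:
            raise CapacityError(f"knockout-set enumeration exceeded {cap} candidates")
        for fam in families:
            if not chosen.intersection(fam):
                for g in fam:
                    recurse(chosen | {g})
                return
        candidates.add(chosen)

    recurse(frozenset())
    minimal = [
        s
        for s in candidates
        if not any(o < s for o in candidates)
    ]
    return sorted((set(s) for s in minimal), key=lambda s: sorted(s))
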