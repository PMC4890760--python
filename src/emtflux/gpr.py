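"""Gene-protein-reaction (GPR) rules.

A GPR is a Boolean expression tree over gene identifiers with operators
``AND``, ``OR`` and ``NOT`` (precedence ``NOT > AND > OR``, parentheses
allowed).  ``AND`` encodes multiprotein complexes (all subunits required),
``OR`` encodes isoforms (any one suffices) and ``NOT`` encodes inhibition:
expression of the inhibitor suppresses the reaction.

Rules are evaluated over *ternary* gene states ``{+1, -1, 0}`` meaning
up-in-epithelial / up-in-mesenchymal / unchanged.  The ternary semantics
extend the Boolean intent monotonically::

    AND = min,   OR = max,   NOT = negation

so an unchanged gene (0) neither activates nor suppresses.  A strict
two-valued mode is available for callers that only deal in on/off states.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping

__all__ = [
    "GPRRule",
    "Gene",
    "And",
    "Or",
    "Not",
    "parse_gpr",
    "format_gpr",
    "evaluate_gpr",
    "gpr_genes",
    "inhibitor_genes",
    "GPRSyntaxError",
]


class GPRSyntaxError(ValueError):
    """Raised when a GPR string cannot be parsed."""


class GPRRule:
    """Base class for GPR expression-tree nodes."""

    def genes(self) -> set[str]:
        return {leaf.gene for leaf in self._leaves()}

    def _leaves(self) -> Iterator["Gene"]:
        raise NotImplementedError

    def __str__(self) -> str:
        return format_gpr(self)

    def __repr__(self) -> str:
        return f"{type(self).__name__}({format_gpr(self)!r})"


@dataclass(frozen=True, repr=False)
class Gene(GPRRule):
    gene: str

    def _leaves(self):
        yield self


@dataclass(frozen=True, repr=False)
class And(GPRRule):
    children: tuple[GPRRule, ...]

    def __post_init__(self):
        # canonical form: associative chains are kept flat
        flat = tuple(
            g for c in self.children for g in (c.children if isinstance(c, And) else (c,))
        )
        object.__setattr__(self, "children", flat)

    def _leaves(self):
        for c in self.children:
            yield from c._leaves()


@dataclass(frozen=True, repr=False)
class Or(GPRRule):
    children: tuple[GPRRule, ...]

    def __post_init__(self):
        flat = tuple(
            g for c in self.children for g in (c.children if isinstance(c, Or) else (c,))
        )
        object.__setattr__(self, "children", flat)

    def _leaves(self):
        for c in self.children:
            yield from c._leaves()


@dataclass(frozen=True, repr=False)
class Not(GPRRule):
    child: GPRRule

    def _leaves(self):
        yield from self.child._leaves()


_TOKEN = re.compile(r"\(|\)|[^\s()]+")
_KEYWORDS = {"and", "or", "not"}


def parse_gpr(text: str) -> GPRRule | None:
    """Parse a GPR string into an expression tree.

    Returns ``None`` for a blank string (no rule).  Gene identifiers are
    arbitrary non-whitespace tokens other than parentheses and the
    (case-insensitive) keywords.
    """
    tokens = _TOKEN.findall(text)
    if not tokens:
        return None
    parser = _Parser(tokens, text)
    rule = parser.parse_or()
    if parser.peek() is not None:
        raise GPRSyntaxError(
            f"unexpected token {parser.peek()!r} at position {parser.pos} in {text!r}"
        )
    return rule


class _Parser:
    def __init__(self, tokens: list[str], text: str):
        self.tokens = tokens
        self.pos = 0
        self.text = text

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GPRSyntaxError(f"unexpected end of rule in {self.text!r}")
        self.pos += 1
        return tok

    def parse_or(self) -> GPRRule:
        terms = [self.parse_and()]
        while (tok := self.peek()) is not None and tok.lower() == "or":
            self.next()
            terms.append(self.parse_and())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_and(self) -> GPRRule:
        factors = [self.parse_not()]
        while (tok := self.peek()) is not None and tok.lower() == "and":
            self.next()
            factors.append(self.parse_not())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def parse_not(self) -> GPRRule:
        tok = self.peek()
        if tok is not None and tok.lower() == "not":
            self.next()
            return Not(self.parse_not())
        return self.parse_atom()

    def parse_atom(self) -> GPRRule:
        tok = self.next()
        if tok == "(":
            inner = self.parse_or()
            closing = self.next()
            if closing != ")":
                raise GPRSyntaxError(f"expected ')' but found {closing!r} in {self.text!r}")
            return inner
        if tok == ")" or tok.lower() in _KEYWORDS:
            raise GPRSyntaxError(f"unexpected token {tok!r} in {self.text!r}")
        return Gene(tok)


def format_gpr(rule: GPRRule) -> str:
    """Render an expression tree back to its canonical string form.

    ``parse_gpr(format_gpr(r))`` reproduces ``r`` exactly; parentheses are
    emitted only where precedence requires them.
    """
    return _fmt(rule, 0)


# precedence levels: OR=1, AND=2, NOT=3
def _fmt(rule: GPRRule, parent_level: int) -> str:
    if isinstance(rule, Gene):
        return rule.gene
    if isinstance(rule, Not):
        inner = _fmt(rule.child, 3)
        text, level = f"NOT {inner}", 3
    elif isinstance(rule, And):
        text, level = " AND ".join(_fmt(c, 2) for c in rule.children), 2
    elif isinstance(rule, Or):
        text, level = " OR ".join(_fmt(c, 1) for c in rule.children), 1
    else:  # pragma: no cover - defensive
        raise TypeError(f"not a GPR node: {rule!r}")
    return f"({text})" if level < parent_level else text


def evaluate_gpr(
    rule: GPRRule | str | None,
    states: Mapping[str, int],
    *,
    strict_boolean: bool = False,
) -> int:
    """Evaluate a GPR over ternary gene states.

    Parameters
    ----------
    rule:
        Expression tree, GPR string, or ``None`` (no rule → 0).
    states:
        Map gene id → state in ``{+1, -1, 0}``.  Genes absent from the map
        default to 0 (unchanged).
    strict_boolean:
        If set, states must be two-valued (+1/-1) and the result is the
        classical Boolean evaluation mapped onto +1/-1.

    Returns
    -------
    int
        Ternary result: ``AND`` is the minimum over children, ``OR`` the
        maximum, ``NOT`` the negation.
    """
    if isinstance(rule, str):
        rule = parse_gpr(rule)
    if rule is None:
        return 0

    def leaf_state(gene: str) -> int:
        value = states.get(gene, 0)
        if value not in (-1, 0, 1):
            raise ValueError(f"gene state for {gene!r} must be -1, 0 or +1, got {value!r}")
        if strict_boolean and value == 0:
            raise ValueError(
                f"strict Boolean mode requires two-valued states; gene {gene!r} is 0"
            )
        return value

    def ev(node: GPRRule) -> int:
        if isinstance(node, Gene):
            return leaf_state(node.gene)
        if isinstance(node, And):
            return min(ev(c) for c in node.children)
        if isinstance(node, Or):
            return max(ev(c) for c in node.children)
        if isinstance(node, Not):
            return -ev(node.child)
        raise TypeError(f"not a GPR node: {node!r}")  # pragma: no cover

    return ev(rule)


def gpr_genes(rule: GPRRule | str | None) -> set[str]:
    """All gene identifiers appearing in a rule (empty set for no rule)."""
    if isinstance(rule, str):
        rule = parse_gpr(rule)
    return set() if rule is None else rule.genes()


def inhibitor_genes(rule: GPRRule | str | None) -> set[str]:
    """Genes appearing under an odd number of ``NOT`` operators.

    These act as inhibitors of the reaction: their expression lowers the
    rule's value.
    """
    if isinstance(rule, str):
        rule = parse_gpr(rule)
    if rule is None:
        return set()
    out: set[str] = set()

    def walk(node: GPRRule, negated: bool) -> None:
        if isinstance(node, Gene):
            if negated:
                out.add(node.gene)
        elif isinstance(node, Not):
            walk(node.child, not negated)
        elif isinstance(node, (And, Or)):
            for c in node.children:
                walk(c, negated)

    walk(rule, False)
    return out
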