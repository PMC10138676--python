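"""Gene–protein–reaction (GPR) boolean rules.

A GPR rule states which gene products a reaction needs: ``AND`` joins
members of an enzyme complex (all required), ``OR`` joins isozymes (any
suffices). Rules are parsed to a small AST with the conventional
precedence AND > OR and parentheses honoured, so ``a or b and c`` reads as
``a or (b and c)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["GPRNode", "Gene", "And", "Or", "parse_gpr", "evaluate_gpr", "GPRParseError"]


class GPRParseError(ValueError):
    """Raised for a syntactically malformed GPR rule."""


class GPRNode:
    """Base class of GPR AST nodes."""

    def evaluate(self, present: frozenset[str] | set[str]) -> bool:
        raise NotImplementedError

    def genes(self) -> frozenset[str]:
        raise NotImplementedError

    def to_string(self) -> str:
        raise NotImplementedError


@dataclass(frozen=True)
class Gene(GPRNode):
    gene_id: str

    def evaluate(self, present):
        return self.gene_id in present

    def genes(self):
        return frozenset({self.gene_id})

    def to_string(self):
        return self.gene_id


@dataclass(frozen=True)
class And(GPRNode):
    children: tuple[GPRNode, ...]

    def evaluate(self, present):
        return all(c.evaluate(present) for c in self.children)

    def genes(self):
        return frozenset().union(*(c.genes() for c in self.children))

    def to_string(self):
        return " and ".join(
            f"({c.to_string()})" if isinstance(c, Or) else c.to_string()
            for c in self.children
        )


@dataclass(frozen=True)
class Or(GPRNode):
    children: tuple[GPRNode, ...]

    def evaluate(self, present):
        return any(c.evaluate(present) for c in self.children)

    def genes(self):
        return frozenset().union(*(c.genes() for c in self.children))

    def to_string(self):
        return " or ".join(c.to_string() for c in self.children)


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(rule: str) -> list[str]:
    return _TOKEN_RE.findall(rule)


class _Parser:
    """Recursive descent over  expr := term (OR term)* ;  term := atom (AND atom)*."""

    def __init__(self, tokens: list[str], rule: str):
        self.tokens = tokens
        self.pos = 0
        self.rule = rule

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of GPR rule {self.rule!r}")
        self.pos += 1
        return tok

    def parse_expr(self) -> GPRNode:
        terms = [self.parse_term()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            terms.append(self.parse_term())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_term(self) -> GPRNode:
        atoms = [self.parse_atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            atoms.append(self.parse_atom())
        return atoms[0] if len(atoms) == 1 else And(tuple(atoms))

    def parse_atom(self) -> GPRNode:
        tok = self.next()
        if tok == "(":
            node = self.parse_expr()
            if self.next() != ")":
                raise GPRParseError(f"unbalanced parentheses in {self.rule!r}")
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"unexpected token {tok!r} in GPR rule {self.rule!r}")
        return Gene(tok)


def parse_gpr(rule: str) -> GPRNode:
    """Parse a GPR rule string into an AST.

    Raises :class:`GPRParseError` on malformed input; an empty rule is a
    caller-side case (no AST; the reaction needs no gene product).
    """
    tokens = _tokenize(rule)
    if not tokens:
        raise GPRParseError("empty GPR rule")
    parser = _Parser(tokens, rule)
    node = parser.parse_expr()
    if parser.peek() is not None:
        raise GPRParseError(f"trailing tokens in GPR rule {rule!r}")
    return node


def evaluate_gpr(gpr_ast: GPRNode | None, present_genes: set[str] | frozenset[str]) -> bool:
    """Evaluate a GPR tree against a set of present genes.

    ``None`` (empty rule) evaluates True: reactions without gene evidence —
    spontaneous reactions and orphan transporters — are always retained.
    """
    if gpr_ast is None:
        return True
    return gpr_ast.evaluate(frozenset(present_genes))
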