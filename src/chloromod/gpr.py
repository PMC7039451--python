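"""Gene-protein-reaction (GPR) boolean rules.

A rule is a boolean expression over gene identifiers with AND / OR
connectives, e.g. ``(psbA and psbB) or psbX``.  Multi-subunit complexes
(PSII, cytochrome b6f, PSI, ATP synthase) use AND across all subunit genes,
so knocking out any one subunit disables every electron transfer carried out
by that complex.  An empty rule means "no gene data" and always evaluates
true (the reaction is unaffected by knockouts).
"""

from __future__ import annotations

import re
from typing import Iterable, Optional

__all__ = ["GPRRule", "GPRParseError"]


class GPRParseError(ValueError):
    pass


class _Node:
    __slots__ = ("op", "children", "gene")

    def __init__(self, op: str, children=None, gene: Optional[str] = None):
        self.op = op  # 'and' | 'or' | 'gene'
        self.children = children or []
        self.gene = gene

    def evaluate(self, knocked: frozenset) -> bool:
        if self.op == "gene":
            return self.gene not in knocked
        if self.op == "and":
            return all(c.evaluate(knocked) for c in self.children)
        return any(c.evaluate(knocked) for c in self.children)

    def genes(self, out: set) -> None:
        if self.op == "gene":
            out.add(self.gene)
        else:
            for c in self.children:
                c.genes(out)

    def to_string(self, parent: Optional[str] = None) -> str:
        if self.op == "gene":
            return self.gene
        joiner = f" {self.op} "
        s = joiner.join(c.to_string(self.op) for c in self.children)
        # parenthesize OR under AND (and anything under a different parent op)
        if parent is not None and parent != self.op:
            return f"({s})"
        return s


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class GPRRule:
    """Parsed GPR expression; construct with :meth:`from_string` or empty."""

    def __init__(self, root: Optional[_Node] = None):
        self._root = root

    @classmethod
    def from_string(cls, text: str) -> "GPRRule":
        """Parse ``and`` / ``or`` (case-insensitive; ``&``/``|`` accepted)
        with parentheses; OR binds looser than AND."""
        tokens = _TOKEN_RE.findall(text or "")
        if not tokens:
            return cls()
        pos = 0

        def peek():
            return tokens[pos] if pos < len(tokens) else None

        def take():
            nonlocal pos
            tok = tokens[pos]
            pos += 1
            return tok

        def parse_or() -> _Node:
            node = parse_and()
            children = [node]
            while peek() is not None and peek().lower() in ("or", "|", "||"):
                take()
                children.append(parse_and())
            return children[0] if len(children) == 1 else _Node("or", children)

        def parse_and() -> _Node:
            node = parse_atom()
            children = [node]
            while peek() is not None and peek().lower() in ("and", "&", "&&"):
                take()
                children.append(parse_atom())
            return children[0] if len(children) == 1 else _Node("and", children)

        def parse_atom() -> _Node:
            tok = peek()
            if tok is None:
                raise GPRParseError(f"unexpected end of GPR expression: {text!r}")
            if tok == "(":
                take()
                node = parse_or()
                if peek() != ")":
                    raise GPRParseError(f"unbalanced parentheses in GPR: {text!r}")
                take()
                return node
            if tok == ")" or tok.lower() in ("and", "or", "&", "|", "&&", "||"):
                raise GPRParseError(f"unexpected token {tok!r} in GPR: {text!r}")
            return _Node("gene", gene=take())

        root = parse_or()
        if pos != len(tokens):
            raise GPRParseError(f"trailing tokens in GPR: {text!r}")
        return cls(root)

    @property
    def is_empty(self) -> bool:
        return self._root is None

    @property
    def genes(self) -> frozenset:
        if self._root is None:
            return frozenset()
        out: set = set()
        self._root.genes(out)
        return frozenset(out)

    def evaluate(self, knocked: Iterable[str] = ()) -> bool:
        """Boolean evaluation with knocked genes false, all others true."""
        if self._root is None:
            return True
        return self._root.evaluate(frozenset(knocked))

    def to_string(self) -> str:
        return "" if self._root is None else self._root.to_string()

    def copy(self) -> "GPRRule":
        return GPRRule.from_string(self.to_string()) if self._root else GPRRule()

    def __bool__(self) -> bool:
        return self._root is not None

    def __repr__(self) -> str:  # pragma: no cover
        return f"GPRRule({self.to_string()!r})"
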