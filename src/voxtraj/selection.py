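"""Focus-selection mini-language.

A small, dependency-neutral expression language resolves the substructure
of interest (e.g. a ligand or a binding site) against a topology:

==================  ====================================================
clause              meaning
==================  ====================================================
``resname:NAME``    residue name equals ``NAME`` (case-insensitive)
``resid:A-B``       residue index in the inclusive range ``A..B``
``resid:A``         residue index equals ``A``
``atomid:A-B``      0-based atom index in the inclusive range ``A..B``
``atomid:A``        atom index equals ``A``
``part:CODE``       part annotation equals integer ``CODE``
``all``             every atom
==================  ====================================================

Clauses combine with ``and``, ``or``, ``not`` and parentheses; ``not``
binds tightest, then ``and``, then ``or``.  Resolution is deterministic
and returns a sorted, duplicate-free index list; an empty selection is
allowed but logged as a warning.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

from .errors import SelectionSyntaxError
from .trajectory import Topology

__all__ = ["FocusSelection", "select_focus"]

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<word>[A-Za-z_][\w.\-]*(?::[\w.\-]+)?))"
)


@dataclass(frozen=True)
class FocusSelection:
    """A selection expression together with its resolution on a topology."""

    expression: str
    resolved_indices: np.ndarray  # sorted unique 0-based atom indices

    @property
    def n_selected(self) -> int:
        return len(self.resolved_indices)


def _tokenize(expression: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(expression):
        m = _TOKEN_RE.match(expression, pos)
        if m is None:
            rest = expression[pos:].strip()
            if not rest:
                break
            raise SelectionSyntaxError(f"unexpected token near {rest.split()[0]!r}")
        if m.group("lpar"):
            tokens.append("(")
        elif m.group("rpar"):
            tokens.append(")")
        else:
            tokens.append(m.group("word"))
        pos = m.end()
    return tokens


def _parse_range(value: str, token: str) -> tuple[int, int]:
    m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", value)
    if m is None:
        raise SelectionSyntaxError(f"bad numeric range in clause {token!r}")
    lo = int(m.group(1))
    hi = int(m.group(2)) if m.group(2) is not None else lo
    return lo, hi


def _clause_mask(token: str, topology: Topology) -> np.ndarray:
    if token.lower() == "all":
        return np.ones(topology.n_atoms, dtype=bool)
    if ":" not in token:
        raise SelectionSyntaxError(f"expected a clause 'key:value', got {token!r}")
    key, value = token.split(":", 1)
    key = key.lower()
    if key == "resname":
        names = np.array([str(r).upper() for r in topology.residue_name])
        return names == value.upper()
    if key == "resid":
        lo, hi = _parse_range(value, token)
        return (topology.residue_index >= lo) & (topology.residue_index <= hi)
    if key == "atomid":
        lo, hi = _parse_range(value, token)
        idx = np.arange(topology.n_atoms)
        return (idx >= lo) & (idx <= hi)
    if key == "part":
        try:
            code = int(value)
        except ValueError as exc:
            raise SelectionSyntaxError(f"part code must be an integer in {token!r}") from exc
        return topology.part_annotation == code
    raise SelectionSyntaxError(f"unknown clause key {key!r} in {token!r}")


class _Parser:
    """Recursive descent over the token stream; precedence not > and > or."""

    def __init__(self, tokens: list[str], topology: Topology):
        self.tokens = tokens
        self.pos = 0
        self.topology = topology

    def peek(self) -> "str | None":
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionSyntaxError("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionSyntaxError(f"unexpected trailing token {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.next()
        if tok.lower() == "not":
            return ~self.factor()
        if tok == "(":
            mask = self.expr()
            closing = self.next()
            if closing != ")":
                raise SelectionSyntaxError(f"expected ')', got {closing!r}")
            return mask
        if tok == ")" or tok.lower() in ("and", "or"):
            raise SelectionSyntaxError(f"unexpected token {tok!r}")
        return _clause_mask(tok, self.topology)


def select_focus(expression: str, topology: Topology) -> FocusSelection:
    """Resolve a selection expression against ``topology``.

    Returns a :class:`FocusSelection` with a sorted, unique index array.
    Raises :class:`~voxtraj.errors.SelectionSyntaxError` naming the
    offending token on a grammar violation.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionSyntaxError("empty selection expression")
    mask = _Parser(tokens, topology).parse()
    indices = np.flatnonzero(mask)
    if indices.size == 0:
        logger.warning("selection %r matched no atoms", expression)
    return FocusSelection(expression=expression, resolved_indices=indices)
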