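"""Atom selection expressions.

A deliberately small selection language covering what the analyses need:

* ``chain A B`` — chain identifiers
* ``resid 5 10-20`` — residue numbers and closed ranges (1-based, PDB style)
* ``resname GLY ALA`` — 3-letter residue names
* ``name CA CB`` — atom names
* ``heavy`` — element is not hydrogen
* ``hetero`` — HETATM records
* ``all`` — every atom

combined with ``and``, ``or``, ``not`` and parentheses (``not`` binds
tightest, then ``and``, then ``or``).  Keywords with several values mean the
union, e.g. ``resid 5 10-20`` matches residue 5 or any residue in 10..20.
Selections evaluate to index arrays in atom order and may be empty.

Examples
--------
>>> select_atoms(system, "chain A and resid 20-228 and name CA")
>>> select_atoms(system, "heavy and not hetero")
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import SelectionError
from .systems import MolecularSystem

_TOKEN_RE = re.compile(r"\s*([()]|[^\s()]+)")
_KEYWORDS = {"and", "or", "not", "(", ")"}
_PRED_WORDS = {"chain", "resid", "resname", "name", "heavy", "hetero", "all"}
_RANGE_RE = re.compile(r"^(-?\d+)(?:-(-?\d+))?$")

Predicate = Callable[[MolecularSystem], np.ndarray]


@dataclass(frozen=True)
class SelectionExpr:
    """A parsed selection expression; calling it yields a boolean mask."""

    expression: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "_pred", _parse(self.expression))

    def mask(self, system: MolecularSystem) -> np.ndarray:
        return self._pred(system)


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str) -> None:
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def pos(self) -> int:
        return self.tokens[self.i][1] if self.i < len(self.tokens) else len(self.text)

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError(
                f"unexpected end of selection at position {len(self.text)}: "
                f"{self.text!r}")
        self.i += 1
        return tok

    def fail(self, msg: str) -> SelectionError:
        return SelectionError(f"{msg} at position {self.pos()} in {self.text!r}")

    # expr := and_expr ("or" and_expr)*
    def expr(self) -> Predicate:
        left = self.and_expr()
        while self.peek() == "or":
            self.take()
            right = self.and_expr()
            left = _combine(left, right, np.logical_or)
        return left

    def and_expr(self) -> Predicate:
        left = self.not_expr()
        while self.peek() == "and":
            self.take()
            right = self.not_expr()
            left = _combine(left, right, np.logical_and)
        return left

    def not_expr(self) -> Predicate:
        if self.peek() == "not":
            self.take()
            inner = self.not_expr()
            return lambda s: ~inner(s)
        if self.peek() == "(":
            self.take()
            inner = self.expr()
            if self.peek() != ")":
                raise self.fail("expected ')'")
            self.take()
            return inner
        return self.predicate()

    def values(self) -> list[str]:
        vals: list[str] = []
        while self.peek() is not None and self.peek() not in _KEYWORDS \
                and self.peek() not in _PRED_WORDS:
            vals.append(self.take())
        if not vals:
            raise self.fail("keyword needs at least one value")
        return vals

    def predicate(self) -> Predicate:
        tok = self.peek()
        if tok is None:
            raise self.fail("expected a predicate")
        if tok not in _PRED_WORDS:
            raise self.fail(f"unknown token {tok!r}")
        self.take()
        if tok == "all":
            return lambda s: np.ones(s.n_atoms, dtype=bool)
        if tok == "heavy":
            return lambda s: np.array(
                [a.element.upper() != "H" for a in s.atoms])
        if tok == "hetero":
            return lambda s: np.array([a.is_hetero for a in s.atoms])
        if tok == "chain":
            vals = set(self.values())
            return lambda s: np.array([a.chain_id in vals for a in s.atoms])
        if tok == "resname":
            vals = {v.upper() for v in self.values()}
            return lambda s: np.array(
                [a.residue_name.upper() in vals for a in s.atoms])
        if tok == "name":
            vals = {v.upper() for v in self.values()}
            return lambda s: np.array(
                [a.atom_name.upper() in vals for a in s.atoms])
        # resid: numbers and closed ranges
        ranges: list[tuple[int, int]] = []
        for v in self.values():
            m = _RANGE_RE.match(v)
            if m is None:
                raise self.fail(f"bad residue number or range {v!r}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) is not None else lo
            if hi < lo:
                raise self.fail(f"empty residue range {v!r}")
            ranges.append((lo, hi))

        def _resid(s: MolecularSystem) -> np.ndarray:
            nums = np.array([a.residue_number for a in s.atoms])
            out = np.zeros(s.n_atoms, dtype=bool)
            for lo, hi in ranges:
                out |= (nums >= lo) & (nums <= hi)
            return out

        return _resid


def _combine(a: Predicate, b: Predicate, op) -> Predicate:
    return lambda s: op(a(s), b(s))


def _parse(text: str) -> Predicate:
    parser = _Parser(text)
    if not parser.tokens:
        raise SelectionError("empty selection expression")
    pred = parser.expr()
    if parser.peek() is not None:
        raise parser.fail(f"trailing token {parser.peek()!r}")
    return pred


def select_atoms(system: MolecularSystem,
                 expr: str | SelectionExpr) -> np.ndarray:
    """Evaluate a selection and return atom indices in atom order.

    The result is deterministic, order-preserving and possibly empty.
    Raises :class:`SelectionError` (with the character position) on a
    syntax error.
    """
    if isinstance(expr, str):
        expr = SelectionExpr(expr)
    return np.flatnonzero(expr.mask(system))
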