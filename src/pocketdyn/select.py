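"""A small selection-expression language over a Topology.

Grammar (case-insensitive keywords)::

    expr      := term ("or" term)*
    term      := factor ("and" factor)*
    factor    := "not" factor | "(" expr ")" | primitive
    primitive := "resid" INT | "resid" INT-INT | "resname" WORD
               | "name" WORD | "chain" WORD | "heavy" | "ligand" | "all"

Residue ranges are inclusive on both ends and use author numbering.
Unknown names select nothing (with a warning); syntax errors raise
:class:`~pocketdyn.errors.SelectionParseError` with the offending position.
"""

from __future__ import annotations

import logging
import re

import numpy as np

from .errors import SelectionParseError
from .model import Selection, Topology

log = logging.getLogger(__name__)

_TOKEN = re.compile(r"\s*([()]|[^\s()]+)")


def _tokenize(query: str) -> list[tuple[str, int]]:
    tokens = []
    pos = 0
    while pos < len(query):
        m = _TOKEN.match(query, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, topology: Topology, query: str):
        self.topo = topology
        self.query = query
        self.tokens = _tokenize(query)
        self.i = 0

    def peek(self) -> str | None:
        return self.tokens[self.i][0].lower() if self.i < len(self.tokens) else None

    def pos(self) -> int:
        return self.tokens[self.i][1] if self.i < len(self.tokens) else len(self.query)

    def take(self) -> str:
        tok = self.tokens[self.i][0]
        self.i += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionParseError("empty selection expression", 0)
        mask = self.expr()
        if self.i < len(self.tokens):
            raise SelectionParseError(
                f"unexpected token {self.tokens[self.i][0]!r}", self.pos()
            )
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise SelectionParseError("unexpected end of expression", self.pos())
        if tok == "not":
            self.take()
            return ~self.factor()
        if tok == "(":
            self.take()
            mask = self.expr()
            if self.peek() != ")":
                raise SelectionParseError("expected ')'", self.pos())
            self.take()
            return mask
        return self.primitive()

    def primitive(self) -> np.ndarray:
        pos = self.pos()
        tok = self.take().lower()
        atoms = self.topo.atoms
        n = len(atoms)
        if tok == "heavy":
            return np.array([a.is_heavy for a in atoms])
        if tok == "all":
            return np.ones(n, dtype=bool)
        if tok == "ligand":
            mask = np.zeros(n, dtype=bool)
            if self.topo.ligand_selection is not None:
                mask[self.topo.ligand_selection.atom_indices] = True
            return mask
        if tok in ("resid", "resname", "name", "chain"):
            if self.i >= len(self.tokens):
                raise SelectionParseError(f"{tok} needs an argument", self.pos())
            argpos = self.pos()
            arg = self.take()
            if tok == "resid":
                m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", arg)
                if m is None:
                    raise SelectionParseError(
                        f"bad residue index/range {arg!r}", argpos
                    )
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) is not None else lo
                return np.array([lo <= a.residue_index <= hi for a in atoms])
            if tok == "resname":
                return np.array([a.residue_name == arg for a in atoms])
            if tok == "name":
                return np.array([a.name == arg for a in atoms])
            return np.array([a.chain_id == arg for a in atoms])
        raise SelectionParseError(f"unknown keyword {tok!r}", pos)


def select(topology: Topology, query: str, label: str | None = None) -> Selection:
    """Evaluate a selection expression; empty results warn but are legal."""
    mask = _Parser(topology, query).parse()
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        log.warning("selection %r matched no atoms", query)
    return Selection(label or query, idx)
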