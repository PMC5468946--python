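"""Gene-protein-reaction (GPR) rules with protein-complex semantics.

A GPR rule states which gene products must be present for a reaction to
carry flux.  Within one enzyme complex every subunit is required (AND);
across isozymes or alternative complex variants any one suffices (OR).
Rules are normalised to disjunctive form on parse: a set of *variants*,
each variant being the set of genes one sufficient complex needs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Set

_TOKEN = re.compile(r"\(|\)|[^\s()]+")


class GPRParseError(ValueError):
    """Raised when a GPR string cannot be parsed."""


@dataclass(frozen=True)
class GPRRule:
    """Disjunction of conjunctions over gene identifiers.

    ``variants`` is a frozenset of frozensets: each inner set is one
    sufficient complex/enzyme, all of whose genes are required.  An empty
    ``variants`` means "no genetic requirement" — the reaction is always
    active (spontaneous, orphan or exchange reactions).
    """

    variants: FrozenSet[FrozenSet[str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for v in self.variants:
            if not v:
                raise ValueError("GPR variant sets must be non-empty")

    @property
    def genes(self) -> Set[str]:
        """All gene ids referenced by any variant."""
        out: Set[str] = set()
        for v in self.variants:
            out |= v
        return out

    @property
    def is_empty(self) -> bool:
        return not self.variants

    def is_active(self, deleted: Iterable[str]) -> bool:
        """True iff at least one variant survives the deletion set.

        An empty rule is always active: reactions without genetic
        requirements are never closed by gene deletions.
        """
        if not self.variants:
            return True
        deleted = set(deleted)
        return any(not (v & deleted) for v in self.variants)

    def to_string(self) -> str:
        """Render as ``(g1 and g2) or g3`` text (deterministic ordering)."""
        parts = []
        for v in sorted(self.variants, key=lambda s: sorted(s)):
            genes = sorted(v)
            if len(genes) == 1:
                parts.append(genes[0])
            else:
                parts.append("(" + " and ".join(genes) + ")")
        return " or ".join(parts)

    @classmethod
    def from_sets(cls, variants: Iterable[Iterable[str]]) -> "GPRRule":
        return cls(frozenset(frozenset(v) for v in variants))

    @classmethod
    def empty(cls) -> "GPRRule":
        return cls(frozenset())


def parse_gpr(text: str) -> GPRRule:
    """Parse GPR text like ``(g1 and g2) or g3`` into a :class:`GPRRule`.

    Grammar: case-insensitive ``and``/``or``, parentheses, bare gene
    tokens.  The boolean expression is expanded to disjunctive normal
    form, so ``g1 and (g2 or g3)`` yields variants {{g1,g2},{g1,g3}} —
    one per functioning complex.  Redundant variants (supersets of
    another variant) are pruned.
    """
    if text is None or not text.strip():
        return GPRRule.empty()
    tokens = _TOKEN.findall(text)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    # each parse function returns a DNF: set of frozensets of genes
    def parse_or() -> Set[FrozenSet[str]]:
        terms = parse_and()
        while peek() is not None and peek().lower() == "or":
            take()
            terms = terms | parse_and()
        return terms

    def parse_and() -> Set[FrozenSet[str]]:
        left = parse_atom()
        while peek() is not None and peek().lower() == "and":
            take()
            right = parse_atom()
            left = {a | b for a in left for b in right}
        return left

    def parse_atom() -> Set[FrozenSet[str]]:
        tok = peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of GPR expression: {text!r}")
        if tok == "(":
            take()
            inner = parse_or()
            if peek() != ")":
                raise GPRParseError(f"unbalanced parentheses in GPR: {text!r}")
            take()
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"unexpected token {tok!r} in GPR: {text!r}")
        take()
        return {frozenset([tok])}

    dnf = parse_or()
    if pos != len(tokens):
        raise GPRParseError(f"trailing tokens in GPR: {text!r}")
    # prune variants that are supersets of another (absorption)
    minimal = {v for v in dnf if not any(w < v for w in dnf)}
    return GPRRule(frozenset(minimal))
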