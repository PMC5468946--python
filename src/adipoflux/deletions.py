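"""Gene deletions: GPR evaluation and deletion-constrained networks.

A deletion closes every reaction whose GPR rule loses all of its complex
variants — each variant needs all of its subunit genes, so knocking out
any subunit disables that variant, while an isozyme or an alternative
complex keeps the reaction active.  Deletion acts on bounds (both set to
0) rather than by removing columns, so flux reports keep a stable
reaction universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Set

from .gpr import GPRRule
from .network import MetabolicNetwork


class UnknownGeneError(ValueError):
    """A deletion references genes not declared in the network."""

    def __init__(self, genes: Iterable[str]):
        self.genes = sorted(genes)
        super().__init__(f"unknown gene ids: {self.genes}")


@dataclass
class DeletionSpec:
    deleted_genes: Set[str] = field(default_factory=set)

    def validate(self, network: MetabolicNetwork) -> None:
        unknown = set(self.deleted_genes) - set(network.genes)
        if unknown:
            raise UnknownGeneError(unknown)


def evaluate_gpr(rule: GPRRule, deleted: Iterable[str]) -> bool:
    """True iff the reaction stays active under the deletion set.

    At least one variant must be disjoint from ``deleted``; an empty
    rule (no genetic requirement) is always active.
    """
    return rule.is_active(deleted)


def apply_deletion(
    network: MetabolicNetwork, spec: DeletionSpec | Set[str]
) -> MetabolicNetwork:
    """Copy of the network with GPR-inactivated reactions closed.

    Reactions whose rule evaluates inactive get lower = upper bound = 0;
    reactions without a GPR (spontaneous, exchange, orphan) are never
    touched — non-genetic reactions stay open under any deletion.
    """
    if not isinstance(spec, DeletionSpec):
        spec = DeletionSpec(set(spec))
    spec.validate(network)
    out = network.copy()
    for r in out.reactions:
        if not r.gpr.is_empty and not evaluate_gpr(r.gpr, spec.deleted_genes):
            r.lower_bound = 0.0
            r.upper_bound = 0.0
    return out


def closed_reactions(network: MetabolicNetwork, deleted: Set[str]) -> List[str]:
    """Ids of reactions a deletion would close (bookkeeping helper)."""
    DeletionSpec(deleted).validate(network)
    return [
        r.id
        for r in network.reactions
        if not r.gpr.is_empty and not evaluate_gpr(r.gpr, deleted)
    ]
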