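"""In-memory genome-scale metabolic network and structural analyses.

The network owns the ingredients of flux balance analysis: the
stoichiometric matrix S (one row per non-boundary metabolite, one column
per reaction), the flux bounds lb/ub, the gene-protein-reaction rules,
and one or more named linear objectives (the c vectors).

Sign conventions
----------------
Stoichiometric coefficients are negative for consumed metabolites and
positive for produced ones.  Exchange reactions are written ``met → ∅``
(coefficient −1 on the exchanged metabolite): uptake is negative flux,
secretion positive.  Default bounds are ±1000 flux units (nominally
mmol·gDW⁻¹·h⁻¹); irreversible reactions have lower bound 0.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .gpr import GPRRule

DEFAULT_BOUND = 1000.0


class NetworkValidationError(ValueError):
    """A network violates one of its structural invariants."""


class ReactionKind(str, Enum):
    ENZYMATIC = "enzymatic"
    TRANSPORT = "transport"
    EXCHANGE = "exchange"
    SPONTANEOUS = "spontaneous"


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    is_boundary: bool = False

    def __post_init__(self) -> None:
        if not self.compartment:
            raise NetworkValidationError(f"metabolite {self.id!r}: empty compartment")

    @property
    def base_id(self) -> str:
        """Species identifier with the compartment tag stripped.

        Distinct compartmental copies of one chemical species share a
        base id, which is what the "unique metabolite" count collapses.
        """
        suffix = "_" + self.compartment
        if self.id.endswith(suffix):
            return self.id[: -len(suffix)]
        # bracket style: glc[c]
        bracket = f"[{self.compartment}]"
        if self.id.endswith(bracket):
            return self.id[: -len(bracket)]
        return self.id


@dataclass
class Reaction:
    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: GPRRule = field(default_factory=GPRRule.empty)
    kind: Optional[ReactionKind] = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise NetworkValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise NetworkValidationError(f"reaction {self.id!r}: empty stoichiometry")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def infer_kind(self, metabolites: Mapping[str, Metabolite]) -> ReactionKind:
        """Classify structurally: exchange < transport < enzymatic/spontaneous."""
        internal = [m for m in self.stoichiometry if not metabolites[m].is_boundary]
        if len(internal) == 1 and all(
            metabolites[m].is_boundary for m in self.stoichiometry if m != internal[0]
        ):
            return ReactionKind.EXCHANGE
        comps = {metabolites[m].compartment for m in self.stoichiometry}
        bases = [metabolites[m].base_id for m in self.stoichiometry]
        if len(comps) > 1 and len(set(bases)) < len(bases):
            return ReactionKind.TRANSPORT
        return ReactionKind.ENZYMATIC if not self.gpr.is_empty else ReactionKind.SPONTANEOUS


@dataclass
class ObjectiveDefinition:
    """A named linear objective: the c vector of the FBA problem.

    ``name`` is conventionally one of ``biomass``, ``lipid_droplet``,
    ``acetyl_coa`` or a custom label; ``coefficients`` maps reaction ids
    to their weight.
    """

    name: str
    coefficients: Dict[str, float]

    def __post_init__(self) -> None:
        if not any(w != 0 for w in self.coefficients.values()):
            raise NetworkValidationError(
                f"objective {self.name!r}: needs at least one nonzero weight"
            )


@dataclass
class MetabolicNetwork:
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    genes: List[str] = field(default_factory=list)
    objectives: Dict[str, ObjectiveDefinition] = field(default_factory=dict)
    id: str = "model"

    # ---- lookups -------------------------------------------------
    @property
    def metabolite_index(self) -> Dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    @property
    def reaction_index(self) -> Dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    def get_reaction(self, rid: str) -> Reaction:
        try:
            return self.reaction_index[rid]
        except KeyError:
            raise KeyError(f"no reaction {rid!r} in network {self.id!r}") from None

    # ---- validation ----------------------------------------------
    def validate(self) -> None:
        """Check the structural invariants; raise on the first violation."""
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dupes = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise NetworkValidationError(f"duplicate metabolite ids: {dupes}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise NetworkValidationError(f"duplicate reaction ids: {dupes}")
        known_mets = set(met_ids)
        known_genes = set(self.genes)
        for r in self.reactions:
            missing = set(r.stoichiometry) - known_mets
            if missing:
                raise NetworkValidationError(
                    f"reaction {r.id!r} references undeclared metabolites: "
                    f"{sorted(missing)}"
                )
            unknown = r.gpr.genes - known_genes
            if unknown:
                raise NetworkValidationError(
                    f"reaction {r.id!r} GPR references undeclared genes: "
                    f"{sorted(unknown)}"
                )
        for obj in self.objectives.values():
            missing = set(obj.coefficients) - set(rxn_ids)
            if missing:
                raise NetworkValidationError(
                    f"objective {obj.name!r} references unknown reactions: "
                    f"{sorted(missing)}"
                )

    # ---- structure ------------------------------------------------
    def internal_metabolites(self) -> List[Metabolite]:
        return [m for m in self.metabolites if not m.is_boundary]

    def stoichiometric_matrix(self) -> Tuple[np.ndarray, List[str], List[str]]:
        """Assemble S with one row per non-boundary metabolite.

        Returns ``(S, metabolite_ids, reaction_ids)``; boundary species
        are excluded so exchange reactions appear as net sources/sinks.
        """
        mets = self.internal_metabolites()
        row = {m.id: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for mid, coef in r.stoichiometry.items():
                i = row.get(mid)
                if i is not None:
                    S[i, j] = coef
        return S, [m.id for m in mets], [r.id for r in self.reactions]

    def exchange_reactions(self) -> List[Reaction]:
        midx = self.metabolite_index
        return [r for r in self.reactions if _is_exchange(r, midx)]

    def copy(self) -> "MetabolicNetwork":
        return _copy.deepcopy(self)


def _is_exchange(r: Reaction, midx: Mapping[str, Metabolite]) -> bool:
    if r.kind is not None:
        return r.kind == ReactionKind.EXCHANGE
    internal = [m for m in r.stoichiometry if not midx[m].is_boundary]
    return len(internal) == 1


# ------------------------------------------------------------------
# dead-end metabolites
# ------------------------------------------------------------------

def find_dead_end_metabolites(
    network: MetabolicNetwork, iterative: bool = False
) -> Set[str]:
    """Metabolites that can only be produced or only consumed.

    A reversible reaction (lb < 0 < ub) counts as both a producer and a
    consumer of every metabolite it touches.  Such metabolites cannot
    carry steady-state flux and are structural impossibilities inside
    the network (boundary species are ignored: they are dead-ends by
    design).

    With ``iterative=True`` reactions touching dead-end metabolites are
    removed and the scan repeated to a fixed point, exposing orphan
    chains whose inner links look balanced on a single pass.
    """
    midx = network.metabolite_index
    active = {r.id for r in network.reactions}
    dead: Set[str] = set()
    internal = {m.id for m in network.internal_metabolites()}
    while True:
        produced: Set[str] = set()
        consumed: Set[str] = set()
        touched: Set[str] = set()
        for r in network.reactions:
            if r.id not in active:
                continue
            fwd = r.upper_bound > 0
            rev = r.lower_bound < 0
            if not (fwd or rev):
                continue  # closed reactions neither produce nor consume
            for mid, coef in r.stoichiometry.items():
                if mid not in internal or coef == 0:
                    continue
                touched.add(mid)
                if coef > 0:
                    if fwd:
                        produced.add(mid)
                    if rev:
                        consumed.add(mid)
                elif coef < 0:
                    if fwd:
                        consumed.add(mid)
                    if rev:
                        produced.add(mid)
        scan = {m for m in touched if (m in produced) != (m in consumed)}
        # declared but untouched metabolites can neither be produced nor
        # consumed; they are degenerate dead-ends on the first pass
        scan |= internal - touched - dead
        new = scan - dead
        if not new or not iterative:
            return dead | scan
        dead |= new
        active = {
            r.id
            for r in network.reactions
            if r.id in active and not (set(r.stoichiometry) & dead)
        }


# ------------------------------------------------------------------
# summary
# ------------------------------------------------------------------

@dataclass
class NetworkSummary:
    genes: int
    reactions: int
    metabolites: int
    unique_metabolites: int
    exchange_metabolites: int
    dead_ends: int

    def as_dict(self) -> Dict[str, int]:
        return {
            "genes": self.genes,
            "reactions": self.reactions,
            "metabolites": self.metabolites,
            "unique_metabolites": self.unique_metabolites,
            "exchange_metabolites": self.exchange_metabolites,
            "dead_ends": self.dead_ends,
        }


def network_summary(network: MetabolicNetwork) -> NetworkSummary:
    """Headline composition counts.

    ``metabolites`` counts non-boundary species (each compartmental copy
    separately); ``unique_metabolites`` collapses compartment tags;
    ``exchange_metabolites`` counts internal species touched by exchange
    reactions.
    """
    internal = network.internal_metabolites()
    midx = network.metabolite_index
    exch_mets: Set[str] = set()
    for r in network.exchange_reactions():
        for mid in r.stoichiometry:
            if not midx[mid].is_boundary:
                exch_mets.add(mid)
    return NetworkSummary(
        genes=len(network.genes),
        reactions=len(network.reactions),
        metabolites=len(internal),
        unique_metabolites=len({m.base_id for m in internal}),
        exchange_metabolites=len(exch_mets),
        dead_ends=len(find_dead_end_metabolites(network)),
    )
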