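"""Tissue-specific networks from expression fold differences.

Microarray fold differences between visceral and subcutaneous adipose
tissue are projected onto reactions through their GPR genes: a reaction
takes the *smallest* fold difference among its genes with data, provided
all of them point the same way; mixed directions (or no data) leave the
reaction neutral.  The favoured tissue keeps the reaction's FVA maximum
as its flux cap while the other tissue gets that maximum divided by the
fold — producing one network per tissue whose deletion screens can then
be compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import pandas as pd

from .network import MetabolicNetwork
from .screening import CandidateRule, DeletionRecord


class Tissue(str, Enum):
    VISCERAL = "visceral"
    SUBCUTANEOUS = "subcutaneous"


NEUTRAL = "neutral"


@dataclass(frozen=True)
class GeneFoldDifference:
    gene: str
    fold: float
    higher_in: Tissue

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError(
                f"fold for {self.gene!r} must be ≥ 1 (direction is separate), "
                f"got {self.fold}"
            )


def reaction_fold(
    network: MetabolicNetwork, folds: Iterable[GeneFoldDifference]
) -> Dict[str, Tuple[float, str]]:
    """Per-reaction (fold, direction) from per-gene fold differences.

    Over the reaction's GPR genes that have data: if every direction
    agrees, the reaction gets the smallest fold and that direction;
    mixed directions, folds all equal to 1, or no data at all make the
    reaction neutral ``(1.0, "neutral")``.
    """
    by_gene: Dict[str, GeneFoldDifference] = {}
    known = set(network.genes)
    for f in folds:
        if f.gene not in known:
            raise ValueError(f"fold table references unknown gene {f.gene!r}")
        by_gene[f.gene] = f
    out: Dict[str, Tuple[float, str]] = {}
    for r in network.reactions:
        data = [by_gene[g] for g in sorted(r.gpr.genes) if g in by_gene]
        informative = [f for f in data if f.fold > 1]
        directions = {f.higher_in for f in informative}
        if not informative or len(directions) > 1:
            out[r.id] = (1.0, NEUTRAL)
        else:
            out[r.id] = (min(f.fold for f in informative), directions.pop().value)
    return out


def build_tissue_networks(
    network: MetabolicNetwork,
    folds: Iterable[GeneFoldDifference],
    fva_max: Mapping[str, float],
    cap_reverse: bool = True,
) -> Tuple[MetabolicNetwork, MetabolicNetwork]:
    """(visceral, subcutaneous) networks with expression-scaled flux caps.

    Every reaction's upper bound is set to its FVA maximum; non-neutral
    reactions keep that cap in the tissue with higher expression and get
    cap/fold in the other.  With ``cap_reverse=True`` reversible
    reactions have the same magnitude applied to the negative direction.
    A reaction with FVA max 0 stays closed in both tissues.
    """
    rfold = reaction_fold(network, folds)
    vis, sub = network.copy(), network.copy()
    for r_vis, r_sub, r0 in zip(vis.reactions, sub.reactions, network.reactions):
        cap = fva_max.get(r0.id)
        if cap is None:
            raise KeyError(f"no FVA maximum supplied for reaction {r0.id!r}")
        fold, direction = rfold[r0.id]
        if fold <= 0:
            raise ValueError(f"fold for reaction {r0.id!r} must be positive")
        caps = {
            Tissue.VISCERAL: cap,
            Tissue.SUBCUTANEOUS: cap,
        }
        if direction != NEUTRAL:
            other = (
                Tissue.SUBCUTANEOUS
                if direction == Tissue.VISCERAL.value
                else Tissue.VISCERAL
            )
            caps[other] = cap / fold
        for rx, tissue in ((r_vis, Tissue.VISCERAL), (r_sub, Tissue.SUBCUTANEOUS)):
            c = caps[tissue]
            rx.upper_bound = min(r0.upper_bound, c)
            if cap_reverse and r0.lower_bound < 0:
                rx.lower_bound = max(r0.lower_bound, -c)
            if rx.lower_bound > rx.upper_bound:  # cap below an equality bound
                rx.lower_bound = rx.upper_bound
    return vis, sub


@dataclass
class TissueComparison:
    stronger_in_visceral: Set[str]
    stronger_in_subcutaneous: Set[str]
    divergent: Set[str]
    candidates_visceral: Set[str]
    candidates_subcutaneous: Set[str]
    candidates_both: Set[str]
    candidates_visceral_only: Set[str]
    candidates_subcutaneous_only: Set[str]


def compare_tissue_deletions(
    visceral_records: Iterable[DeletionRecord],
    subcutaneous_records: Iterable[DeletionRecord],
    divergence_min: float = 0.10,
    rule: Optional[CandidateRule] = None,
) -> TissueComparison:
    """Genes whose deletion effect differs between tissues.

    A gene is divergent when its relative biomass or relative lipid
    production differs by more than ``divergence_min`` between the two
    tissue networks; "stronger in X" means the deletion hurts production
    more (lower relative value) in tissue X.  The candidate rule is also
    applied per tissue and the resulting sets partitioned.
    """
    rule = rule or CandidateRule()
    vis = {r.gene: r for r in visceral_records}
    sub = {r.gene: r for r in subcutaneous_records}
    if set(vis) != set(sub):
        diff = set(vis) ^ set(sub)
        raise ValueError(f"gene universes differ between tissues: {sorted(diff)}")
    stronger_vis, stronger_sub, divergent = set(), set(), set()
    for gene in vis:
        rv, rs = vis[gene], sub[gene]
        deltas = (
            rv.relative_biomass - rs.relative_biomass,
            rv.relative_lipid - rs.relative_lipid,
        )
        if any(abs(d) > divergence_min for d in deltas):
            divergent.add(gene)
            # lower relative production = stronger deletion effect
            worst = min(deltas)
            best = max(deltas)
            if worst < -divergence_min:
                stronger_vis.add(gene)
            if best > divergence_min:
                stronger_sub.add(gene)
    cand_vis = {g for g, r in vis.items() if rule.is_candidate(r)}
    cand_sub = {g for g, r in sub.items() if rule.is_candidate(r)}
    return TissueComparison(
        stronger_in_visceral=stronger_vis,
        stronger_in_subcutaneous=stronger_sub,
        divergent=divergent,
        candidates_visceral=cand_vis,
        candidates_subcutaneous=cand_sub,
        candidates_both=cand_vis & cand_sub,
        candidates_visceral_only=cand_vis - cand_sub,
        candidates_subcutaneous_only=cand_sub - cand_vis,
    )


# ------------------------------------------------------------------
# tabular I/O
# ------------------------------------------------------------------

def read_folds_tsv(path) -> List[GeneFoldDifference]:
    """Read fold table: columns ``gene``, ``fold``, ``higher_in``."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "fold", "higher_in"}
    if not required.issubset(df.columns):
        raise ValueError(f"fold table needs columns {sorted(required)}")
    return [
        GeneFoldDifference(gene=str(r.gene), fold=float(r.fold), higher_in=Tissue(r.higher_in))
        for r in df.itertuples()
    ]


def write_folds_tsv(folds: Iterable[GeneFoldDifference], path) -> None:
    pd.DataFrame(
        [{"gene": f.gene, "fold": f.fold, "higher_in": f.higher_in.value} for f in folds]
    ).to_csv(path, sep="\t", index=False)
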