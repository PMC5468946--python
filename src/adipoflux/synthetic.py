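"""Synthetic metabolic networks and screen data with known ground truth.

The generator builds small networks exhibiting every structure the
pipeline manipulates — exchange/transport/enzymatic reactions, isozyme
(OR) and complex (AND, incl. variant complexes) GPRs, two separate drain
objectives, planted dead-end metabolites — together with a ground-truth
record of what each analysis stage should recover.

Topology
--------
``n_linear_pathways`` uptake pathways (exchange → transport → enzymatic
step) converge on a hub metabolite.  From the hub:

* a biomass chain, one reaction per planted essential gene (sole gates on
  the only biomass route: deletion ⇒ relative biomass 0), ending in the
  ``biomass`` drain;
* a lipid branch: ``n_lipid_pair_segments`` segments of two parallel,
  individually sufficient reactions (the substrate of tissue-divergence
  experiments), then one reaction per planted candidate gene (sole gates
  on the lipid route: deletion ⇒ relative lipid 0, biomass untouched),
  ending in the ``lipid_droplet`` drain.

Deleting a single-pathway gene removes one of n interchangeable uptake
routes, so its relative biomass is (n−1)/n — the planted separating
threshold between essential and non-essential genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .calibration import Call, EssentialityCall
from .gpr import GPRRule, parse_gpr
from .network import (
    Metabolite,
    MetabolicNetwork,
    ObjectiveDefinition,
    Reaction,
)
from .screening import MediumDefinition
from .tissue import GeneFoldDifference, Tissue

#: uptake capacity of every pathway exchange in the generated medium
PATHWAY_UPTAKE = 10.0


class UnsatisfiableSpecError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    n_linear_pathways: int = 4
    n_isozyme_reactions: int = 1
    n_complex_reactions: int = 2  # one plain AND + one variant complex per pair
    n_dead_ends: int = 2
    planted_essentials: Tuple[str, ...] = ("ess_1", "ess_2")
    planted_candidates: Tuple[str, ...] = ("cand_1", "cand_2")
    n_lipid_pair_segments: int = 1
    seed: int = 0

    def validate(self) -> None:
        if min(
            self.n_linear_pathways,
            self.n_isozyme_reactions,
            self.n_complex_reactions,
            self.n_dead_ends,
            self.n_lipid_pair_segments,
        ) < 0:
            raise UnsatisfiableSpecError("counts must be ≥ 0")
        if self.n_linear_pathways < 1:
            raise UnsatisfiableSpecError("need at least one uptake pathway")
        if self.n_isozyme_reactions + self.n_complex_reactions > self.n_linear_pathways:
            raise UnsatisfiableSpecError(
                "isozyme + complex reactions exceed the number of pathway steps"
            )
        overlap = set(self.planted_essentials) & set(self.planted_candidates)
        if overlap:
            raise UnsatisfiableSpecError(
                f"genes planted as both essential and candidate: {sorted(overlap)}"
            )


@dataclass
class GroundTruth:
    essential_genes: Set[str]
    candidate_genes: Set[str]
    pathway_genes: Set[str]
    neutral_genes: Set[str]
    dead_end_metabolites: Set[str]
    lipid_pairs: List[Tuple[str, str]]  # (gene_a, gene_b) per parallel segment
    separating_threshold: float
    wt_optimum: float
    expected_relative_biomass: Dict[str, float]

    @property
    def essentiality_truth(self) -> Dict[str, bool]:
        genes = (
            self.essential_genes
            | self.candidate_genes
            | self.pathway_genes
            | self.neutral_genes
        )
        return {g: g in self.essential_genes for g in sorted(genes)}


def generate_network(spec: SyntheticSpec) -> Tuple[MetabolicNetwork, GroundTruth]:
    """Build a network from a :class:`SyntheticSpec`; deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mets: List[Metabolite] = []
    rxns: List[Reaction] = []
    genes: List[str] = []
    pathway_genes: Set[str] = set()
    neutral_genes: Set[str] = set()
    rel_bio: Dict[str, float] = {}

    n = spec.n_linear_pathways
    partial = (n - 1) / n  # relative biomass after losing one pathway

    def add_gene(g: str) -> str:
        if g not in genes:
            genes.append(g)
        return g

    mets.append(Metabolite(id="hub_c", compartment="c"))

    # GPR style per pathway: isozyme, complex (plain/variant alternating), single
    styles = (
        ["isozyme"] * spec.n_isozyme_reactions
        + ["complex"] * spec.n_complex_reactions
        + ["single"] * (n - spec.n_isozyme_reactions - spec.n_complex_reactions)
    )
    for i in range(n):
        s_e, s_c = f"s{i}_e", f"s{i}_c"
        mets.append(Metabolite(id=s_e, compartment="e"))
        mets.append(Metabolite(id=s_c, compartment="c"))
        rxns.append(
            Reaction(
                id=f"EX_s{i}",
                stoichiometry={s_e: -1.0},
                lower_bound=-PATHWAY_UPTAKE,
                upper_bound=1000.0,
            )
        )
        gt = add_gene(f"gt{i}")
        pathway_genes.add(gt)
        rel_bio[gt] = partial
        rxns.append(
            Reaction(
                id=f"T{i}",
                stoichiometry={s_e: -1.0, s_c: 1.0},
                lower_bound=0.0,
                upper_bound=1000.0,
                gpr=GPRRule.from_sets([{gt}]),
            )
        )
        style = styles[i]
        if style == "isozyme":
            ga, gb = add_gene(f"ge{i}a"), add_gene(f"ge{i}b")
            gpr = GPRRule.from_sets([{ga}, {gb}])
            neutral_genes |= {ga, gb}
            rel_bio[ga] = rel_bio[gb] = 1.0
        elif style == "complex" and i % 2 == 0:
            ga, gb = add_gene(f"ge{i}a"), add_gene(f"ge{i}b")
            gpr = GPRRule.from_sets([{ga, gb}])
            pathway_genes |= {ga, gb}
            rel_bio[ga] = rel_bio[gb] = partial
        elif style == "complex":
            # variant complex: shared subunit a with either b or c
            ga, gb, gc = add_gene(f"ge{i}a"), add_gene(f"ge{i}b"), add_gene(f"ge{i}c")
            gpr = GPRRule.from_sets([{ga, gb}, {ga, gc}])
            pathway_genes.add(ga)
            neutral_genes |= {gb, gc}
            rel_bio[ga] = partial
            rel_bio[gb] = rel_bio[gc] = 1.0
        else:
            ge = add_gene(f"ge{i}")
            gpr = GPRRule.from_sets([{ge}])
            pathway_genes.add(ge)
            rel_bio[ge] = partial
        rxns.append(
            Reaction(
                id=f"E{i}",
                stoichiometry={s_c: -1.0, "hub_c": 1.0},
                lower_bound=0.0,
                upper_bound=1000.0,
                gpr=gpr,
            )
        )

    # biomass chain: hub → bm1 → … → bmK, each step gated by one essential
    prev = "hub_c"
    for k, ess in enumerate(spec.planted_essentials, start=1):
        add_gene(ess)
        rel_bio[ess] = 0.0
        nxt = f"bm{k}_c"
        mets.append(Metabolite(id=nxt, compartment="c"))
        rxns.append(
            Reaction(
                id=f"B{k}",
                stoichiometry={prev: -1.0, nxt: 1.0},
                lower_bound=0.0,
                upper_bound=1000.0,
                gpr=GPRRule.from_sets([{ess}]),
            )
        )
        prev = nxt
    rxns.append(
        Reaction(
            id="DM_biomass",
            stoichiometry={prev: -1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
        )
    )

    # lipid branch: parallel pair segments, then candidate-gated chain
    lipid_pairs: List[Tuple[str, str]] = []
    prev = "hub_c"
    for d in range(spec.n_lipid_pair_segments):
        nxt = f"lp{d}_c"
        mets.append(Metabolite(id=nxt, compartment="c"))
        ga, gb = add_gene(f"g_alt{d}a"), add_gene(f"g_alt{d}b")
        neutral_genes |= {ga, gb}
        rel_bio[ga] = rel_bio[gb] = 1.0
        for tag, g in (("a", ga), ("b", gb)):
            rxns.append(
                Reaction(
                    id=f"LP{d}{tag}",
                    stoichiometry={prev: -1.0, nxt: 1.0},
                    lower_bound=0.0,
                    upper_bound=1000.0,
                    gpr=GPRRule.from_sets([{g}]),
                )
            )
        lipid_pairs.append((ga, gb))
        prev = nxt
    for k, cand in enumerate(spec.planted_candidates, start=1):
        add_gene(cand)
        rel_bio[cand] = 1.0
        nxt = f"l{k}_c"
        mets.append(Metabolite(id=nxt, compartment="c"))
        rxns.append(
            Reaction(
                id=f"L{k}",
                stoichiometry={prev: -1.0, nxt: 1.0},
                lower_bound=0.0,
                upper_bound=1000.0,
                gpr=GPRRule.from_sets([{cand}]),
            )
        )
        prev = nxt
    rxns.append(
        Reaction(
            id="DM_lipid",
            stoichiometry={prev: -1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
        )
    )

    # planted dead-ends: terminal metabolites that are only produced
    dead: Set[str] = set()
    for j in range(spec.n_dead_ends):
        mid = f"dead{j}_c"
        mets.append(Metabolite(id=mid, compartment="c"))
        rxns.append(
            Reaction(
                id=f"DEAD{j}",
                stoichiometry={"hub_c": -1.0, mid: 1.0},
                lower_bound=0.0,
                upper_bound=1000.0,
            )
        )
        dead.add(mid)

    net = MetabolicNetwork(
        metabolites=mets,
        reactions=rxns,
        genes=genes,
        objectives={
            "biomass": ObjectiveDefinition("biomass", {"DM_biomass": 1.0}),
            "lipid_droplet": ObjectiveDefinition("lipid_droplet", {"DM_lipid": 1.0}),
        },
        id=f"synthetic_{spec.seed}",
    )
    net.validate()
    truth = GroundTruth(
        essential_genes=set(spec.planted_essentials),
        candidate_genes=set(spec.planted_candidates),
        pathway_genes=pathway_genes,
        neutral_genes=neutral_genes,
        dead_end_metabolites=dead,
        lipid_pairs=lipid_pairs,
        separating_threshold=partial,
        wt_optimum=PATHWAY_UPTAKE * n,
        expected_relative_biomass=rel_bio,
    )
    return net, truth


def rich_medium(network: MetabolicNetwork, uptake: float = PATHWAY_UPTAKE) -> MediumDefinition:
    """Medium opening every pathway exchange at the given uptake."""
    bounds = {
        r.id: (-uptake, 1000.0)
        for r in network.exchange_reactions()
        if r.id.startswith("EX_")
    }
    return MediumDefinition(name="rich", exchange_bounds=bounds)


# ------------------------------------------------------------------
# essentiality calls
# ------------------------------------------------------------------

def generate_essentiality_calls(
    truth: Mapping[str, bool],
    n_experiments: int = 6,
    flip_rate: float = 0.0,
    seed: int = 0,
) -> List[EssentialityCall]:
    """Noisy multi-experiment calls from a gene → is-essential truth map.

    Each experiment reports the true call independently flipped with
    probability ``flip_rate``; the expected no-consensus fraction per
    gene is the binomial 1 − (1−p)ⁿ − pⁿ.
    """
    if not 0 <= flip_rate < 0.5:
        raise ValueError("flip_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    calls: List[EssentialityCall] = []
    for gene in sorted(truth):
        essential = truth[gene]
        for e in range(1, n_experiments + 1):
            flip = rng.random() < flip_rate
            reported = essential ^ flip
            calls.append(
                EssentialityCall(
                    gene=gene,
                    experiment=f"exp{e}",
                    call=Call.ESSENTIAL if reported else Call.NON_ESSENTIAL,
                )
            )
    return calls


def expected_no_consensus_fraction(flip_rate: float, n_experiments: int) -> float:
    """Closed-form chance that n independent flips disagree on one gene."""
    p, n = flip_rate, n_experiments
    return 1.0 - (1.0 - p) ** n - p ** n


# ------------------------------------------------------------------
# expression fold tables
# ------------------------------------------------------------------

def generate_fold_table(
    network: MetabolicNetwork,
    truth: GroundTruth,
    n_divergent: int = 1,
    fold_range: Tuple[float, float] = (2.0, 2.0),
    seed: int = 0,
) -> Tuple[List[GeneFoldDifference], Set[str]]:
    """Fold table planting per-tissue divergence on the lipid pair genes.

    For each of the first ``n_divergent`` parallel lipid segments, the
    "b" gene gets a fold drawn from ``fold_range`` (direction random by
    seed); all other genes get fold 1 (neutral).  Returns the table and
    the set of genes the differential deletion screen is expected to
    flag — the "a" partners, whose deletion forces flux through the
    capped "b" reaction in the lower-expression tissue.
    """
    if n_divergent > len(truth.lipid_pairs):
        raise UnsatisfiableSpecError(
            f"n_divergent={n_divergent} exceeds the {len(truth.lipid_pairs)} "
            "parallel lipid segments in the network"
        )
    rng = np.random.default_rng(seed)
    lo, hi = fold_range
    if lo < 1 or hi < lo:
        raise ValueError("fold_range must satisfy 1 ≤ lo ≤ hi")
    planted: Dict[str, GeneFoldDifference] = {}
    expected_divergent: Set[str] = set()
    for d in range(n_divergent):
        ga, gb = truth.lipid_pairs[d]
        fold = float(rng.uniform(lo, hi)) if hi > lo else lo
        direction = Tissue.VISCERAL if rng.random() < 0.5 else Tissue.SUBCUTANEOUS
        planted[gb] = GeneFoldDifference(gene=gb, fold=fold, higher_in=direction)
        expected_divergent.add(ga)
    table = [
        planted.get(g, GeneFoldDifference(gene=g, fold=1.0, higher_in=Tissue.VISCERAL))
        for g in network.genes
    ]
    return table, expected_divergent


# ------------------------------------------------------------------
# time-course toy model
# ------------------------------------------------------------------

def toy_adipocyte_network() -> MetabolicNetwork:
    """Small adipocyte-like model for time-course simulation.

    Glucose is split into two acetyl-CoA; TAG is hydrolysed into three
    fatty acids plus glycerol; fatty acids are either re-esterified with
    glycerol (plus Pi/NH₃/H⁺ cofactor uptake) into a lipid droplet,
    β-oxidised to acetyl-CoA (consuming O₂, releasing CO₂/H₂O), or
    released as NEFA.  Stoichiometries are illustrative, not elemental.
    """
    comp = "c"
    met_ids = ["glc", "tag", "fa", "glyc", "accoa", "ld", "o2", "h2o", "co2", "pi", "nh3", "h"]
    mets = [Metabolite(id=m, compartment=comp) for m in met_ids]
    rxns = [
        Reaction("EX_glc", {"glc": -1.0}, -1000, 1000),
        Reaction("EX_tag", {"tag": -1.0}, -1000, 1000),
        Reaction("EX_nefa", {"fa": -1.0}, -1000, 1000),
        Reaction("EX_o2", {"o2": -1.0}, -1000, 0),
        Reaction("EX_h2o", {"h2o": -1.0}, 0, 1000),
        Reaction("EX_co2", {"co2": -1.0}, 0, 1000),
        Reaction("EX_pi", {"pi": -1.0}, -1000, 0),
        Reaction("EX_nh3", {"nh3": -1.0}, -1000, 0),
        Reaction("EX_h", {"h": -1.0}, -1000, 0),
        Reaction("GLYC", {"glc": -1.0, "accoa": 2.0, "co2": 2.0}, 0, 1000),
        Reaction("LIPOLYSIS", {"tag": -1.0, "fa": 3.0, "glyc": 1.0}, 0, 1000),
        Reaction(
            "FAOX",
            {"fa": -1.0, "o2": -1.0, "accoa": 4.0, "co2": 1.0, "h2o": 1.0},
            0,
            1000,
        ),
        Reaction("GLYC_OX", {"glyc": -1.0, "accoa": 1.0, "h2o": 1.0}, 0, 1000),
        Reaction(
            "LD_SYNTH",
            {"fa": -3.0, "glyc": -1.0, "pi": -1.0, "nh3": -1.0, "h": -1.0, "ld": 1.0},
            0,
            1000,
        ),
        Reaction("DM_ld", {"ld": -1.0}, 0, 1000),
        Reaction("DM_accoa", {"accoa": -1.0}, 0, 1000),
    ]
    net = MetabolicNetwork(
        metabolites=mets,
        reactions=rxns,
        genes=[],
        objectives={
            "lipid_droplet": ObjectiveDefinition("lipid_droplet", {"DM_ld": 1.0}),
            "acetyl_coa": ObjectiveDefinition("acetyl_coa", {"DM_accoa": 1.0}),
        },
        id="toy_adipocyte",
    )
    net.validate()
    return net


def random_spec(seed: int) -> SyntheticSpec:
    """A randomised but always-satisfiable spec for property sweeps."""
    rng = np.random.default_rng(seed)
    # n ≤ 4 keeps the single-pathway relative biomass (n−1)/n below the
    # 0.80 candidate floor, so pathway genes never masquerade as candidates
    n = int(rng.integers(2, 5))
    n_iso = int(rng.integers(0, n))
    n_cplx = int(rng.integers(0, n - n_iso + 1))
    return SyntheticSpec(
        n_linear_pathways=n,
        n_isozyme_reactions=n_iso,
        n_complex_reactions=n_cplx,
        n_dead_ends=int(rng.integers(0, 4)),
        planted_essentials=tuple(f"ess_{k}" for k in range(1, int(rng.integers(1, 4)))),
        planted_candidates=tuple(f"cand_{k}" for k in range(1, int(rng.integers(1, 4)))),
        n_lipid_pair_segments=int(rng.integers(1, 3)),
        seed=seed,
    )
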