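"""Dual-objective single-gene-deletion screen and candidate classification.

Every gene is deleted in turn and the network's maximal biomass and
lipid-droplet production are recomputed by FBA, normalised to the
wild-type optimum of the same medium and objective.  Genes whose
deletion cuts lipid-droplet output while leaving biomass near wild type
are candidates for reducing adipocyte hypertrophy without impairing
proliferation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple, Union

import pandas as pd

from .deletions import apply_deletion
from .lp import SolverStatus, solve_fba
from .network import MetabolicNetwork, ObjectiveDefinition

#: slack allowed on relative values before a >1 ratio flags solver trouble
RATIO_TOL = 1e-6


@dataclass
class MediumDefinition:
    """Named set of exchange-reaction bounds.

    Uptake is negative flux, so a medium supplying glucose at up to 10
    units sets the glucose exchange bounds to ``(-10, upper)``.
    """

    name: str
    exchange_bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def validate(self, network: Optional[MetabolicNetwork] = None) -> None:
        for rid, (lo, hi) in self.exchange_bounds.items():
            if lo > hi:
                raise ValueError(f"medium {self.name!r}: inverted bounds on {rid!r}")
        if network is not None:
            known = {r.id for r in network.reactions}
            missing = set(self.exchange_bounds) - known
            if missing:
                raise ValueError(
                    f"medium {self.name!r} references unknown exchanges: "
                    f"{sorted(missing)}"
                )


@dataclass
class DeletionRecord:
    gene: str
    condition: str
    relative_biomass: float
    relative_lipid: float
    status_note: str = ""


@dataclass
class CandidateRule:
    """Selection region for hypertrophy-reducing gene candidates.

    A gene qualifies when deleting it cuts lipid-droplet production by
    more than ``lipid_reduction_min`` (strictly below
    ``1 − lipid_reduction_min`` relative) while biomass stays at or
    above ``biomass_floor`` of wild type (inclusive).
    """

    lipid_reduction_min: float = 0.05
    biomass_floor: float = 0.80

    def __post_init__(self) -> None:
        if not (0 < self.lipid_reduction_min < 1 and 0 < self.biomass_floor < 1):
            raise ValueError("rule fractions must lie in (0, 1)")

    def is_candidate(self, record: DeletionRecord) -> bool:
        return (
            record.relative_lipid < 1.0 - self.lipid_reduction_min
            and record.relative_biomass >= self.biomass_floor
        )


class UnusableMediumError(RuntimeError):
    """Wild-type optimum is zero or infeasible under a medium."""


def apply_medium(
    network: MetabolicNetwork,
    medium: MediumDefinition,
    closed_default: bool = True,
) -> MetabolicNetwork:
    """Copy of the network with the medium's exchange bounds installed.

    With ``closed_default=True`` all exchange lower bounds are first set
    to 0 — no uptake of anything the medium does not supply — while
    secretion (positive flux) stays open; the medium's explicit bounds
    are then applied.
    """
    medium.validate(network)
    out = network.copy()
    if closed_default:
        for r in out.exchange_reactions():
            if r.lower_bound < 0:
                r.lower_bound = 0.0
    for rid, (lo, hi) in medium.exchange_bounds.items():
        r = out.get_reaction(rid)
        r.lower_bound, r.upper_bound = lo, hi
    return out


def restrict_uptake(
    medium: MediumDefinition, caps: Mapping[str, float]
) -> MediumDefinition:
    """New medium with uptake magnitudes capped on selected exchanges.

    ``caps`` maps exchange ids to the maximal uptake magnitude; the
    lower bound is raised toward 0 to ``max(lower, −cap)``.  Secretion
    bounds are untouched.
    """
    for rid, cap in caps.items():
        if cap < 0:
            raise ValueError(f"cap magnitude for {rid!r} must be ≥ 0, got {cap}")
        if rid not in medium.exchange_bounds:
            raise ValueError(f"medium {medium.name!r} has no exchange {rid!r}")
    bounds = dict(medium.exchange_bounds)
    for rid, cap in caps.items():
        lo, hi = bounds[rid]
        bounds[rid] = (max(lo, -abs(cap)), hi)
    return MediumDefinition(name=f"{medium.name}_restricted", exchange_bounds=bounds)


def wild_type_optima(
    network: MetabolicNetwork,
    medium: MediumDefinition,
    objectives: Mapping[str, Union[str, ObjectiveDefinition]],
    closed_default: bool = True,
) -> Tuple[MetabolicNetwork, Dict[str, float]]:
    """Medium-conditioned network and its wild-type optimum per objective."""
    conditioned = apply_medium(network, medium, closed_default)
    optima: Dict[str, float] = {}
    for label, obj in objectives.items():
        res = solve_fba(conditioned, obj)
        if not res.ok or res.objective_value <= RATIO_TOL:
            raise UnusableMediumError(
                f"medium {medium.name!r}: wild-type {label} optimum is "
                f"{'infeasible' if not res.ok else res.objective_value}; "
                "screen cannot be normalised"
            )
        optima[label] = res.objective_value
    return conditioned, optima


def run_deletion_screen(
    network: MetabolicNetwork,
    media: Iterable[MediumDefinition],
    objectives: Optional[Mapping[str, Union[str, ObjectiveDefinition]]] = None,
    genes: Optional[Iterable[str]] = None,
    closed_default: bool = True,
) -> List[DeletionRecord]:
    """Single-gene deletion screen under each medium.

    For every (gene, medium) pair both objectives are re-optimised on the
    deleted network and divided by the medium's wild-type optimum
    (computed once per medium; normalisation is never cross-condition).
    Infeasible deletion LPs yield relative value 0 with a status note.
    """
    if objectives is None:
        objectives = {"biomass": "biomass", "lipid_droplet": "lipid_droplet"}
    gene_list = list(genes) if genes is not None else list(network.genes)
    records: List[DeletionRecord] = []
    for medium in media:
        conditioned, wt = wild_type_optima(network, medium, objectives, closed_default)
        for gene in gene_list:
            deleted = apply_deletion(conditioned, {gene})
            rel: Dict[str, float] = {}
            notes = []
            for label, obj in objectives.items():
                res = solve_fba(deleted, obj)
                if res.ok:
                    rel[label] = res.objective_value / wt[label]
                else:
                    rel[label] = 0.0
                    notes.append(f"{label}:{res.status.value}")
            records.append(
                DeletionRecord(
                    gene=gene,
                    condition=medium.name,
                    relative_biomass=rel["biomass"],
                    relative_lipid=rel["lipid_droplet"],
                    status_note=";".join(notes),
                )
            )
    return records


@dataclass
class CandidateSummary:
    per_condition: Dict[str, Set[str]]
    union: Set[str]
    intersection: Set[str]
    only_in: Dict[str, Set[str]]


def classify_candidates(
    records: Iterable[DeletionRecord], rule: Optional[CandidateRule] = None
) -> CandidateSummary:
    """Partition candidate genes across screen conditions.

    Returns the per-condition candidate sets plus their union,
    intersection, and the genes exclusive to each condition.
    """
    rule = rule or CandidateRule()
    per: Dict[str, Set[str]] = {}
    for rec in records:
        per.setdefault(rec.condition, set())
        if rule.is_candidate(rec):
            per[rec.condition].add(rec.gene)
    sets = list(per.values())
    union: Set[str] = set().union(*sets) if sets else set()
    inter: Set[str] = set.intersection(*sets) if sets else set()
    only = {
        cond: genes - set().union(*(g for c, g in per.items() if c != cond))
        for cond, genes in per.items()
    }
    return CandidateSummary(
        per_condition=per, union=union, intersection=inter, only_in=only
    )


# ------------------------------------------------------------------
# tabular I/O
# ------------------------------------------------------------------

def read_medium_tsv(path, name: Optional[str] = None) -> MediumDefinition:
    """Read a medium table: columns ``exchange_id``, ``lower``, ``upper``."""
    df = pd.read_csv(path, sep="\t")
    required = {"exchange_id", "lower", "upper"}
    if not required.issubset(df.columns):
        raise ValueError(f"medium table needs columns {sorted(required)}")
    bounds = {
        str(row.exchange_id): (float(row.lower), float(row.upper))
        for row in df.itertuples()
    }
    return MediumDefinition(name=name or str(path), exchange_bounds=bounds)


def write_medium_tsv(medium: MediumDefinition, path) -> None:
    rows = [
        {"exchange_id": rid, "lower": lo, "upper": hi}
        for rid, (lo, hi) in sorted(medium.exchange_bounds.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def records_to_frame(
    records: Iterable[DeletionRecord], rule: Optional[CandidateRule] = None
) -> pd.DataFrame:
    rule = rule or CandidateRule()
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "condition": r.condition,
                "relative_biomass": r.relative_biomass,
                "relative_lipid": r.relative_lipid,
                "candidate": rule.is_candidate(r),
                "status_note": r.status_note,
            }
            for r in records
        ]
    )


def frame_to_records(df: pd.DataFrame) -> List[DeletionRecord]:
    return [
        DeletionRecord(
            gene=str(r.gene),
            condition=str(r.condition),
            relative_biomass=float(r.relative_biomass),
            relative_lipid=float(r.relative_lipid),
            status_note=str(getattr(r, "status_note", "") or ""),
        )
        for r in df.itertuples()
    ]
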