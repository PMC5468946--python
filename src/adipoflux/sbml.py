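"""SBML reading and writing.

Writes SBML Level 3 + FBC v2 (species, flux-bound parameters, gene
products, geneProductAssociation trees preserving complex variants, and
one fbc objective per named network objective).  The reader is tolerant:
it accepts FBC documents as well as older COBRA-style encodings where
bounds live in kinetic-law parameters and GPRs in ``GENE_ASSOCIATION``
notes — genome-scale human reconstructions circulate in both dialects.
Missing bounds default to ±1000 (0 lower bound for irreversible
reactions).
"""

from __future__ import annotations

import re
from typing import Dict, List, Optional, Tuple

import libsbml

from .gpr import GPRRule, parse_gpr
from .network import (
    DEFAULT_BOUND,
    Metabolite,
    MetabolicNetwork,
    ObjectiveDefinition,
    Reaction,
)


class SBMLReadError(ValueError):
    """Malformed SBML; the message names the offending element."""


class SBMLWriteError(IOError):
    pass


_SID_BAD = re.compile(r"[^A-Za-z0-9_]")


def _sid(raw: str, prefix: str = "x") -> str:
    s = _SID_BAD.sub("_", raw)
    if not s or not (s[0].isalpha() or s[0] == "_"):
        s = f"{prefix}_{s}"
    return s


# ------------------------------------------------------------------
# writing
# ------------------------------------------------------------------

def write_sbml(network: MetabolicNetwork, path) -> str:
    """Serialise to SBML L3V1 + FBC v2; returns the path written.

    ``read_sbml(write_sbml(n))`` is structurally equal to ``n`` (same
    ids, stoichiometries, bounds, GPR variant sets and objectives).
    """
    network.validate()
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    model.setId(_sid(network.id, "m"))
    mplug = model.getPlugin("fbc")
    mplug.setStrict(True)

    for comp_id in sorted({m.compartment for m in network.metabolites}):
        c = model.createCompartment()
        c.setId(_sid(comp_id, "c"))
        c.setConstant(True)

    for m in network.metabolites:
        sp = model.createSpecies()
        sp.setId(_sid(m.id, "M"))
        sp.setName(m.name or m.id)
        sp.setCompartment(_sid(m.compartment, "c"))
        sp.setBoundaryCondition(m.is_boundary)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)

    gene_to_gp: Dict[str, str] = {}
    for i, gene in enumerate(network.genes):
        gp = mplug.createGeneProduct()
        gp.setId(f"G_{_sid(gene)}")
        gp.setLabel(gene)
        gene_to_gp[gene] = gp.getId()

    bound_params: Dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for r in network.reactions:
        rx = model.createReaction()
        rx.setId(_sid(r.id, "R"))
        rx.setName(r.name or r.id)
        rx.setReversible(r.lower_bound < 0)
        rx.setFast(False)
        for mid, coef in r.stoichiometry.items():
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies(_sid(mid, "M"))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(r.lower_bound))
        rplug.setUpperFluxBound(bound_param(r.upper_bound))
        if not r.gpr.is_empty:
            gpa = rplug.createGeneProductAssociation()
            # libsbml resolves tokens against geneProduct *labels*
            text = " or ".join(
                "(" + " and ".join(sorted(v)) + ")"
                for v in sorted(r.gpr.variants, key=lambda s: sorted(s))
            )
            gpa.setAssociation(text)

    for idx, (name, obj) in enumerate(sorted(network.objectives.items())):
        o = mplug.createObjective()
        o.setId(_sid(name, "obj"))
        o.setType("maximize")
        for rid, w in sorted(obj.coefficients.items()):
            fo = o.createFluxObjective()
            fo.setReaction(_sid(rid, "R"))
            fo.setCoefficient(w)
    if network.objectives:
        active = "biomass" if "biomass" in network.objectives else sorted(network.objectives)[0]
        mplug.setActiveObjectiveId(_sid(active, "obj"))

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise SBMLWriteError(f"could not write SBML to {path!r}")
    return str(path)


# ------------------------------------------------------------------
# reading
# ------------------------------------------------------------------

def read_sbml(path, dialect: str = "auto") -> MetabolicNetwork:
    """Parse an SBML file into a :class:`MetabolicNetwork`.

    ``dialect`` selects where GPRs are looked up: ``"fbc"``
    (geneProductAssociation), ``"cobra_notes"`` (GENE_ASSOCIATION notes)
    or ``"auto"`` (FBC first, notes as fallback, per reaction).
    """
    if dialect not in ("fbc", "cobra_notes", "auto"):
        raise ValueError(f"unknown dialect {dialect!r}")
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLReadError(
            f"SBML parse error in {path!r} at line {err.getLine()}: {err.getMessage()}"
        )
    model = doc.getModel()
    if model is None:
        raise SBMLReadError(f"{path!r}: document contains no <model> element")
    mplug = model.getPlugin("fbc")

    metabolites: List[Metabolite] = []
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "c",
                is_boundary=bool(sp.getBoundaryCondition()),
            )
        )

    gp_label: Dict[str, str] = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gp_label[gp.getId()] = gp.getLabel() or gp.getId()

    param_value = {
        model.getParameter(i).getId(): model.getParameter(i).getValue()
        for i in range(model.getNumParameters())
    }

    reactions: List[Reaction] = []
    genes: set = set()
    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        stoich: Dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        if not stoich:
            raise SBMLReadError(f"reaction {rx.getId()!r} has empty stoichiometry")
        lb, ub = _read_bounds(rx, param_value)
        gpr = _read_gpr(rx, gp_label, dialect)
        genes |= gpr.genes
        reactions.append(
            Reaction(
                id=rx.getId(),
                name=rx.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
            )
        )

    objectives: Dict[str, ObjectiveDefinition] = {}
    if mplug is not None:
        for i in range(mplug.getNumObjectives()):
            o = mplug.getObjective(i)
            coeffs = {
                o.getFluxObjective(j).getReaction(): o.getFluxObjective(j).getCoefficient()
                for j in range(o.getNumFluxObjectives())
            }
            coeffs = {k: v for k, v in coeffs.items() if v != 0}
            name = _strip_prefix(o.getId(), "obj_")
            if coeffs:
                objectives[name] = ObjectiveDefinition(name=name, coefficients=coeffs)

    declared = [gp_label[g] for g in gp_label] if gp_label else []
    all_genes = sorted(set(declared) | genes)
    net = MetabolicNetwork(
        metabolites=metabolites,
        reactions=reactions,
        genes=all_genes,
        objectives=objectives,
        id=model.getId() or "model",
    )
    net.validate()
    return net


def _strip_prefix(s: str, prefix: str) -> str:
    return s[len(prefix):] if s.startswith(prefix) else s


def _read_bounds(rx, param_value: Dict[str, float]) -> Tuple[float, float]:
    lb: Optional[float] = None
    ub: Optional[float] = None
    rplug = rx.getPlugin("fbc")
    if rplug is not None:
        lb_id, ub_id = rplug.getLowerFluxBound(), rplug.getUpperFluxBound()
        if lb_id and lb_id in param_value:
            lb = param_value[lb_id]
        if ub_id and ub_id in param_value:
            ub = param_value[ub_id]
    if (lb is None or ub is None) and rx.isSetKineticLaw():
        kl = rx.getKineticLaw()
        for j in range(kl.getNumParameters()):
            p = kl.getParameter(j)
            if p.getId() == "LOWER_BOUND" and lb is None:
                lb = p.getValue()
            elif p.getId() == "UPPER_BOUND" and ub is None:
                ub = p.getValue()
    if lb is None:
        lb = -DEFAULT_BOUND if rx.getReversible() else 0.0
    if ub is None:
        ub = DEFAULT_BOUND
    return lb, ub


_NOTE_GPR = re.compile(
    r"GENE[_ ]?ASSOCIATION\s*:\s*([^<\n]*)", re.IGNORECASE
)


def _read_gpr(rx, gp_label: Dict[str, str], dialect: str) -> GPRRule:
    if dialect in ("fbc", "auto"):
        rplug = rx.getPlugin("fbc")
        if rplug is not None and rplug.isSetGeneProductAssociation():
            assoc = rplug.getGeneProductAssociation().getAssociation()
            rule = _assoc_to_rule(assoc)
            # map geneProduct ids back to their labels
            return GPRRule.from_sets(
                [{gp_label.get(g, g) for g in v} for v in rule.variants]
            )
        if dialect == "fbc":
            return GPRRule.empty()
    notes = rx.getNotesString() if rx.isSetNotes() else ""
    m = _NOTE_GPR.search(notes)
    if m:
        text = m.group(1).strip()
        if text and text.lower() not in ("none", "n/a", "na", "-"):
            return parse_gpr(text)
    return GPRRule.empty()


def _assoc_to_rule(assoc) -> GPRRule:
    """Convert a libsbml FbcAssociation tree to a GPR rule in DNF."""
    if assoc is None:
        return GPRRule.empty()
    code = assoc.getTypeCode()
    if code == libsbml.SBML_FBC_GENEPRODUCTREF:
        return GPRRule.from_sets([{assoc.getGeneProduct()}])
    children = [
        _assoc_to_rule(assoc.getAssociation(i))
        for i in range(assoc.getNumAssociations())
    ]
    if code == libsbml.SBML_FBC_OR:
        variants = set()
        for c in children:
            variants |= set(c.variants)
        return GPRRule(frozenset(variants))
    if code == libsbml.SBML_FBC_AND:
        variants = {frozenset()}
        for c in children:
            variants = {a | b for a in variants for b in c.variants}
        return GPRRule(frozenset(variants))
    raise SBMLReadError(f"unsupported geneProductAssociation node (type {code})")
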