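"""Flux balance analysis (FBA) and flux variability analysis (FVA).

FBA solves  max c·v  subject to  S·v = 0,  lb ≤ v ≤ ub : steady-state
mass balance over the internal metabolites with flux bounds encoding
reversibility and medium composition.  FVA then reports, per reaction,
the minimum and maximum flux compatible with holding the objective at a
chosen fraction of its optimum.

The LP itself is delegated to the HiGHS solvers behind
``scipy.optimize.linprog``; this module owns the formulation.  Optimal
objective values are contract-guaranteed; a returned flux vector is one
witness among possibly many alternate optima.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Optional, Tuple, Union

import numpy as np
from scipy.optimize import linprog

from .network import MetabolicNetwork, ObjectiveDefinition

#: solver-side feasibility/optimality tolerance
SOLVER_TOL = 1e-9
#: tolerance for post-hoc assertions on returned solutions
ASSERT_TOL = 1e-6


class SolverStatus(str, Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"


class InfeasibleProblemError(RuntimeError):
    """The base FBA problem has no feasible solution."""


@dataclass
class FBAResult:
    status: SolverStatus
    objective_value: Optional[float]
    fluxes: Dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == SolverStatus.OPTIMAL


@dataclass
class FVAResult:
    ranges: Dict[str, Tuple[float, float]]
    optimum: float

    def __getitem__(self, rid: str) -> Tuple[float, float]:
        return self.ranges[rid]


def _objective_vector(
    network: MetabolicNetwork,
    objective: Union[ObjectiveDefinition, str],
    rxn_ids: list,
) -> np.ndarray:
    if isinstance(objective, str):
        try:
            objective = network.objectives[objective]
        except KeyError:
            raise KeyError(
                f"network has no objective {objective!r}; "
                f"known: {sorted(network.objectives)}"
            ) from None
    col = {rid: j for j, rid in enumerate(rxn_ids)}
    c = np.zeros(len(rxn_ids))
    for rid, w in objective.coefficients.items():
        if rid not in col:
            raise KeyError(f"objective {objective.name!r}: unknown reaction {rid!r}")
        c[col[rid]] = w
    return c


def _linprog(c_min, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
    return linprog(
        c_min,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": SOLVER_TOL,
                 "dual_feasibility_tolerance": SOLVER_TOL},
    )


_STATUS = {0: SolverStatus.OPTIMAL, 2: SolverStatus.INFEASIBLE, 3: SolverStatus.UNBOUNDED}


def solve_fba(
    network: MetabolicNetwork,
    objective: Union[ObjectiveDefinition, str],
    sense: str = "maximize",
) -> FBAResult:
    """Solve one flux balance problem.

    Parameters
    ----------
    objective:
        An :class:`ObjectiveDefinition` or the name of one registered on
        the network.
    sense:
        ``"maximize"`` (default) or ``"minimize"``.

    Solver failures are reported through ``status`` — never as silent
    zeros.
    """
    if sense not in ("maximize", "minimize"):
        raise ValueError(f"sense must be 'maximize' or 'minimize', got {sense!r}")
    S, _, rxn_ids = network.stoichiometric_matrix()
    c = _objective_vector(network, objective, rxn_ids)
    bounds = [(r.lower_bound, r.upper_bound) for r in network.reactions]
    sign = -1.0 if sense == "maximize" else 1.0
    res = _linprog(sign * c, S, np.zeros(S.shape[0]), bounds)
    status = _STATUS.get(res.status, SolverStatus.INFEASIBLE)
    if status != SolverStatus.OPTIMAL:
        return FBAResult(status=status, objective_value=None)
    fluxes = dict(zip(rxn_ids, res.x))
    return FBAResult(
        status=SolverStatus.OPTIMAL,
        objective_value=float(sign * res.fun),
        fluxes=fluxes,
    )


def solve_fva(
    network: MetabolicNetwork,
    objective: Union[ObjectiveDefinition, str],
    fraction_of_optimum: float = 1.0,
    reactions: Optional[list] = None,
) -> FVAResult:
    """Per-reaction flux ranges compatible with near-optimal objective.

    The base problem is solved first; its optimum, scaled by
    ``fraction_of_optimum`` ∈ [0, 1], becomes a floor constraint
    ``c·v ≥ fraction × optimum`` under which each reaction's flux is
    minimised and maximised.  ``fraction_of_optimum=0`` reduces to plain
    per-reaction min/max LPs over the original constraints.
    """
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must be in [0, 1]")
    S, _, rxn_ids = network.stoichiometric_matrix()
    c = _objective_vector(network, objective, rxn_ids)
    bounds = [(r.lower_bound, r.upper_bound) for r in network.reactions]
    base = solve_fba(network, objective, "maximize")
    if not base.ok:
        raise InfeasibleProblemError(
            f"base FBA problem is {base.status.value}; FVA aborted"
        )
    if fraction_of_optimum > 0:
        floor = fraction_of_optimum * base.objective_value
        A_ub = (-c).reshape(1, -1)
        b_ub = np.array([-floor])
    else:  # fraction 0: plain per-reaction min/max, no objective floor
        A_ub = b_ub = None
    targets = reactions if reactions is not None else rxn_ids
    col = {rid: j for j, rid in enumerate(rxn_ids)}
    b_eq = np.zeros(S.shape[0])
    ranges: Dict[str, Tuple[float, float]] = {}
    for rid in targets:
        j = col[rid]
        e = np.zeros(len(rxn_ids))
        e[j] = 1.0
        lo = _linprog(e, S, b_eq, bounds, A_ub, b_ub)
        hi = _linprog(-e, S, b_eq, bounds, A_ub, b_ub)
        if lo.status != 0 or hi.status != 0:
            raise InfeasibleProblemError(
                f"FVA subproblem for {rid!r} failed (status {lo.status}/{hi.status})"
            )
        vmin, vmax = float(lo.fun), float(-hi.fun)
        if vmin > vmax:  # numerical jitter on pinned fluxes
            vmin = vmax = 0.5 * (vmin + vmax)
        ranges[rid] = (vmin, vmax)
    return FVAResult(ranges=ranges, optimum=base.objective_value)


def max_flux_per_reaction(
    network: MetabolicNetwork,
    objectives: list,
    fraction_of_optimum: float = 1.0,
) -> Dict[str, float]:
    """Elementwise maximum of FVA max-fluxes across several objectives.

    The tissue-restriction workflow needs one cap per reaction while two
    drains (biomass, lipid droplet) are of interest; running FVA per
    objective and taking the larger max keeps either optimum reachable.
    Magnitude is taken over both flow directions so reversible reactions
    are capped symmetrically.
    """
    out: Dict[str, float] = {}
    for obj in objectives:
        fva = solve_fva(network, obj, fraction_of_optimum)
        for rid, (vmin, vmax) in fva.ranges.items():
            mag = max(abs(vmin), abs(vmax))
            out[rid] = max(out.get(rid, 0.0), mag)
    return out
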