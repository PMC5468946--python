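"""Metabolic-task battery: feasibility checks and negative controls.

A task asks whether the network can synthesise required outputs from a
restricted set of allowed inputs — or, for negative controls such as
essential-amino-acid synthesis, verifies that it *cannot*.  Each task is
evaluated with every exchange closed, temporary uptakes opened for the
allowed inputs, and temporary drains added for the required outputs; the
summed drain flux is maximised by FBA and compared against the expected
verdict.

Semantics are strict: anything not listed has no sink, so obligatory
byproducts (CO₂, water, …) must appear in ``required_outputs`` — with a
minimum of 0 they act as allowed sinks without being demanded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional

import pandas as pd

from .lp import solve_fba
from .network import (
    DEFAULT_BOUND,
    MetabolicNetwork,
    ObjectiveDefinition,
    Reaction,
)

#: a drain optimum above this counts as "the network can produce it"
FEASIBILITY_TOL = 1e-6


class Verdict(str, Enum):
    PASS = "pass"
    FAIL = "fail"
    UNRESOLVABLE = "unresolvable"


@dataclass(frozen=True)
class MetabolicTask:
    id: str
    allowed_inputs: Dict[str, float] = field(default_factory=dict)
    required_outputs: Dict[str, float] = field(default_factory=dict)
    expect_feasible: bool = True
    description: str = ""


@dataclass
class TaskResult:
    task_id: str
    verdict: Verdict
    feasible: Optional[bool]
    optimum: Optional[float]
    diagnostic: str = ""


def run_task(network: MetabolicNetwork, task: MetabolicTask) -> TaskResult:
    """Evaluate one task; the input network is left unmodified.

    Tasks referencing metabolites absent from the model are reported
    ``unresolvable`` (a third verdict, so task suites remain portable
    across model variants) rather than failed.
    """
    known = {m.id for m in network.metabolites}
    missing = (set(task.allowed_inputs) | set(task.required_outputs)) - known
    if missing:
        return TaskResult(
            task_id=task.id,
            verdict=Verdict.UNRESOLVABLE,
            feasible=None,
            optimum=None,
            diagnostic=f"metabolites not in model: {sorted(missing)}",
        )
    if not task.required_outputs:
        return TaskResult(
            task_id=task.id,
            verdict=Verdict.UNRESOLVABLE,
            feasible=None,
            optimum=None,
            diagnostic="task defines no required outputs",
        )
    work = network.copy()
    midx = work.metabolite_index
    for r in work.exchange_reactions():
        r.lower_bound = r.upper_bound = 0.0
    existing = {r.id for r in work.reactions}
    for mid, max_uptake in task.allowed_inputs.items():
        rid = _fresh_id(f"TASK_IN_{mid}", existing)
        work.reactions.append(
            Reaction(
                id=rid,
                stoichiometry={mid: -1.0},
                lower_bound=-abs(max_uptake),
                upper_bound=0.0,
            )
        )
        existing.add(rid)
    drain_ids: List[str] = []
    for mid, min_prod in task.required_outputs.items():
        rid = _fresh_id(f"TASK_OUT_{mid}", existing)
        work.reactions.append(
            Reaction(
                id=rid,
                stoichiometry={mid: -1.0},
                lower_bound=max(0.0, min_prod),
                upper_bound=DEFAULT_BOUND,
            )
        )
        existing.add(rid)
        drain_ids.append(rid)
    objective = ObjectiveDefinition(
        name=f"task_{task.id}", coefficients={rid: 1.0 for rid in drain_ids}
    )
    res = solve_fba(work, objective)
    feasible = res.ok and res.objective_value > FEASIBILITY_TOL
    verdict = Verdict.PASS if feasible == task.expect_feasible else Verdict.FAIL
    return TaskResult(
        task_id=task.id,
        verdict=verdict,
        feasible=feasible,
        optimum=res.objective_value if res.ok else None,
        diagnostic="" if verdict == Verdict.PASS else (
            f"expected {'feasible' if task.expect_feasible else 'infeasible'}, "
            f"solver status {res.status.value}, optimum {res.objective_value}"
        ),
    )


def _fresh_id(base: str, existing: Iterable[str]) -> str:
    existing = set(existing)
    rid, k = base, 1
    while rid in existing:
        rid = f"{base}_{k}"
        k += 1
    return rid


@dataclass
class SuiteReport:
    results: List[TaskResult]

    @property
    def n_pass(self) -> int:
        return sum(r.verdict == Verdict.PASS for r in self.results)

    @property
    def n_fail(self) -> int:
        return sum(r.verdict == Verdict.FAIL for r in self.results)

    @property
    def n_unresolvable(self) -> int:
        return sum(r.verdict == Verdict.UNRESOLVABLE for r in self.results)

    @property
    def all_passed(self) -> bool:
        return self.n_fail == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "task_id": r.task_id,
                    "verdict": r.verdict.value,
                    "feasible": r.feasible,
                    "optimum": r.optimum,
                    "diagnostic": r.diagnostic,
                }
                for r in self.results
            ]
        )


def run_suite(network: MetabolicNetwork, tasks: Iterable[MetabolicTask]) -> SuiteReport:
    """Run all tasks in their given order (deterministic report)."""
    tasks = list(tasks)
    if not tasks:
        raise ValueError("task suite is empty")
    return SuiteReport(results=[run_task(network, t) for t in tasks])


# ------------------------------------------------------------------
# task file I/O
# ------------------------------------------------------------------
# JSON: list of {id, allowed_inputs: {met: max}, required_outputs: {met: min},
#                expect_feasible, description}
# TSV: columns id, allowed_inputs ("met:max;met:max"), required_outputs,
#      expect_feasible (true/false), description

def read_tasks(path) -> List[MetabolicTask]:
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            raw = json.load(fh)
        return [
            MetabolicTask(
                id=str(t["id"]),
                allowed_inputs={k: float(v) for k, v in t.get("allowed_inputs", {}).items()},
                required_outputs={k: float(v) for k, v in t.get("required_outputs", {}).items()},
                expect_feasible=bool(t.get("expect_feasible", True)),
                description=str(t.get("description", "")),
            )
            for t in raw
        ]
    df = pd.read_csv(path, sep="\t")
    tasks = []
    for r in df.itertuples():
        tasks.append(
            MetabolicTask(
                id=str(r.id),
                allowed_inputs=_parse_pairs(getattr(r, "allowed_inputs", "")),
                required_outputs=_parse_pairs(getattr(r, "required_outputs", "")),
                expect_feasible=str(getattr(r, "expect_feasible", "true")).lower()
                in ("true", "1", "yes"),
                description=str(getattr(r, "description", "") or ""),
            )
        )
    return tasks


def _parse_pairs(text) -> Dict[str, float]:
    if text is None or (isinstance(text, float) and pd.isna(text)) or not str(text).strip():
        return {}
    out = {}
    for item in str(text).split(";"):
        met, _, val = item.partition(":")
        out[met.strip()] = float(val) if val else DEFAULT_BOUND
    return out
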