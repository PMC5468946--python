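"""Postprandial time-course simulation as a sequence of equilibrium FBAs.

FBA is an equilibrium technique, so time dependence is modelled by
pinning measured uptake/release rates — triacylglycerol (TAG) and
glucose uptake, non-esterified fatty acid (NEFA) release — to the
corresponding exchange reactions at each time point, yielding one
independent steady-state network per point.  Each is optimised for
lipid-droplet or acetyl-CoA production; no state is carried between
points.

During these runs every other exchange is closed except a fixed set of
auxiliary exchanges: O₂ uptake and H₂O/CO₂ secretion for both targets,
plus inorganic phosphate, ammonia and hydrogen-ion uptake for
lipid-droplet synthesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

from .lp import solve_fba
from .network import DEFAULT_BOUND, MetabolicNetwork


@dataclass(frozen=True)
class UptakeTimePoint:
    """Measured exchange rates at one postprandial time point.

    Magnitudes are non-negative; the uptake/release sign convention is
    applied when the bounds are installed.
    """

    time: float
    tag_uptake: float
    glucose_uptake: float
    nefa_release: float
    cohort: str = "lean"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be ≥ 0")
        if min(self.tag_uptake, self.glucose_uptake, self.nefa_release) < 0:
            raise ValueError("uptake/release magnitudes must be ≥ 0")


@dataclass
class ExchangeMap:
    """Which exchange reaction carries each measured or auxiliary flux."""

    tag: str = "EX_tag"
    glucose: str = "EX_glc"
    nefa: str = "EX_nefa"
    oxygen: str = "EX_o2"
    water: str = "EX_h2o"
    co2: str = "EX_co2"
    phosphate: str = "EX_pi"
    ammonia: str = "EX_nh3"
    proton: str = "EX_h"

    def auxiliary_uptake(self, objective: str) -> List[str]:
        aux = [self.oxygen]
        if objective == "lipid_droplet":
            aux += [self.phosphate, self.ammonia, self.proton]
        return aux

    def auxiliary_secretion(self) -> List[str]:
        return [self.water, self.co2]


class MissingExchangeError(KeyError):
    pass


@dataclass
class TimePointResult:
    time: float
    production: Optional[float]
    feasible: bool
    cohort: str


def constrain_timepoint(
    network: MetabolicNetwork,
    point: UptakeTimePoint,
    objective: str = "lipid_droplet",
    exchanges: Optional[ExchangeMap] = None,
    slack: float = 0.0,
) -> MetabolicNetwork:
    """Equilibrium network for one time point.

    The three measured exchanges are pinned to equality bounds (uptake
    negative, release positive); all other exchanges are closed except
    the auxiliary set for the chosen objective.  ``slack`` widens the
    pins to ±slack around the measurement, useful when diagnosing
    infeasible points.
    """
    ex = exchanges or ExchangeMap()
    out = network.copy()
    ridx = out.reaction_index
    needed = [ex.tag, ex.glucose, ex.nefa]
    needed += ex.auxiliary_uptake(objective) + ex.auxiliary_secretion()
    for rid in needed:
        if rid not in ridx:
            raise MissingExchangeError(
                f"model lacks required exchange reaction {rid!r}"
            )
    pins = {
        ex.tag: -point.tag_uptake,
        ex.glucose: -point.glucose_uptake,
        ex.nefa: point.nefa_release,
    }
    for r in out.exchange_reactions():
        if r.id in pins:
            v = pins[r.id]
            r.lower_bound, r.upper_bound = v - slack, v + slack
        elif r.id in ex.auxiliary_uptake(objective):
            r.lower_bound, r.upper_bound = -DEFAULT_BOUND, 0.0
        elif r.id in ex.auxiliary_secretion():
            r.lower_bound, r.upper_bound = 0.0, DEFAULT_BOUND
        elif r.id in [obj_rid for o in out.objectives.values() for obj_rid in o.coefficients]:
            # objective drains stay open in the forward direction
            r.lower_bound = max(r.lower_bound, 0.0)
        else:
            r.lower_bound = r.upper_bound = 0.0
    return out


def simulate_series(
    network: MetabolicNetwork,
    series: Sequence[UptakeTimePoint],
    objective: str = "lipid_droplet",
    exchanges: Optional[ExchangeMap] = None,
    slack: float = 0.0,
) -> List[TimePointResult]:
    """Optimal production per time point, each an independent FBA.

    Infeasible points are reported with ``feasible=False`` and a None
    production — never silently as zero.
    """
    results: List[TimePointResult] = []
    for point in series:
        constrained = constrain_timepoint(network, point, objective, exchanges, slack)
        res = solve_fba(constrained, objective)
        results.append(
            TimePointResult(
                time=point.time,
                production=res.objective_value if res.ok else None,
                feasible=res.ok,
                cohort=point.cohort,
            )
        )
    return results


# ------------------------------------------------------------------
# tabular I/O
# ------------------------------------------------------------------

def read_series_tsv(path, cohort: Optional[str] = None) -> List[UptakeTimePoint]:
    """Read a series: columns ``time, tag, glucose, nefa[, cohort]``."""
    df = pd.read_csv(path, sep="\t")
    required = {"time", "tag", "glucose", "nefa"}
    if not required.issubset(df.columns):
        raise ValueError(f"series table needs columns {sorted(required)}")
    points = []
    for r in df.itertuples():
        c = str(getattr(r, "cohort", "lean"))
        if cohort is not None and c != cohort:
            continue
        points.append(
            UptakeTimePoint(
                time=float(r.time),
                tag_uptake=float(r.tag),
                glucose_uptake=float(r.glucose),
                nefa_release=float(r.nefa),
                cohort=c,
            )
        )
    return sorted(points, key=lambda p: p.time)


def results_to_frame(results: Iterable[TimePointResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "time": r.time,
                "production": r.production,
                "feasible": r.feasible,
                "cohort": r.cohort,
            }
            for r in results
        ]
    )
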