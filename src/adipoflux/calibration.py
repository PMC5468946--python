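"""Essentiality-threshold calibration against experimental screens.

In-silico essentiality is a thresholded call — a gene is predicted
essential when its deletion drops biomass production strictly below a
fraction of the wild-type optimum.  The threshold is calibrated by
scanning a grid and keeping the value that maximises accuracy against a
consensus of experimental knockout screens (gene-trap mutagenesis and
CRISPR across cell lines): unanimous experiments give the gene a call,
disagreement marks it "no consensus" and keeps it out of the counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .screening import DeletionRecord


class Call(str, Enum):
    ESSENTIAL = "essential"
    NON_ESSENTIAL = "non_essential"
    NO_CONSENSUS = "no_consensus"


@dataclass(frozen=True)
class EssentialityCall:
    gene: str
    experiment: str
    call: Call


@dataclass(frozen=True)
class EssentialityConsensus:
    gene: str
    call: Call
    n_experiments: int


@dataclass(frozen=True)
class ConfusionCounts:
    """tp/fp/fn/tn with "essential" as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Metrics:
    """Percentages; a metric with an empty denominator is None."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]


class UndefinedMetricError(ZeroDivisionError):
    pass


def build_consensus(
    calls: Iterable[EssentialityCall],
    experiments: Optional[Iterable[str]] = None,
) -> List[EssentialityConsensus]:
    """Per-gene consensus over the selected experiments.

    Unanimous calls carry over; any disagreement yields
    ``no_consensus``.  Genes unreported in every selected experiment are
    omitted.  Duplicate (gene, experiment) pairs are an input error.
    """
    calls = list(calls)
    if experiments is not None:
        chosen = set(experiments)
        if not chosen:
            raise ValueError("experiment selection must be nonempty")
        calls = [c for c in calls if c.experiment in chosen]
    seen = set()
    by_gene: Dict[str, List[Call]] = {}
    for c in calls:
        key = (c.gene, c.experiment)
        if key in seen:
            raise ValueError(f"duplicate call for gene {c.gene!r} in {c.experiment!r}")
        seen.add(key)
        by_gene.setdefault(c.gene, []).append(c.call)
    out = []
    for gene in sorted(by_gene):
        votes = by_gene[gene]
        uniq = set(votes)
        call = uniq.pop() if len(uniq) == 1 else Call.NO_CONSENSUS
        out.append(EssentialityConsensus(gene=gene, call=call, n_experiments=len(votes)))
    return out


def predict_essentiality(
    records: Iterable[DeletionRecord], threshold: float
) -> Dict[str, Call]:
    """Predicted call per gene: essential iff relative biomass < threshold.

    The inequality is strict, so a gene sitting exactly at the threshold
    is non-essential — consistent with the ≥ floor used for candidate
    selection.  Records must come from a single medium condition.
    """
    records = list(records)
    conditions = {r.condition for r in records}
    if len(conditions) > 1:
        raise ValueError(
            f"records span several conditions {sorted(conditions)}; "
            "predict per condition"
        )
    return {
        r.gene: Call.ESSENTIAL if r.relative_biomass < threshold else Call.NON_ESSENTIAL
        for r in records
    }


def confusion_and_metrics(
    pred: Mapping[str, Call],
    consensus: Iterable[EssentialityConsensus],
) -> Tuple[ConfusionCounts, Metrics, int]:
    """Confusion counts and percentage metrics against a consensus.

    Only genes present in both the predictions and the consensus with a
    definite call enter the counts; no-consensus genes are tallied
    separately and returned as the third element.
    """
    tp = fp = fn = tn = no_cons = 0
    for c in consensus:
        if c.gene not in pred:
            continue
        if c.call == Call.NO_CONSENSUS:
            no_cons += 1
            continue
        predicted_essential = pred[c.gene] == Call.ESSENTIAL
        actually_essential = c.call == Call.ESSENTIAL
        if predicted_essential and actually_essential:
            tp += 1
        elif predicted_essential:
            fp += 1
        elif actually_essential:
            fn += 1
        else:
            tn += 1
    counts = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
    return counts, metrics_from_counts(counts), no_cons


def metrics_from_counts(counts: ConfusionCounts) -> Metrics:
    """sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), accuracy =
    (tp+tn)/total — all as percentages; empty denominators give None."""

    def pct(num: int, den: int) -> Optional[float]:
        return 100.0 * num / den if den else None

    return Metrics(
        sensitivity=pct(counts.tp, counts.tp + counts.fn),
        specificity=pct(counts.tn, counts.tn + counts.fp),
        accuracy=pct(counts.tp + counts.tn, counts.total),
    )


DEFAULT_GRID: Tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0001, 0.01), 2))


@dataclass
class ThresholdScan:
    table: pd.DataFrame
    selected: float


def threshold_scan(
    records: Iterable[DeletionRecord],
    consensus: Iterable[EssentialityConsensus],
    grid: Sequence[float] = DEFAULT_GRID,
) -> ThresholdScan:
    """Metrics along a threshold grid; selects the accuracy maximiser.

    Ties are broken toward the largest threshold, so among equally
    accurate cutoffs the scan reports the most permissive definition of
    essentiality.
    """
    if len(grid) == 0:
        raise ValueError("threshold grid must be nonempty")
    records = list(records)
    consensus = list(consensus)
    rows = []
    best: Tuple[float, float] = (-1.0, -1.0)  # (accuracy, threshold)
    for t in grid:
        pred = predict_essentiality(records, t)
        counts, m, no_cons = confusion_and_metrics(pred, consensus)
        rows.append(
            {
                "threshold": t,
                "tp": counts.tp,
                "fp": counts.fp,
                "fn": counts.fn,
                "tn": counts.tn,
                "no_consensus": no_cons,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "accuracy": m.accuracy,
            }
        )
        acc = m.accuracy if m.accuracy is not None else -1.0
        if (acc, t) >= best:
            best = (acc, t)
    return ThresholdScan(table=pd.DataFrame(rows), selected=best[1])


# ------------------------------------------------------------------
# tabular I/O
# ------------------------------------------------------------------

def read_calls_tsv(path) -> List[EssentialityCall]:
    """Read calls: columns ``gene``, ``experiment``, ``call``."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "experiment", "call"}
    if not required.issubset(df.columns):
        raise ValueError(f"calls table needs columns {sorted(required)}")
    return [
        EssentialityCall(gene=str(r.gene), experiment=str(r.experiment), call=Call(r.call))
        for r in df.itertuples()
    ]


def write_calls_tsv(calls: Iterable[EssentialityCall], path) -> None:
    pd.DataFrame(
        [{"gene": c.gene, "experiment": c.experiment, "call": c.call.value} for c in calls]
    ).to_csv(path, sep="\t", index=False)
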