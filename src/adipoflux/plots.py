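"""Plot exports for the screen, the threshold scan and the time course."""

from __future__ import annotations

from typing import Iterable, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .screening import CandidateRule, DeletionRecord, records_to_frame
from .timecourse import TimePointResult, results_to_frame


def plot_screen(
    records: Iterable[DeletionRecord],
    path,
    rule: Optional[CandidateRule] = None,
    condition: Optional[str] = None,
) -> str:
    """Scatter of relative biomass vs relative lipid-droplet production.

    The candidate region (lipid cut by more than the rule's minimum,
    biomass at or above its floor) is shaded.
    """
    rule = rule or CandidateRule()
    df = records_to_frame(records, rule)
    if condition is not None:
        df = df[df.condition == condition]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.axvspan(rule.biomass_floor, 1.02, ymax=(1 - rule.lipid_reduction_min) / 1.02,
               color="tab:blue", alpha=0.12)
    ax.scatter(df.relative_biomass, df.relative_lipid,
               c=df.candidate.map({True: "tab:blue", False: "0.6"}), s=14)
    ax.set_xlabel("relative biomass production")
    ax.set_ylabel("relative lipid-droplet production")
    ax.set_xlim(-0.02, 1.05)
    ax.set_ylim(-0.02, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)


def plot_threshold_scan(table: pd.DataFrame, path, selected: Optional[float] = None) -> str:
    """Sensitivity/specificity/accuracy along the threshold grid."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for col in ("sensitivity", "specificity", "accuracy"):
        ax.plot(table.threshold, table[col], label=col)
    if selected is not None:
        ax.axvline(selected, color="k", ls="--", lw=0.8, label=f"selected {selected:.2f}")
    ax.set_xlabel("biomass threshold (fraction of wild type)")
    ax.set_ylabel("percent")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)


def plot_timecourse(results: Iterable[TimePointResult], path, label: str = "production") -> str:
    """Optimal production across time points, one line per cohort."""
    df = results_to_frame(results)
    fig, ax = plt.subplots(figsize=(6, 4))
    for cohort, sub in df.groupby("cohort"):
        ax.plot(sub.time, sub.production, marker="o", label=cohort)
    ax.set_xlabel("time (h)")
    ax.set_ylabel(f"optimal {label} (flux units)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)
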