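"""Calibrate the essentiality threshold against experimental screens.

A gene is predicted essential when its deletion drops biomass strictly
below a fraction of wild type.  The fraction is chosen by scanning a
grid and maximising accuracy against a consensus of knockout
experiments; disagreeing experiments leave a gene at "no consensus" and
out of the confusion counts.
"""

from adipoflux import (
    ConfusionCounts,
    SyntheticSpec,
    build_consensus,
    generate_essentiality_calls,
    generate_network,
    metrics_from_counts,
    rich_medium,
    run_deletion_screen,
    threshold_scan,
)

# metrics from a confusion table (percentages)
m = metrics_from_counts(ConfusionCounts(tp=30, fp=23, fn=117, tn=1020))
print(f"example confusion table -> accuracy {m.accuracy:.1f}%, "
      f"sensitivity {m.sensitivity:.1f}%, specificity {m.specificity:.1f}%")

# full calibration on synthetic data: with two uptake pathways the
# weakest non-essential gene sits at 0.5 relative biomass, so the scan
# should select 50%
spec = SyntheticSpec(n_linear_pathways=2, n_isozyme_reactions=1,
                     n_complex_reactions=0, seed=8)
net, truth = generate_network(spec)
records = run_deletion_screen(net, [rich_medium(net)])
calls = generate_essentiality_calls(truth.essentiality_truth,
                                    n_experiments=6, flip_rate=0.0, seed=8)
scan = threshold_scan(records, build_consensus(calls))
print("selected threshold:", scan.selected,
      "| planted separation:", truth.separating_threshold)
print(scan.table.loc[scan.table.threshold.isin([0.25, 0.5, 0.75]),
                     ["threshold", "accuracy", "sensitivity", "specificity"]])
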