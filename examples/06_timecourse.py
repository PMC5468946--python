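"""Postprandial time-course as a sequence of independent equilibria.

Measured TAG/glucose uptake and NEFA release are pinned to their
exchange reactions at each time point; each point is an independent FBA
(no state carries over), tracing optimal lipid-droplet and acetyl-CoA
production over the day.
"""

from adipoflux import UptakeTimePoint, simulate_series, toy_adipocyte_network

net = toy_adipocyte_network()

# a stylised postprandial wave: uptake rises after the meal and decays
series = [
    UptakeTimePoint(time=t, tag_uptake=tag, glucose_uptake=glc, nefa_release=nefa)
    for t, tag, glc, nefa in [
        (0, 0.2, 1.0, 0.5), (2, 1.0, 3.0, 0.3), (5, 1.5, 2.0, 0.6),
        (8, 0.8, 1.5, 0.9), (11, 2.0, 2.5, 0.4), (24, 0.3, 1.0, 0.7),
    ]
]

for objective in ("lipid_droplet", "acetyl_coa"):
    curve = simulate_series(net, series, objective)
    values = ", ".join(f"{r.time:.0f}h={r.production:.2f}" for r in curve)
    print(f"{objective}: {values}")
# lipid-droplet production tracks TAG uptake net of NEFA release
# ((3*TAG − NEFA)/3 on this toy stoichiometry); acetyl-CoA additionally
# draws on glucose (2 per glucose)
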