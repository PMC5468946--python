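"""Flux balance and flux variability analysis on a generated network.

FBA maximises a drain (here biomass) subject to steady-state mass
balance; FVA reports, per reaction, the flux range compatible with
holding the objective at its optimum — wide ranges reveal redundant
routes, pinned ranges reveal bottlenecks.
"""

from adipoflux import SyntheticSpec, generate_network, solve_fba, solve_fva

net, _ = generate_network(SyntheticSpec(seed=0))

res = solve_fba(net, "biomass")
print("wild-type biomass optimum:", res.objective_value)
# 4 uptake pathways x 10 flux units each = 40

fva = solve_fva(net, "lipid_droplet", fraction_of_optimum=1.0)
for rid in ("LP0a", "LP0b", "DM_lipid"):
    lo, hi = fva[rid]
    print(f"{rid}: flux range [{lo:.1f}, {hi:.1f}] at the lipid optimum")
# the two parallel lipid-branch reactions are interchangeable (range
# 0..40) while the drain itself is pinned at 40
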