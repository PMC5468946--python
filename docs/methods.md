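# Methods

## Model

The central object is a genome-scale metabolic network: metabolites with
compartments, reactions with signed stoichiometries and flux bounds,
gene–protein–reaction (GPR) rules, and named linear objectives.  Flux
balance analysis (FBA) solves

    max  c·v   s.t.   S·v = 0,   lb ≤ v ≤ ub

where S has one row per non-boundary metabolite and one column per
reaction.  Flux variability analysis (FVA) re-solves a min and a max LP
per reaction under the extra constraint `c·v ≥ f·z*` with `z*` the FBA
optimum and `f ∈ [0,1]` the `fraction_of_optimum`; at `f = 0` the floor
is dropped entirely, reducing to plain per-reaction min/max LPs.
Degenerate optima are the rule in these models, so only objective values
are contract-guaranteed; any returned flux vector is a witness, not
"the" solution.

Sign conventions: exchanges are written `met → ∅`, uptake is negative
flux, secretion positive; default bounds are ±1000 flux units
(nominally mmol·gDW⁻¹·h⁻¹), with lower bound 0 for irreversible
reactions, applied whenever an SBML file omits bounds.

### GPR semantics

A rule is normalised on parse to a disjunction of conjunctions — a set
of *variants*, each the gene set of one sufficient enzyme or complex.
Complexes are assumed permanent and every subunit necessary, while some
complexes have multiple variants using different subunits; an isozyme is
the one-gene special case of a variant.  A deletion closes a reaction
iff every variant intersects the deleted set.  Reactions without a GPR
(spontaneous, exchange, orphan) are never closed by deletions.  Deletion
acts on bounds (set to 0) rather than removing columns, keeping a stable
reaction universe across reports.

### Dead-end metabolites

A dead-end is a metabolite that can only be produced or only consumed
(reversible reactions count on both sides); such metabolites cannot
carry steady-state flux.  Closed reactions (both bounds 0) contribute
nothing, and metabolites declared but untouched by any open reaction are
degenerate dead-ends.  The iterative mode removes reactions touching
dead-ends and re-scans to a fixed point, which unravels orphan chains
whose interior looks balanced on a single pass.

### Screen and candidate rule

The screen deletes one gene at a time and re-optimises biomass and
lipid-droplet production under each medium, normalising by that medium's
wild-type optimum (never across conditions).  The candidate rule flags
genes with `relative_lipid < 1 − lipid_reduction_min` (default 0.05,
strict, "more than 5% reduction") and `relative_biomass ≥ biomass_floor`
(default 0.80, inclusive).  The matching essentiality prediction is
strict in the other direction — essential iff
`relative_biomass < threshold` — so a gene sitting exactly at the 80%
floor is consistently non-essential and a viable candidate.

### Threshold calibration

Experimental essentiality calls are aggregated per gene across selected
experiments: unanimous calls carry over, any disagreement yields
`no_consensus`, and only definite-consensus genes enter the confusion
counts (no-consensus genes are tallied separately; genes absent from all
experiments are unscorable and excluded).  Sensitivity = tp/(tp+fn),
specificity = tn/(tn+fp), accuracy = (tp+tn)/total, reported as
percentages with empty denominators surfaced as undefined rather than 0.
The scan grid defaults to 0.00–1.00 in steps of 0.01; accuracy is the
selection criterion and ties break toward the largest threshold.

### Tissue restriction

Expression fold differences (fold ≥ 1, direction carried separately) are
projected onto reactions: over a reaction's GPR genes with data, all
directions agreeing gives (smallest fold, that direction); mixed
directions, unit folds or no data leave the reaction neutral.  Per-
reaction caps come from FVA maxima taken elementwise over the biomass
and lipid-droplet objectives (flux magnitude over both directions), so
either optimum stays reachable.  The favoured tissue keeps the cap, the
other gets cap/fold; neutral reactions keep the cap in both; reversible
reactions are capped symmetrically in magnitude by default
(`cap_reverse=False` restricts only the forward direction — the choice
is exposed because only the maximal flux is well-defined by the
procedure).  Reactions with cap 0 stay closed in both tissues.

### Time course

FBA is an equilibrium technique, so time dependence is modelled as a
sequence of unrelated equilibria: at each measured time point the TAG
and glucose uptakes and the NEFA release are pinned as equality bounds
on their exchange reactions (a ±slack option exists for diagnosing
infeasible points), all other exchanges are closed except a fixed
auxiliary set — O₂ uptake and H₂O/CO₂ secretion always, plus inorganic
phosphate, ammonia and hydrogen-ion uptake for lipid-droplet runs — and
the objective (lipid droplet or acetyl-CoA) is maximised independently
per point.  No storage state carries between points; infeasible points
are flagged, never reported as zero production.

### Metabolic tasks

A task closes every exchange, opens temporary uptakes for its allowed
inputs, adds temporary drains for its required outputs, and maximises
the summed drain flux; the network "can" perform the task when the
optimum exceeds 1e−6.  Semantics are strict: obligatory byproducts must
be listed as outputs (a minimum of 0 makes them permitted sinks without
being demanded).  Tasks referencing metabolites missing from the model
are a third verdict, `unresolvable`, keeping task suites portable across
model variants.  Verdicts compare feasibility against the task's
expectation, so negative controls ("must not synthesise X") pass by
being infeasible.

## Synthetic data generator

The generator emulates the structures the pipeline manipulates, not
realistic adipocyte stoichiometry.  `n_linear_pathways` uptake pathways
(exchange at 10 flux units → gene-gated transport → gene-gated enzymatic
step) converge on a hub metabolite.  Pathway enzymatic steps carry, in
order, isozyme GPRs (`a or b`), complexes (plain `a and b` alternating
with variant complexes `(a and b) or (a and c)`), and single genes.
From the hub, a biomass chain gated one reaction per planted essential
gene ends in the biomass drain, and a lipid branch — parallel
two-reaction segments (for tissue-divergence experiments) followed by
one reaction per planted candidate gene — ends in the lipid-droplet
drain.  Dead-ends are planted as terminal only-produced metabolites that
cannot carry flux and leave optima untouched.  Objectives are
single-metabolite drains to keep optima analytic: both wild-type optima
equal 10·n.

Consequences used as ground truth: essential genes give relative biomass
0; candidates give relative lipid 0 at relative biomass 1; a
single-pathway gene gives (n−1)/n, which is therefore the planted
separating threshold recovered by the calibration scan (n = 2 plants
0.5).  Essentiality calls flip the true call independently per
experiment with probability `flip_rate`; the expected no-consensus
fraction is the binomial `1 − (1−p)ⁿ − pⁿ`.  Fold tables plant a fold on
the "b" member of a parallel lipid segment; the differential screen then
flags the "a" partner, whose deletion forces flux through the capped
route — per-gene divergence can only surface at the redundant partner of
a capped reaction, because deleting the capped gene removes the capped
reaction itself.  A single integer seed drives all randomness and
regenerating with the same seed reproduces byte-identical SBML.

What passing on synthetic data does *not* show: behaviour under the
thousands-of-reactions scale, alternate-optima pathologies of real
reconstructions, biological plausibility of media, or noise structure of
real knockout screens beyond independent flips.

## Numerical choices

* LP solving: HiGHS via `scipy.optimize.linprog`; solver tolerances
  1e−9, post-hoc assertions at 1e−6 (genome-scale LPs with ±1000
  bounds).
* Task feasibility: drain optimum > 1e−6.
* Relative screen values above 1 + 1e−6 indicate solver trouble and are
  treated as errors by the tests.
* FVA min/max jitter on pinned fluxes is averaged when min exceeds max
  by numerical noise.
* Infeasible deletion LPs enter the screen as relative value 0 with a
  status note (the deletion genuinely admits no steady state).

## Problem sizes

The test suite and the reproduction script run on synthetic networks of
roughly 15–25 reactions: vertex-enumeration cross-checks use
8-reaction networks (where enumerating basic feasible solutions is
exact and cheap), GPR truth tables up to 6 genes (64 assignments), the
consensus-noise check 1000 genes × 6 experiments, and the invariant
sweep 100 generated networks.  These sizes make every oracle exhaustive
rather than sampled; the pipeline itself has no size-dependent logic.

## Known limitations

* No parsimonious FBA, MOMA/ROOM, or true dynamic FBA; the time course
  is deliberately a sequence of independent equilibria.
* Tissue restriction uses only relative fold differences — absolute
  expression integration (GIMME/iMAT/E-flux style) is out of scope.
* Double deletions and partial knock-downs are not implemented.
* SBML identifiers outside the SId grammar are sanitised on write, so a
  round-trip preserves structure but may normalise exotic ids.
* The tolerant reader covers FBC v2 and COBRA-notes dialects; kinetic
  laws are read only for their bound parameters.
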