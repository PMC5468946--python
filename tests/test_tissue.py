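"""Expression-fold flux caps and per-tissue deletion comparison."""

import pytest

from adipoflux import (
    GeneFoldDifference,
    MediumDefinition,
    Tissue,
    apply_medium,
    build_tissue_networks,
    compare_tissue_deletions,
    generate_fold_table,
    reaction_fold,
    rich_medium,
    run_deletion_screen,
    solve_fba,
)
from adipoflux.lp import max_flux_per_reaction
from adipoflux.screening import DeletionRecord
from adipoflux.tissue import NEUTRAL


def _fold(gene, fold, tissue=Tissue.VISCERAL):
    return GeneFoldDifference(gene=gene, fold=fold, higher_in=tissue)


class TestReactionFold:
    def test_smallest_fold_of_agreeing_genes(self, synthetic_net_truth):
        net, _ = synthetic_net_truth
        # ge0a / ge0b are isozymes of the same reaction E0
        folds = [_fold("ge0a", 2.0), _fold("ge0b", 3.0)]
        assert reaction_fold(net, folds)["E0"] == (2.0, "visceral")

    def test_conflicting_directions_neutralise(self, synthetic_net_truth):
        net, _ = synthetic_net_truth
        folds = [_fold("ge0a", 2.0, Tissue.VISCERAL), _fold("ge0b", 3.0, Tissue.SUBCUTANEOUS)]
        assert reaction_fold(net, folds)["E0"] == (1.0, NEUTRAL)

    def test_unit_folds_are_neutral(self, synthetic_net_truth):
        net, _ = synthetic_net_truth
        folds = [_fold(g, 1.0) for g in net.genes]
        assert all(v == (1.0, NEUTRAL) for v in reaction_fold(net, folds).values())

    def test_reactions_without_data_are_neutral(self, synthetic_net_truth):
        net, _ = synthetic_net_truth
        assert reaction_fold(net, [])["T0"] == (1.0, NEUTRAL)

    def test_unknown_gene_rejected(self, synthetic_net_truth):
        net, _ = synthetic_net_truth
        with pytest.raises(ValueError, match="unknown gene"):
            reaction_fold(net, [_fold("nope", 2.0)])

    def test_sub_unit_fold_rejected(self):
        with pytest.raises(ValueError, match="≥ 1"):
            GeneFoldDifference(gene="g", fold=0.5, higher_in=Tissue.VISCERAL)


class TestBuildTissueNetworks:
    def test_favoured_tissue_keeps_cap_other_divided(self, chain_network):
        folds = [_fold("g1", 2.0, Tissue.VISCERAL)]
        fva_max = {r.id: 10.0 for r in chain_network.reactions}
        vis, sub = build_tissue_networks(chain_network, folds, fva_max)
        assert vis.get_reaction("R1").upper_bound == 10.0
        assert sub.get_reaction("R1").upper_bound == 5.0

    def test_neutral_reactions_identical(self, chain_network):
        fva_max = {r.id: 10.0 for r in chain_network.reactions}
        vis, sub = build_tissue_networks(chain_network, [], fva_max)
        for rv, rs in zip(vis.reactions, sub.reactions):
            assert (rv.lower_bound, rv.upper_bound) == (rs.lower_bound, rs.upper_bound)

    def test_reversible_reaction_capped_symmetrically(self, chain_network):
        folds = [_fold("g1", 2.0, Tissue.VISCERAL)]
        net = chain_network.copy()
        net.get_reaction("R1").lower_bound = -1000.0
        fva_max = {r.id: 10.0 for r in net.reactions}
        vis, sub = build_tissue_networks(net, folds, fva_max)
        assert sub.get_reaction("R1").lower_bound == -5.0
        vis2, sub2 = build_tissue_networks(net, folds, fva_max, cap_reverse=False)
        assert sub2.get_reaction("R1").lower_bound == -1000.0

    def test_zero_fva_max_stays_closed(self, chain_network):
        folds = [_fold("g1", 2.0, Tissue.VISCERAL)]
        fva_max = {r.id: 0.0 for r in chain_network.reactions}
        vis, sub = build_tissue_networks(chain_network, folds, fva_max)
        assert vis.get_reaction("R1").upper_bound == 0.0
        assert sub.get_reaction("R1").upper_bound == 0.0

    def test_missing_fva_entry_rejected(self, chain_network):
        with pytest.raises(KeyError, match="FVA maximum"):
            build_tissue_networks(chain_network, [], {"R1": 1.0})

    def test_caps_only_tighten(self, synthetic_net_truth):
        net, truth = synthetic_net_truth
        conditioned = apply_medium(net, rich_medium(net))
        fva_max = max_flux_per_reaction(conditioned, ["biomass", "lipid_droplet"])
        folds, _ = generate_fold_table(net, truth, n_divergent=1, seed=4)
        vis, sub = build_tissue_networks(conditioned, folds, fva_max)
        base = solve_fba(conditioned, "biomass").objective_value
        for tissue_net in (vis, sub):
            assert solve_fba(tissue_net, "biomass").objective_value <= base + 1e-6


class TestCompare:
    def _rec(self, gene, bio, lip, cond="t"):
        return DeletionRecord(gene=gene, condition=cond,
                              relative_biomass=bio, relative_lipid=lip)

    def test_identical_records_no_divergence(self):
        recs = [self._rec("g", 0.9, 0.9)]
        cmp = compare_tissue_deletions(recs, recs)
        assert cmp.divergent == set()

    def test_planted_divergence_flagged_exactly(self):
        vis = [self._rec("g0", 1.0, 1.0), self._rec("g1", 1.0, 1.0)]
        sub = [self._rec("g0", 1.0, 1.0), self._rec("g1", 1.0, 0.85)]
        cmp = compare_tissue_deletions(vis, sub)
        assert cmp.divergent == {"g1"}
        assert cmp.stronger_in_subcutaneous == {"g1"}

    def test_label_swap_symmetry(self):
        vis = [self._rec("g", 0.6, 1.0)]
        sub = [self._rec("g", 1.0, 1.0)]
        fwd = compare_tissue_deletions(vis, sub)
        rev = compare_tissue_deletions(sub, vis)
        assert fwd.stronger_in_visceral == rev.stronger_in_subcutaneous == {"g"}

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError, match="universes"):
            compare_tissue_deletions([self._rec("g1", 1, 1)], [self._rec("g2", 1, 1)])

    def test_divergence_threshold_boundary(self):
        vis = [self._rec("g", 1.0, 1.0)]
        sub = [self._rec("g", 0.90, 1.0)]  # exactly 0.10 is not "more than"
        assert compare_tissue_deletions(vis, sub).divergent == set()


class TestEndToEnd:
    def _screens(self, net, truth, n_divergent, seed):
        conditioned = apply_medium(net, rich_medium(net))
        folds, expected = generate_fold_table(net, truth, n_divergent, seed=seed)
        fva_max = max_flux_per_reaction(conditioned, ["biomass", "lipid_droplet"])
        vis, sub = build_tissue_networks(conditioned, folds, fva_max)
        med = MediumDefinition(name="t")
        rv = run_deletion_screen(vis, [med], closed_default=False)
        rs = run_deletion_screen(sub, [med], closed_default=False)
        return compare_tissue_deletions(rv, rs), expected

    def test_fold_free_tissues_never_diverge(self, synthetic_net_truth):
        net, truth = synthetic_net_truth
        cmp, _ = self._screens(net, truth, n_divergent=0, seed=2)
        assert cmp.divergent == set()

    def test_planted_fold_reveals_partner_gene(self, synthetic_net_truth):
        net, truth = synthetic_net_truth
        cmp, expected = self._screens(net, truth, n_divergent=1, seed=2)
        assert cmp.divergent == expected
        # the candidate sets themselves stay tissue-independent here: the
        # planted fold only caps one member of a redundant pair
        assert cmp.candidates_both == truth.candidate_genes
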