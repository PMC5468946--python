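"""Media handling, the dual-objective screen and candidate classification."""

import numpy as np
import pytest

from adipoflux import (
    CandidateRule,
    DeletionRecord,
    MediumDefinition,
    apply_deletion,
    apply_medium,
    classify_candidates,
    restrict_uptake,
    rich_medium,
    run_deletion_screen,
    solve_fba,
)
from adipoflux.screening import (
    UnusableMediumError,
    read_medium_tsv,
    records_to_frame,
    wild_type_optima,
    write_medium_tsv,
)


class TestApplyMedium:
    def test_empty_medium_closes_all_uptake(self, synthetic_net_truth):
        net, _ = synthetic_net_truth
        out = apply_medium(net, MediumDefinition(name="empty"), closed_default=True)
        assert solve_fba(out, "biomass").objective_value == pytest.approx(0.0, abs=1e-9)

    def test_chain_medium_sets_uptake(self, chain_network):
        closed = apply_medium(chain_network, MediumDefinition(name="none"))
        assert solve_fba(closed, "drain").objective_value == pytest.approx(0.0, abs=1e-9)
        med = MediumDefinition(name="A", exchange_bounds={"EX_A": (-10.0, 0.0)})
        out = apply_medium(chain_network, med)
        assert solve_fba(out, "drain").objective_value == pytest.approx(10.0)

    def test_secretion_stays_open_under_closed_default(self, chain_network):
        out = apply_medium(chain_network, MediumDefinition(name="none"))
        assert out.get_reaction("EX_A").upper_bound == 1000.0
        assert out.get_reaction("DM_B").upper_bound == 1000.0

    def test_restricted_medium_never_beats_rich(self, synthetic_net_truth):
        net, _ = synthetic_net_truth
        rich = rich_medium(net)
        rng = np.random.default_rng(3)
        rich_opt = solve_fba(apply_medium(net, rich), "biomass").objective_value
        for _ in range(10):
            sub_bounds = {
                rid: (float(-rng.uniform(0, 10)), hi)
                for rid, (lo, hi) in rich.exchange_bounds.items()
            }
            sub = MediumDefinition(name="sub", exchange_bounds=sub_bounds)
            sub_opt = solve_fba(apply_medium(net, sub), "biomass").objective_value
            assert sub_opt <= rich_opt + 1e-9

    def test_inverted_bounds_rejected(self, chain_network):
        med = MediumDefinition(name="bad", exchange_bounds={"EX_A": (1.0, -1.0)})
        with pytest.raises(ValueError, match="inverted"):
            apply_medium(chain_network, med)

    def test_unknown_exchange_rejected(self, chain_network):
        med = MediumDefinition(name="bad", exchange_bounds={"EX_Z": (-1.0, 1.0)})
        with pytest.raises(ValueError, match="unknown exchanges"):
            apply_medium(chain_network, med)


class TestRestrictUptake:
    def test_cap_to_zero_closes_uptake(self):
        med = MediumDefinition(name="m", exchange_bounds={"EX_A": (-10.0, 5.0)})
        out = restrict_uptake(med, {"EX_A": 0.0})
        assert out.exchange_bounds["EX_A"] == (0.0, 5.0)

    def test_cap_at_current_magnitude_is_identity(self):
        med = MediumDefinition(name="m", exchange_bounds={"EX_A": (-10.0, 5.0)})
        out = restrict_uptake(med, {"EX_A": 10.0})
        assert out.exchange_bounds == med.exchange_bounds

    def test_negative_cap_rejected(self):
        med = MediumDefinition(name="m", exchange_bounds={"EX_A": (-10.0, 5.0)})
        with pytest.raises(ValueError, match="≥ 0"):
            restrict_uptake(med, {"EX_A": -1.0})

    def test_capping_carbon_lowers_the_optimum(self, synthetic_net_truth):
        net, _ = synthetic_net_truth
        rich = rich_medium(net)
        capped = restrict_uptake(rich, {"EX_s0": 2.0, "EX_s1": 2.0})
        full = solve_fba(apply_medium(net, rich), "biomass").objective_value
        less = solve_fba(apply_medium(net, capped), "biomass").objective_value
        assert less < full
        assert less == pytest.approx(full - 16.0)  # two pathways cut 10→2


class TestScreen:
    def test_matches_per_gene_manual_fba(self, synthetic_net_truth):
        net, _ = synthetic_net_truth
        med = rich_medium(net)
        records = run_deletion_screen(net, [med])
        conditioned, wt = wild_type_optima(
            net, med, {"biomass": "biomass", "lipid_droplet": "lipid_droplet"}
        )
        by_gene = {r.gene: r for r in records}
        assert set(by_gene) == set(net.genes)
        for gene in net.genes:
            deleted = apply_deletion(conditioned, {gene})
            bio = solve_fba(deleted, "biomass").objective_value / wt["biomass"]
            lip = solve_fba(deleted, "lipid_droplet").objective_value / wt["lipid_droplet"]
            assert by_gene[gene].relative_biomass == pytest.approx(bio, abs=1e-9)
            assert by_gene[gene].relative_lipid == pytest.approx(lip, abs=1e-9)

    def test_relative_values_never_exceed_one(self, synthetic_net_truth):
        net, _ = synthetic_net_truth
        records = run_deletion_screen(net, [rich_medium(net)])
        for r in records:
            assert r.relative_biomass <= 1 + 1e-6
            assert r.relative_lipid <= 1 + 1e-6

    def test_gene_order_invariance(self, synthetic_net_truth):
        net, _ = synthetic_net_truth
        med = rich_medium(net)
        fwd = run_deletion_screen(net, [med], genes=net.genes)
        rev = run_deletion_screen(net, [med], genes=list(reversed(net.genes)))
        fwd_map = {r.gene: (r.relative_biomass, r.relative_lipid) for r in fwd}
        rev_map = {r.gene: (r.relative_biomass, r.relative_lipid) for r in rev}
        assert fwd_map == rev_map

    def test_unusable_medium_reported(self, synthetic_net_truth):
        net, _ = synthetic_net_truth
        with pytest.raises(UnusableMediumError):
            run_deletion_screen(net, [MediumDefinition(name="empty")])


class TestClassify:
    def _rec(self, lipid, biomass, gene="g", cond="c1"):
        return DeletionRecord(gene=gene, condition=cond,
                              relative_biomass=biomass, relative_lipid=lipid)

    def test_lipid_cut_with_healthy_biomass_is_candidate(self):
        s = classify_candidates([self._rec(0.90, 0.95)])
        assert s.union == {"g"}

    def test_growth_impairing_gene_excluded(self):
        s = classify_candidates([self._rec(0.90, 0.70)])
        assert s.union == set()

    def test_boundaries_strict_lipid_inclusive_biomass(self):
        # exactly 5% lipid reduction is not "more than 5%"
        assert classify_candidates([self._rec(0.95, 0.9)]).union == set()
        # exactly at the 80% biomass floor still qualifies
        assert classify_candidates([self._rec(0.90, 0.80)]).union == {"g"}

    def test_partitions(self):
        recs = [
            self._rec(0.5, 1.0, "both", "c1"), self._rec(0.5, 1.0, "both", "c2"),
            self._rec(0.5, 1.0, "only1", "c1"), self._rec(1.0, 1.0, "only1", "c2"),
            self._rec(1.0, 1.0, "neither", "c1"), self._rec(1.0, 1.0, "neither", "c2"),
        ]
        s = classify_candidates(recs)
        assert s.union == {"both", "only1"}
        assert s.intersection == {"both"}
        assert s.only_in == {"c1": {"only1"}, "c2": set()}

    def test_loosening_biomass_floor_grows_the_set(self, synthetic_net_truth):
        net, _ = synthetic_net_truth
        records = run_deletion_screen(net, [rich_medium(net)])
        tight = classify_candidates(records, CandidateRule(biomass_floor=0.9)).union
        loose = classify_candidates(records, CandidateRule(biomass_floor=0.5)).union
        assert tight <= loose


def test_medium_tsv_roundtrip(tmp_path):
    med = MediumDefinition(name="m", exchange_bounds={"EX_A": (-10.0, 5.0), "EX_B": (0.0, 1000.0)})
    p = tmp_path / "medium.tsv"
    write_medium_tsv(med, p)
    back = read_medium_tsv(p, name="m")
    assert back.exchange_bounds == med.exchange_bounds


def test_records_frame_has_candidate_flags(synthetic_net_truth):
    net, truth = synthetic_net_truth
    records = run_deletion_screen(net, [rich_medium(net)])
    df = records_to_frame(records)
    flagged = set(df[df.candidate].gene)
    assert flagged == truth.candidate_genes
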