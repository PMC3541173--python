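"""Decision tree, gene-model selection, rescue, orphan clustering."""
import numpy as np
import pytest

from plantsdr.errors import ConfigurationError
from plantsdr.inventory import (
    DecisionOutcome,
    HmmHit,
    InventoryConfig,
    TypeCutoffs,
    cluster_orphans,
    decide,
    family_type,
    rescue_truncated,
    select_gene_model,
)
from plantsdr.synthfam import derive_sequence, random_ancestor


def hit(sid="s1", model="SDR110C", cls="family_set", score=200.0,
        cutoff=True, floor=False):
    return HmmHit(sid, model, cls, score, cutoff, floor)


class TestTypeCutoffs:
    def test_published_defaults(self):
        c = TypeCutoffs()
        assert c.inclusion == {
            "classical": 138.0, "extended": 108.0, "intermediate": 162.0,
            "divergent": 160.0, "complex": 140.0,
        }
        assert c.unknown_floor == {
            "classical": 29.0, "extended": 75.0, "divergent": 100.0,
        }

    def test_plant_configuration_drops_types_absent_from_plants(self):
        c = TypeCutoffs.default_plant()
        assert set(c.inclusion) == {"classical", "extended", "divergent"}

    def test_floor_must_sit_below_cutoff(self):
        with pytest.raises(Exception):
            TypeCutoffs(inclusion={"classical": 100.0},
                        unknown_floor={"classical": 150.0})


class TestFamilyTypeSuffix:
    @pytest.mark.parametrize("fam,typ", [
        ("SDR110C", "classical"), ("SDR108E", "extended"), ("SDR87D", "divergent"),
        ("SDR75U", "unknown"), ("SDR460A", "atypical"),
    ])
    def test_suffix_letter_maps_to_type(self, fam, typ):
        assert family_type(fam) == typ


class TestDecide:
    def test_family_tier_pass_is_directly_positive(self):
        out = decide("s1", [hit(model="SDR108E")])
        assert (out.verdict, out.sdr_type, out.family_id) == \
            ("positive", "extended", "SDR108E")

    def test_atypical_family_positive_despite_failing_type_floors(self):
        hits = [
            hit(model="SDR460A", score=55.0),
            hit(model="classical", cls="type_set", score=10.0,
                cutoff=False, floor=False),
            hit(model="PF1", cls="pfam_set", score=5.0, cutoff=False),
        ]
        out = decide("s1", hits)
        assert out.verdict == "positive"
        assert out.sdr_type == "atypical"

    def test_pfam_plus_passing_type_is_positive_with_best_type(self):
        hits = [
            hit(model="PF1", cls="pfam_set", score=150.0),
            hit(model="classical", cls="type_set", score=150.0, floor=True),
            hit(model="extended", cls="type_set", score=120.0, floor=True),
        ]
        out = decide("s1", hits)
        assert (out.verdict, out.sdr_type) == ("positive", "classical")
        assert out.family_id is None

    def test_equal_type_scores_break_by_fixed_order(self):
        hits = [
            hit(model="PF1", cls="pfam_set", score=150.0),
            hit(model="extended", cls="type_set", score=150.0, floor=True),
            hit(model="classical", cls="type_set", score=150.0, floor=True),
        ]
        assert decide("s1", hits).sdr_type == "classical"

    def test_pfam_plus_floor_only_is_positive_unknown(self):
        hits = [
            hit(model="PF1", cls="pfam_set", score=150.0),
            hit(model="classical", cls="type_set", score=30.0,
                cutoff=False, floor=True),
        ]
        out = decide("s1", hits)
        assert (out.verdict, out.sdr_type) == ("positive", "unknown")

    def test_single_tier_recognition_is_ambiguous(self):
        out = decide("s1", [hit(model="PF1", cls="pfam_set", score=150.0)])
        assert out.verdict == "ambiguous"
        assert out.evidence

    def test_lone_type_pass_without_pfam_is_ambiguous(self):
        hits = [hit(model="classical", cls="type_set", score=200.0, floor=True)]
        assert decide("s1", hits).verdict == "ambiguous"

    def test_whitelist_turns_single_tier_hit_positive(self):
        hits = [hit(model="PF1", cls="pfam_set", score=150.0)]
        out = decide("s1", hits, whitelist={"s1": "atypical"})
        assert (out.verdict, out.sdr_type) == ("positive", "atypical")

    def test_exclusion_turns_single_tier_hit_negative(self):
        hits = [hit(model="PF1", cls="pfam_set", score=150.0)]
        assert decide("s1", hits, exclusion={"s1"}).verdict == "negative"

    def test_contradictory_lists_raise(self):
        with pytest.raises(ConfigurationError):
            decide("s1", [], whitelist={"s1": "atypical"}, exclusion={"s1"})

    def test_no_recognition_is_negative(self):
        hits = [
            hit(model="PF1", cls="pfam_set", score=3.0, cutoff=False),
            hit(model="classical", cls="type_set", score=2.0,
                cutoff=False, floor=False),
            hit(model="SDR110C", score=1.0, cutoff=False),
        ]
        out = decide("s1", hits)
        assert out.verdict == "negative"
        assert out.sdr_type is None and out.family_id is None

    def test_hit_order_never_changes_the_outcome(self, rng):
        hits = [
            hit(model="PF1", cls="pfam_set", score=150.0),
            hit(model="classical", cls="type_set", score=140.0, floor=True),
            hit(model="extended", cls="type_set", score=120.0,
                cutoff=False, floor=True),
            hit(model="SDR110C", score=90.0, cutoff=False),
        ]
        ref = decide("s1", hits)
        for _ in range(10):
            perm = [hits[k] for k in rng.permutation(len(hits))]
            out = decide("s1", perm)
            assert (out.verdict, out.sdr_type, out.family_id) == \
                (ref.verdict, ref.sdr_type, ref.family_id)


class TestSelectGeneModel:
    def test_max_hmm_score_wins(self):
        models = {"m1": "ACDEFGHIKL", "m2": "ACDEFGHIKL"}
        hits = [hit(sid="m1", score=120.0), hit(sid="m2", score=90.0)]
        assert select_gene_model(models, hits) == ("m1", False)

    def test_hmm_tie_breaks_on_alignment_score(self):
        anc, _ = random_ancestor(80, np.random.default_rng(0))
        models = {"m1": anc, "m2": anc[:40]}
        hits = [hit(sid="m1", score=100.0), hit(sid="m2", score=100.0)]
        cross = {"x": anc}
        winner, flag = select_gene_model(models, hits, cross)
        assert winner == "m1"
        assert not flag

    def test_disagreement_flags_manual_review_and_keeps_hmm_winner(self):
        anc, _ = random_ancestor(80, np.random.default_rng(0))
        models = {"m1": anc[:40], "m2": anc}
        hits = [hit(sid="m1", score=120.0), hit(sid="m2", score=90.0)]
        cross = {"x": anc}
        winner, flag = select_gene_model(models, hits, cross)
        assert winner == "m1"
        assert flag


@pytest.fixture(scope="module")
def classified():
    rng = np.random.default_rng(1)
    anc1, m1 = random_ancestor(250, rng)
    anc2, m2 = random_ancestor(250, rng)
    p1 = derive_sequence(anc1, 0.8, rng, m1)[0]
    p2 = derive_sequence(anc2, 0.8, rng, m2)[0]
    return [
        ("pos1", p1, "classical", "FAM1C"),
        ("pos2", p2, "extended", "FAM2E"),
    ]


class TestRescue:

    def test_long_exact_fragment_inherits_the_family(self, classified):
        frag = classified[0][1][50:130]  # 80 residues
        got = rescue_truncated({"u1": frag}, classified)
        assert got["u1"].family_id == "FAM1C"
        assert got["u1"].sdr_type == "classical"

    def test_short_fragment_not_rescued(self, classified):
        frag = classified[0][1][50:100]  # 50 residues < 60-column window
        assert rescue_truncated({"u1": frag}, classified) == {}

    def test_best_scoring_homolog_wins(self, classified):
        # fragment strictly longer vs pos2 than vs pos1: higher score wins
        frag = classified[1][1][20:150]
        got = rescue_truncated({"u1": frag}, classified)
        assert got["u1"].family_id == "FAM2E"
        assert got["u1"].homolog_id == "pos2"


class TestClusterOrphans:
    def test_chained_links_form_one_cluster(self):
        rng = np.random.default_rng(2)
        x, _ = random_ancestor(150, rng)
        y, _ = random_ancestor(150, rng)
        z, _ = random_ancestor(150, rng)
        orphans = {"A": x + z, "B": x + y, "C": z[::-1] + y}
        clusters, unclassified = cluster_orphans(orphans, evalue_threshold=1e-40)
        assert len(clusters) == 1
        assert sorted(clusters[0].member_ids) == ["A", "B", "C"]
        assert not unclassified
        assert clusters[0].representative_id in {"A", "B", "C"}
        assert 0 < clusters[0].mean_pairwise_identity <= 1

    def test_unlinked_orphan_stays_unclassified(self):
        rng = np.random.default_rng(3)
        x, _ = random_ancestor(150, rng)
        lonely, _ = random_ancestor(150, np.random.default_rng(99))
        orphans = {"A": x, "B": x, "C": lonely}
        clusters, unclassified = cluster_orphans(orphans, evalue_threshold=1e-40)
        assert unclassified == ["C"]
        assert len(clusters) == 1 and sorted(clusters[0].member_ids) == ["A", "B"]

    def test_no_orphans_is_empty(self):
        assert cluster_orphans({}) == ([], [])


class TestInventoryIntegration:
    def test_every_locus_lands_in_exactly_one_list(self, e2e_result):
        gs, inv, _, _ = e2e_result
        loci = {(p.genome, p.locus) for p in gs.proteins}
        seen = [o.sequence_id for lst in (inv.main, inv.ambiguous, inv.negative)
                for o in lst]
        assert len(seen) == len(set(seen)) == len(loci)

    def test_counts_match_main_list(self, e2e_result):
        _, inv, _, _ = e2e_result
        assert int(inv.counts.to_numpy().sum()) == sum(
            1 for o in inv.main if o.family_id
        )
        for genome in inv.genomes:
            assert inv.counts[genome].sum() == sum(
                1 for o in inv.main
                if o.family_id and o.sequence_id.startswith(genome + "|")
            )

    def test_rescued_outcomes_carry_alignment_evidence(self, e2e_result):
        _, inv, _, _ = e2e_result
        rescued = [o for o in inv.main if any("rescued" in e for e in o.evidence)]
        assert rescued, "expected at least one rescued truncation"
        for o in rescued:
            assert any("identity" in e for e in o.evidence)

    def test_inventory_files_written(self, e2e_result, tmp_path):
        _, inv, _, _ = e2e_result
        inv.write(tmp_path)
        assert (tmp_path / "main_inventory.tsv").exists()
        assert (tmp_path / "ambiguous.tsv").exists()
        lines = (tmp_path / "main_inventory.tsv").read_text().splitlines()
        assert len(lines) == len(inv.main) + 1


def test_invalid_config_rejected():
    with pytest.raises(ConfigurationError):
        InventoryConfig(rescue_window=0)
    with pytest.raises(ConfigurationError):
        InventoryConfig(whitelist={"a": "classical"}, exclusion=frozenset({"a"}))
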