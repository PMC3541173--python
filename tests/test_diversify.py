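"""Distribution matrix, occurrence classes, heat-map export, PCA."""
import numpy as np
import pandas as pd
import pytest

from plantsdr.diversify import (
    DistributionMatrix,
    assign_occurrence,
    distribution_matrix,
    heatmap_export,
    pca,
    pca_robustness,
)
from plantsdr.errors import DegenerateVarianceError, EmptyFamilyError
from plantsdr.inventory import DecisionOutcome, InventoryTable
from plantsdr.synthfam import make_expansion_matrix


def tiny_inventory(rows):
    """rows: (genome, locus, family) triples, all positive/classical."""
    genomes = sorted({g for g, _, _ in rows})
    main = [
        DecisionOutcome(f"{g}|{l}|m1", "positive", "classical", fam, ["x"])
        for g, l, fam in rows
    ]
    fam_ids = sorted({f for _, _, f in rows})
    counts = pd.DataFrame(0, index=fam_ids, columns=genomes, dtype=int)
    for g, _, f in rows:
        counts.loc[f, g] += 1
    tiers = {g: "angiosperm" for g in genomes}
    return InventoryTable(main, [], [], counts, [], [], genomes, tiers)


def matrix(data, tiers):
    df = pd.DataFrame(data["counts"], index=data["families"],
                      columns=data["genomes"], dtype=int)
    return DistributionMatrix(df, tiers)


class TestDistributionMatrix:
    def test_counts_follow_the_main_list(self):
        inv = tiny_inventory([
            ("g1", "l1", "FAM1C"), ("g1", "l2", "FAM1C"), ("g2", "l3", "FAM2C"),
        ])
        m = distribution_matrix(inv)
        assert m.counts.loc["FAM1C", "g1"] == 2
        assert m.counts.loc["FAM2C", "g2"] == 1
        assert int(m.counts.to_numpy().sum()) == 3

    def test_empty_inventory_gives_empty_matrix(self):
        inv = InventoryTable([], [], [], pd.DataFrame(), [], [], ["g1"],
                             {"g1": "alga"})
        m = distribution_matrix(inv)
        assert m.counts.size == 0

    def test_column_sums_match_genome_main_counts(self, e2e_result):
        _, inv, _, _ = e2e_result
        m = distribution_matrix(inv)
        for g in inv.genomes:
            expected = sum(
                1 for o in inv.main
                if o.family_id and o.sequence_id.startswith(g + "|")
            )
            assert int(m.counts[g].sum()) == expected

    def test_synthetic_truth_counts_recovered(self, e2e_result):
        gs, inv, _, report = e2e_result
        m = distribution_matrix(inv)
        # for perfectly recovered families the matrix row equals the truth
        truth_counts = {}
        for t in gs.truth:
            if t.family_id and not t.truncated:
                truth_counts.setdefault(t.family_id, {}).setdefault(t.genome_id, 0)
        for t in gs.truth:
            if t.family_id and not t.truncated and not t.locus_id.endswith("t"):
                truth_counts[t.family_id][t.genome_id] += 1
        misassigned = {s.split("|")[1].rsplit("_", 2)[0]
                       for s in report.details["misassigned_members"]}
        clean = [f for f in truth_counts if f not in misassigned]
        assert clean, "expected at least one perfectly recovered family"
        for fam in clean:
            for genome, n in truth_counts[fam].items():
                # rescued truncations may add to the count; never subtract
                assert m.counts.loc[fam, genome] >= n


TIERS4 = {"g1": "alga", "g2": "bryophyte", "g3": "lycophyte", "g4": "angiosperm"}


class TestOccurrence:
    def test_deepest_tier_present_wins(self):
        m = matrix(
            {
                "families": ["FV", "FL", "FT", "FF"],
                "genomes": ["g1", "g2", "g3", "g4"],
                "counts": [
                    [1, 1, 0, 1],  # alga present -> ViridP
                    [0, 2, 0, 1],  # moss but no alga -> LandP
                    [0, 0, 1, 1],  # lycophyte first -> TracheoP
                    [0, 0, 0, 3],  # angiosperm only -> FlowerP
                ],
            },
            TIERS4,
        )
        labels = {o.family_id: o.label for o in assign_occurrence(m)}
        assert labels == {"FV": "ViridP", "FL": "LandP", "FT": "TracheoP",
                          "FF": "FlowerP"}

    def test_every_family_gets_exactly_one_label(self):
        m = make_expansion_matrix(20, 8, {"F01", "F02"}, rng_seed=3)
        labels = assign_occurrence(m)
        assert sorted(o.family_id for o in labels) == sorted(m.counts.index)

    def test_all_zero_family_rejected(self):
        m = matrix(
            {"families": ["FA", "FB"], "genomes": ["g1", "g4"],
             "counts": [[1, 1], [0, 0]]},
            {"g1": "alga", "g4": "angiosperm"},
        )
        with pytest.raises(EmptyFamilyError):
            assign_occurrence(m)

    def test_starred_override_forces_viridp(self):
        m = matrix(
            {"families": ["FX"], "genomes": ["g2", "g4"], "counts": [[1, 1]]},
            {"g2": "bryophyte", "g4": "angiosperm"},
        )
        (label,) = assign_occurrence(m, starred_overrides=["FX"])
        assert (label.label, label.starred) == ("ViridP", True)


class TestPca:
    def test_single_varying_column_explains_everything(self):
        m = matrix(
            {"families": ["a", "b", "c"], "genomes": ["g1", "g4"],
             "counts": [[1, 1], [1, 5], [1, 9]]},
            {"g1": "alga", "g4": "angiosperm"},
        )
        res = pca(m)
        assert res.variance_pct[0] == pytest.approx(100.0)

    def test_two_by_two_closed_form(self):
        m = matrix(
            {"families": ["a", "b"], "genomes": ["g1", "g4"],
             "counts": [[0, 0], [2, 4]]},
            {"g1": "alga", "g4": "angiosperm"},
        )
        res = pca(m)
        # centered matrix [[-1,-2],[1,2]]: single nonzero eigenvalue 10
        assert res.variance_pct[0] == pytest.approx(100.0)
        assert abs(res.scores.to_numpy()[:, 0]) == pytest.approx(
            np.array([np.sqrt(5.0), np.sqrt(5.0)])
        )

    def test_variance_fractions_sum_to_100(self):
        m = make_expansion_matrix(30, 6, {"F01", "F05"}, rng_seed=8)
        res = pca(m)
        assert res.variance_pct.sum() == pytest.approx(100.0, abs=1e-9)

    def test_reconstruction_from_all_components(self):
        m = make_expansion_matrix(15, 5, {"F02"}, rng_seed=4)
        res = pca(m)
        X = m.counts.to_numpy(dtype=float)
        Xc = X - X.mean(axis=0)
        approx = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(approx, Xc, atol=1e-8)

    def test_loadings_orthonormal(self):
        m = make_expansion_matrix(15, 5, {"F02"}, rng_seed=4)
        V = pca(m).loadings.to_numpy()
        np.testing.assert_allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-8)

    def test_matches_sklearn(self):
        from sklearn.decomposition import PCA as SkPCA

        m = make_expansion_matrix(25, 7, {"F01", "F02", "F03"}, rng_seed=6)
        res = pca(m)
        X = m.counts.to_numpy(dtype=float)
        sk = SkPCA()
        sk_scores = sk.fit_transform(X)
        np.testing.assert_allclose(
            np.abs(res.scores.to_numpy()[:, : sk_scores.shape[1]]),
            np.abs(sk_scores),
            atol=1e-8,
        )
        np.testing.assert_allclose(
            res.variance_pct[: len(sk.explained_variance_ratio_)] / 100.0,
            sk.explained_variance_ratio_,
            atol=1e-9,
        )

    def test_constant_matrix_rejected(self):
        m = matrix(
            {"families": ["a", "b"], "genomes": ["g1", "g4"],
             "counts": [[2, 2], [2, 2]]},
            {"g1": "alga", "g4": "angiosperm"},
        )
        with pytest.raises(DegenerateVarianceError):
            pca(m)


class TestPcaRobustness:
    def test_extreme_row_identified_and_removed(self):
        m = matrix(
            {
                "families": ["quiet1", "quiet2", "quiet3", "huge"],
                "genomes": ["g1", "g4"],
                "counts": [[1, 2], [2, 1], [1, 1], [40, 90]],
            },
            {"g1": "alga", "g4": "angiosperm"},
        )
        rob = pca_robustness(m)
        assert rob.removed_family == "huge"
        assert "huge" not in rob.reduced.scores.index
        assert -1.0 <= rob.rank_concordance <= 1.0

    def test_planted_families_keep_leading_scores_after_removal(self):
        planted = {"F01", "F02", "F03", "F04", "F05"}
        m = make_expansion_matrix(49, 10, planted, rng_seed=12)
        rob = pca_robustness(m)
        assert rob.removed_family in planted
        remaining = planted - {rob.removed_family}
        top4 = set(
            rob.reduced.scores["PC1"].sort_values(ascending=False).index[:4]
        )
        assert top4 == remaining


class TestHeatmapExport:
    def test_tsv_roundtrip_and_determinism(self, tmp_path):
        m = make_expansion_matrix(10, 5, {"F01"}, rng_seed=2)
        out1 = heatmap_export(m, tmp_path / "heat1")
        out2 = heatmap_export(m, tmp_path / "heat2")
        t1 = (tmp_path / "heat1.tsv").read_bytes()
        t2 = (tmp_path / "heat2.tsv").read_bytes()
        assert t1 == t2
        back = DistributionMatrix.from_tsv(tmp_path / "heat1.tsv", m.tiers)
        assert back.counts.equals(m.counts)
        assert str(tmp_path / "heat1.tsv") in out1
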