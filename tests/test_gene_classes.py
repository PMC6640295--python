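import numpy as np
import pandas as pd
import pytest

from pollenselect import gene_classes as gc

SIDES = {
    "pollen_mature": "pollen",
    "pollen_tube": "pollen",
    "pollen_tube_a": "pollen",
    "pollen_tube_b": "pollen",
    "leaf": "sporophyte",
    "root": "sporophyte",
    "xylem": "sporophyte",
    "guard_cell": "sporophyte",
    "stem": "sporophyte",
    "seed": "sporophyte",
    "flower": "sporophyte",
}


def expr_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "level", "presence"])


class TestMergePollenTube:
    def test_elementwise_max(self):
        df = expr_frame([("g1", "pollen_tube_a", 1200, 0.95), ("g1", "pollen_tube_b", 800, 0.99)])
        out = gc.merge_pollen_tube(df, "pollen_tube_a", "pollen_tube_b")
        assert len(out) == 1
        row = out.iloc[0]
        assert row["tissue"] == "pollen_tube"
        assert (row["level"], row["presence"]) == (1200, 0.99)

    def test_missing_tissue_errors(self):
        df = expr_frame([("g1", "pollen_tube_a", 1, 0.5)])
        with pytest.raises(KeyError):
            gc.merge_pollen_tube(df, "pollen_tube_a", "pollen_tube_b")

    def test_merge_then_classify_equals_premerged(self):
        rows = [
            ("g1", "pollen_tube_a", 1200, 0.95),
            ("g1", "pollen_tube_b", 800, 0.99),
            ("g1", "leaf", 50, 0.2),
            ("g2", "pollen_tube_a", 10, 0.1),
            ("g2", "leaf", 900, 0.97),
        ]
        merged = gc.merge_pollen_tube(expr_frame(rows), "pollen_tube_a", "pollen_tube_b")
        premerged = expr_frame(
            [("g1", "pollen_tube", 1200, 0.99), ("g1", "leaf", 50, 0.2),
             ("g2", "pollen_tube", 10, 0.1), ("g2", "leaf", 900, 0.97)]
        )
        a = gc.classify_table(merged, SIDES)
        b = gc.classify_table(premerged, SIDES)
        pd.testing.assert_frame_equal(a, b, check_dtype=False)


class TestClassifyLifeStage:
    def test_pollen_specific_at_threshold(self):
        p = gc.classify_life_stage(
            "g1", {"pollen_mature": (1200, 0.95), "leaf": (800, 0.2)}, SIDES
        )
        assert p.life_stage_class == "pollen_specific"
        assert p.expression_level == 1200

    def test_shared(self):
        p = gc.classify_life_stage(
            "g1", {"pollen_mature": (10, 0.95), "leaf": (20, 0.95)}, SIDES
        )
        assert p.life_stage_class == "shared"

    def test_all_below_threshold_is_not_expressed(self):
        p = gc.classify_life_stage(
            "g1", {"pollen_mature": (10, 0.89), "leaf": (20, 0.89)}, SIDES
        )
        assert p.life_stage_class == "not_expressed"
        assert p.expression_level == 0.0

    def test_unknown_tissue_errors(self):
        with pytest.raises(KeyError):
            gc.classify_life_stage("g1", {"mystery": (10, 0.95)}, SIDES)

    def test_present_with_zero_level_errors(self):
        with pytest.raises(ValueError, match="zero"):
            gc.classify_life_stage("g1", {"leaf": (0, 0.95)}, SIDES)

    def test_threshold_monotonicity(self, rng):
        """Raising the threshold can only move genes toward not_expressed,
        never between the two specific classes."""
        tissues = list(SIDES)
        for _ in range(50):
            prof = {t: (10.0, float(rng.uniform(0, 1))) for t in tissues}
            classes = [
                gc.classify_life_stage("g", prof, SIDES, threshold=th).life_stage_class
                for th in (0.5, 0.7, 0.9, 0.99)
            ]
            for lo, hi in zip(classes, classes[1:]):
                # raising the threshold can only remove presences
                assert (lo, hi) not in (
                    ("pollen_specific", "sporophyte_specific"),
                    ("sporophyte_specific", "pollen_specific"),
                )
                if lo == "not_expressed":
                    assert hi == "not_expressed"

    def test_partition_on_synthetic(self, small_dataset):
        merged = gc.merge_pollen_tube(
            small_dataset.expression, "pollen_tube_a", "pollen_tube_b"
        )
        sides = small_dataset.config.tissue_sides()
        sides["pollen_tube"] = "pollen"
        profiles = gc.classify_table(merged, sides)
        assert len(profiles) == len(small_dataset.truth)
        assert profiles["life_stage_class"].isin(gc.CLASSES).all()

    def test_recovers_generator_truth(self, small_dataset):
        merged = gc.merge_pollen_tube(
            small_dataset.expression, "pollen_tube_a", "pollen_tube_b"
        )
        sides = small_dataset.config.tissue_sides()
        sides["pollen_tube"] = "pollen"
        profiles = gc.classify_table(merged, sides)
        truth = small_dataset.truth.assign(
            expected=lambda d: d["life_stage_class"].replace({"silent": "not_expressed"})
        )
        merged_df = profiles.merge(truth[["gene_id", "expected"]], on="gene_id")
        assert (merged_df["life_stage_class"] == merged_df["expected"]).all()


class TestComparisonGroups:
    @pytest.fixture
    def profiles(self):
        return pd.DataFrame(
            {
                "gene_id": ["p1", "s1", "s2", "s3", "n1"],
                "life_stage_class": [
                    "pollen_specific", "sporophyte_specific", "sporophyte_specific",
                    "sporophyte_specific", "not_expressed",
                ],
                "sporophyte_tissue_count": [0, 1, 5, 1, 0],
                "sporophyte_tissues": ["", "xylem", "leaf,root,stem,seed,flower", "leaf", ""],
                "expression_level": [100, 50, 60, 70, 0],
            }
        )

    def test_single_tissue_set(self, profiles):
        groups = gc.select_comparison_groups(profiles, "pollen_vs_single_tissue")
        assert groups["other"] == {"s1"}  # xylem yes, leaf-only not a listed cell type

    def test_broad_set(self, profiles):
        groups = gc.select_comparison_groups(profiles, "pollen_vs_broad")
        assert groups["other"] == {"s2"}

    def test_pollen_disjoint_from_sporophyte_sets(self, profiles):
        for grouping in ("pollen_vs_sporophyte", "pollen_vs_single_tissue", "pollen_vs_broad"):
            groups = gc.select_comparison_groups(profiles, grouping)
            assert groups["pollen"] == {"p1"}
            assert not groups["pollen"] & groups["other"]


class TestChromosomeDistribution:
    def test_proportional_counts_give_zero(self):
        allc = {"c1": 100, "c2": 300}
        chi2, df, p = gc.chromosome_distribution_test({"c1": 10, "c2": 30}, allc)
        assert chi2 == pytest.approx(0.0)
        assert df == 1

    def test_zero_expected_errors(self):
        with pytest.raises(ValueError, match="c2"):
            gc.chromosome_distribution_test({"c1": 10}, {"c1": 100, "c2": 0})

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="empty"):
            gc.chromosome_distribution_test({"c1": 0, "c2": 0}, {"c1": 1, "c2": 1})
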