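"""Unit and property tests for the abundance-to-polarity processing chain."""

import numpy as np
import pandas as pd
import pytest

import polarscope as ps
from polarscope.datasets import myeloid_activation_log2fc

from conftest import random_abundance


def brute_force_chain(values: pd.DataFrame, design: pd.DataFrame):
    """Literal per-cell recomputation of normalize -> FC -> center -> aggregate."""
    totals = {s: sum(values[s]) for s in values.columns}
    target = sum(totals.values()) / len(totals)
    norm = pd.DataFrame(
        {s: [v * target / totals[s] for v in values[s]] for s in values.columns},
        index=values.index,
    )
    controls = [s for s in values.columns if design.loc[s, "is_control"]]
    others = [s for s in values.columns if not design.loc[s, "is_control"]]
    fc = {}
    for s in others:
        col = []
        for p in values.index:
            ctrl_mean = sum(norm.loc[p, c] for c in controls) / len(controls)
            col.append(np.log2(norm.loc[p, s] / ctrl_mean))
        fc[s] = col
    fc = pd.DataFrame(fc, index=values.index)
    centered = fc - fc.median(axis=0)
    subtype_means = {}
    for st in design.loc[others, "subtype"].unique():
        cols = [s for s in others if design.loc[s, "subtype"] == st]
        subtype_means[st] = centered[cols].mean(axis=1)
    return centered, pd.DataFrame(subtype_means)


class TestNormalize:
    def test_hand_example(self):
        m = random_abundance(2, 2, 1, np.random.default_rng(0))
        m.values.loc[:, "s0"] = [1.0, 3.0]
        m.values.loc[:, "s1"] = [2.0, 6.0]
        m = ps.AbundanceMatrix(values=m.values, design=m.design)
        out = ps.normalize_total_abundance(m)
        np.testing.assert_allclose(out.values["s0"], [1.5, 4.5])
        np.testing.assert_allclose(out.values["s1"], [1.5, 4.5])

    def test_equal_totals_is_fixed_point(self, tiny_matrix):
        out1 = ps.normalize_total_abundance(tiny_matrix)
        out2 = ps.normalize_total_abundance(out1)
        pd.testing.assert_frame_equal(out1.values, out2.values)

    def test_single_sample_unchanged(self):
        m = random_abundance(5, 1, 1, np.random.default_rng(1))
        out = ps.normalize_total_abundance(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_preserves_proportions_and_equalizes_totals(self):
        m = random_abundance(20, 5, 2, np.random.default_rng(2))
        out = ps.normalize_total_abundance(m)
        totals = out.values.sum(axis=0)
        np.testing.assert_allclose(totals, totals.iloc[0], rtol=1e-9)
        for s in m.values.columns:
            np.testing.assert_allclose(
                out.values[s] / out.values[s].sum(), m.values[s] / m.values[s].sum()
            )

    def test_zero_total_rejected_with_sample_name(self):
        m = random_abundance(3, 3, 1, np.random.default_rng(3))
        m.values["s1"] = 0.0
        with pytest.raises(ValueError, match="s1"):
            ps.normalize_total_abundance(ps.AbundanceMatrix(m.values, m.design))


class TestFoldChange:
    def test_examples(self, tiny_matrix):
        # tiny_matrix columns already share totals, so normalization is identity
        fc = ps.log2_fold_change_vs_control(tiny_matrix)
        assert fc.log2fc.loc["pA", "s1"] == pytest.approx(2.0)  # 16 vs ctrl mean 4
        assert fc.log2fc.loc["pC", "s1"] == pytest.approx(0.0)
        assert fc.log2fc.loc["pD", "s2"] == pytest.approx(1.0)

    def test_zero_control_mean_dropped_and_reported(self, tiny_matrix):
        v = tiny_matrix.values.copy()
        v.loc["pB", ["c1", "c2"]] = 0.0
        fc = ps.log2_fold_change_vs_control(ps.AbundanceMatrix(v, tiny_matrix.design))
        assert "pB" not in fc.log2fc.index
        assert fc.dropped == ["pB"]

    def test_no_controls_rejected(self, tiny_matrix):
        design = tiny_matrix.design.copy()
        design["is_control"] = False
        with pytest.raises(ValueError, match="control"):
            ps.log2_fold_change_vs_control(
                ps.AbundanceMatrix(tiny_matrix.values, design)
            )


class TestMedianCenter:
    def test_examples(self):
        fc = ps.FoldChangeMatrix(
            log2fc=pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.0, -1.0, 1.0], "c": [5.0, 5.0, 5.0]}),
            design=pd.DataFrame(),
        )
        out = ps.median_center(fc)
        np.testing.assert_allclose(out.log2fc["a"], [-1, 0, 1])
        np.testing.assert_allclose(out.log2fc["b"], [0, -1, 1])  # median already 0
        np.testing.assert_allclose(out.log2fc["c"], [0, 0, 0])  # constant column
        assert out.centered

    def test_column_medians_zero_after_centering(self):
        rng = np.random.default_rng(4)
        fc = ps.FoldChangeMatrix(
            log2fc=pd.DataFrame(rng.normal(3, 2, size=(31, 6))), design=pd.DataFrame()
        )
        out = ps.median_center(fc)
        np.testing.assert_allclose(out.log2fc.median(axis=0), 0, atol=1e-9)

    def test_double_centering_rejected(self):
        fc = ps.FoldChangeMatrix(
            log2fc=pd.DataFrame({"a": [1.0, 2.0]}), design=pd.DataFrame(), centered=True
        )
        with pytest.raises(ValueError):
            ps.median_center(fc)


class TestMeanBySubtype:
    def _fc(self, data, subtypes):
        cols = list(data)
        design = pd.DataFrame(
            {
                "subtype": subtypes,
                "donor": [f"d{i}" for i in range(len(cols))],
                "is_control": False,
            },
            index=pd.Index(cols, name="sample_id"),
        )
        return ps.FoldChangeMatrix(log2fc=pd.DataFrame(data), design=design)

    def test_arithmetic_mean_and_single_replicate(self):
        fc = self._fc({"r1": [1.0], "r2": [3.0], "q1": [5.0]}, ["A", "A", "B"])
        out = ps.mean_by_subtype(fc)
        assert out.subtype_means.loc[0, "A"] == pytest.approx(2.0)
        assert out.subtype_means.loc[0, "B"] == pytest.approx(5.0)

    def test_missing_replicate_uses_finite_mean_with_flag(self):
        fc = self._fc({"r1": [2.0], "r2": [np.nan]}, ["A", "A"])
        out = ps.mean_by_subtype(fc)
        assert out.subtype_means.loc[0, "A"] == pytest.approx(2.0)
        assert out.completeness.loc[0, "A"] == 1  # only one finite replicate


class TestClassification:
    def _means_fc(self, means: pd.DataFrame) -> ps.FoldChangeMatrix:
        return ps.FoldChangeMatrix(
            log2fc=means, design=pd.DataFrame(), centered=True, subtype_means=means
        )

    def test_published_myeloid_activation_calls(self):
        """The +/-1 rule on the 20-protein reference table gives the expected directions."""
        table = myeloid_activation_log2fc()
        calls = ps.classify_polarity(self._means_fc(table)).calls
        assert calls.loc["CR1", "M1"] == "down"  # -3.02
        assert calls.loc["CD63", "M2c"] == "up"  # 1.48
        assert calls.loc["ITGAL", "M1"] == "unchanged"  # 0.66
        # full expected table, derived by hand from the printed values
        expected = table.apply(
            lambda col: np.where(col >= 1, "up", np.where(col <= -1, "down", "unchanged"))
        )
        assert (calls.to_numpy() == expected.to_numpy()).all()

    @pytest.mark.parametrize(
        "value,inclusive,expected",
        [
            (1.0, True, "up"),
            (1.0, False, "unchanged"),
            (-1.0, True, "down"),
            (-1.0, False, "unchanged"),
            (0.999999, True, "unchanged"),
            (1.000001, False, "up"),
        ],
    )
    def test_boundary_rule(self, value, inclusive, expected):
        means = pd.DataFrame({"A": [value]}, index=["p"])
        calls = ps.classify_polarity(self._means_fc(means), boundary_inclusive=inclusive)
        assert calls.calls.loc["p", "A"] == expected

    def test_bad_thresholds_rejected(self):
        means = pd.DataFrame({"A": [0.0]})
        with pytest.raises(ValueError):
            ps.classify_polarity(self._means_fc(means), up_threshold=-1, down_threshold=1)

    def test_core_and_partition(self):
        means = pd.DataFrame(
            {"A": [0.0, 2.0, 0.0], "B": [0.0, 0.0, -1.5], "C": [0.0, 0.0, 0.4]},
            index=["p1", "p2", "p3"],
        )
        calls = ps.classify_polarity(self._means_fc(means))
        core = ps.core_proteome(calls)
        diff = ps.differential_proteome(calls)
        assert list(core) == ["p1"]
        assert set(diff) == {"p2", "p3"}
        assert set(core) | set(diff) == {"p1", "p2", "p3"}
        assert set(core) & set(diff) == set()

    def test_all_zero_means_all_core(self):
        means = pd.DataFrame(0.0, index=["p1", "p2"], columns=["A", "B"])
        calls = ps.classify_polarity(self._means_fc(means))
        assert list(ps.core_proteome(calls)) == ["p1", "p2"]


class TestVenn:
    def _calls(self, sets, universe, subtypes):
        calls = pd.DataFrame("unchanged", index=universe, columns=subtypes)
        for st, members in sets.items():
            for p in members:
                calls.loc[p, st] = "up"
        return ps.PolarityCallTable(calls=calls)

    def test_two_set_overlap(self):
        v = ps.venn_overlap(
            self._calls({"A": ["p1", "p2"], "B": ["p2", "p3"]}, ["p1", "p2", "p3"], ["A", "B"])
        )
        assert v["per_subtype"] == {"A": 2, "B": 2}
        assert v["exact"][frozenset({"A"})] == 1
        assert v["exact"][frozenset({"B"})] == 1
        assert v["exact"][frozenset({"A", "B"})] == 1
        assert v["union"] == 3
        assert sum(v["exact"].values()) == v["union"]

    def test_identical_sets_all_in_full_intersection(self):
        v = ps.venn_overlap(
            self._calls({"A": ["p1", "p2"], "B": ["p1", "p2"]}, ["p1", "p2"], ["A", "B"])
        )
        assert v["exact"] == {frozenset({"A", "B"}): 2}

    def test_disjoint_sets(self):
        v = ps.venn_overlap(
            self._calls({"A": ["p1"], "B": ["p2"]}, ["p1", "p2"], ["A", "B"])
        )
        assert frozenset({"A", "B"}) not in v["exact"]


class TestSurfaceFilter:
    def test_partial_match_report(self):
        atlas = ps.SurfaceAtlas(identifiers={"CD63", "CD44"})
        kept, report = ps.filter_surface(["CD63", "CD44", "ACTB"], atlas)
        assert kept == ["CD63", "CD44"]
        assert report == {"retained": 2, "total": 3}

    def test_case_insensitive(self):
        atlas = ps.SurfaceAtlas(identifiers={"cd63"})
        kept, _ = ps.filter_surface(["CD63"], atlas)
        assert kept == ["CD63"]

    def test_empty_input(self):
        kept, report = ps.filter_surface([], ps.SurfaceAtlas(identifiers={"CD63"}))
        assert kept == [] and report["total"] == 0

    def test_zero_retained_warns_not_errors(self):
        with pytest.warns(UserWarning):
            kept, _ = ps.filter_surface(["ACTB"], ps.SurfaceAtlas(identifiers={"CD63"}))
        assert kept == []

    def test_empty_atlas_rejected(self):
        with pytest.raises(ValueError):
            ps.filter_surface(["CD63"], ps.SurfaceAtlas(identifiers=set()))

    def test_fold_change_matrix_restriction(self):
        means = pd.DataFrame({"A": [1.0, 2.0, 3.0]}, index=["CD63", "ACTB", "CD44"])
        fc = ps.FoldChangeMatrix(log2fc=means, design=pd.DataFrame(), subtype_means=means)
        out, report = ps.filter_surface(fc, ps.SurfaceAtlas(identifiers={"CD63", "CD44"}))
        assert list(out.log2fc.index) == ["CD63", "CD44"]
        assert report == {"retained": 2, "total": 3}


class TestHierarchicalOrder:
    def test_closest_pair_merges_first_and_sits_adjacent(self):
        # d(0,1)=1, d(0,2)=10, d(1,2)~10
        m = pd.DataFrame({"x": [0.0, 1.0, 10.0]})
        fc = ps.FoldChangeMatrix(log2fc=m, design=pd.DataFrame(), subtype_means=m)
        order = list(ps.hierarchical_order(fc))
        assert abs(order.index(0) - order.index(1)) == 1

    def test_duplicates_adjacent(self):
        m = pd.DataFrame({"x": [0.0, 5.0, 0.0, 9.0]})
        fc = ps.FoldChangeMatrix(log2fc=m, design=pd.DataFrame(), subtype_means=m)
        order = list(ps.hierarchical_order(fc))
        assert abs(order.index(0) - order.index(2)) == 1

    def test_single_row(self):
        m = pd.DataFrame({"x": [1.0]})
        fc = ps.FoldChangeMatrix(log2fc=m, design=pd.DataFrame(), subtype_means=m)
        assert list(ps.hierarchical_order(fc)) == [0]

    def test_nonfinite_rejected(self):
        m = pd.DataFrame({"x": [1.0, np.nan]})
        fc = ps.FoldChangeMatrix(log2fc=m, design=pd.DataFrame(), subtype_means=m)
        with pytest.raises(ValueError):
            ps.hierarchical_order(fc)


class TestPCA:
    def test_degenerate_subtype_clusters(self):
        # identical replicate columns within each of 4 planted groups
        rng = np.random.default_rng(5)
        profiles = rng.normal(0, 1, size=(30, 4))
        cols = {}
        for g in range(4):
            for r in range(3):
                cols[f"g{g}_r{r}"] = profiles[:, g]
        fc = ps.FoldChangeMatrix(log2fc=pd.DataFrame(cols), design=pd.DataFrame())
        scores, _ = ps.pca_scores(fc, k=2)
        for g in range(4):
            block = scores.loc[[f"g{g}_r{r}" for r in range(3)]]
            assert block.std(axis=0).max() == pytest.approx(0, abs=1e-9)
        centers = {tuple(np.round(scores.loc[f"g{g}_r0"], 6)) for g in range(4)}
        assert len(centers) == 4

    def test_variance_on_one_axis(self):
        fc = ps.FoldChangeMatrix(
            log2fc=pd.DataFrame({"a": [1.0, 0.0], "b": [2.0, 0.0], "c": [3.0, 0.0]}),
            design=pd.DataFrame(),
        )
        with pytest.warns(UserWarning):
            scores, evr = ps.pca_scores(fc, k=2)
        assert evr[0] == pytest.approx(1.0)

    def test_planted_subtypes_separate(self, planted_proteome):
        from sklearn.metrics import silhouette_score

        _, _, result = planted_proteome
        scores, _ = ps.pca_scores(result["fc"], k=2)
        labels = result["fc"].design.loc[scores.index, "subtype"]
        assert silhouette_score(scores.to_numpy(), labels) >= 0.5

    def test_deterministic_sign(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.normal(size=(10, 5)))
        fc = ps.FoldChangeMatrix(log2fc=m, design=pd.DataFrame())
        s1, _ = ps.pca_scores(fc, k=2)
        s2, _ = ps.pca_scores(fc, k=2)
        pd.testing.assert_frame_equal(s1, s2)


class TestChainProperties:
    def test_oracle_equivalence_on_small_matrices(self):
        """Full chain matches literal per-cell recomputation to 1e-12."""
        for seed in range(5):
            m = random_abundance(10, 6, 2, np.random.default_rng(seed))
            fc = ps.mean_by_subtype(
                ps.median_center(
                    ps.log2_fold_change_vs_control(ps.normalize_total_abundance(m))
                )
            )
            centered, means = brute_force_chain(m.values, m.design)
            np.testing.assert_allclose(
                fc.log2fc.to_numpy(), centered.to_numpy(), atol=1e-12
            )
            np.testing.assert_allclose(
                fc.subtype_means.to_numpy(), means[fc.subtype_means.columns].to_numpy(),
                atol=1e-12,
            )

    def test_scale_invariance(self):
        """Rescaling any raw sample column leaves all log2FC unchanged."""
        m = random_abundance(15, 5, 2, np.random.default_rng(7))
        scaled_values = m.values.copy()
        scaled_values["s0"] *= 37.5
        scaled_values["s3"] *= 0.004
        base = ps.mean_by_subtype(
            ps.median_center(
                ps.log2_fold_change_vs_control(ps.normalize_total_abundance(m))
            )
        )
        scaled = ps.mean_by_subtype(
            ps.median_center(
                ps.log2_fold_change_vs_control(
                    ps.normalize_total_abundance(
                        ps.AbundanceMatrix(scaled_values, m.design)
                    )
                )
            )
        )
        np.testing.assert_allclose(
            base.log2fc.to_numpy(), scaled.log2fc.to_numpy(), atol=1e-9
        )

    def test_planted_recovery(self, planted_proteome):
        """Core recall/precision >= 0.95 under realistic noise."""
        _, truth, result = planted_proteome
        core = set(result["core"])
        true_core = set(truth.core_ids)
        recall = len(core & true_core) / len(true_core)
        precision = len(core & true_core) / len(core)
        assert recall >= 0.95 and precision >= 0.95
        # recovered core fraction close to the planted fraction
        assert len(core) / len(truth.protein_ids) == pytest.approx(0.5, abs=0.03)
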