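import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy as sp_hierarchy
from scipy.spatial.distance import squareform

from lrenrich import (
    ProfileMatrix,
    filter_concepts,
    hierarchical_cluster,
    merge_results,
    read_cdt,
    uncentered_pearson_distance,
    write_treeview,
)
from lrenrich.cross_study import leaf_order
from lrenrich.enrichment import EnrichmentResult, ResultSet
from lrenrich.errors import ConsistencyError, InputError

from .oracles import pairwise_uncentered_distances


def result(cid, p, direction, slope=1.0):
    return EnrichmentResult(cid, cid, "t", 20, slope, 0.1, slope / 0.1, p, p, 1.0, direction, [], True)


def run_of(study, rows, mode="nondirectional", arm="twosided"):
    return ResultSet(study, mode, arm, [result(*r) for r in rows])


class TestMergeResults:
    def test_signed_scores(self):
        a = run_of("s1", [("C", 0.01, "enriched")])
        b = run_of("s2", [("C", 0.1, "depleted")])
        m = merge_results([a, b])
        assert m.values.loc["C", "s1"] == pytest.approx(2.0)
        assert m.values.loc["C", "s2"] == pytest.approx(-1.0)

    def test_concept_missing_in_one_study(self):
        a = run_of("s1", [("C", 0.01, "enriched"), ("D", 0.5, "enriched")])
        b = run_of("s2", [("C", 0.1, "depleted")])
        m = merge_results([a, b])
        assert np.isnan(m.values.loc["D", "s2"])

    def test_identical_runs_give_identical_columns(self):
        rows = [("C", 0.01, "enriched"), ("D", 0.2, "depleted")]
        m = merge_results([run_of("s1", rows), run_of("s2", rows)])
        np.testing.assert_allclose(m.values["s1"], m.values["s2"])

    def test_mixed_modes_rejected(self):
        a = run_of("s1", [("C", 0.01, "enriched")])
        b = run_of("s2", [("C", 0.01, "up")], mode="directional", arm="up")
        with pytest.raises(InputError):
            merge_results([a, b])

    def test_directional_takes_best_arm_with_sign(self):
        up = run_of("s1", [("C", 0.001, "up"), ("D", 0.5, "up")], "directional", "up")
        dn = run_of("s1", [("C", 0.5, "down"), ("D", 0.001, "down")], "directional", "down")
        up2 = run_of("s2", [("C", 0.2, "up"), ("D", 0.2, "up")], "directional", "up")
        dn2 = run_of("s2", [("C", 0.3, "down"), ("D", 0.3, "down")], "directional", "down")
        m = merge_results([up, dn, up2, dn2])
        assert m.values.loc["C", "s1"] == pytest.approx(3.0)   # up wins, positive
        assert m.values.loc["D", "s1"] == pytest.approx(-3.0)  # down wins, negative


class TestFilterConcepts:
    def make(self, rows):
        return ProfileMatrix(pd.DataFrame(rows, index=[f"C{i}" for i in range(len(rows))],
                                          columns=["s1", "s2", "s3"]))

    def test_count_rule_keeps_row(self):
        m = self.make([[4.5, 3.2, 5.0]])
        assert len(filter_concepts(m, 1e-4, 2).values) == 1

    def test_boundary_min_studies(self):
        m = self.make([[4.5, 3.2, 5.0]])
        assert len(filter_concepts(m, 1e-4, 3).values) == 0

    def test_cutoff_one_keeps_everything(self):
        m = self.make([[0.1, 0.0, -0.2], [1.0, 2.0, 3.0]])
        assert len(filter_concepts(m, 1.0, 1).values) == 2

    def test_single_study_criterion(self):
        m = self.make([[11.5, 0.2, 0.1], [3.0, 3.0, 3.0]])
        out = filter_concepts(m, 1e-11, 1)
        assert list(out.values.index) == ["C0"]


class TestUncenteredPearsonDistance:
    def test_self_distance_zero(self):
        a = np.array([1.0, 2.0, -3.0])
        assert uncentered_pearson_distance(a, a) == pytest.approx(0.0)

    def test_orthogonal_vectors(self):
        assert uncentered_pearson_distance(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(1.0)

    def test_anti_proportional_vectors(self):
        a = np.array([1.0, 2.0, 3.0])
        assert uncentered_pearson_distance(a, -a) == pytest.approx(2.0)

    def test_all_zero_vector_is_orthogonal_by_convention(self):
        assert uncentered_pearson_distance(np.zeros(3), np.array([1.0, 2.0, 3.0])) == 1.0

    def test_no_overlap_rejected(self):
        a = np.array([1.0, np.nan])
        b = np.array([np.nan, 1.0])
        with pytest.raises(InputError):
            uncentered_pearson_distance(a, b)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(8, 5))
        data[rng.uniform(size=data.shape) < 0.15] = np.nan
        brute = pairwise_uncentered_distances(data)
        for i in range(8):
            for j in range(8):
                assert uncentered_pearson_distance(data[i], data[j]) == pytest.approx(brute[i, j])


class TestHierarchicalCluster:
    def test_identical_rows_merge_first_at_similarity_one(self):
        frame = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [-5.0, 0.0, 1.0]],
            index=["a", "b", "c"], columns=["s1", "s2", "s3"],
        )
        records = hierarchical_cluster(ProfileMatrix(frame), "rows", "centroid")
        assert (records[0].left, records[0].right) == (0, 1)
        assert records[0].similarity == pytest.approx(1.0)

    @pytest.mark.parametrize("linkage", ["centroid", "average", "complete"])
    def test_n_minus_one_records(self, linkage):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(rng.normal(size=(7, 4)))
        frame.index = [f"r{i}" for i in range(7)]
        records = hierarchical_cluster(ProfileMatrix(frame), "rows", linkage)
        assert len(records) == 6

    @pytest.mark.parametrize("linkage", ["average", "complete"])
    def test_merge_heights_monotone(self, linkage):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame(rng.normal(size=(6, 4)), index=[f"r{i}" for i in range(6)])
        records = hierarchical_cluster(ProfileMatrix(frame), "rows", linkage)
        heights = [1.0 - r.similarity for r in records]
        assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))

    def test_average_linkage_heights_match_scipy(self):
        rng = np.random.default_rng(8)
        data = rng.normal(size=(9, 5))
        frame = pd.DataFrame(data, index=[f"r{i}" for i in range(9)])
        records = hierarchical_cluster(ProfileMatrix(frame), "rows", "average")
        dmat = pairwise_uncentered_distances(data)
        Z = sp_hierarchy.linkage(squareform(dmat, checks=False), method="average")
        np.testing.assert_allclose(
            sorted(1.0 - r.similarity for r in records), sorted(Z[:, 2]), atol=1e-10
        )

    def test_row_permutation_invariance_of_tree_topology(self):
        rng = np.random.default_rng(12)
        data = rng.normal(size=(6, 4))
        idx = [f"r{i}" for i in range(6)]
        m1 = ProfileMatrix(pd.DataFrame(data, index=idx))
        perm = [3, 0, 5, 1, 4, 2]
        m2 = ProfileMatrix(pd.DataFrame(data[perm], index=[idx[i] for i in perm]))
        r1 = hierarchical_cluster(m1, "rows", "average")
        r2 = hierarchical_cluster(m2, "rows", "average")

        def merged_label_sets(records, labels, n):
            members = {i: frozenset([labels[i]]) for i in range(n)}
            out = []
            for r in records:
                members[r.node_id] = members[r.left] | members[r.right]
                out.append((members[r.node_id], round(1 - r.similarity, 10)))
            return out

        assert merged_label_sets(r1, idx, 6) == merged_label_sets(r2, [idx[i] for i in perm], 6)

    def test_too_few_items_rejected(self):
        frame = pd.DataFrame([[1.0, 2.0]], index=["only"])
        with pytest.raises(InputError):
            hierarchical_cluster(ProfileMatrix(frame), "rows", "average")


class TestTreeview:
    def make_matrix(self, seed=4, nan=True):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(6, 4))
        if nan:
            data[1, 2] = np.nan
        return ProfileMatrix(
            pd.DataFrame(data, index=[f"C{i}" for i in range(6)], columns=[f"s{i}" for i in range(4)])
        )

    def test_matrix_without_trees_writes_cdt_only(self, tmp_path):
        m = self.make_matrix()
        files = write_treeview(m, prefix=tmp_path / "plain")
        assert set(files) == {"cdt"}
        back = read_cdt(files["cdt"])
        assert list(back.values.index) == m.concept_ids  # original order

    def test_cdt_roundtrip_to_six_significant_digits(self, tmp_path):
        m = self.make_matrix()
        rt = hierarchical_cluster(m, "rows", "centroid")
        ct = hierarchical_cluster(m, "columns", "centroid")
        files = write_treeview(m, rt, ct, tmp_path / "full")
        assert set(files) == {"cdt", "gtr", "atr"}
        back = read_cdt(files["cdt"])
        aligned = back.values.loc[m.concept_ids, m.study_ids]
        np.testing.assert_allclose(aligned, m.values, rtol=1e-5, equal_nan=True)

    def test_tree_similarities_in_range(self, tmp_path):
        m = self.make_matrix(seed=9)
        rt = hierarchical_cluster(m, "rows", "centroid")
        files = write_treeview(m, rt, None, tmp_path / "sim")
        for line in open(files["gtr"]):
            sim = float(line.split("\t")[3])
            assert -1.0 <= sim <= 1.0

    def test_rows_emitted_in_leaf_order(self, tmp_path):
        m = self.make_matrix(seed=2, nan=False)
        rt = hierarchical_cluster(m, "rows", "average")
        files = write_treeview(m, rt, None, tmp_path / "ord")
        order = leaf_order(rt, 6)
        with open(files["cdt"]) as fh:
            lines = [ln.split("\t") for ln in fh.read().splitlines()]
        ids = [ln[1] for ln in lines if ln[0].startswith("GENE")]
        assert ids == [m.concept_ids[i] for i in order]

    def test_inconsistent_tree_rejected(self, tmp_path):
        m = self.make_matrix()
        rt = hierarchical_cluster(m, "rows", "average")
        with pytest.raises(ConsistencyError):
            write_treeview(m, rt[:-2], None, tmp_path / "bad")

    def test_column_permutation_permutes_cdt_columns(self, tmp_path):
        m = self.make_matrix(nan=False)
        perm = ["s2", "s0", "s3", "s1"]
        m2 = ProfileMatrix(m.values[perm])
        f1 = write_treeview(m, prefix=tmp_path / "a")["cdt"]
        f2 = write_treeview(m2, prefix=tmp_path / "b")["cdt"]
        b1, b2 = read_cdt(f1), read_cdt(f2)
        np.testing.assert_allclose(b1.values[perm].to_numpy(), b2.values.to_numpy(), rtol=1e-5)
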