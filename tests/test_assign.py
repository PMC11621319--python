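"""Hamming distance, Kuhn–Munkres assignment and per-cell label propagation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import snpdemux as sd
from snpdemux.assign import INVALID_PENALTY
from snpdemux.profiles import MISSING, ProfileMatrix, VariantKey


def keys(n):
    return [VariantKey.make("1", 100 + 10 * i, "A", "G") for i in range(n)]


def pm(codes, prefix="S"):
    codes = np.asarray(codes, dtype=np.int8)
    return ProfileMatrix(
        loci=keys(codes.shape[0]),
        samples=[f"{prefix}{j}" for j in range(codes.shape[1])],
        codes=codes,
    )


def brute_force_min_cost(cost):
    n_c, n_p = cost.shape
    return min(
        sum(cost[i, p] for i, p in enumerate(perm))
        for perm in itertools.permutations(range(n_p), n_c)
    )


def dist_matrix(cost, min_support=1):
    cost = np.asarray(cost, dtype=float)
    n_c, n_p = cost.shape
    return sd.DistanceMatrix(
        clusters=[f"C{i}" for i in range(n_c)],
        patients=[f"P{j}" for j in range(n_p)],
        dist=cost,
        support=np.full((n_c, n_p), 100, dtype=np.int64),
        valid=np.ones((n_c, n_p), dtype=bool),
        min_support=min_support,
    )


class TestHammingMatrix:
    def test_profile_against_itself_is_zero(self):
        codes = np.array([[0], [1], [2], [MISSING], [1]], dtype=np.int8)
        dm = sd.hamming_matrix(pm(codes, "C"), pm(codes, "P"), min_support=1)
        assert dm.dist[0, 0] == 0.0
        assert dm.support[0, 0] == 4  # the MISSING locus is not co-typed

    def test_hand_counted_example(self):
        cluster = np.array([[0], [1], [2], [MISSING], [1]], dtype=np.int8)
        patient = np.array([[0], [2], [2], [1], [0]], dtype=np.int8)
        dm = sd.hamming_matrix(pm(cluster, "C"), pm(patient, "P"), min_support=1)
        # co-typed loci 1,2,3,5; mismatches at loci 2 and 5
        assert dm.support[0, 0] == 4
        assert dm.dist[0, 0] == pytest.approx(0.5)

    def test_complement_profiles_distance_one(self):
        a = np.array([[0], [1], [2]], dtype=np.int8)
        b = np.array([[1], [2], [0]], dtype=np.int8)
        dm = sd.hamming_matrix(pm(a, "C"), pm(b, "P"), min_support=1)
        assert dm.dist[0, 0] == 1.0

    def test_dosage_weighted_option(self):
        a = np.array([[0], [0]], dtype=np.int8)
        b = np.array([[2], [1]], dtype=np.int8)
        dm = sd.hamming_matrix(pm(a, "C"), pm(b, "P"), min_support=1,
                               dosage_weighted=True)
        assert dm.dist[0, 0] == pytest.approx((1.0 + 0.5) / 2)

    def test_min_support_flags_invalid_pairs(self):
        cluster = np.array([[1, 1], [0, 0], [1, MISSING]], dtype=np.int8)
        bulk = np.array([[1, MISSING], [0, MISSING], [1, 1]], dtype=np.int8)
        dm = sd.hamming_matrix(pm(cluster, "C"), pm(bulk, "P"), min_support=2)
        # C0 vs P1 and C1 vs P1 have support 1 and 0: flagged invalid
        assert dm.valid[:, 0].all()
        assert not dm.valid[:, 1].any()
        assert np.isnan(dm.dist[:, 1]).all()
        assert dm.support[0, 1] == 1 and dm.support[1, 1] == 0

    def test_cluster_invalid_everywhere_is_an_error(self):
        cluster = np.array([[1], [MISSING]], dtype=np.int8)
        bulk = np.array([[1, 0], [0, 1]], dtype=np.int8)
        with pytest.raises(sd.AssignmentError, match="C0"):
            sd.hamming_matrix(pm(cluster, "C"), pm(bulk, "P"), min_support=2)

    def test_no_common_loci_error(self):
        a = ProfileMatrix(loci=keys(2), samples=["C0"],
                          codes=np.zeros((2, 1), dtype=np.int8))
        b = ProfileMatrix(
            loci=[VariantKey.make("2", 5, "A", "G"), VariantKey.make("2", 6, "A", "G")],
            samples=["P0"], codes=np.zeros((2, 1), dtype=np.int8),
        )
        with pytest.raises(sd.AssignmentError, match="no loci"):
            sd.hamming_matrix(a, b, min_support=1)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_symmetry_and_locus_reorder_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n_loci = int(rng.integers(5, 40))
        a_codes = rng.choice([MISSING, 0, 1, 2], size=(n_loci, 2)).astype(np.int8)
        b_codes = rng.choice([MISSING, 0, 1, 2], size=(n_loci, 3)).astype(np.int8)
        a, b = pm(a_codes, "C"), pm(b_codes, "P")
        try:
            dm = sd.hamming_matrix(a, b, min_support=1)
        except sd.AssignmentError:
            return  # degenerate draw: some cluster co-typed with nobody
        dm_t = sd.hamming_matrix(b, a, min_support=1)
        np.testing.assert_allclose(dm.dist, dm_t.dist.T, equal_nan=True)
        # shuffling locus order changes nothing
        order = rng.permutation(n_loci)
        a2 = ProfileMatrix(loci=[a.loci[i] for i in order], samples=list(a.samples),
                           codes=a_codes[order])
        dm2 = sd.hamming_matrix(a2, b, min_support=1)
        np.testing.assert_allclose(dm.dist, dm2.dist, equal_nan=True)


class TestKuhnMunkres:
    def test_identity_on_diagonal_zero(self):
        cost = np.ones((4, 4)) - np.eye(4)
        res = sd.kuhn_munkres(dist_matrix(cost))
        assert res.mapping == {f"C{i}": f"P{i}" for i in range(4)}
        assert res.total_cost == 0.0

    def test_three_by_three_bruteforce_example(self):
        cost = np.array([[0.4, 0.1, 0.9], [0.2, 0.8, 0.3], [0.7, 0.6, 0.1]])
        res = sd.kuhn_munkres(dist_matrix(cost))
        assert res.mapping == {"C0": "P1", "C1": "P0", "C2": "P2"}
        assert res.total_cost == pytest.approx(0.4)
        assert res.total_cost == pytest.approx(brute_force_min_cost(cost))

    def test_rectangular_leaves_patients_unmatched(self):
        cost = np.array([[0.0, 1.0, 1.0], [1.0, 1.0, 0.0]])
        res = sd.kuhn_munkres(dist_matrix(cost))
        assert res.mapping == {"C0": "P0", "C1": "P2"}
        assert res.unmatched_patients == ["P1"]

    def test_more_clusters_than_patients_rejected(self):
        with pytest.raises(sd.AssignmentError, match="pool"):
            sd.kuhn_munkres(dist_matrix(np.zeros((3, 2))))

    def test_invalid_cells_get_finite_penalty(self):
        dm = dist_matrix(np.array([[0.1, np.nan], [0.2, np.nan]]))
        dm.valid[:, 1] = False
        res = sd.kuhn_munkres(dm)
        assert res.total_cost == pytest.approx(min(0.1, 0.2) + INVALID_PENALTY)

    def test_margin_can_be_negative_when_global_beats_rowmin(self):
        # C0's row minimum is P0, but the global optimum gives P0 to C1
        cost = np.array([[0.1, 0.2], [0.11, 0.9]])
        res = sd.kuhn_munkres(dist_matrix(cost))
        assert res.mapping == {"C0": "P1", "C1": "P0"}
        assert res.margin["C0"] == pytest.approx(0.1 - 0.2)
        assert res.margin["C0"] < 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_total_cost_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n_p = int(rng.integers(2, 8))
        n_c = int(rng.integers(2, n_p + 1))
        cost = rng.random((n_c, n_p))
        res = sd.kuhn_munkres(dist_matrix(cost))
        assert res.total_cost == pytest.approx(brute_force_min_cost(cost))

    def test_patient_permutation_equivariance(self, noisy_truth):
        dm = sd.hamming_matrix(noisy_truth.clusters, noisy_truth.bulk, min_support=10)
        res = sd.kuhn_munkres(dm)
        rng = np.random.default_rng(5)
        order = rng.permutation(noisy_truth.bulk.n_samples)
        bulk2 = ProfileMatrix(
            loci=list(noisy_truth.bulk.loci),
            samples=[noisy_truth.bulk.samples[i] for i in order],
            codes=noisy_truth.bulk.codes[:, order],
        )
        res2 = sd.kuhn_munkres(sd.hamming_matrix(noisy_truth.clusters, bulk2,
                                                 min_support=10))
        assert res2.mapping == res.mapping


class TestAssignCells:
    def cells(self):
        rows = []
        for i in range(7):
            rows.append((f"BC{i:02d}", "singlet", i % 2))
        rows += [("BC07", "doublet", None), ("BC08", "doublet", None),
                 ("BC09", "unassigned", None)]
        df = pd.DataFrame(rows, columns=["barcode", "status", "cluster"])
        df["cluster"] = pd.array(df["cluster"], dtype="Int64")
        df["patient"] = pd.array([None] * len(df), dtype="string")
        return df

    def result(self):
        return sd.AssignmentResult(
            mapping={"0": "PA", "1": "PB"},
            per_cluster_distance={"0": 0.0, "1": 0.0},
            margin={"0": 0.5, "1": 0.5},
            total_cost=0.0,
        )

    def test_mixed_table_gets_exactly_seven_patient_labels(self):
        out = sd.assign_cells(self.result(), self.cells())
        assert len(out) == 10
        labeled = out["patient"].isin(["PA", "PB"])
        assert labeled.sum() == 7
        assert (out.loc[out["status"] == "doublet", "patient"] == "doublet").all()
        assert (out.loc[out["status"] == "unassigned", "patient"] == "unassigned").all()

    def test_propagation_within_cluster(self):
        cells = self.cells()
        out = sd.assign_cells(self.result(), cells)
        in_c0 = out[(out["status"] == "singlet") & (out["cluster"] == 0)]
        assert (in_c0["patient"] == "PA").all()

    def test_unmapped_singlet_cluster_is_an_error(self):
        res = self.result()
        del res.mapping["1"]
        with pytest.raises(sd.AssignmentError, match="cluster"):
            sd.assign_cells(res, self.cells())


class TestAssignToGroups:
    def make_cells(self, cluster_sizes):
        rows = []
        i = 0
        for cluster, groups in cluster_sizes.items():
            for group, n in groups.items():
                for _ in range(n):
                    rows.append((f"BC{i:04d}", "singlet", cluster, group))
                    i += 1
        df = pd.DataFrame(rows, columns=["barcode", "status", "cluster", "group"])
        df["cluster"] = pd.array(df["cluster"], dtype="Int64")
        df["patient"] = pd.array([None] * len(df), dtype="string")
        reference = dict(zip(df["barcode"], df.pop("group")))
        return df, reference

    def test_majority_overlap_bruteforce(self):
        cells, ref = self.make_cells(
            {0: {"CD4 T": 90, "B": 10}, 1: {"B": 80, "CD4 T": 5}}
        )
        mapping = sd.assign_to_groups(cells, ref)
        # brute force over both injective mappings: 90+80 beats 10+5
        assert mapping == {0: "CD4 T", 1: "B"}

    def test_perfect_nesting(self):
        cells, ref = self.make_cells({0: {"G0": 40}, 1: {"G1": 30}})
        assert sd.assign_to_groups(cells, ref) == {0: "G0", 1: "G1"}

    def test_more_clusters_than_groups_warns(self):
        cells, ref = self.make_cells({0: {"G": 10}, 1: {"G": 10}})
        with pytest.warns(UserWarning):
            mapping = sd.assign_to_groups(cells, ref)
        assert len(mapping) == 1

    def test_empty_overlap_error(self):
        cells, _ = self.make_cells({0: {"G": 5}})
        with pytest.raises(sd.AssignmentError, match="no singlet barcodes"):
            sd.assign_to_groups(cells, {"ZZZZ-1": "G"})
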