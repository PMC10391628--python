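"""Clonal inference: identity and threshold modes against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from bcrep.clones import (
    assign_clones_identity,
    assign_clones_threshold,
    distance_to_nearest,
    find_threshold,
    first_gene,
)
from conftest import make_records


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        self.parent[self.find(i)] = self.find(j)

    def labels(self):
        return [self.find(i) for i in range(len(self.parent))]


def _random_records(n, rng, n_v=4, n_j=3, junction_pool=8):
    """Records with deliberately colliding V/J/junction combinations."""
    juncs = []
    for _ in range(junction_pool):
        L = int(rng.integers(4, 7))
        juncs.append("".join(rng.choice(list("ACGT"), 3 * L)))
    rows = []
    for _ in range(n):
        jn = juncs[int(rng.integers(junction_pool))]
        rows.append(
            {
                "v_call": f"IGHV{int(rng.integers(n_v)) + 1}*0{int(rng.integers(1, 3))}",
                "j_call": f"IGHJ{int(rng.integers(n_j)) + 1}*01",
                "junction": jn,
                "junction_aa": "X" * (len(jn) // 3),  # aa identity == nt identity here
            }
        )
    df = make_records(rows)
    # make aa junctions actually distinct per nt junction
    df["junction_aa"] = df["junction"].map(lambda s: s[::3])
    return df


@pytest.mark.parametrize("call,expected", [
    ("IGHV1-2*01", "IGHV1-2"),
    ("IGHV1*01,IGHV3*02", "IGHV1"),
    ("IGHJ4", "IGHJ4"),
])
def test_first_gene_strips_alleles_and_ties(call, expected):
    assert first_gene(call) == expected


class TestIdentityMode:
    def test_identical_triple_shares_a_clone(self):
        df = make_records([
            {"v_call": "IGHV1", "j_call": "IGHJ2", "junction_aa": "CARDYW"},
            {"v_call": "IGHV1", "j_call": "IGHJ2", "junction_aa": "CARDYW"},
        ])
        part = assign_clones_identity(df)
        assert len(part.clones) == 1
        assert part.clones["size"].iloc[0] == 2

    def test_same_v_and_cdr3_different_j_split(self):
        df = make_records([
            {"v_call": "IGHV1", "j_call": "IGHJ1", "junction_aa": "CARDYW"},
            {"v_call": "IGHV1", "j_call": "IGHJ2", "junction_aa": "CARDYW"},
        ])
        assert len(assign_clones_identity(df).clones) == 2

    def test_allele_suffix_ignored_in_grouping(self):
        df = make_records([
            {"v_call": "IGHV1*01", "j_call": "IGHJ1*01", "junction_aa": "CARDYW"},
            {"v_call": "IGHV1*02", "j_call": "IGHJ1*03", "junction_aa": "CARDYW"},
        ])
        assert len(assign_clones_identity(df).clones) == 1

    def test_empty_junction_aa_excluded_and_reported(self):
        df = make_records([{}, {"junction_aa": ""}])
        with pytest.warns(UserWarning, match="excluded"):
            part = assign_clones_identity(df)
        assert part.excluded == ("seq001",)
        assert len(part.assignments) == 1

    def test_matches_brute_force_triple_grouping(self):
        """200 colliding records: partition equals O(n^2) union-find by
        (V gene, J gene, junction_aa) triple equality."""
        rng = np.random.default_rng(42)
        df = _random_records(200, rng)
        part = assign_clones_identity(df)

        keys = [
            (first_gene(v), first_gene(j), aa)
            for v, j, aa in zip(df["v_call"], df["j_call"], df["junction_aa"])
        ]
        uf = _UnionFind(len(df))
        for i in range(len(df)):
            for k in range(i + 1, len(df)):
                if keys[i] == keys[k]:
                    uf.union(i, k)
        oracle = pd.factorize(np.array(uf.labels()))[0]
        pred = pd.factorize(part.assignments.loc[df["sequence_id"]])[0]
        from sklearn.metrics import rand_score

        assert rand_score(oracle, pred) == 1.0

    def test_sizes_invariant_under_row_permutation(self):
        rng = np.random.default_rng(3)
        df = _random_records(80, rng)
        sizes_a = assign_clones_identity(df).sizes.sort_index()
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        sizes_b = assign_clones_identity(shuffled).sizes.sort_index()
        pd.testing.assert_series_equal(sizes_a, sizes_b)

    def test_stable_clone_ids_across_runs(self):
        df = make_records([{"v_call": "IGHV1", "j_call": "IGHJ2", "junction_aa": "CARDYW"}])
        id1 = assign_clones_identity(df).clones["clone_id"].iloc[0]
        id2 = assign_clones_identity(df.copy()).clones["clone_id"].iloc[0]
        assert id1 == id2


class TestDistanceToNearest:
    def test_single_mismatch_pair(self):
        df = make_records([
            {"junction": "AAAAAA", "junction_aa": "KK"},
            {"junction": "AAAAAT", "junction_aa": "KN"},
        ])
        d = distance_to_nearest(df)
        assert d.tolist() == pytest.approx([1 / 6, 1 / 6])

    def test_identical_junctions_distance_zero(self):
        df = make_records([{}, {}])
        assert distance_to_nearest(df).tolist() == [0.0, 0.0]

    def test_different_groups_not_compared(self):
        df = make_records([
            {"junction": "AAAAAA", "junction_aa": "KK"},
            {"junction": "AAAAAT", "junction_aa": "KN", "v_call": "IGHV9*01"},
        ])
        with pytest.warns(UserWarning, match="no group"):
            assert len(distance_to_nearest(df)) == 0

    def test_matches_all_pairs_oracle(self):
        """100 junctions: vector equals exhaustive all-pairs Hamming minimum."""
        rng = np.random.default_rng(7)
        df = _random_records(100, rng)
        got = distance_to_nearest(df)

        def ham(a, b):
            return sum(x != y for x, y in zip(a, b)) / len(a)

        keys = [
            (first_gene(v), first_gene(j), len(jn))
            for v, j, jn in zip(df["v_call"], df["j_call"], df["junction"])
        ]
        for i, sid in enumerate(df["sequence_id"]):
            peers = [
                k for k in range(len(df)) if k != i and keys[k] == keys[i]
            ]
            if not peers:
                assert sid not in got.index
                continue
            expected = min(ham(df["junction"][i], df["junction"][k]) for k in peers)
            assert got[sid] == pytest.approx(expected)


class TestFindThreshold:
    def test_bimodal_mixture_valley_located(self):
        rng = np.random.default_rng(0)
        d = np.r_[rng.normal(0.02, 0.01, 1000), rng.normal(0.30, 0.05, 1000)]
        res = find_threshold(np.clip(d, 0, 1))
        assert not res.fallback_used
        assert 0.05 < res.threshold < 0.25

    def test_degenerate_all_zero_distances_fall_back(self):
        res = find_threshold(np.zeros(100))
        assert res.fallback_used
        assert res.threshold == 0.1

    def test_too_few_distances_error(self):
        with pytest.raises(ValueError, match="identity"):
            find_threshold(np.full(10, 0.2))


class TestThresholdMode:
    def test_single_linkage_transitivity(self):
        # A-B at 0.05, B-C at 0.05, A-C at 0.10; threshold 0.06 links all three
        a = "A" * 20
        b = "T" + "A" * 19
        c = "TC" + "A" * 18
        df = make_records([
            {"junction": a, "junction_aa": "X"},
            {"junction": b, "junction_aa": "Y"},
            {"junction": c, "junction_aa": "Z"},
        ])
        part = assign_clones_threshold(df, 0.06)
        assert len(part.clones) == 1
        assert part.clones["size"].iloc[0] == 3

    def test_zero_threshold_is_identity_on_nt_junctions(self):
        rng = np.random.default_rng(11)
        df = _random_records(60, rng)
        part = assign_clones_threshold(df, 0.0)
        by_nt = df.groupby(
            [df["v_call"].map(first_gene), df["j_call"].map(first_gene), df["junction"]]
        ).ngroups
        assert len(part.clones) == by_nt

    def test_matches_graph_components_oracle(self):
        """150 records: clones equal brute-force connected components of the
        <=-threshold Hamming graph within (V, J, length) groups."""
        rng = np.random.default_rng(23)
        df = _random_records(150, rng)
        # perturb some junctions so near- but not identical pairs exist
        jn = df["junction"].tolist()
        for i in range(0, len(jn), 5):
            s = list(jn[i])
            s[0] = "A" if s[0] != "A" else "C"
            jn[i] = "".join(s)
        df["junction"] = jn
        t = 0.2
        part = assign_clones_threshold(df, t)

        keys = [
            (first_gene(v), first_gene(j), len(x))
            for v, j, x in zip(df["v_call"], df["j_call"], df["junction"])
        ]
        uf = _UnionFind(len(df))
        for i in range(len(df)):
            for k in range(i + 1, len(df)):
                if keys[i] != keys[k]:
                    continue
                d = sum(a != b for a, b in zip(df["junction"][i], df["junction"][k]))
                if d / len(df["junction"][i]) <= t:
                    uf.union(i, k)
        from sklearn.metrics import rand_score

        oracle = pd.factorize(np.array(uf.labels()))[0]
        pred = pd.factorize(part.assignments.loc[df["sequence_id"]])[0]
        assert rand_score(oracle, pred) == 1.0

    def test_invalid_threshold_rejected(self):
        df = make_records([{}])
        with pytest.raises(ValueError):
            assign_clones_threshold(df, 1.5)


class TestAgainstPlantedTruth:
    def test_both_modes_recover_ground_truth(self, small_sample):
        """Without junction mutations both clone definitions must recover the
        planted partition exactly."""
        from sklearn.metrics import rand_score

        df, truth = small_sample
        for part in (
            assign_clones_identity(df),
            assign_clones_threshold(df, 0.1),
        ):
            pred = pd.factorize(part.assignments.loc[df["sequence_id"]])[0]
            assert rand_score(truth.clone_of_seq, pred) == 1.0

    def test_identity_refines_threshold_partition(self, small_sample):
        df, _ = small_sample
        ident = assign_clones_identity(df)
        thr = assign_clones_threshold(df, 0.25)
        merged = pd.DataFrame(
            {
                "ident": ident.assignments.loc[df["sequence_id"]].values,
                "thr": thr.assignments.loc[df["sequence_id"]].values,
            }
        )
        # every identity clone sits wholly inside one threshold clone
        assert (merged.groupby("ident")["thr"].nunique() == 1).all()

    def test_sample_specific_threshold_pipeline(self, small_sample):
        """Distance distribution of real-structured data is bimodal (zero
        intra-clone vs large inter-clone) and the detected threshold
        separates the modes."""
        from sklearn.metrics import rand_score

        df, truth = small_sample
        d = distance_to_nearest(df)
        res = find_threshold(d.to_numpy())
        assert not res.fallback_used
        part = assign_clones_threshold(df, res.threshold)
        pred = pd.factorize(part.assignments.loc[df["sequence_id"]])[0]
        assert rand_score(truth.clone_of_seq, pred) == 1.0
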