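"""Greedy mismatch-radius clustering against hand traces and a brute-force oracle."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from aptapool.clustering import (
    ClusterParams,
    UniqueSequence,
    assign_members,
    cluster_pool,
    pick_centroids,
    read_count_table,
    sequence_distance,
    tabulate_uniques,
    write_count_table,
)

from conftest import brute_force_cluster, naive_distance, random_pool


def U(vr: str, count: int) -> UniqueSequence:
    return UniqueSequence.from_counts(vr, {"R1": count})


class TestSequenceDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", 0),
            ("AAAA", "AAAT", 1),
            ("ACGTA", "ACGT", 1),  # single deletion, unequal lengths
            ("ACGT", "TGCA", 4),
        ],
    )
    def test_known_distances(self, a, b, expected):
        assert sequence_distance(a, b) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sequence_distance("", "ACGT")

    @settings(derandomize=True, max_examples=200)
    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=12),
        st.text(alphabet="ACGT", min_size=1, max_size=12),
    )
    def test_matches_naive_dp_and_symmetry(self, a, b):
        d = sequence_distance(a, b)
        assert d == sequence_distance(b, a) == naive_distance(a, b)
        assert (d == 0) == (a == b) or len(a) != len(b)


class TestPickCentroids:
    def test_single_sequence_is_sole_centroid(self):
        u = U("ACGTACGT", 5)
        assert pick_centroids([u], ClusterParams()) == [u]

    def test_within_radius_blocks_centroid(self):
        a, b = U("AAAAAAAA", 10), U("AAAAAATT", 3)  # distance 2 <= radius 4
        assert pick_centroids([a, b], ClusterParams(radius=4)) == [a]

    def test_beyond_radius_admits_centroid(self):
        a, b = U("AAAAAAAA", 10), U("TTTTTTAA", 8)  # distance 6 > radius 4
        assert pick_centroids([a, b], ClusterParams(radius=4)) == [a, b]

    def test_distance_exactly_radius_blocks(self):
        a, b = U("AAAAAAAA", 10), U("AAAATTTT", 8)  # distance 4, "within" is inclusive
        assert pick_centroids([a, b], ClusterParams(radius=4)) == [a]

    def test_count_tie_broken_lexicographically(self):
        a, b = U("TTTTTTTT", 5), U("AAAAAAAA", 5)
        assert pick_centroids([a, b], ClusterParams())[0] == b

    def test_empty_input(self):
        assert pick_centroids([], ClusterParams()) == []


class TestAssignMembers:
    def test_equidistant_sequence_is_ambiguous(self):
        a, b = U("AAAAAAAAAA", 10), U("TTTTTTAAAA", 8)  # distance 6
        c = U("AAATTTAAAA", 1)  # distance 3 to both
        result = assign_members([a, b, c], [a, b], ClusterParams())
        assert [e.sequence for e in result.ambiguous] == [c]
        assert result.ambiguous[0].tied_centroids == (0, 1)
        assert result.ambiguous[0].reason == "tie"

    def test_nearest_centroid_wins(self):
        a, b = U("AAAAAAAA", 10), U("TTTTTTTT", 8)
        c = U("AAAAAAAT", 1)  # 1 from a, 7 from b
        result = assign_members([a, b, c], [a, b], ClusterParams())
        assert result.clusters[0].members == [(c, 1)]
        assert result.clusters[1].members == []

    def test_no_members_leaves_empty_clusters(self):
        a, b = U("AAAAAAAA", 10), U("TTTTTTTT", 8)
        result = assign_members([a, b], [a, b], ClusterParams())
        assert all(cl.members == [] for cl in result.clusters)
        assert result.ambiguous == []

    def test_max_assignment_distance_flags_far_sequences(self):
        a = U("AAAAAAAA", 10)
        far = U("TTTTTTTT", 1)
        result = assign_members([a, far], [a], ClusterParams(max_assignment_distance=3))
        assert result.ambiguous[0].reason == "too_far"
        assert result.ambiguous[0].sequence == far


class TestClusterPool:
    def test_planted_family_forms_one_cluster(self):
        rng = random.Random(11)
        centroid = "".join(rng.choice("ACGT") for _ in range(20))
        satellites = []
        for k in range(5):
            s = list(centroid)
            for pos in rng.sample(range(20), k % 2 + 1):
                s[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[pos]]
            satellites.append("".join(s))
        uniques = [U(centroid, 100)] + [U(s, i + 1) for i, s in enumerate(set(satellites))]
        result = cluster_pool(uniques, ClusterParams(radius=4))
        assert len(result.clusters) == 1
        assert result.clusters[0].centroid.vr == centroid
        assert len(result.clusters[0].members) == len(uniques) - 1
        for member, dist in result.clusters[0].members:
            assert dist == naive_distance(member.vr, centroid)

    def test_two_distant_families_stay_separate(self):
        a, b = "A" * 20, "T" * 20  # distance 20 >= 10
        uniques = [U(a, 50), U(b, 40), U("A" * 19 + "T", 3), U("T" * 19 + "A", 2)]
        result = cluster_pool(uniques, ClusterParams(radius=4))
        assert [c.centroid.vr for c in result.clusters] == [a, b]
        assert len(result.ambiguous) == 0

    def test_duplicate_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_pool([U("ACGT", 1), U("ACGT", 2)], ClusterParams())

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        rng = random.Random(seed)
        uniques = random_pool(rng)
        params = ClusterParams(radius=rng.choice([2, 3, 4]))
        result = cluster_pool(uniques, params)
        oracle = brute_force_cluster(uniques, params.radius)
        assert [c.centroid.vr for c in result.clusters] == oracle.centroids
        for cl in result.clusters:
            assert [(m.vr, d) for m, d in cl.members] == oracle.members[cl.centroid.vr]
        assert [(e.sequence.vr, e.tied_centroids) for e in result.ambiguous] == oracle.ambiguous

    def test_partition_and_permutation_invariance(self):
        rng = random.Random(99)
        uniques = random_pool(rng)
        params = ClusterParams()
        result = cluster_pool(uniques, params)
        seen = sorted(u.vr for u in result.all_sequences())
        assert seen == sorted(u.vr for u in uniques)
        shuffled = uniques[:]
        rng.shuffle(shuffled)
        other = cluster_pool(shuffled, params)
        assert [c.centroid.vr for c in other.clusters] == [c.centroid.vr for c in result.clusters]
        assert [(e.sequence.vr, e.tied_centroids) for e in other.ambiguous] == [
            (e.sequence.vr, e.tied_centroids) for e in result.ambiguous
        ]


class TestCountTables:
    def test_tabulate_counts_per_round(self):
        uniques = tabulate_uniques({"R1": ["AAAA", "AAAA", "CCCC"], "R2": ["AAAA"]})
        by_vr = {u.vr: u.count_map for u in uniques}
        assert by_vr == {"AAAA": {"R1": 2, "R2": 1}, "CCCC": {"R1": 1, "R2": 0}}

    def test_round_trip_and_percent_columns_ignored(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text(
            "sequence\tR1\tR2\tR1 %\tR2 %\n"
            "ACGTACGT\t5\t10\t33.3\t66.7\n"
            "TTTTAAAA\t10\t0\t66.7\t0.0\n"
        )
        uniques = read_count_table(str(path))
        assert [(u.vr, u.count_map) for u in uniques] == [
            ("ACGTACGT", {"R1": 5, "R2": 10}),
            ("TTTTAAAA", {"R1": 10, "R2": 0}),
        ]
        out = tmp_path / "out.tsv"
        write_count_table(str(out), uniques, "params")
        assert read_count_table(str(out)) == uniques
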