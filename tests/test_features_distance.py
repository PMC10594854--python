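import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kmerphylo import (
    DistanceMatrix,
    KmerCountVector,
    build_feature_set,
    count_kmers,
    distance_matrix,
    pairwise_distance,
    read_phylip,
    relative_frequency,
    write_phylip,
)
from kmerphylo.features_distance import FeatureSetSpec, FeatureVector
from conftest import make_genome


def counts_from(values, k, taxon_id="t"):
    arr = np.asarray(values, dtype=np.int64)
    return KmerCountVector(k=k, taxon_id=taxon_id, counts=arr,
                           total_windows=int(arr.sum()))


def tiny_spec(member_indices, k=2, name="custom"):
    idx = np.asarray(member_indices, dtype=np.int64)
    return FeatureSetSpec(name=name, k=k, member_indices=idx,
                          member_classes=np.zeros(idx.size, dtype=np.uint8))


def rank_vector(ranks, spec, taxon_id="t", tie_policy="ordinal"):
    return FeatureVector(taxon_id=taxon_id, spec=spec,
                         ranks=np.asarray(ranks, dtype=np.float64),
                         tie_policy=tie_policy)


class TestBuildFeatureSet:
    @pytest.mark.parametrize("name,size", [
        ("CG12", 24991), ("TA12", 24991), ("CG0", 40545), ("TOTAL", 65536),
    ])
    def test_preset_sizes_at_k8(self, name, size):
        spec = build_feature_set(8, name)
        assert spec.size == size
        assert np.all(np.diff(spec.member_indices) > 0)

    def test_custom_union(self):
        spec = build_feature_set(8, ("CG", [1, 2]))
        assert spec.size == 24991
        assert spec.name == "CG12"

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="unknown feature set"):
            build_feature_set(8, "GC99")


class TestRelativeFrequency:
    def test_simple_ordering(self):
        kcv = counts_from([5, 2, 9, 0], k=1)
        spec = tiny_spec([0, 1, 2], k=1)
        fv = relative_frequency(kcv, spec)
        assert fv.ranks.tolist() == [2.0, 1.0, 3.0]

    def test_ordinal_tie_broken_by_kmer_index(self):
        kcv = counts_from([4, 4, 1, 0], k=1)
        fv = relative_frequency(kcv, tiny_spec([0, 1, 2], k=1), "ordinal")
        assert fv.ranks.tolist() == [2.0, 3.0, 1.0]

    def test_average_ties_share_mean_rank(self):
        kcv = counts_from([4, 4, 1, 0], k=1)
        fv = relative_frequency(kcv, tiny_spec([0, 1, 2], k=1), "average")
        assert fv.ranks.tolist() == [2.5, 2.5, 1.0]
        assert fv.ranks.sum() == 3 * 4 / 2

    def test_per_class_scope_ranks_within_classes(self):
        idx = np.array([0, 1, 2, 3], dtype=np.int64)
        spec = FeatureSetSpec(name="mix", k=1, member_indices=idx,
                              member_classes=np.array([1, 2, 1, 2], dtype=np.uint8))
        kcv = counts_from([9, 9, 3, 1], k=1)
        fv = relative_frequency(kcv, spec, rank_scope="per-class")
        assert fv.ranks.tolist() == [2.0, 2.0, 1.0, 1.0]

    @given(st.lists(st.integers(min_value=0, max_value=10**6),
                    min_size=2, max_size=40))
    @settings(deadline=None)
    def test_ordinal_ranks_are_a_permutation(self, values):
        n = len(values)
        kcv_vals = np.zeros(4**4, dtype=np.int64)
        kcv_vals[:n] = values
        kcv = counts_from(kcv_vals, k=4)
        fv = relative_frequency(kcv, tiny_spec(list(range(n)), k=4))
        assert sorted(fv.ranks.tolist()) == list(map(float, range(1, n + 1)))

    @given(st.lists(st.integers(min_value=0, max_value=1000),
                    min_size=3, max_size=30))
    @settings(deadline=None)
    def test_invariant_under_strictly_increasing_transform(self, values):
        n = len(values)
        spec = tiny_spec(list(range(n)), k=4)

        def as_counts(vals):
            arr = np.zeros(4**4, dtype=np.int64)
            arr[:n] = vals
            return counts_from(arr, k=4)

        base = relative_frequency(as_counts(values), spec)
        transformed = [3 * v**2 + 7 * v + 1 for v in values]  # strictly increasing on v >= 0
        other = relative_frequency(as_counts(transformed), spec)
        assert np.array_equal(base.ranks, other.ranks)


class TestPairwiseDistance:
    def test_worked_example(self):
        spec = tiny_spec([0, 1, 2], k=1)
        a = rank_vector([1, 2, 3], spec)
        b = rank_vector([3, 2, 1], spec, taxon_id="u")
        assert pairwise_distance(a, b) == pytest.approx(np.sqrt(8 / 3))
        assert pairwise_distance(b, a) == pairwise_distance(a, b)
        assert pairwise_distance(a, a) == 0.0

    def test_mismatched_specs_rejected(self):
        a = rank_vector([1, 2], tiny_spec([0, 1], name="s1"))
        b = rank_vector([1, 2], tiny_spec([0, 2], name="s2"), taxon_id="u")
        with pytest.raises(ValueError, match="not comparable"):
            pairwise_distance(a, b)

    @given(st.integers(min_value=2, max_value=8), st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=40)
    def test_metric_axioms_on_random_rank_vectors(self, n, seed):
        rng = np.random.default_rng(seed)
        spec = tiny_spec(list(range(n)), k=4)
        vs = [rank_vector(rng.permutation(n) + 1, spec, taxon_id=f"t{i}")
              for i in range(3)]
        a, b, c = vs
        dab, dbc, dac = (pairwise_distance(a, b), pairwise_distance(b, c),
                         pairwise_distance(a, c))
        assert dab >= 0 and dbc >= 0 and dac >= 0
        assert dac <= dab + dbc + 1e-12
        assert dab == pairwise_distance(b, a)
        if np.array_equal(a.ranks, b.ranks):
            assert dab == 0

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_max_distance_bound_exhaustive(self, n):
        # D <= sqrt((N^2 - 1)/3), attained by a rank vector and its reversal
        perms = np.array(list(itertools.permutations(range(1, n + 1))), dtype=float)
        sq = (perms**2).sum(axis=1)
        d2 = (sq[:, None] + sq[None, :] - 2 * perms @ perms.T) / n
        bound = np.sqrt((n**2 - 1) / 3)
        assert np.sqrt(d2.max()) == pytest.approx(bound)
        assert np.all(np.sqrt(np.maximum(d2, 0)) <= bound + 1e-9)


class TestDistanceMatrix:
    def test_identical_genomes_zero_matrix(self):
        spec = build_feature_set(4, ("CG", [1, 2]))
        g = make_genome("ACGTACGGCCGTAGCTAGCATCGGATCG" * 20)
        kcv = count_kmers(g, 4)
        vecs = [
            FeatureVector(taxon_id=f"t{i}", spec=spec,
                          ranks=relative_frequency(kcv, spec).ranks,
                          tie_policy="ordinal")
            for i in range(3)
        ]
        dm = distance_matrix(vecs)
        assert np.all(dm.d == 0)

    def test_four_taxa_symmetric(self):
        rng = np.random.default_rng(2)
        spec = tiny_spec(list(range(10)), k=4)
        vecs = [rank_vector(rng.permutation(10) + 1, spec, taxon_id=f"t{i}")
                for i in range(4)]
        dm = distance_matrix(vecs)
        off = dm.d[np.triu_indices(4, 1)]
        assert len(off) == 6
        assert np.array_equal(dm.d, dm.d.T)

    def test_duplicate_taxon_rejected(self):
        spec = tiny_spec([0, 1], k=2)
        vecs = [rank_vector([1, 2], spec, taxon_id="same") for _ in range(3)]
        with pytest.raises(ValueError, match="duplicate"):
            distance_matrix(vecs)

    def test_fewer_than_three_taxa_rejected(self):
        spec = tiny_spec([0, 1], k=2)
        vecs = [rank_vector([1, 2], spec, taxon_id=f"t{i}") for i in range(2)]
        with pytest.raises(ValueError, match="at least 3"):
            distance_matrix(vecs)


class TestPhylipRoundTrip:
    def test_zero_matrix_layout(self, tmp_path):
        dm = DistanceMatrix(("a", "b", "c"), np.zeros((3, 3)))
        p = tmp_path / "m.phy"
        write_phylip(dm, p)
        lines = p.read_text().splitlines()
        assert lines[0] == "3"
        assert len(lines) == 4
        assert lines[1].split() == ["a", "0.000000", "0.000000", "0.000000"]

    def test_round_trip_to_written_precision(self, tmp_path):
        rng = np.random.default_rng(7)
        raw = rng.uniform(0, 10, size=(5, 5))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(tuple("abcde"), d)
        p = tmp_path / "m.phy"
        write_phylip(dm, p)
        back = read_phylip(p)
        assert back.taxa == dm.taxa
        assert np.allclose(back.d, dm.d, atol=1e-6)

    def test_name_with_whitespace_rejected(self, tmp_path):
        dm = DistanceMatrix(("a b", "c", "d"), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="PHYLIP"):
            write_phylip(dm, tmp_path / "m.phy")

    def test_malformed_header(self, tmp_path):
        p = tmp_path / "bad.phy"
        p.write_text("not-a-count\n")
        with pytest.raises(ValueError, match="malformed PHYLIP header"):
            read_phylip(p)

    def test_row_count_mismatch(self, tmp_path):
        p = tmp_path / "bad.phy"
        p.write_text("3\na 0.0 0.1 0.2\n")
        with pytest.raises(ValueError, match="expected 3 matrix rows"):
            read_phylip(p)
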