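"""MinHash/Mash distances, fragment ANI, dotplots and threshold clustering."""

import numpy as np
import pandas as pd
import pytest

from phagediv.benchmarks import _exact_jaccard_strings
from phagediv.distance import (
    DistanceResult,
    cluster_genomes,
    canonical_kmer_codes,
    distance_frame,
    dotplot_matrix,
    fragment_ani,
    mash_ani_correlation,
    mash_distance,
    minhash_sketch,
)
from phagediv.records import GenomeRecord
from phagediv.simulate import FamilySpec, GenomeSpec, generate_family, generate_genome


def _rec(name, seq):
    return GenomeRecord(id=name, sequence=seq)


class TestSketch:
    def test_identical_sequences_identical_sketches(self, random_dna):
        seq = random_dna(3000)
        a = minhash_sketch(_rec("a", seq))
        b = minhash_sketch(_rec("b", seq))
        assert np.array_equal(a.hashes, b.hashes)

    def test_reverse_complement_invariance(self, random_dna):
        seq = random_dna(3000)
        from oracles import revcomp as rc

        a = minhash_sketch(_rec("a", seq))
        b = minhash_sketch(_rec("b", rc(seq)))
        assert np.array_equal(a.hashes, b.hashes)

    def test_sketch_size_bound(self, random_dna):
        seq = random_dna(10_000)
        sk = minhash_sketch(_rec("a", seq), k=21, s=1000)
        n_distinct = canonical_kmer_codes(seq, 21).size
        assert sk.hashes.size == min(1000, n_distinct)
        assert np.all(np.diff(sk.hashes.astype(np.int64)) > 0)

    def test_sequence_shorter_than_k_rejected(self):
        with pytest.raises(ValueError, match="shorter than k"):
            minhash_sketch(_rec("a", "ACGT"), k=21)


class TestMashDistance:
    def test_identical_zero(self, random_dna):
        sk = minhash_sketch(_rec("a", random_dna(5000)))
        d = mash_distance(sk, sk)
        assert d.jaccard_est == 1.0
        assert d.mash_distance == 0.0

    def test_disjoint_capped_at_one(self, random_dna):
        a = minhash_sketch(_rec("a", generate_genome(
            GenomeSpec(length=5000, gc_target=0.5, seed=1)).sequence))
        b = minhash_sketch(_rec("b", generate_genome(
            GenomeSpec(length=5000, gc_target=0.5, seed=2)).sequence))
        d = mash_distance(a, b)
        assert d.jaccard_est == pytest.approx(0.0, abs=0.01)
        if d.jaccard_est == 0.0:
            assert d.mash_distance == 1.0

    def test_k_mismatch_rejected(self, random_dna):
        seq = random_dna(1000)
        with pytest.raises(ValueError, match="k mismatch"):
            mash_distance(minhash_sketch(_rec("a", seq), k=21),
                          minhash_sketch(_rec("b", seq), k=15))

    def test_jaccard_close_to_exact_on_family_pair(self):
        fam, _ = generate_family(
            FamilySpec(ancestor=GenomeSpec(length=50_000, gc_target=0.42, seed=5),
                       n_members=2, substitution_rate=0.01, seed=6)
        )
        j_exact = _exact_jaccard_strings(fam[0].sequence, fam[1].sequence, 21)
        d = mash_distance(minhash_sketch(fam[0]), minhash_sketch(fam[1]))
        assert abs(d.jaccard_est - j_exact) <= 0.05

    def test_symmetry(self, random_dna):
        a = minhash_sketch(_rec("a", random_dna(4000)))
        b = minhash_sketch(_rec("b", random_dna(4000)))
        assert mash_distance(a, b).mash_distance == mash_distance(b, a).mash_distance

    def test_monotone_in_substitution_rate(self):
        dists = []
        for i, r in enumerate(np.arange(0.0, 0.121, 0.02)):
            fam, _ = generate_family(
                FamilySpec(ancestor=GenomeSpec(length=30_000, gc_target=0.42, seed=40 + i),
                           n_members=2, substitution_rate=float(r), seed=60 + i)
            )
            dists.append(
                mash_distance(minhash_sketch(fam[0]), minhash_sketch(fam[1])).mash_distance
            )
        assert np.all(np.diff(dists) > 0)


class TestFragmentANI:
    def test_identical_genomes_ani_one(self):
        g = generate_genome(GenomeSpec(length=10_000, gc_target=0.42, seed=7))
        assert fragment_ani(g, g) == pytest.approx(1.0)

    def test_family_matches_closed_form(self):
        fam, truth = generate_family(
            FamilySpec(ancestor=GenomeSpec(length=20_000, gc_target=0.42, seed=8),
                       n_members=2, substitution_rate=0.05, seed=9)
        )
        ani = fragment_ani(fam[0], fam[1])
        assert ani is not None
        assert abs(ani - truth["expected_identity"].iloc[0]) <= 0.02

    def test_unrelated_genomes_undefined(self):
        a = generate_genome(GenomeSpec(length=5000, gc_target=0.5, seed=10, name="a"))
        b = generate_genome(GenomeSpec(length=5000, gc_target=0.5, seed=11, name="b"))
        assert fragment_ani(a, b) is None

    def test_short_sequence_rejected(self):
        g = generate_genome(GenomeSpec(length=500, gc_target=0.5, seed=12))
        with pytest.raises(ValueError, match="fragment_len"):
            fragment_ani(g, g)


class TestDotplot:
    def test_identical_20mers_diagonal(self, rng):
        # random 20-mer with all distinct 10-words
        while True:
            seq = "".join(rng.choice(list("ACGT"), size=20))
            words = {seq[i:i + 10] for i in range(11)}
            if len(words) == 11:
                break
        rec = _rec("x", seq)
        coords = dotplot_matrix(rec, rec, word_len=10)
        assert coords.shape == (11, 2)
        assert np.array_equal(coords, np.array([(i, i) for i in range(11)]))

    def test_no_shared_words_empty(self):
        a = _rec("a", "A" * 50)
        b = _rec("b", "C" * 50)
        assert dotplot_matrix(a, b).shape == (0, 2)

    def test_self_plot_symmetric(self, random_dna):
        rec = _rec("x", random_dna(200))
        coords = dotplot_matrix(rec, rec)
        pairs = {(int(x), int(y)) for x, y in coords}
        assert all((y, x) in pairs for x, y in pairs)
        assert all((i, i) in pairs for i in range(len(rec.sequence) - 10 + 1))


class TestClusterGenomes:
    @staticmethod
    def _matrix(ids, entries):
        df = pd.DataFrame(0.0, index=ids, columns=ids)
        for a, b, d in entries:
            df.loc[a, b] = d
            df.loc[b, a] = d
        return df

    def test_all_zero_one_cluster(self):
        df = self._matrix(list("abc"), [("a", "b", 0.0), ("a", "c", 0.0), ("b", "c", 0.0)])
        out = cluster_genomes(df)
        assert len({a.cluster_label for a in out}) == 1
        assert len({a.supercluster_label for a in out}) == 1

    def test_two_families_two_thresholds(self):
        ids = ["a1", "a2", "b1", "b2"]
        entries = [("a1", "a2", 0.05), ("b1", "b2", 0.08),
                   ("a1", "b1", 0.4), ("a1", "b2", 0.4),
                   ("a2", "b1", 0.4), ("a2", "b2", 0.4)]
        out = cluster_genomes(self._matrix(ids, entries), 0.1, 0.2)
        clusters = {a.record_id: a.cluster_label for a in out}
        supers = {a.record_id: a.supercluster_label for a in out}
        assert clusters["a1"] == clusters["a2"] != clusters["b1"] == clusters["b2"]
        assert len(set(supers.values())) == 2

    def test_supercluster_merges_at_larger_threshold(self):
        ids = ["a1", "a2", "b1", "b2"]
        entries = [("a1", "a2", 0.05), ("b1", "b2", 0.08),
                   ("a1", "b1", 0.3), ("a1", "b2", 0.3),
                   ("a2", "b1", 0.3), ("a2", "b2", 0.3)]
        out = cluster_genomes(self._matrix(ids, entries), 0.1, 0.35)
        assert len({a.cluster_label for a in out}) == 2
        assert len({a.supercluster_label for a in out}) == 1

    def test_clusters_nest_in_superclusters(self, rng):
        ids = [f"g{i}" for i in range(12)]
        mat = rng.uniform(0, 1, size=(12, 12))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0.0)
        df = pd.DataFrame(mat, index=ids, columns=ids)
        out = cluster_genomes(df, 0.2, 0.5)
        sup_of_cluster = {}
        for a in out:
            sup_of_cluster.setdefault(a.cluster_label, set()).add(a.supercluster_label)
        assert all(len(s) == 1 for s in sup_of_cluster.values())

    def test_missing_entries_rejected(self):
        df = self._matrix(list("ab"), [("a", "b", np.nan)])
        with pytest.raises(ValueError, match="missing"):
            cluster_genomes(df)

    def test_threshold_order_enforced(self):
        df = self._matrix(list("ab"), [("a", "b", 0.1)])
        with pytest.raises(ValueError):
            cluster_genomes(df, 0.5, 0.1)


class TestMashAniCorrelation:
    @staticmethod
    def _results(pairs):
        return [
            DistanceResult(pair=(f"x{i}", f"y{i}"), jaccard_est=0.5,
                           mash_distance=d, ani=a)
            for i, (d, a) in enumerate(pairs)
        ]

    def test_perfectly_linear(self):
        pairs = [(d, 1.0 - d) for d in (0.01, 0.05, 0.10, 0.20)]
        assert mash_ani_correlation(self._results(pairs)) == pytest.approx(1.0)

    def test_anti_linear(self):
        pairs = [(d, d) for d in (0.01, 0.05, 0.10, 0.20)]
        assert mash_ani_correlation(self._results(pairs)) == pytest.approx(-1.0)

    def test_too_few_defined_rejected(self):
        with pytest.raises(ValueError):
            mash_ani_correlation(self._results([(0.1, 0.9), (0.2, None)])[:1])

    def test_distance_frame_symmetric(self, random_dna):
        recs = [_rec(f"r{i}", random_dna(2000)) for i in range(4)]
        from phagediv.distance import pairwise_mash

        df = distance_frame(pairwise_mash(recs))
        assert np.allclose(df.values, df.values.T)
        assert np.allclose(np.diag(df.values), 0.0)
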