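"""Six-frame translation, marker search, identity score and prevalence profiling."""

import pandas as pd
import pytest

from oracles import revcomp
from phagediv.markers import (
    HitRecord,
    MarkerProtein,
    identity_score,
    prevalence_by_site,
    profile_prevalence,
    read_hits_table,
    search_markers,
    six_frame_translate,
    species_presence,
    supercluster_presence,
)
from phagediv.records import GenomeRecord, SampleMetadata
from phagediv.simulate import (
    GenomeSpec,
    generate_genome,
    mutate_protein,
    plant_gene,
    random_protein,
    reverse_translate,
)


def _hit(marker="m", contig="c", sample="s", qlen=100, span=100, pid=100.0, ev=1e-100):
    return HitRecord(
        marker_id=marker, contig_id=contig, sample_id=sample,
        query_len=qlen, aligned_query_span=span, percent_identity=pid, e_value=ev,
    )


class TestSixFrameTranslate:
    def test_simple_codons(self):
        frames = six_frame_translate(GenomeRecord(id="c", sequence="ATGGCC"))
        assert frames[0] == "MA"

    def test_stop_codon_sentinel(self):
        frames = six_frame_translate(GenomeRecord(id="c", sequence="TAA"))
        assert frames[0] == "*"

    def test_partial_codons_dropped(self):
        frames = six_frame_translate(GenomeRecord(id="c", sequence="ATGGC"))
        assert frames[0] == "M"
        assert frames[1] == "W"  # TGG from offset 1

    def test_revcomp_symmetry(self, random_dna):
        seq = random_dna(99)
        fwd = six_frame_translate(GenomeRecord(id="a", sequence=seq))
        rev = six_frame_translate(GenomeRecord(id="b", sequence=revcomp(seq)))
        assert fwd[3:6] == rev[0:3]
        assert fwd[0:3] == rev[3:6]


@pytest.fixture(scope="module")
def planted_setup():
    host = generate_genome(GenomeSpec(length=3000, gc_target=0.45, seed=21, name="ctg"))
    prot = random_protein(120, seed=22)
    contig = plant_gene(host, reverse_translate(prot, seed=23), 900)
    marker = MarkerProtein(marker_id="mk", cluster_label="cl", sequence=prot)
    return marker, contig, prot


class TestSearchMarkers:
    def test_verbatim_marker_found_full_identity(self, planted_setup):
        marker, contig, _ = planted_setup
        (hit,) = search_markers([marker], [contig])
        assert hit.percent_identity == pytest.approx(100.0)
        assert hit.aligned_query_span == len(marker.sequence)
        assert identity_score(hit) == pytest.approx(100.0)

    def test_marker_on_reverse_strand_found(self, planted_setup):
        marker, contig, _ = planted_setup
        flipped = GenomeRecord(id="rc", sequence=revcomp(contig.sequence))
        (hit,) = search_markers([marker], [flipped])
        assert hit.percent_identity == pytest.approx(100.0)

    def test_score_invariant_under_revcomp(self, planted_setup):
        marker, contig, _ = planted_setup
        (fwd,) = search_markers([marker], [contig])
        (rev,) = search_markers(
            [marker], [GenomeRecord(id="rc", sequence=revcomp(contig.sequence))]
        )
        assert fwd.score == rev.score

    def test_random_contigs_give_no_hit(self, planted_setup):
        marker, _, _ = planted_setup
        misses = 0
        n = 100
        for i in range(n):
            rnd = generate_genome(
                GenomeSpec(length=1000, gc_target=0.5, seed=500 + i, name=f"r{i}")
            )
            misses += len(search_markers([marker], [rnd])) == 0
        assert misses / n >= 0.99

    def test_divergent_marker_identity_tracks_divergence(self, planted_setup):
        marker, _, prot = planted_setup
        host = generate_genome(GenomeSpec(length=3000, gc_target=0.45, seed=31, name="c2"))
        mut = mutate_protein(prot, 0.10, seed=32)
        contig = plant_gene(host, reverse_translate(mut, seed=33), 900)
        (hit,) = search_markers([marker], [contig])
        assert abs(hit.percent_identity - 90.0) <= 3.0


class TestIdentityScore:
    @pytest.mark.parametrize(
        "span,qlen,pid,expected",
        [
            (100, 100, 96.0, 96.0),  # full coverage, 96% identity: retained
            (90, 100, 100.0, 90.0),  # 90% coverage at full identity: filtered out
            (100, 100, 95.0, 95.0),  # exactly 95: retained (inclusive)
        ],
    )
    def test_formula(self, span, qlen, pid, expected):
        assert identity_score(_hit(span=span, qlen=qlen, pid=pid)) == pytest.approx(expected)

    def test_never_exceeds_identity(self, rng):
        for _ in range(50):
            qlen = int(rng.integers(50, 300))
            span = int(rng.integers(1, qlen + 1))
            pid = float(rng.uniform(0, 100))
            assert identity_score(_hit(span=span, qlen=qlen, pid=pid)) <= pid + 1e-9

    def test_span_exceeding_qlen_rejected(self):
        with pytest.raises(ValueError):
            _hit(span=120, qlen=100)


class TestProfilePrevalence:
    @pytest.fixture
    def metadata(self):
        return [SampleMetadata(f"t{i}", "tongue") for i in range(10)]

    def test_one_positive_of_ten(self, metadata):
        hits = [_hit(sample="t3")]
        table = profile_prevalence(hits, metadata, {"m": "cl1"})
        prev = prevalence_by_site(table)
        assert prev.loc[prev["cluster"] == "cl1", "prevalence"].iloc[0] == 0.1

    def test_evalue_cutoff_excludes(self, metadata):
        hits = [_hit(sample="t3", ev=1e-50)]
        table = profile_prevalence(hits, metadata, {"m": "cl1"}, evalue_cutoff=1e-80)
        assert not table.data.any().any()

    def test_score_threshold_inclusive_at_95(self, metadata):
        hits = [_hit(sample="t0", pid=95.0), _hit(sample="t1", pid=94.999, marker="m")]
        table = profile_prevalence(hits, metadata, {"m": "cl1"}, score_cutoff=95.0)
        assert bool(table.data.loc["t0", "cl1"]) is True
        assert bool(table.data.loc["t1", "cl1"]) is False

    def test_unknown_sample_rejected(self, metadata):
        with pytest.raises(ValueError, match="unknown sample"):
            profile_prevalence([_hit(sample="zz")], metadata, {"m": "cl1"})

    def test_raising_cutoffs_never_increases_prevalence(self, metadata, rng):
        hits = [
            _hit(marker="m", sample=f"t{rng.integers(10)}",
                 pid=float(rng.uniform(80, 100)),
                 span=int(rng.integers(80, 101)),
                 ev=float(10.0 ** -rng.integers(60, 120)))
            for _ in range(40)
        ]
        prev_counts = []
        for score_cut in (80.0, 90.0, 95.0):
            t = profile_prevalence(hits, metadata, {"m": "c"},
                                   evalue_cutoff=1e-80, score_cutoff=score_cut)
            prev_counts.append(int(t.data.sum().sum()))
        assert prev_counts == sorted(prev_counts, reverse=True)
        ev_counts = []
        for ev_cut in (1e-60, 1e-80, 1e-100):  # stricter left to right
            t = profile_prevalence(hits, metadata, {"m": "c"},
                                   evalue_cutoff=ev_cut, score_cutoff=90.0)
            ev_counts.append(int(t.data.sum().sum()))
        assert ev_counts == sorted(ev_counts, reverse=True)

    def test_supercluster_union(self, metadata):
        hits = [_hit(marker="m1", sample="t0"), _hit(marker="m2", sample="t5")]
        table = profile_prevalence(hits, metadata, {"m1": "cl1", "m2": "cl2"})
        sup = supercluster_presence(table, {"cl1": "SC", "cl2": "SC"})
        assert int(sup.data["SC"].sum()) == 2  # union of disjoint sample sets


class TestSpeciesPresence:
    def test_threshold_strict(self):
        table = pd.DataFrame({"s1": [0.2, 0.1, 0.0]}, index=["a", "b", "c"]).T
        out = species_presence(table, 0.1)
        assert out.loc["s1"].tolist() == [True, False, False]


class TestHitsTableIngestion:
    def test_thirteen_column_roundtrip(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("mk1\tctg7\t97.5\t110\t2\t0\t1\t110\t5\t334\t1e-90\t250\t120\n")
        (hit,) = read_hits_table(p)
        assert hit.marker_id == "mk1"
        assert hit.query_len == 120
        assert hit.aligned_query_span == 110
        assert identity_score(hit) == pytest.approx(110 / 120 * 97.5)

    def test_twelve_columns_need_lengths(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("mk1\tctg7\t97.5\t110\t2\t0\t1\t110\t5\t334\t1e-90\t250\n")
        with pytest.raises(ValueError, match="query_lengths"):
            read_hits_table(p)
        (hit,) = read_hits_table(p, query_lengths={"mk1": 120})
        assert hit.query_len == 120
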