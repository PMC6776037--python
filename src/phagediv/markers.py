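"""Marker-protein screening of metagenome contigs.

Phage clusters are diagnosed in metagenomes by searching cluster-specific marker
proteins (head morphogenesis / DNA packaging genes) against six-frame translations of
assembled contigs.  A hit is summarized by the identity score — the fraction of the
query covered by the hit times the hit's percent identity, a 0-100 scale — and
retained at score >= 95 and E-value <= 1e-80 (the thresholds used with a real
translated-search database).  Retained hits give per-sample presence of phage
clusters and per-body-site prevalence.

The built-in aligner is a plain affine-gap local aligner (BLOSUM62, open -11,
extend -1) intended for desk-scale data; its E-values use fixed Karlin-Altschul
constants and are approximate.  Hit tables from an external search tool in standard
12-column tabular format can be ingested instead and feed the same identity score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .records import GenomeRecord, SampleMetadata
from .stats import PresenceTable

__all__ = [
    "MarkerProtein",
    "HitRecord",
    "six_frame_translate",
    "search_markers",
    "identity_score",
    "profile_prevalence",
    "prevalence_by_site",
    "supercluster_presence",
    "species_presence",
    "read_hits_table",
]

DEFAULT_EVALUE_CUTOFF = 1e-80
DEFAULT_SCORE_CUTOFF = 95.0
DEFAULT_MIN_ALIGN_SCORE = 60.0
# Karlin-Altschul constants for gapped BLOSUM62 (open 11 / extend 1) searches.
_KA_LAMBDA = 0.267
_KA_K = 0.041

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class MarkerProtein:
    """A cluster-diagnostic marker protein sequence."""

    marker_id: str
    cluster_label: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 30:
            raise ValueError(f"{self.marker_id}: marker must be >= 30 aa")
        bad = set(seq) - _AA_ALPHABET
        if bad:
            raise ValueError(f"{self.marker_id}: invalid residues {sorted(bad)!r}")


@dataclass(frozen=True)
class HitRecord:
    """One translated-search hit of a marker against a contig."""

    marker_id: str
    contig_id: str
    sample_id: str
    query_len: int
    aligned_query_span: int
    percent_identity: float
    e_value: float
    score: float = float("nan")

    def __post_init__(self) -> None:
        if self.aligned_query_span > self.query_len:
            raise ValueError(
                f"{self.marker_id}/{self.contig_id}: aligned span exceeds query length"
            )


def six_frame_translate(contig: GenomeRecord) -> list[str]:
    """Translate all six reading frames (plain codon translation, stops as '*').

    Frames 0-2 are offsets +1..+3 of the forward strand; frames 3-5 are the three
    frames of the reverse complement.  Trailing partial codons are dropped.
    """
    seq = Seq(contig.sequence)
    rc = seq.reverse_complement()
    frames = []
    for strand in (seq, rc):
        for off in range(3):
            sub = strand[off : off + 3 * ((len(strand) - off) // 3)]
            frames.append(str(sub.translate()))
    return frames


def _make_aligner(gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def _alignment_stats(alignment) -> tuple[int, int, int]:
    """(matches, columns, query_span) of a local alignment."""
    target, query = alignment.target, alignment.query
    matches = 0
    columns = 0
    prev_q = prev_t = None
    tb, qb = alignment.aligned  # (target_blocks, query_blocks)
    for (ts, te), (qs, qe) in zip(tb, qb):
        seg_t = target[ts:te]
        seg_q = query[qs:qe]
        matches += sum(1 for x, y in zip(seg_t, seg_q) if x == y)
        if prev_q is not None:
            columns += (qs - prev_q) + (ts - prev_t)  # gap columns between blocks
        columns += te - ts
        prev_q, prev_t = qe, te
    q_start, q_end = qb[0][0], qb[-1][1]
    return matches, columns, q_end - q_start


def search_markers(
    markers: Sequence[MarkerProtein],
    contigs: Sequence[GenomeRecord],
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    min_align_score: float = DEFAULT_MIN_ALIGN_SCORE,
    sample_of: Mapping[str, str] | None = None,
) -> list[HitRecord]:
    """Align every marker against the six frames of every contig; keep best hits.

    For each (marker, contig) pair the best-scoring frame wins and only that hit
    is emitted; pairs whose best raw alignment score falls below
    ``min_align_score`` produce no hit, which is how random sequence is rejected.
    The E-value is ``K * m * n * exp(-lambda * S)`` over the contig's translated
    search space — approximate by construction.  ``sample_of`` maps contig id to
    sample id (default: the contig id itself).
    """
    if not markers or not contigs:
        raise ValueError("markers and contigs must be non-empty")
    aligner = _make_aligner(gap_open, gap_extend)
    hits: list[HitRecord] = []
    for contig in contigs:
        frames = six_frame_translate(contig)
        space = sum(len(f) for f in frames)
        sample = sample_of.get(contig.id, contig.id) if sample_of else contig.id
        for marker in markers:
            best_score = -math.inf
            best_aln = None
            for frame in frames:
                if len(frame) == 0:
                    continue
                score = aligner.score(frame, marker.sequence)
                if score > best_score:
                    best_score = score
                    best_frame = frame
            if best_score < min_align_score:
                continue
            best_aln = next(iter(aligner.align(best_frame, marker.sequence)))
            matches, columns, span = _alignment_stats(best_aln)
            if columns == 0:
                continue
            evalue = _KA_K * len(marker.sequence) * space * math.exp(
                -_KA_LAMBDA * best_score
            )
            hits.append(
                HitRecord(
                    marker_id=marker.marker_id,
                    contig_id=contig.id,
                    sample_id=sample,
                    query_len=len(marker.sequence),
                    aligned_query_span=min(span, len(marker.sequence)),
                    percent_identity=100.0 * matches / columns,
                    e_value=evalue,
                    score=float(best_score),
                )
            )
    return hits


def identity_score(hit: HitRecord) -> float:
    """Query-coverage fraction times percent identity: a 0-100 hit-quality score.

    Full coverage at 96% identity scores 96; 90% coverage at perfect identity
    scores 90 and fails the default >= 95 retention threshold.
    """
    return (hit.aligned_query_span / hit.query_len) * hit.percent_identity


def profile_prevalence(
    hits: Iterable[HitRecord],
    metadata: Sequence[SampleMetadata],
    cluster_of_marker: Mapping[str, str],
    evalue_cutoff: float | None = DEFAULT_EVALUE_CUTOFF,
    score_cutoff: float = DEFAULT_SCORE_CUTOFF,
) -> PresenceTable:
    """Per-sample phage-cluster presence from retained hits, grouped by body site.

    A sample is positive for a cluster iff at least one hit from any of that
    cluster's markers survives both filters: E-value <= ``evalue_cutoff`` (pass
    ``None`` to disable the E-value gate, e.g. with the approximate built-in
    aligner) and identity score >= ``score_cutoff`` (inclusive at exactly 95).
    """
    meta_by_id = {m.sample_id: m for m in metadata}
    clusters = sorted(set(cluster_of_marker.values()))
    data = pd.DataFrame(
        False, index=[m.sample_id for m in metadata], columns=clusters
    )
    for hit in hits:
        if hit.sample_id not in meta_by_id:
            raise ValueError(f"hit references unknown sample {hit.sample_id!r}")
        if evalue_cutoff is not None and hit.e_value > evalue_cutoff:
            continue
        if identity_score(hit) < score_cutoff:
            continue
        cluster = cluster_of_marker.get(hit.marker_id)
        if cluster is None:
            raise ValueError(f"no cluster mapping for marker {hit.marker_id!r}")
        data.loc[hit.sample_id, cluster] = True
    groups = pd.Series(
        {m.sample_id: m.body_site for m in metadata}, name="group"
    ).loc[data.index]
    return PresenceTable(data=data, groups=groups)


def prevalence_by_site(table: PresenceTable) -> pd.DataFrame:
    """Fraction of positive samples per (body site, cluster)."""
    rows = []
    for site in table.groups.unique():
        in_site = table.groups == site
        n = int(in_site.sum())
        for cluster in table.clusters:
            k = int(table.data.loc[in_site, cluster].sum())
            rows.append(
                {"body_site": site, "cluster": cluster, "n": n, "prevalence": k / n}
            )
    return pd.DataFrame(rows)


def supercluster_presence(
    table: PresenceTable, supercluster_of: Mapping[str, str]
) -> PresenceTable:
    """Collapse cluster presence to superclusters by union over member clusters."""
    supers = sorted(set(supercluster_of.values()))
    data = pd.DataFrame(False, index=table.data.index, columns=supers)
    for cluster in table.clusters:
        sc = supercluster_of.get(cluster)
        if sc is None:
            raise ValueError(f"no supercluster mapping for cluster {cluster!r}")
        data[sc] |= table.data[cluster]
    return PresenceTable(data=data, groups=table.groups)


def species_presence(
    abundance: pd.DataFrame, threshold_percent: float = 0.1
) -> pd.DataFrame:
    """Species-presence calls from a relative-abundance table (percent scale).

    Present iff abundance is strictly greater than ``threshold_percent``
    (default 0.1%): an abundance of exactly 0.1% is absent.
    """
    return abundance > threshold_percent


def read_hits_table(
    path: str | Path,
    query_lengths: Mapping[str, int] | None = None,
    sample_of: Mapping[str, str] | None = None,
) -> list[HitRecord]:
    """Ingest a standard 12-column tabular hit file (plus optional 13th qlen column).

    Columns: query, subject, %identity, alignment length, mismatches, gap opens,
    qstart, qend, sstart, send, evalue, bitscore[, qlen].  Query lengths come from
    the 13th column or from ``query_lengths``.
    """
    names = [
        "query", "subject", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 13:
        df.columns = names + ["qlen"]
    elif df.shape[1] == 12:
        df.columns = names
        if query_lengths is None:
            raise ValueError("12-column hit table requires query_lengths")
        df["qlen"] = df["query"].map(query_lengths)
        if df["qlen"].isna().any():
            missing = sorted(df.loc[df["qlen"].isna(), "query"].unique())
            raise ValueError(f"missing query lengths for {missing}")
    else:
        raise ValueError(f"{path}: expected 12 or 13 columns, got {df.shape[1]}")
    hits = []
    for row in df.itertuples(index=False):
        contig = str(row.subject)
        hits.append(
            HitRecord(
                marker_id=str(row.query),
                contig_id=contig,
                sample_id=sample_of.get(contig, contig) if sample_of else contig,
                query_len=int(row.qlen),
                aligned_query_span=int(abs(row.qend - row.qstart) + 1),
                percent_identity=float(row.pident),
                e_value=float(row.evalue),
                score=float(row.bitscore),
            )
        )
    return hits
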