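"""Whole-genome comparison and clustering of phage genomes.

Three complementary distance views, mirroring how phage classification schemes are
usually built:

* MinHash sketches (default k=21, sketch size 1000) with the Mash distance
  ``d = -(1/k) * ln(2j / (1+j))`` on the merged-bottom-sketch Jaccard estimate ``j``.
* A simplified fragment-based average nucleotide identity (ANI): genomes cut into
  1020-nt fragments, fragments paired by seed-anchored best-diagonal ungapped
  alignment, reciprocal best pairs above 35% identity and 35% coverage averaged.
* An exact-word dotplot matrix (default word length 10) for visual inspection.

Genomes are then grouped by single-linkage connected components at two Mash
thresholds: clusters (genus-like, default <= 0.09) nested in superclusters
(subfamily-like, default <= 0.25).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import pearsonr

from ._sequtil import encode, window_valid
from .records import GenomeRecord

__all__ = [
    "Sketch",
    "DistanceResult",
    "ClusterAssignment",
    "minhash_sketch",
    "mash_distance",
    "pairwise_mash",
    "distance_frame",
    "fragment_ani",
    "dotplot_matrix",
    "cluster_genomes",
    "mash_ani_correlation",
]

DEFAULT_K = 21
DEFAULT_SKETCH_SIZE = 1000
#: Seed XORed into every k-mer code before hashing; fixed so sketches are
#: comparable across runs and machines.
HASH_SEED = np.uint64(0x9E2A_77CB_5A5B_F3D1)

DEFAULT_CLUSTER_THRESHOLD = 0.09
DEFAULT_SUPERCLUSTER_THRESHOLD = 0.25

DEFAULT_FRAGMENT_LEN = 1020
_ANI_SEED_LEN = 12
_ANI_MIN_IDENTITY = 0.35
_ANI_MIN_COVERAGE = 0.35


@dataclass(frozen=True)
class Sketch:
    """Bottom-s MinHash sketch over canonical k-mers."""

    record_id: str
    k: int
    s: int
    hashes: np.ndarray  # sorted, strictly increasing uint64, |hashes| <= s


@dataclass(frozen=True)
class DistanceResult:
    """One genome pair: Jaccard estimate, Mash distance, optional fragment ANI."""

    pair: tuple[str, str]
    jaccard_est: float
    mash_distance: float
    ani: float | None = None


@dataclass(frozen=True)
class ClusterAssignment:
    record_id: str
    cluster_label: int
    supercluster_label: int


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorized splitmix64 finalizer: a fixed, well-mixed 64-bit hash."""
    x = x.astype(np.uint64)
    with np.errstate(over="ignore"):
        x = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
        x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        x = x ^ (x >> np.uint64(31))
    return x


def _kmer_codes(codes: np.ndarray, valid: np.ndarray, k: int) -> np.ndarray:
    """2-bit integer codes of all valid (ACGT-only) k-mer windows."""
    n = codes.size
    if n < k:
        return np.zeros(0, dtype=np.uint64)
    vals = np.zeros(n - k + 1, dtype=np.uint64)
    for j in range(k):
        vals = (vals << np.uint64(2)) | codes[j : n - k + 1 + j].astype(np.uint64)
    return vals[window_valid(valid, k)]


def canonical_kmer_codes(sequence: str, k: int) -> np.ndarray:
    """Distinct canonical k-mer codes (min of forward and reverse-complement code)."""
    codes, valid = encode(sequence)
    fwd = _kmer_codes(codes, valid, k)
    rc_codes = (3 - codes)[::-1].astype(np.uint8)
    rev = _kmer_codes(rc_codes, valid[::-1], k)[::-1]
    if fwd.size != rev.size:  # pragma: no cover - same validity pattern both ways
        raise AssertionError("forward/reverse k-mer count mismatch")
    return np.unique(np.minimum(fwd, rev))


def minhash_sketch(
    record: GenomeRecord, k: int = DEFAULT_K, s: int = DEFAULT_SKETCH_SIZE
) -> Sketch:
    """Bottom-s sketch of the genome's canonical k-mers.

    K-mers containing non-ACGT characters are skipped.  Requires k <= 31 so the
    2-bit code fits a 64-bit word; a sequence shorter than k is an error.
    """
    if not 1 <= k <= 31:
        raise ValueError("k must be in 1..31")
    if s < 1:
        raise ValueError("sketch size must be >= 1")
    if len(record.sequence) < k:
        raise ValueError(
            f"sequence {record.id!r} shorter than k={k}"
        )
    kmers = canonical_kmer_codes(record.sequence, k)
    hashes = np.sort(np.unique(_splitmix64(kmers ^ HASH_SEED)))[:s]
    return Sketch(record_id=record.id, k=k, s=s, hashes=hashes)


def mash_distance(a: Sketch, b: Sketch) -> DistanceResult:
    """Mash distance from two sketches via the merged bottom-sketch Jaccard estimator.

    The smallest ``s`` hashes of the union are taken; ``j`` is the fraction of
    those present in both sketches.  ``d = -(1/k) * ln(2j/(1+j))``, with ``j = 0``
    reported as ``d = 1.0`` and d capped at 1.
    """
    if a.k != b.k:
        raise ValueError(f"k mismatch: {a.k} vs {b.k}")
    s = min(a.s, b.s)
    union = np.union1d(a.hashes, b.hashes)[:s]
    shared = np.intersect1d(a.hashes, b.hashes, assume_unique=True)
    n_shared = int(np.isin(union, shared, assume_unique=True).sum())
    j = n_shared / union.size if union.size else 0.0
    if j <= 0.0:
        d = 1.0
    elif j >= 1.0:
        j, d = 1.0, 0.0
    else:
        d = min(1.0, -np.log(2.0 * j / (1.0 + j)) / a.k)
    return DistanceResult(pair=(a.record_id, b.record_id), jaccard_est=j, mash_distance=d)


def pairwise_mash(
    records: Sequence[GenomeRecord], k: int = DEFAULT_K, s: int = DEFAULT_SKETCH_SIZE
) -> list[DistanceResult]:
    sketches = [minhash_sketch(r, k, s) for r in records]
    out = []
    for i in range(len(sketches)):
        for j in range(i + 1, len(sketches)):
            out.append(mash_distance(sketches[i], sketches[j]))
    return out


def distance_frame(results: Sequence[DistanceResult]) -> pd.DataFrame:
    """Square symmetric Mash distance matrix (zero diagonal) from pair results."""
    ids = sorted({rid for r in results for rid in r.pair})
    df = pd.DataFrame(np.full((len(ids), len(ids)), np.nan), index=ids, columns=ids)
    np.fill_diagonal(df.values, 0.0)
    for r in results:
        a, b = r.pair
        df.loc[a, b] = r.mash_distance
        df.loc[b, a] = r.mash_distance
    return df


def _fragment_seeds(frag: np.ndarray, seed_len: int) -> dict[int, list[int]]:
    vals = np.zeros(frag.size - seed_len + 1, dtype=np.int64)
    for j in range(seed_len):
        vals = (vals << 2) | frag[j : frag.size - seed_len + 1 + j].astype(np.int64)
    index: dict[int, list[int]] = {}
    for pos, v in enumerate(vals):
        index.setdefault(int(v), []).append(pos)
    return index


def _best_fragment_match(
    qfrag: np.ndarray, tfrags: list[np.ndarray], tindex: list[dict[int, list[int]]],
    seed_len: int,
) -> tuple[int, float, float] | None:
    """Best (target_fragment, identity, coverage) by seed-anchored ungapped diagonals."""
    qindex = _fragment_seeds(qfrag, seed_len)
    best: tuple[int, float, float] | None = None
    best_score = 0.0
    for ti, tidx in enumerate(tindex):
        diagonals: set[int] = set()
        for kmer, qpositions in qindex.items():
            tpositions = tidx.get(kmer)
            if not tpositions:
                continue
            for qp in qpositions:
                for tp in tpositions:
                    diagonals.add(tp - qp)
        tfrag = tfrags[ti]
        for diag in diagonals:
            qs, ts = (0, diag) if diag >= 0 else (-diag, 0)
            ov = min(qfrag.size - qs, tfrag.size - ts)
            if ov < seed_len:
                continue
            ident = float(np.mean(qfrag[qs : qs + ov] == tfrag[ts : ts + ov]))
            cov = ov / qfrag.size
            score = ident * ov
            if score > best_score:
                best_score = score
                best = (ti, ident, cov)
    return best


def _cut_fragments(seq: str, fragment_len: int) -> list[np.ndarray]:
    codes, valid = encode(seq)
    codes = np.where(valid, codes, 4).astype(np.int8)  # 4 never matches a seed/base
    return [
        codes[i : i + fragment_len]
        for i in range(0, codes.size - fragment_len + 1, fragment_len)
    ]


def fragment_ani(
    a: GenomeRecord,
    b: GenomeRecord,
    fragment_len: int = DEFAULT_FRAGMENT_LEN,
    min_identity: float = _ANI_MIN_IDENTITY,
    min_coverage: float = _ANI_MIN_COVERAGE,
) -> float | None:
    """Simplified fragment-based average nucleotide identity.

    ``a`` is cut into consecutive ``fragment_len``-nt fragments (default 1020) and
    so is ``b``; each fragment is matched to the other genome's fragments by the
    best seed-anchored ungapped diagonal, reciprocal best fragment pairs are kept
    if they reach ``min_identity`` and ``min_coverage``, and ANI is the mean
    identity over those pairs.  Returns ``None`` (undefined) when no pair
    qualifies — e.g. for unrelated genomes whose fragments share no seed word.
    """
    if len(a.sequence) < fragment_len or len(b.sequence) < fragment_len:
        raise ValueError(f"both sequences must be >= fragment_len={fragment_len}")
    frags_a = _cut_fragments(a.sequence, fragment_len)
    frags_b = _cut_fragments(b.sequence, fragment_len)
    idx_a = [_fragment_seeds(f, _ANI_SEED_LEN) for f in frags_a]
    idx_b = [_fragment_seeds(f, _ANI_SEED_LEN) for f in frags_b]

    best_ab = [
        _best_fragment_match(f, frags_b, idx_b, _ANI_SEED_LEN) for f in frags_a
    ]
    best_ba = [
        _best_fragment_match(f, frags_a, idx_a, _ANI_SEED_LEN) for f in frags_b
    ]
    identities = []
    for ia, hit in enumerate(best_ab):
        if hit is None:
            continue
        ib, ident_ab, cov_ab = hit
        rec = best_ba[ib]
        if rec is None or rec[0] != ia:
            continue
        _, ident_ba, cov_ba = rec
        ident = 0.5 * (ident_ab + ident_ba)
        cov = min(cov_ab, cov_ba)
        if ident >= min_identity and cov >= min_coverage:
            identities.append(ident)
    if not identities:
        return None
    return float(np.mean(identities))


def dotplot_matrix(
    x: GenomeRecord, y: GenomeRecord, word_len: int = 10
) -> np.ndarray:
    """All 0-based (x_pos, y_pos) coordinates of exact forward-strand word matches.

    The raw material of a similarity dotplot: a dot wherever ``word_len``
    consecutive residues match between the two sequences.
    """
    if len(x.sequence) < word_len or len(y.sequence) < word_len:
        return np.zeros((0, 2), dtype=np.int64)
    xc, xv = encode(x.sequence)
    yc, yv = encode(y.sequence)

    def words(codes: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        vals = np.zeros(codes.size - word_len + 1, dtype=np.int64)
        for j in range(word_len):
            vals = (vals << 2) | codes[j : codes.size - word_len + 1 + j].astype(np.int64)
        ok = window_valid(valid, word_len)
        pos = np.nonzero(ok)[0]
        return vals[ok], pos

    xw, xpos = words(xc, xv)
    yw, ypos = words(yc, yv)
    yindex: dict[int, list[int]] = {}
    for p, v in zip(ypos, yw):
        yindex.setdefault(int(v), []).append(int(p))
    coords = [
        (int(xp), yp) for xp, v in zip(xpos, xw) for yp in yindex.get(int(v), ())
    ]
    if not coords:
        return np.zeros((0, 2), dtype=np.int64)
    return np.array(sorted(coords), dtype=np.int64)


def _components(df: pd.DataFrame, threshold: float) -> np.ndarray:
    adj = csr_matrix((df.to_numpy() <= threshold).astype(np.int8))
    _, labels = connected_components(adj, directed=False)
    return labels


def cluster_genomes(
    distances: pd.DataFrame,
    cluster_threshold: float = DEFAULT_CLUSTER_THRESHOLD,
    supercluster_threshold: float = DEFAULT_SUPERCLUSTER_THRESHOLD,
) -> list[ClusterAssignment]:
    """Single-linkage connected-component clustering at two nested Mash thresholds.

    ``distances`` is a complete square symmetric matrix (rows/columns are record
    ids).  Components at ``<= cluster_threshold`` are clusters; components at
    ``<= supercluster_threshold`` are superclusters; clusters nest inside
    superclusters because the cluster graph is a subgraph of the supercluster
    graph.  Integer labels are assigned in order of each component's smallest
    member id.
    """
    if cluster_threshold > supercluster_threshold:
        raise ValueError("cluster_threshold must be <= supercluster_threshold")
    if not distances.index.equals(distances.columns):
        raise ValueError("distance matrix must be square with matching labels")
    if distances.isna().any().any():
        raise ValueError("distance matrix has missing entries")
    df = distances.sort_index().sort_index(axis=1)
    ids = list(df.index)

    def relabel(raw: np.ndarray) -> dict[str, int]:
        first_member: dict[int, str] = {}
        for rid, lab in zip(ids, raw):
            first_member.setdefault(int(lab), rid)
        order = sorted(first_member, key=lambda lab: first_member[lab])
        remap = {lab: i for i, lab in enumerate(order)}
        return {rid: remap[int(lab)] for rid, lab in zip(ids, raw)}

    clu = relabel(_components(df, cluster_threshold))
    sup = relabel(_components(df, supercluster_threshold))
    return [
        ClusterAssignment(record_id=rid, cluster_label=clu[rid], supercluster_label=sup[rid])
        for rid in ids
    ]


def mash_ani_correlation(results: Sequence[DistanceResult]) -> float:
    """Pearson correlation between Mash distance and (1 - ANI) over defined pairs."""
    pairs = [(r.mash_distance, 1.0 - r.ani) for r in results if r.ani is not None]
    if len(pairs) < 3:
        raise ValueError("need >= 3 results with defined ANI")
    x, y = np.array(pairs).T
    if np.allclose(x.var(), 0) or np.allclose(y.var(), 0):
        raise ValueError("zero variance; correlation undefined")
    return float(pearsonr(x, y).statistic)
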