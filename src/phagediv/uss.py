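"""Uptake-signal-sequence (USS) and GC-content profiling of phage and bacterial genomes.

Naturally competent Pasteurellaceae preferentially take up DNA carrying short uptake
signal sequences, which come in two main dialects: the *H. influenzae*-like Hin-USS
(core ``AAGTGCGGT``) and the *Actinobacillus pleuropneumoniae*-like Apl-USS (core
``ACAAGCGGT``).  Because USSs accumulate slowly, their genomic density is a proxy for
how long a phage has co-evolved with a Pasteurellaceae host: phages lysogenizing these
species carry >= ~100 USS copies per Mb while unrelated phages carry essentially none.

This module counts USS cores in both orientations (exact and with a single-nucleotide
mismatch), normalizes to copies per 1 Mb of unambiguous (A/C/G/T) sequence, measures
GC%, and applies the per-Mb cutoff classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._sequtil import encode, reverse_complement, window_mismatches, window_valid
from .records import GenomeRecord

__all__ = [
    "MotifSpec",
    "USSProfile",
    "HIN_USS",
    "APL_USS",
    "DEFAULT_CUTOFF_PER_MB",
    "count_motif",
    "profile",
    "profile_many",
    "classify_lysogenizer",
    "profiles_to_frame",
]

DEFAULT_CUTOFF_PER_MB = 100.0


@dataclass(frozen=True)
class MotifSpec:
    """A short motif counted in both orientations.

    The core must not be its own reverse complement: both-orientation counting
    sums forward and reverse-complement occurrences and a palindromic core would
    count every site twice.
    """

    name: str
    core: str
    max_mismatch: int = 1

    def __post_init__(self) -> None:
        core = self.core.upper()
        object.__setattr__(self, "core", core)
        if len(core) < 4:
            raise ValueError(f"{self.name}: core must be >= 4 nt")
        if set(core) - set("ACGT"):
            raise ValueError(f"{self.name}: core must contain only A,C,G,T")
        if core == reverse_complement(core):
            raise ValueError(f"{self.name}: core is its own reverse complement")
        if self.max_mismatch not in (0, 1):
            raise ValueError("max_mismatch must be 0 or 1")


HIN_USS = MotifSpec(name="Hin-USS", core="AAGTGCGGT")
APL_USS = MotifSpec(name="Apl-USS", core="ACAAGCGGT")


@dataclass(frozen=True)
class USSProfile:
    """Per-genome USS frequencies (per Mb of A/C/G/T sequence) and GC%."""

    record_id: str
    length_acgt: int
    gc_percent: float
    hin_per_mb: float
    apl_per_mb: float
    hin_per_mb_1mm: float
    apl_per_mb_1mm: float


def count_motif(sequence: str, motif: MotifSpec) -> tuple[int, int]:
    """Count motif occurrences in both orientations, overlaps allowed.

    Returns ``(exact_count, one_mismatch_count)``.  The one-mismatch count uses
    Hamming distance <= 1 and therefore includes the exact matches.  Windows
    containing any non-ACGT character are excluded from both counts.  A motif
    longer than the sequence yields ``(0, 0)``.
    """
    codes, valid = encode(sequence.upper())
    w = len(motif.core)
    if codes.size < w:
        return 0, 0
    ok = window_valid(valid, w)
    exact = 0
    one_mm = 0
    for core in (motif.core, reverse_complement(motif.core)):
        pat, _ = encode(core)
        mism = window_mismatches(codes, pat)
        exact += int(np.count_nonzero(ok & (mism == 0)))
        one_mm += int(np.count_nonzero(ok & (mism <= 1)))
    return exact, one_mm


def profile(
    record: GenomeRecord,
    motifs: tuple[MotifSpec, MotifSpec] = (HIN_USS, APL_USS),
) -> USSProfile:
    """Profile one genome: GC% and per-Mb USS frequencies, exact and 1-mismatch.

    The denominator for both GC% and the per-Mb frequencies is the number of
    unambiguous A/C/G/T bases, so N-padding cannot deflate densities.  A sequence
    with zero A/C/G/T bases is an error.
    """
    codes, valid = encode(record.sequence)
    length_acgt = int(np.count_nonzero(valid))
    if length_acgt == 0:
        raise ValueError(f"record {record.id!r}: no A/C/G/T bases to profile")
    gc = int(np.count_nonzero(valid & ((codes == 1) | (codes == 2))))
    gc_percent = 100.0 * gc / length_acgt

    hin, apl = motifs
    hin_exact, hin_1mm = count_motif(record.sequence, hin)
    apl_exact, apl_1mm = count_motif(record.sequence, apl)
    scale = 1e6 / length_acgt
    return USSProfile(
        record_id=record.id,
        length_acgt=length_acgt,
        gc_percent=gc_percent,
        hin_per_mb=hin_exact * scale,
        apl_per_mb=apl_exact * scale,
        hin_per_mb_1mm=hin_1mm * scale,
        apl_per_mb_1mm=apl_1mm * scale,
    )


def profile_many(
    records: Iterable[GenomeRecord],
    motifs: tuple[MotifSpec, MotifSpec] = (HIN_USS, APL_USS),
) -> list[USSProfile]:
    return [profile(r, motifs) for r in records]


def classify_lysogenizer(p: USSProfile, cutoff_per_mb: float = DEFAULT_CUTOFF_PER_MB) -> bool:
    """True iff either USS dialect reaches the per-Mb cutoff (inclusive, default 100).

    Phages above the cutoff are called Pasteurellaceae-lysogenizing.
    """
    if cutoff_per_mb < 0:
        raise ValueError("cutoff must be non-negative")
    return p.hin_per_mb >= cutoff_per_mb or p.apl_per_mb >= cutoff_per_mb


def profiles_to_frame(
    profiles: Sequence[USSProfile], cutoff_per_mb: float = DEFAULT_CUTOFF_PER_MB
) -> pd.DataFrame:
    """Tabulate profiles with the cutoff classification as the last column."""
    df = pd.DataFrame(
        {
            "record_id": [p.record_id for p in profiles],
            "length_acgt": [p.length_acgt for p in profiles],
            "gc_percent": [p.gc_percent for p in profiles],
            "hin_per_mb": [p.hin_per_mb for p in profiles],
            "apl_per_mb": [p.apl_per_mb for p in profiles],
            "hin_per_mb_1mm": [p.hin_per_mb_1mm for p in profiles],
            "apl_per_mb_1mm": [p.apl_per_mb_1mm for p in profiles],
        }
    )
    df["classified"] = [int(classify_lysogenizer(p, cutoff_per_mb)) for p in profiles]
    return df
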