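"""Shared sequence/metadata data model, FASTA and tabular I/O, and the prophage inclusion filter.

Prophage predictions (completeness score, ORF count) are inputs produced by an external
predictor; this module decides which of them enter the analysis: putatively intact
(score strictly above 90), encoding at least 40 ORFs, and not duplicated within the
dataset.  Duplicate screening — done by hand in typical studies — is automated here as
"near-identical sequence (distance <= 0.001) in a host of the same species".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

__all__ = [
    "GenomeRecord",
    "ProphageAnnotation",
    "SampleMetadata",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "write_annotations",
    "filter_prophages",
    "deduplicate",
    "FastaFormatError",
]

#: IUPAC nucleotide one-letter codes (uppercase).
IUPAC_NUCLEOTIDES = frozenset("ACGTUNRYSWKMBDHV")

DEFAULT_MIN_SCORE = 90
DEFAULT_MIN_ORFS = 40
DEFAULT_DUP_DISTANCE = 0.001


class FastaFormatError(ValueError):
    """Malformed FASTA input (bad header or non-IUPAC character)."""


@dataclass
class GenomeRecord:
    """A nucleotide sequence with optional host/niche metadata.

    The unit flowing through every pipeline stage: bacterial genomes, prophage
    regions, phage assemblies and metagenome contigs are all GenomeRecords.
    """

    id: str
    sequence: str
    species: str = ""
    clade: str = ""
    niche: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - IUPAC_NUCLEOTIDES
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProphageAnnotation:
    """One predicted prophage region: completeness score, ORF count, host link."""

    prophage_id: str
    host_genome_id: str
    completeness_score: int
    orf_count: int
    sequence: str = ""
    host_species: str = ""
    is_duplicate: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.completeness_score <= 150:
            raise ValueError(
                f"{self.prophage_id}: completeness_score {self.completeness_score} "
                "outside 0-150"
            )
        if self.orf_count < 0:
            raise ValueError(f"{self.prophage_id}: orf_count must be >= 0")


@dataclass(frozen=True)
class SampleMetadata:
    """Metagenome sample label: body site and optional subject group."""

    sample_id: str
    body_site: str
    subject_group: str = ""


_HEADER_RE = re.compile(r">(\S+)")


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    Sequences are uppercased, record order is preserved and the identifier is the
    first whitespace-delimited token of the header.  A malformed header or a
    non-IUPAC character raises :class:`FastaFormatError` naming the line.
    """
    records: list[GenomeRecord] = []
    current_id: str | None = None
    chunks: list[str] = []
    seen: set[str] = set()

    def _flush(line_no: int) -> None:
        if current_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaFormatError(f"{path}: record {current_id!r} has no sequence")
        records.append(GenomeRecord(id=current_id, sequence=seq))

    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                m = _HEADER_RE.match(line)
                if not m:
                    raise FastaFormatError(f"{path}:{line_no}: empty FASTA header")
                _flush(line_no)
                current_id = m.group(1)
                if current_id in seen:
                    raise FastaFormatError(
                        f"{path}:{line_no}: duplicate record id {current_id!r}"
                    )
                seen.add(current_id)
                chunks = []
            else:
                if current_id is None:
                    raise FastaFormatError(
                        f"{path}:{line_no}: sequence data before first header"
                    )
                up = line.upper()
                bad = set(up) - IUPAC_NUCLEOTIDES
                if bad:
                    raise FastaFormatError(
                        f"{path}:{line_no}: non-IUPAC characters {sorted(bad)!r}"
                    )
                chunks.append(up)
    _flush(-1)
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    """Write records as wrapped FASTA (default 70 columns)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


_ANNOT_COLUMNS = ["prophage_id", "host_genome_id", "completeness_score", "orf_count"]


def read_annotations(path: str | Path) -> list[ProphageAnnotation]:
    """Read a prophage annotation table (TSV with header row).

    Required columns: prophage_id, host_genome_id, completeness_score, orf_count.
    Optional: sequence, host_species.
    """
    df = pd.read_csv(path, sep="\t", dtype={"prophage_id": str, "host_genome_id": str})
    missing = [c for c in _ANNOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ProphageAnnotation(
                prophage_id=str(row.prophage_id),
                host_genome_id=str(row.host_genome_id),
                completeness_score=int(row.completeness_score),
                orf_count=int(row.orf_count),
                sequence=str(getattr(row, "sequence", "") or ""),
                host_species=str(getattr(row, "host_species", "") or ""),
            )
        )
    return out


def write_annotations(annotations: Iterable[ProphageAnnotation], path: str | Path) -> None:
    rows = [
        {
            "prophage_id": a.prophage_id,
            "host_genome_id": a.host_genome_id,
            "completeness_score": a.completeness_score,
            "orf_count": a.orf_count,
            "host_species": a.host_species,
            "is_duplicate": int(a.is_duplicate),
        }
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def filter_prophages(
    annotations: Sequence[ProphageAnnotation],
    min_score: int = DEFAULT_MIN_SCORE,
    min_orfs: int = DEFAULT_MIN_ORFS,
) -> list[ProphageAnnotation]:
    """Keep putatively intact, sufficiently gene-rich, non-duplicated prophages.

    Retains annotations with completeness_score strictly greater than ``min_score``
    (score 90 itself is excluded), orf_count >= ``min_orfs`` (40 kept), and the
    duplicate flag unset.  Idempotent; may return an empty list.
    """
    if not annotations:
        raise ValueError("annotations collection is empty")
    if min_score < 0 or min_orfs < 0:
        raise ValueError("thresholds must be non-negative")
    return [
        a
        for a in annotations
        if a.completeness_score > min_score
        and a.orf_count >= min_orfs
        and not a.is_duplicate
    ]


def deduplicate(
    annotations: Sequence[ProphageAnnotation],
    distance_fn: Callable[[str, str], float],
    max_distance: float = DEFAULT_DUP_DISTANCE,
) -> list[ProphageAnnotation]:
    """Flag near-identical prophages found in hosts of the same species.

    Within every connected group of records at pairwise sequence distance
    <= ``max_distance`` AND identical host species, all but the first record in
    id sort order are flagged ``is_duplicate``.  The first member of each group
    always survives, so a group is never emptied.  Returns new annotation objects;
    the input is not mutated.
    """
    items = sorted(annotations, key=lambda a: a.prophage_id)
    n = len(items)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if items[i].host_species != items[j].host_species:
                continue
            d = distance_fn(items[i].sequence, items[j].sequence)
            if d < 0:
                raise ValueError("distance_fn returned a negative distance")
            if d <= max_distance:
                parent[find(i)] = find(j)

    first_of_group: dict[int, int] = {}
    for i in range(n):  # items sorted by id, so first index seen is group keeper
        root = find(i)
        first_of_group.setdefault(root, i)

    out = []
    for i, a in enumerate(items):
        dup = first_of_group[find(i)] != i
        out.append(replace(a, is_duplicate=dup))
    return out
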