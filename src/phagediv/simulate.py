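"""Seeded generators emulating the statistical structure of the study inputs.

Real analyses of this kind start from downloaded bacterial genomes, prophage
predictions and metagenome assemblies.  This module generates stand-ins with known
ground truth: i.i.d. background genomes with a controlled GC fraction and USS motifs
planted at a chosen density, phage families diverged from a common ancestor at a
chosen substitution rate (with the closed-form expected pairwise identity recorded),
lysogeny presence/absence tables with clade-specific carriage probabilities, and
fragmented metagenome contigs sampled from phage genomes in proportion to abundance.

All generators are pure functions of their spec — the seed is part of the spec and
reruns are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._sequtil import decode, encode
from .records import GenomeRecord
from .stats import PresenceTable
from .uss import APL_USS, HIN_USS, MotifSpec

__all__ = [
    "GenomeSpec",
    "FamilySpec",
    "LysogenyDesign",
    "generate_genome",
    "generate_family",
    "generate_family_from_ancestor",
    "expected_identity",
    "generate_lysogeny_table",
    "generate_metagenome",
    "random_protein",
    "mutate_protein",
    "reverse_translate",
    "plant_gene",
]

_PLACEMENT_RETRIES = 10_000


@dataclass(frozen=True)
class GenomeSpec:
    """Background genome parameters: length, GC target and planted USS densities.

    Densities are in planted copies per Mb; the realized planted count is
    ``round(density * length / 1e6)``, exact by construction.  Planted copies
    overwrite background bases (no insertion) so the length stays exact, and are
    placed at non-overlapping positions, each independently in forward or
    reverse-complement orientation with probability 1/2.
    """

    length: int
    gc_target: float
    hin_density: float = 0.0
    apl_density: float = 0.0
    seed: int = 0
    name: str = "genome"
    hin_motif: MotifSpec = field(default=HIN_USS)
    apl_motif: MotifSpec = field(default=APL_USS)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not 0.0 <= self.gc_target <= 1.0:
            raise ValueError("gc_target must be in [0, 1]")
        if self.hin_density < 0 or self.apl_density < 0:
            raise ValueError("densities must be non-negative")

    def planted_counts(self) -> tuple[int, int]:
        n_hin = int(np.rint(self.hin_density * self.length / 1e6))
        n_apl = int(np.rint(self.apl_density * self.length / 1e6))
        return n_hin, n_apl


@dataclass(frozen=True)
class FamilySpec:
    """A phage family: one ancestor and members diverged by i.i.d. substitutions.

    Substitutions follow a Jukes–Cantor-like model: each site mutates with
    probability ``substitution_rate`` to one of the three alternative bases chosen
    uniformly.  Two members then share expected per-site identity
    ``(1-r)^2 + r^2/3``.
    """

    ancestor: GenomeSpec
    n_members: int
    substitution_rate: float
    seed: int = 0
    name: str = "fam"

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if not 0.0 <= self.substitution_rate < 0.5:
            raise ValueError("substitution_rate must be in [0, 0.5)")


@dataclass(frozen=True)
class LysogenyDesign:
    """Clade x phage-cluster carriage probabilities and per-clade genome counts."""

    clade_names: Sequence[str]
    cluster_names: Sequence[str]
    prevalence_matrix: Sequence[Sequence[float]]
    n_per_clade: Sequence[int]
    seed: int = 0

    def __post_init__(self) -> None:
        mat = np.asarray(self.prevalence_matrix, dtype=float)
        if mat.shape != (len(self.clade_names), len(self.cluster_names)):
            raise ValueError("prevalence_matrix shape must be (n_clades, n_clusters)")
        if (mat < 0).any() or (mat > 1).any():
            raise ValueError("prevalence probabilities must be in [0, 1]")
        if len(self.n_per_clade) != len(self.clade_names):
            raise ValueError("n_per_clade must match clade_names")
        if any(n < 1 for n in self.n_per_clade):
            raise ValueError("n_per_clade entries must be >= 1")


def _plant(
    codes: np.ndarray,
    motif: MotifSpec,
    count: int,
    rng: np.random.Generator,
    occupied: np.ndarray,
    density_label: str,
) -> None:
    from ._sequtil import reverse_complement

    m = len(motif.core)
    length = codes.size
    if count == 0:
        return
    if m * count > length or m > length:
        raise ValueError(
            f"cannot plant {count} copies ({density_label}) of a {m}-nt motif "
            f"in a {length}-nt genome"
        )
    fwd, _ = encode(motif.core)
    rev, _ = encode(reverse_complement(motif.core))
    placed = 0
    attempts = 0
    while placed < count:
        if attempts >= _PLACEMENT_RETRIES:
            raise ValueError(
                f"non-overlapping placement failed for {density_label} "
                f"after {_PLACEMENT_RETRIES} attempts"
            )
        start = int(rng.integers(0, length - m + 1))
        attempts += 1
        if occupied[start : start + m].any():
            continue
        pat = rev if rng.random() < 0.5 else fwd
        codes[start : start + m] = pat
        occupied[start : start + m] = True
        placed += 1


def generate_genome(spec: GenomeSpec) -> GenomeRecord:
    """Generate an i.i.d. background genome with planted USS motifs.

    Base probabilities are P(G)=P(C)=gc_target/2, P(A)=P(T)=(1-gc_target)/2.
    Background chance hits of the 9-mers (expected ~length/4^9 per strand and
    orientation) are left in place: a real profiler sees them too.
    """
    rng = np.random.default_rng(spec.seed)
    p_gc = spec.gc_target / 2.0
    p_at = (1.0 - spec.gc_target) / 2.0
    codes = rng.choice(4, size=spec.length, p=[p_at, p_gc, p_gc, p_at]).astype(np.uint8)
    occupied = np.zeros(spec.length, dtype=bool)
    n_hin, n_apl = spec.planted_counts()
    _plant(codes, spec.hin_motif, n_hin, rng, occupied, f"hin_density={spec.hin_density}")
    _plant(codes, spec.apl_motif, n_apl, rng, occupied, f"apl_density={spec.apl_density}")
    return GenomeRecord(id=spec.name, sequence=decode(codes))


def expected_identity(r: float) -> float:
    """Expected per-site identity between two members mutated independently at rate r."""
    return (1.0 - r) ** 2 + r**2 / 3.0


def generate_family_from_ancestor(
    ancestor: GenomeRecord,
    n_members: int,
    substitution_rate: float,
    seed: int,
    name: str = "fam",
) -> tuple[list[GenomeRecord], pd.DataFrame]:
    """Derive family members from a given ancestor by i.i.d. substitutions.

    Same model as :func:`generate_family` but starting from an explicit ancestor
    record (useful when the ancestor carries planted genes).
    """
    rng = np.random.default_rng(seed)
    anc_codes, _ = encode(ancestor.sequence)
    r = substitution_rate
    members: list[GenomeRecord] = []
    for i in range(n_members):
        codes = anc_codes.copy()
        mutate = rng.random(codes.size) < r
        # uniform choice among the 3 alternative bases via a 1..3 offset mod 4
        offsets = rng.integers(1, 4, size=int(mutate.sum()), dtype=np.uint8)
        codes[mutate] = (codes[mutate] + offsets) % 4
        members.append(GenomeRecord(id=f"{name}_{i:03d}", sequence=decode(codes)))
    exp_id = expected_identity(r)
    rows = [
        {"a": members[i].id, "b": members[j].id, "expected_identity": exp_id}
        for i in range(n_members)
        for j in range(i + 1, n_members)
    ]
    truth = pd.DataFrame(rows, columns=["a", "b", "expected_identity"])
    return members, truth


def generate_family(spec: FamilySpec) -> tuple[list[GenomeRecord], pd.DataFrame]:
    """Generate family members plus a truth table of expected pairwise identity.

    Returns ``(members, truth)`` where truth has one row per unordered member
    pair with the closed-form expected identity ``(1-r)^2 + r^2/3``.
    """
    ancestor = generate_genome(spec.ancestor)
    members, truth = generate_family_from_ancestor(
        ancestor, spec.n_members, spec.substitution_rate, spec.seed, spec.name
    )
    return members, truth


def generate_lysogeny_table(design: LysogenyDesign) -> PresenceTable:
    """Draw per-genome phage-cluster carriage from the design's Bernoulli matrix."""
    rng = np.random.default_rng(design.seed)
    mat = np.asarray(design.prevalence_matrix, dtype=float)
    ids: list[str] = []
    groups: list[str] = []
    rows: list[np.ndarray] = []
    for ci, clade in enumerate(design.clade_names):
        n = design.n_per_clade[ci]
        draws = rng.random((n, len(design.cluster_names))) < mat[ci]
        for gi in range(n):
            ids.append(f"{clade}_g{gi:03d}")
            groups.append(clade)
            rows.append(draws[gi])
    data = pd.DataFrame(np.array(rows, dtype=bool), index=ids, columns=list(design.cluster_names))
    return PresenceTable(data=data, groups=pd.Series(groups, index=ids, name="group"))


def generate_metagenome(
    phages: Sequence[GenomeRecord],
    marker_positions: Mapping[str, tuple[int, int]],
    abundance: Sequence[float],
    n_contigs: int,
    contig_len_range: tuple[int, int],
    seed: int,
) -> tuple[list[GenomeRecord], pd.DataFrame]:
    """Sample contigs from phage genomes proportionally to abundance.

    ``marker_positions`` maps phage id -> half-open (start, end) interval of its
    diagnostic marker gene.  Truth labels record the source phage, the sampled
    window and whether the window overlaps the source's marker interval by at
    least half the marker length.
    """
    if len(abundance) != len(phages):
        raise ValueError("abundance must have one entry per phage")
    ab = np.asarray(abundance, dtype=float)
    if (ab < 0).any() or ab.sum() <= 0:
        raise ValueError("abundances must be non-negative and sum > 0")
    lo, hi = contig_len_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid contig length range")
    for ph in phages:
        if lo > len(ph.sequence):
            raise ValueError(
                f"contig length {lo} exceeds genome length of {ph.id} ({len(ph.sequence)})"
            )
    rng = np.random.default_rng(seed)
    probs = ab / ab.sum()
    src_idx = rng.choice(len(phages), size=n_contigs, p=probs)
    contigs: list[GenomeRecord] = []
    truth_rows = []
    for i, si in enumerate(src_idx):
        ph = phages[si]
        glen = len(ph.sequence)
        clen = int(rng.integers(lo, min(hi, glen) + 1))
        start = int(rng.integers(0, glen - clen + 1))
        cid = f"contig_{i:05d}"
        contigs.append(GenomeRecord(id=cid, sequence=ph.sequence[start : start + clen]))
        marker_hit = False
        if ph.id in marker_positions:
            ms, me = marker_positions[ph.id]
            overlap = max(0, min(start + clen, me) - max(start, ms))
            marker_hit = overlap >= 0.5 * (me - ms)
        truth_rows.append(
            {
                "contig_id": cid,
                "source_phage": ph.id,
                "start": start,
                "end": start + clen,
                "marker_overlap": marker_hit,
            }
        )
    truth = pd.DataFrame(
        truth_rows, columns=["contig_id", "source_phage", "start", "end", "marker_overlap"]
    )
    return contigs, truth


_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _codon_map() -> dict[str, list[str]]:
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[11].forward_table
    out: dict[str, list[str]] = {}
    for codon, aa in table.items():
        out.setdefault(aa, []).append(codon)
    return {aa: sorted(codons) for aa, codons in out.items()}


def random_protein(length: int, seed: int) -> str:
    """Uniform random protein over the 20 standard amino acids."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(_AMINO_ACIDS), size=length))


def mutate_protein(protein: str, rate: float, seed: int) -> str:
    """Substitute residues i.i.d. at ``rate``, each to a different random residue."""
    rng = np.random.default_rng(seed)
    out = []
    for aa in protein:
        if rng.random() < rate:
            choices = _AMINO_ACIDS.replace(aa, "")
            out.append(choices[int(rng.integers(len(choices)))])
        else:
            out.append(aa)
    return "".join(out)


def reverse_translate(protein: str, seed: int) -> str:
    """Encode a protein as DNA, choosing synonymous codons uniformly at random."""
    rng = np.random.default_rng(seed)
    cmap = _codon_map()
    return "".join(cmap[aa][int(rng.integers(len(cmap[aa])))] for aa in protein)


def plant_gene(record: GenomeRecord, gene: str, start: int) -> GenomeRecord:
    """Overwrite a genome region with a gene sequence (length preserved)."""
    if start < 0 or start + len(gene) > len(record.sequence):
        raise ValueError(
            f"gene of length {len(gene)} does not fit at {start} in {record.id}"
        )
    seq = record.sequence[:start] + gene.upper() + record.sequence[start + len(gene):]
    return GenomeRecord(
        id=record.id, sequence=seq, species=record.species,
        clade=record.clade, niche=record.niche,
    )
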