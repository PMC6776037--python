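"""Synthetic evaluation benchmarks with known ground truth.

Each function builds a seeded synthetic dataset at the package's standard study
conditions, runs the relevant analysis end to end, and returns the measured
quantities.  These are the desk-scale analogues of the headline analyses on real
data: the USS cutoff classifier separating Pasteurellaceae-lysogenizing phages from
the rest, MinHash calibration against exact Jaccard, the Mash-vs-(1-ANI)
correlation, Fisher-test calibration, rarefaction against its closed form, the
marker identity-score screen, and host recovery in the coevolution ordination.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .distance import (
    DistanceResult,
    fragment_ani,
    mash_distance,
    minhash_sketch,
)
from .markers import MarkerProtein, profile_prevalence, search_markers
from .ordination import bray_curtis, build_features, nmds
from .records import GenomeRecord, SampleMetadata
from .simulate import (
    FamilySpec,
    GenomeSpec,
    generate_family,
    generate_genome,
    generate_metagenome,
    mutate_protein,
    plant_gene,
    random_protein,
    reverse_translate,
)
from .stats import PresenceTable, fisher_exact_2x2
from .uss import HIN_USS, classify_lysogenizer, profile

__all__ = [
    "expected_background_per_mb",
    "planted_density_recovery",
    "classifier_benchmark",
    "minhash_calibration",
    "mash_ani_experiment",
    "fisher_type1_error",
    "rarefaction_benchmark",
    "marker_screen_benchmark",
    "coevolution_benchmark",
]


def expected_background_per_mb(motif_len: int, gc: float, length: int) -> float:
    """Expected chance occurrences of a USS core per Mb in an i.i.d. background.

    Both orientations; assumes the canonical cores' composition (the reverse
    complement has the same base composition because complementation swaps A/T
    and G/C).  For the 9-mers used here: 4 A/T-class and 5 G/C-class positions.
    """
    p_at = (1.0 - gc) / 2.0
    p_gc = gc / 2.0
    p_window = (p_at**4) * (p_gc**5)
    windows = max(length - motif_len + 1, 0)
    return 2.0 * p_window * windows * 1e6 / length


def planted_density_recovery(
    seed: int, densities: tuple[float, ...] = (0.0, 50.0, 100.0, 400.0, 750.0),
    length: int = 1_000_000, gc: float = 0.40,
) -> pd.DataFrame:
    """Profile 1-Mb genomes with planted Hin-USS at each density.

    Returns per density: planted density, expected frequency (planted plus the
    analytic background expectation), observed exact frequency, and the deviation
    in units of sqrt(expected) (Poisson scale).
    """
    rows = []
    for i, dens in enumerate(densities):
        g = generate_genome(
            GenomeSpec(length=length, gc_target=gc, hin_density=dens,
                       seed=seed + i, name=f"planted_{int(dens)}")
        )
        p = profile(g)
        expected = dens + expected_background_per_mb(len(HIN_USS.core), gc, length)
        dev_sigma = abs(p.hin_per_mb - expected) / np.sqrt(expected)
        rows.append(
            {"planted_per_mb": dens, "expected_per_mb": expected,
             "observed_per_mb": p.hin_per_mb, "abs_dev_sigma": dev_sigma}
        )
    return pd.DataFrame(rows)


def classifier_benchmark(
    seed: int, n_lysogenizing: int = 200, n_other: int = 2000,
    genome_len: int = 40_000, planted_density: float = 400.0,
    cutoff: float = 100.0, gc: float = 0.40,
) -> dict[str, float]:
    """Sensitivity/specificity of the USS cutoff classifier on synthetic genomes.

    Positives carry the planted Hin-USS density; negatives carry none (background
    chance hits only).  Mirrors the clean separation of Pasteurellaceae
    lysogenizers from other tailed phages at the 100/Mb cutoff.
    """
    rng = np.random.default_rng(seed)
    tp = fn = tn = fp = 0
    for i in range(n_lysogenizing):
        g = generate_genome(
            GenomeSpec(length=genome_len, gc_target=gc, hin_density=planted_density,
                       seed=int(rng.integers(2**31)), name=f"lys_{i}")
        )
        if classify_lysogenizer(profile(g), cutoff):
            tp += 1
        else:
            fn += 1
    for i in range(n_other):
        g = generate_genome(
            GenomeSpec(length=genome_len, gc_target=gc, hin_density=0.0,
                       seed=int(rng.integers(2**31)), name=f"oth_{i}")
        )
        if classify_lysogenizer(profile(g), cutoff):
            fp += 1
        else:
            tn += 1
    return {
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "n_positive": n_lysogenizing,
        "n_negative": n_other,
    }


def _exact_jaccard_strings(seq_a: str, seq_b: str, k: int) -> float:
    """Exact Jaccard over canonical k-mer sets, computed with plain string sets.

    Reference route, independent of the packed-integer hashing used by the
    sketches.
    """
    from ._sequtil import reverse_complement

    def kmers(seq: str) -> set[str]:
        out = set()
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if set(km) - set("ACGT"):
                continue
            out.add(min(km, reverse_complement(km)))
        return out

    A, B = kmers(seq_a), kmers(seq_b)
    if not A and not B:
        return 0.0
    return len(A & B) / len(A | B)


def minhash_calibration(
    seed: int, n_pairs: int = 100, genome_len: int = 50_000,
    k: int = 21, s: int = 1000,
) -> dict[str, float]:
    """Sketch-estimated vs exact Jaccard on family pairs, plus rate monotonicity.

    Returns the fraction of pairs whose sketch estimate falls within
    ``3*sqrt(j(1-j)/s)`` of the exact canonical-k-mer Jaccard, and the Spearman
    correlation of Mash distance with the substitution rate over a 0-0.12 grid.
    """
    rng = np.random.default_rng(seed)
    rates = np.linspace(0.0, 0.12, n_pairs)
    within = 0
    checked = 0
    for i, r in enumerate(rates):
        fam, _ = generate_family(
            FamilySpec(
                ancestor=GenomeSpec(length=genome_len, gc_target=0.42,
                                    seed=int(rng.integers(2**31))),
                n_members=2, substitution_rate=float(r),
                seed=int(rng.integers(2**31)), name=f"cal{i}",
            )
        )
        j_exact = _exact_jaccard_strings(fam[0].sequence, fam[1].sequence, k)
        est = mash_distance(minhash_sketch(fam[0], k, s), minhash_sketch(fam[1], k, s))
        tol = 3.0 * np.sqrt(max(j_exact * (1.0 - j_exact), 1e-12) / s)
        checked += 1
        if abs(est.jaccard_est - j_exact) <= tol:
            within += 1

    grid = np.arange(0.0, 0.121, 0.01)
    dists = []
    for i, r in enumerate(grid):
        fam, _ = generate_family(
            FamilySpec(
                ancestor=GenomeSpec(length=genome_len, gc_target=0.42,
                                    seed=int(rng.integers(2**31))),
                n_members=2, substitution_rate=float(r),
                seed=int(rng.integers(2**31)), name=f"grid{i}",
            )
        )
        est = mash_distance(minhash_sketch(fam[0], k, s), minhash_sketch(fam[1], k, s))
        dists.append(est.mash_distance)
    rho = float(spearmanr(grid, dists).statistic)
    return {
        "fraction_within_3sigma": within / checked,
        "rate_spearman": rho,
        "n_pairs": checked,
    }


def mash_ani_experiment(
    seed: int, n_pairs: int = 30, genome_len: int = 20_000
) -> dict[str, float]:
    """Pearson correlation of Mash distance with (1 - fragment ANI) on family pairs.

    Pairs span substitution rates 0-12%; the real-data analogue reported a strong
    positive correlation between the two distance measures.
    """
    rng = np.random.default_rng(seed)
    rates = np.linspace(0.0, 0.12, n_pairs)
    results: list[DistanceResult] = []
    for i, r in enumerate(rates):
        fam, _ = generate_family(
            FamilySpec(
                ancestor=GenomeSpec(length=genome_len, gc_target=0.42,
                                    seed=int(rng.integers(2**31))),
                n_members=2, substitution_rate=float(r),
                seed=int(rng.integers(2**31)), name=f"ma{i}",
            )
        )
        est = mash_distance(minhash_sketch(fam[0]), minhash_sketch(fam[1]))
        ani = fragment_ani(fam[0], fam[1])
        results.append(
            DistanceResult(pair=est.pair, jaccard_est=est.jaccard_est,
                           mash_distance=est.mash_distance, ani=ani)
        )
    defined = [r for r in results if r.ani is not None]
    x = np.array([r.mash_distance for r in defined])
    y = np.array([1.0 - r.ani for r in defined])
    return {
        "pearson_r": float(pearsonr(x, y).statistic),
        "n_defined": len(defined),
        "n_pairs": n_pairs,
    }


def fisher_type1_error(
    seed: int, n_tables: int = 2000, n_per_group: int = 50,
    prevalence: float = 0.3, alpha: float = 0.05,
) -> dict[str, float]:
    """Type-I error of the two-sided Fisher test on null (equal-prevalence) tables."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_tables):
        a = int(rng.binomial(n_per_group, prevalence))
        c = int(rng.binomial(n_per_group, prevalence))
        p = fisher_exact_2x2([[a, n_per_group - a], [c, n_per_group - c]])
        if p < alpha:
            rejections += 1
    return {"type1_error": rejections / n_tables, "n_tables": n_tables}


def rarefaction_benchmark(
    seed: int, n_genomes: int = 50, n_clusters: int = 20,
    carriage: float = 0.3, replicates: int = 1000,
) -> dict[str, float]:
    """Replicate-mean rarefaction curve vs the hypergeometric closed form.

    Returns the maximum relative deviation of the replicate mean from
    ``E[S_n] = sum_i [1 - C(G-g_i, n)/C(G, n)]`` and whether every replicate
    curve is non-decreasing.
    """
    from .stats import expected_richness, rarefy

    rng = np.random.default_rng(seed)
    data = pd.DataFrame(
        rng.random((n_genomes, n_clusters)) < carriage,
        index=[f"g{i:03d}" for i in range(n_genomes)],
        columns=[f"c{j:02d}" for j in range(n_clusters)],
    )
    table = PresenceTable(
        data=data, groups=pd.Series(["all"] * n_genomes, index=data.index)
    )
    curve = rarefy(table, replicates=replicates, seed=seed + 1)
    expected = expected_richness(table)
    rel = np.abs(curve.mean_richness - expected) / expected
    monotone = bool(np.all(np.diff(curve.replicate_curves, axis=1) >= 0))
    return {
        "max_relative_error": float(rel.max()),
        "all_replicates_monotone": monotone,
        "n_replicates": replicates,
    }


def marker_screen_benchmark(
    seed: int, aa_divergence: float, n_clusters: int = 2,
    variants_per_cluster: int = 12, genome_len: int = 6000,
    marker_len: int = 150, n_samples: int = 10, contigs_per_sample: int = 60,
    contig_len_range: tuple[int, int] = (2000, 3000),
    score_cutoff: float = 95.0,
) -> dict[str, float]:
    """Marker screen against a synthetic metagenome with planted marker genes.

    Each phage cluster has one marker protein; every phage variant carries a gene
    encoding that marker independently mutated at ``aa_divergence`` (a
    quasispecies).  Truth: a sample is positive for a cluster iff any of its
    contigs from that cluster overlaps the marker gene by at least half its
    length.  Detection: hits filtered on identity score >= ``score_cutoff``
    (E-value gate disabled — the built-in aligner's E-values are approximate).
    Returns sample-level sensitivity, false-positive count and whether the
    detected presence table equals the truth table exactly.
    """
    rng = np.random.default_rng(seed)
    gene_start = 3 * ((genome_len // 2) // 3)
    gene_len = 3 * marker_len
    markers: list[MarkerProtein] = []
    phages: list[GenomeRecord] = []
    cluster_of_phage: dict[str, str] = {}
    marker_positions: dict[str, tuple[int, int]] = {}
    for c in range(n_clusters):
        cname = f"cluster{c}"
        prot = random_protein(marker_len, seed=int(rng.integers(2**31)))
        markers.append(MarkerProtein(f"marker{c}", cname, prot))
        base = generate_genome(
            GenomeSpec(length=genome_len, gc_target=0.42,
                       seed=int(rng.integers(2**31)), name=f"{cname}_base")
        )
        for v in range(variants_per_cluster):
            carried = mutate_protein(prot, aa_divergence, seed=int(rng.integers(2**31)))
            gene = reverse_translate(carried, seed=int(rng.integers(2**31)))
            variant = plant_gene(base, gene, gene_start)
            variant = GenomeRecord(id=f"{cname}_v{v:02d}", sequence=variant.sequence)
            phages.append(variant)
            cluster_of_phage[variant.id] = cname
            marker_positions[variant.id] = (gene_start, gene_start + gene_len)

    sites = ["tongue", "buccal_mucosa"]
    metadata = [
        SampleMetadata(sample_id=f"S{i:02d}", body_site=sites[i % len(sites)])
        for i in range(n_samples)
    ]
    cluster_names = sorted({c for c in cluster_of_phage.values()})
    truth = pd.DataFrame(
        False, index=[m.sample_id for m in metadata], columns=cluster_names
    )
    all_contigs: list[GenomeRecord] = []
    sample_of: dict[str, str] = {}
    abundance = [1.0] * len(phages)
    for m in metadata:
        contigs, labels = generate_metagenome(
            phages, marker_positions, abundance,
            n_contigs=contigs_per_sample, contig_len_range=contig_len_range,
            seed=int(rng.integers(2**31)),
        )
        for contig, row in zip(contigs, labels.itertuples(index=False)):
            renamed = GenomeRecord(id=f"{m.sample_id}_{contig.id}", sequence=contig.sequence)
            all_contigs.append(renamed)
            sample_of[renamed.id] = m.sample_id
            if row.marker_overlap:
                truth.loc[m.sample_id, cluster_of_phage[row.source_phage]] = True

    hits = search_markers(markers, all_contigs, sample_of=sample_of)
    detected = profile_prevalence(
        hits, metadata, {mk.marker_id: mk.cluster_label for mk in markers},
        evalue_cutoff=None, score_cutoff=score_cutoff,
    )
    det = detected.data[cluster_names]
    tp = int((det & truth).to_numpy().sum())
    fn = int((~det & truth).to_numpy().sum())
    fp = int((det & ~truth).to_numpy().sum())
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "false_positives": fp,
        "exact_match": bool(det.equals(truth)),
        "n_truth_positive": tp + fn,
    }


_COEVOLUTION_CLADES: Mapping[str, tuple[float, float, float]] = {
    # clade -> (GC fraction, Hin-USS per Mb, Apl-USS per Mb)
    "cladeA": (0.37, 700.0, 0.0),
    "cladeB": (0.40, 350.0, 0.0),
    "cladeC": (0.42, 0.0, 400.0),
    "cladeD": (0.45, 150.0, 0.0),
    "cladeE": (0.47, 0.0, 150.0),
}


def coevolution_benchmark(
    seed: int, phage_clusters_per_clade: int = 3, members_per_cluster: int = 2,
    bacteria_per_clade: int = 2, bacterial_len: int = 40_000,
    phage_len: int = 25_000, noise: float = 0.15, n_restarts: int = 10,
) -> dict[str, float]:
    """Host recovery in the USS/GC coevolution ordination.

    Bacterial clades get distinct (GC, Hin, Apl) profiles; each phage cluster
    inherits its designated host clade's profile perturbed by up to ``noise``
    relative error.  After feature building, Bray-Curtis and nMDS, host recovery
    is the fraction of phage entities whose nearest bacterial entity in the
    ordination is the true host clade.
    """
    rng = np.random.default_rng(seed)
    profiles = []
    grouping: dict[str, str] = {}
    host_of: dict[str, str] = {}
    for clade, (gc, hin, apl) in _COEVOLUTION_CLADES.items():
        for b in range(bacteria_per_clade):
            g = generate_genome(
                GenomeSpec(length=bacterial_len, gc_target=gc, hin_density=hin,
                           apl_density=apl, seed=int(rng.integers(2**31)),
                           name=f"{clade}_g{b}")
            )
            profiles.append(profile(g))
            grouping[g.id] = clade
        for c in range(phage_clusters_per_clade):
            cname = f"phage_{clade}_{c}"
            host_of[cname] = clade
            jitter = rng.uniform(1.0 - noise, 1.0 + noise, size=3)
            pgc = float(np.clip(gc + rng.uniform(-0.01, 0.01), 0.0, 1.0))
            for m in range(members_per_cluster):
                g = generate_genome(
                    GenomeSpec(length=phage_len, gc_target=pgc,
                               hin_density=hin * jitter[1], apl_density=apl * jitter[2],
                               seed=int(rng.integers(2**31)), name=f"{cname}_m{m}")
                )
                profiles.append(profile(g))
                grouping[g.id] = cname

    features = build_features(profiles, grouping)
    diss = bray_curtis(features)
    result = nmds(diss, n_restarts=n_restarts, seed=int(rng.integers(2**31)))
    coords = result.coordinates
    bacterial = [e for e in features.entities if e.startswith("clade")]
    phage_entities = [e for e in features.entities if e.startswith("phage_")]
    correct = 0
    for pe in phage_entities:
        d = ((coords.loc[bacterial] - coords.loc[pe]) ** 2).sum(axis=1)
        if str(d.idxmin()) == host_of[pe]:
            correct += 1
    return {
        "host_recovery": correct / len(phage_entities),
        "stress": result.stress,
        "n_phage_entities": len(phage_entities),
    }
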