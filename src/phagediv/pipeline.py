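"""Configuration-driven end-to-end pipeline with a reproducibility manifest.

Stages run in dependency order: simulate -> filter -> cluster -> profile-uss ->
screen -> stats -> ordinate.  Every stage reads and writes plain files inside the
run directory, so any stage can be rerun in isolation; the manifest records the
config hash, seeds, package version and per-stage row counts (the input -> output
funnel).  Reruns with the same config are byte-identical for deterministic stages
— which is all of them, since every random draw is seeded from the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .distance import (
    cluster_genomes,
    distance_frame,
    mash_distance,
    minhash_sketch,
    pairwise_mash,
)
from .markers import MarkerProtein, prevalence_by_site, profile_prevalence, search_markers
from .ordination import bray_curtis, build_features, fit_vectors, nmds
from .records import (
    GenomeRecord,
    ProphageAnnotation,
    SampleMetadata,
    deduplicate,
    filter_prophages,
    read_annotations,
    read_fasta,
    write_annotations,
    write_fasta,
)
from .simulate import (
    GenomeSpec,
    LysogenyDesign,
    generate_family_from_ancestor,
    generate_genome,
    generate_lysogeny_table,
    generate_metagenome,
    mutate_protein,
    plant_gene,
    random_protein,
    reverse_translate,
)
from .stats import PresenceTable, group_association_tests, prevalence_summary, rarefy
from .uss import profile_many, profiles_to_frame

__all__ = ["PipelineConfig", "run", "load_config", "default_config_path"]

log = logging.getLogger("phagediv.pipeline")

_STAGES = ["simulate", "filter", "cluster", "profile_uss", "screen", "stats", "ordinate"]

_SCHEMA: dict[str, Any] = {
    "seed": int,
    "stages": {s: bool for s in _STAGES},
    "thresholds": {
        "min_score": int,
        "min_orfs": int,
        "k": int,
        "sketch_size": int,
        "word_len": int,
        "evalue": (float, type(None)),
        "identity_score": (int, float),
        "uss_cutoff": (int, float),
        "presence_percent": (int, float),
        "cluster_threshold": (int, float),
        "supercluster_threshold": (int, float),
        "dup_distance": (int, float),
    },
    "simulate": {
        "clades": [
            {"name": str, "n_genomes": int, "length": int, "gc": (int, float),
             "hin_density": (int, float), "apl_density": (int, float)}
        ],
        "families": [
            {"name": str, "host_clade": str, "n_members": int,
             "substitution_rate": (int, float), "length": int, "gc": (int, float),
             "hin_density": (int, float), "apl_density": (int, float)}
        ],
        "annotations": {"score_range": [int], "orf_range": [int]},
        "lysogeny": {"n_per_clade": int, "prevalence": dict},
        "metagenome": {
            "samples": dict, "contigs_per_sample": int, "contig_len": [int],
            "marker_len_aa": int, "marker_divergence_aa": (int, float),
            "abundance": dict,
        },
    },
    "ordination": {"restarts": int, "max_iter": int, "dims": int},
}


class PipelineConfig(dict):
    """Validated pipeline configuration (a dict with strict schema checking)."""

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        _validate(raw, _SCHEMA, path="")
        return cls(raw)

    def content_hash(self) -> str:
        canon = json.dumps(self, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _validate(value: Any, schema: Any, path: str) -> None:
    where = path or "<root>"
    if isinstance(schema, dict):
        if not isinstance(value, dict):
            raise ValueError(f"{where}: expected a mapping")
        unknown = set(value) - set(schema)
        if unknown:
            raise ValueError(f"{where}: unknown config keys {sorted(unknown)}")
        for key, sub in schema.items():
            if key in value:
                _validate(value[key], sub, f"{path}.{key}".lstrip("."))
    elif isinstance(schema, list):
        if not isinstance(value, list):
            raise ValueError(f"{where}: expected a list")
        for i, item in enumerate(value):
            _validate(item, schema[0], f"{path}[{i}]")
    elif schema is dict:
        if not isinstance(value, dict):
            raise ValueError(f"{where}: expected a mapping")
    else:
        if isinstance(value, bool) and schema is int:
            raise ValueError(f"{where}: expected int, got bool")
        if not isinstance(value, schema):
            raise ValueError(f"{where}: expected {schema}, got {type(value).__name__}")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig.from_mapping(raw)


def default_config_path() -> Path:
    return Path(__file__).parent / "data" / "default_config.yaml"


def _write_tsv(df: pd.DataFrame, path: Path, **kw: Any) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g", **kw)


def _seed_for(config: PipelineConfig, label: str) -> int:
    """Stable per-stage substream seed derived from the config seed."""
    digest = hashlib.sha256(f"{config['seed']}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _stage_simulate(config: PipelineConfig, outdir: Path, counts: dict) -> None:
    sim = config["simulate"]

    # bacterial clade genomes
    bacteria: list[GenomeRecord] = []
    clade_of: dict[str, str] = {}
    for spec in sim["clades"]:
        for gi in range(spec["n_genomes"]):
            g = generate_genome(
                GenomeSpec(
                    length=spec["length"], gc_target=spec["gc"],
                    hin_density=spec["hin_density"], apl_density=spec["apl_density"],
                    seed=_seed_for(config, f"clade:{spec['name']}:{gi}"),
                    name=f"{spec['name']}_g{gi:02d}",
                )
            )
            bacteria.append(g)
            clade_of[g.id] = spec["name"]
    write_fasta(bacteria, outdir / "bacteria.fasta")

    # phage families with one planted marker gene per family
    meta = sim["metagenome"]
    marker_len = meta["marker_len_aa"]
    phages: list[GenomeRecord] = []
    ancestors: list[GenomeRecord] = []
    markers: list[MarkerProtein] = []
    family_of: dict[str, str] = {}
    marker_positions: dict[str, tuple[int, int]] = {}
    annotations: list[ProphageAnnotation] = []
    ann_rng = np.random.default_rng(_seed_for(config, "annotations"))
    score_lo, score_hi = sim["annotations"]["score_range"]
    orf_lo, orf_hi = sim["annotations"]["orf_range"]
    for fam in sim["families"]:
        fseed = _seed_for(config, f"family:{fam['name']}")
        ancestor = generate_genome(
            GenomeSpec(
                length=fam["length"], gc_target=fam["gc"],
                hin_density=fam["hin_density"], apl_density=fam["apl_density"],
                seed=fseed, name=f"{fam['name']}_anc",
            )
        )
        protein = random_protein(marker_len, seed=fseed + 1)
        carried = mutate_protein(
            protein, meta["marker_divergence_aa"], seed=fseed + 4
        )
        gene = reverse_translate(carried, seed=fseed + 2)
        gene_start = 3 * ((fam["length"] // 4) // 3)
        ancestor = plant_gene(ancestor, gene, gene_start)
        ancestors.append(ancestor)
        marker_positions[ancestor.id] = (gene_start, gene_start + 3 * marker_len)
        members, _ = generate_family_from_ancestor(
            ancestor, fam["n_members"], fam["substitution_rate"],
            seed=fseed + 3, name=fam["name"],
        )
        markers.append(
            MarkerProtein(
                marker_id=f"{fam['name']}_marker", cluster_label=fam["name"],
                sequence=protein,
            )
        )
        for m in members:
            phages.append(m)
            family_of[m.id] = fam["name"]
            annotations.append(
                ProphageAnnotation(
                    prophage_id=m.id,
                    host_genome_id=f"host_of_{m.id}",
                    completeness_score=int(ann_rng.integers(score_lo, score_hi + 1)),
                    orf_count=int(ann_rng.integers(orf_lo, orf_hi + 1)),
                    sequence=m.sequence,
                    host_species=fam["host_clade"],
                )
            )
    write_fasta(phages, outdir / "phages.fasta")
    write_annotations(annotations, outdir / "annotations.tsv")
    with open(outdir / "markers.faa", "w", encoding="utf-8") as fh:
        for mk in markers:
            fh.write(f">{mk.marker_id} cluster={mk.cluster_label}\n{mk.sequence}\n")
    pd.DataFrame(
        sorted(family_of.items()), columns=["record_id", "family"]
    ).to_csv(outdir / "phage_families.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(clade_of.items()), columns=["record_id", "clade"]
    ).to_csv(outdir / "bacteria_clades.tsv", sep="\t", index=False)

    # lysogeny presence table
    lys = sim["lysogeny"]
    clade_names = [c["name"] for c in sim["clades"]]
    cluster_names = [f["name"] for f in sim["families"]]
    prev = [[lys["prevalence"][cl][fam] for fam in cluster_names] for cl in clade_names]
    table = generate_lysogeny_table(
        LysogenyDesign(
            clade_names=clade_names, cluster_names=cluster_names,
            prevalence_matrix=prev,
            n_per_clade=[lys["n_per_clade"]] * len(clade_names),
            seed=_seed_for(config, "lysogeny"),
        )
    )
    table.to_tsv(outdir / "lysogeny.tsv")

    # metagenome contigs per sample, sampled from the family ancestors (the
    # "phage population" whose marker carries the configured aa divergence)
    abundance = [meta["abundance"][f["name"]] for f in sim["families"]]
    representatives = ancestors
    all_contigs: list[GenomeRecord] = []
    sample_rows = []
    sample_of: dict[str, str] = {}
    for sample_id, site in sorted(meta["samples"].items()):
        contigs, _truth = generate_metagenome(
            representatives,
            {r.id: marker_positions[r.id] for r in representatives},
            abundance,
            n_contigs=meta["contigs_per_sample"],
            contig_len_range=tuple(meta["contig_len"]),
            seed=_seed_for(config, f"metagenome:{sample_id}"),
        )
        for c in contigs:
            renamed = GenomeRecord(id=f"{sample_id}_{c.id}", sequence=c.sequence)
            all_contigs.append(renamed)
            sample_of[renamed.id] = sample_id
        sample_rows.append({"sample_id": sample_id, "body_site": site})
    write_fasta(all_contigs, outdir / "contigs.fasta")
    pd.DataFrame(sample_rows).to_csv(outdir / "samples.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(sample_of.items()), columns=["contig_id", "sample_id"]
    ).to_csv(outdir / "contig_samples.tsv", sep="\t", index=False)

    counts["simulate"] = {
        "bacteria": len(bacteria), "phages": len(phages),
        "annotations": len(annotations), "markers": len(markers),
        "lysogeny_rows": table.n_entities, "contigs": len(all_contigs),
    }


def _stage_filter(config: PipelineConfig, outdir: Path, counts: dict) -> None:
    th = config["thresholds"]
    annotations = read_annotations(outdir / "annotations.tsv")
    seqs = {r.id: r for r in read_fasta(outdir / "phages.fasta")}
    for a in annotations:
        a.sequence = seqs[a.prophage_id].sequence

    k, s = th["k"], th["sketch_size"]
    sketch_cache: dict[str, Any] = {}

    def mash_fn(x: str, y: str) -> float:
        def sk(seq: str):
            key = hashlib.sha1(seq.encode()).hexdigest()
            if key not in sketch_cache:
                sketch_cache[key] = minhash_sketch(
                    GenomeRecord(id=key, sequence=seq), k=k, s=s
                )
            return sketch_cache[key]

        return mash_distance(sk(x), sk(y)).mash_distance

    deduped = deduplicate(annotations, mash_fn, max_distance=th["dup_distance"])
    kept = filter_prophages(deduped, min_score=th["min_score"], min_orfs=th["min_orfs"])
    write_annotations(deduped, outdir / "annotations_dedup.tsv")
    write_annotations(kept, outdir / "prophages_kept.tsv")
    counts["filter"] = {
        "input": len(annotations),
        "duplicates_flagged": sum(a.is_duplicate for a in deduped),
        "kept": len(kept),
    }
    log.info("filter: %d -> %d prophages", len(annotations), len(kept))


def _stage_cluster(config: PipelineConfig, outdir: Path, counts: dict) -> None:
    th = config["thresholds"]
    kept = read_annotations(outdir / "prophages_kept.tsv")
    kept_ids = {a.prophage_id for a in kept}
    phages = [r for r in read_fasta(outdir / "phages.fasta") if r.id in kept_ids]
    results = pairwise_mash(phages, k=th["k"], s=th["sketch_size"])
    dmat = distance_frame(results)
    _write_tsv(dmat, outdir / "mash_distances.tsv", index_label="record_id")
    assignments = cluster_genomes(
        dmat,
        cluster_threshold=th["cluster_threshold"],
        supercluster_threshold=th["supercluster_threshold"],
    )
    df = pd.DataFrame(
        [
            {"record_id": a.record_id, "cluster": a.cluster_label,
             "supercluster": a.supercluster_label}
            for a in assignments
        ]
    )
    _write_tsv(df, outdir / "clusters.tsv", index=False)
    counts["cluster"] = {
        "genomes": len(phages),
        "clusters": int(df["cluster"].nunique()),
        "superclusters": int(df["supercluster"].nunique()),
    }


def _stage_profile_uss(config: PipelineConfig, outdir: Path, counts: dict) -> None:
    th = config["thresholds"]
    phages = read_fasta(outdir / "phages.fasta")
    bacteria = read_fasta(outdir / "bacteria.fasta")
    profs = profile_many(phages + bacteria)
    df = profiles_to_frame(profs, cutoff_per_mb=th["uss_cutoff"])
    _write_tsv(df, outdir / "uss_profiles.tsv", index=False)
    counts["profile_uss"] = {
        "profiled": len(profs),
        "classified_lysogenizing": int(df["classified"].sum()),
    }


def _stage_screen(config: PipelineConfig, outdir: Path, counts: dict) -> None:
    th = config["thresholds"]
    contigs = read_fasta(outdir / "contigs.fasta")
    markers, cluster_of_marker = _read_markers(outdir / "markers.faa")
    sample_of = dict(
        pd.read_csv(outdir / "contig_samples.tsv", sep="\t").itertuples(index=False)
    )
    meta_df = pd.read_csv(outdir / "samples.tsv", sep="\t")
    metadata = [
        SampleMetadata(sample_id=r.sample_id, body_site=r.body_site)
        for r in meta_df.itertuples(index=False)
    ]
    hits = search_markers(markers, contigs, sample_of=sample_of)
    presence = profile_prevalence(
        hits, metadata, cluster_of_marker,
        evalue_cutoff=th["evalue"], score_cutoff=th["identity_score"],
    )
    presence.to_tsv(outdir / "metagenome_presence.tsv")
    _write_tsv(prevalence_by_site(presence), outdir / "metagenome_prevalence.tsv", index=False)
    counts["screen"] = {
        "contigs": len(contigs), "markers": len(markers), "hits": len(hits),
        "positive_samples": int(presence.data.any(axis=1).sum()),
    }


def _read_markers(path: Path) -> tuple[list[MarkerProtein], dict[str, str]]:
    markers: list[MarkerProtein] = []
    cluster_of: dict[str, str] = {}
    marker_id = None
    cluster = ""
    seq_lines: list[str] = []

    def flush() -> None:
        if marker_id is None:
            return
        mk = MarkerProtein(
            marker_id=marker_id, cluster_label=cluster, sequence="".join(seq_lines)
        )
        markers.append(mk)
        cluster_of[mk.marker_id] = mk.cluster_label

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split()
                marker_id = parts[0]
                cluster = ""
                for p in parts[1:]:
                    if p.startswith("cluster="):
                        cluster = p.split("=", 1)[1]
                seq_lines = []
            else:
                seq_lines.append(line)
    flush()
    return markers, cluster_of


def _stage_stats(config: PipelineConfig, outdir: Path, counts: dict) -> None:
    table = PresenceTable.from_tsv(outdir / "lysogeny.tsv")
    tests = group_association_tests(table)
    df = pd.DataFrame(
        [
            {"comparison": t.comparison_id, "p_value": t.p_value,
             "p_adjusted": t.p_adjusted, "stars": t.stars}
            for t in tests
        ]
    )
    _write_tsv(df, outdir / "fisher_tests.tsv", index=False)
    curve = rarefy(table, replicates=10, seed=_seed_for(config, "rarefy"))
    _write_tsv(curve.to_frame(), outdir / "rarefaction.tsv", index=False)
    _write_tsv(prevalence_summary(table), outdir / "prevalence_summary.tsv", index=False)
    counts["stats"] = {
        "fisher_tests": len(tests),
        "significant_after_bonferroni": int((df["p_adjusted"] < 0.05).sum()),
    }


def _stage_ordinate(config: PipelineConfig, outdir: Path, counts: dict) -> None:
    ordc = config.get("ordination", {})
    profiles_df = pd.read_csv(outdir / "uss_profiles.tsv", sep="\t")
    fam = pd.read_csv(outdir / "phage_families.tsv", sep="\t")
    clades = pd.read_csv(outdir / "bacteria_clades.tsv", sep="\t")
    grouping = dict(fam.itertuples(index=False)) | dict(clades.itertuples(index=False))
    from .uss import USSProfile

    profiles = [
        USSProfile(
            record_id=r.record_id, length_acgt=int(r.length_acgt),
            gc_percent=r.gc_percent, hin_per_mb=r.hin_per_mb, apl_per_mb=r.apl_per_mb,
            hin_per_mb_1mm=r.hin_per_mb_1mm, apl_per_mb_1mm=r.apl_per_mb_1mm,
        )
        for r in profiles_df.itertuples(index=False)
        if r.record_id in grouping
    ]
    features = build_features(profiles, grouping)
    _write_tsv(features.values, outdir / "features.tsv", index_label="entity")
    diss = bray_curtis(features)
    _write_tsv(diss, outdir / "bray_curtis.tsv", index_label="entity")
    result = nmds(
        diss, dims=ordc.get("dims", 2), n_restarts=ordc.get("restarts", 20),
        max_iter=ordc.get("max_iter", 300), seed=_seed_for(config, "nmds"),
    )
    _write_tsv(result.coordinates, outdir / "nmds_coordinates.tsv", index_label="entity")
    vectors = fit_vectors(result, features)
    _write_tsv(vectors, outdir / "nmds_vectors.tsv")
    with open(outdir / "ordination_report.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "stress": round(result.stress, 6),
                "n_restarts": result.n_restarts,
                "n_iterations": int(result.stress_trace.size),
                "degenerate_columns": features.degenerate_columns,
            },
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    counts["ordinate"] = {"entities": len(features.entities),
                          "stress": round(result.stress, 6)}


_STAGE_FN = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "cluster": _stage_cluster,
    "profile_uss": _stage_profile_uss,
    "screen": _stage_screen,
    "stats": _stage_stats,
    "ordinate": _stage_ordinate,
}

_STAGE_INPUTS = {
    "filter": ["annotations.tsv", "phages.fasta"],
    "cluster": ["prophages_kept.tsv", "phages.fasta"],
    "profile_uss": ["phages.fasta", "bacteria.fasta"],
    "screen": ["contigs.fasta", "markers.faa", "samples.tsv", "contig_samples.tsv"],
    "stats": ["lysogeny.tsv"],
    "ordinate": ["uss_profiles.tsv", "phage_families.tsv", "bacteria_clades.tsv"],
}


def run(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute enabled stages in order and write a manifest.

    Raises if a stage's upstream outputs are missing (naming the stage), so a
    partially toggled pipeline fails loudly rather than silently skipping work.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, Any] = {}
    skipped: list[str] = []
    for stage in _STAGES:
        if not config["stages"].get(stage, False):
            skipped.append(stage)
            log.info("stage %s: skipped", stage)
            continue
        for needed in _STAGE_INPUTS.get(stage, []):
            if not (outdir / needed).exists():
                raise FileNotFoundError(
                    f"stage {stage!r}: missing upstream output {needed!r}"
                )
        log.info("stage %s: running", stage)
        _STAGE_FN[stage](config, outdir, counts)
    manifest = {
        "package_version": __version__,
        "config_hash": config.content_hash(),
        "seed": config["seed"],
        "stages_run": [s for s in _STAGES if s not in skipped],
        "stages_skipped": skipped,
        "counts": counts,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir / "manifest.json"
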