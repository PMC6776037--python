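# Default synthetic end-to-end run: three bacterial clades with distinct GC%/USS
# profiles, four phage families co-evolved with them, a clade-structured lysogeny
# table and a small fragmented metagenome.  All thresholds carry the standard
# defaults (prophage score >90, >=40 ORFs, Mash k=21/s=1000, dotplot word 10,
# identity score >=95, USS cutoff 100/Mb, species presence >0.1%).
seed: 7

stages:
  simulate: true
  filter: true
  cluster: true
  profile_uss: true
  screen: true
  stats: true
  ordinate: true

thresholds:
  min_score: 90
  min_orfs: 40
  k: 21
  sketch_size: 1000
  word_len: 10
  evalue: null          # built-in aligner E-values are approximate; gate on score
  identity_score: 95.0
  uss_cutoff: 100.0
  presence_percent: 0.1
  cluster_threshold: 0.09
  supercluster_threshold: 0.25
  dup_distance: 0.001

simulate:
  clades:
    - {name: cladeA, n_genomes: 2, length: 40000, gc: 0.38, hin_density: 600, apl_density: 0}
    - {name: cladeB, n_genomes: 2, length: 40000, gc: 0.42, hin_density: 0, apl_density: 450}
    - {name: cladeC, n_genomes: 2, length: 40000, gc: 0.45, hin_density: 300, apl_density: 0}
  families:
    - {name: famA1, host_clade: cladeA, n_members: 4, substitution_rate: 0.02,
       length: 30000, gc: 0.38, hin_density: 500, apl_density: 0}
    - {name: famA2, host_clade: cladeA, n_members: 4, substitution_rate: 0.04,
       length: 30000, gc: 0.39, hin_density: 400, apl_density: 0}
    - {name: famB1, host_clade: cladeB, n_members: 4, substitution_rate: 0.03,
       length: 30000, gc: 0.42, hin_density: 0, apl_density: 350}
    - {name: famC1, host_clade: cladeC, n_members: 4, substitution_rate: 0.02,
       length: 30000, gc: 0.45, hin_density: 250, apl_density: 0}
  annotations:
    score_range: [60, 150]   # uniform; the >90 filter keeps roughly the top 60%
    orf_range: [20, 80]      # uniform; the >=40 filter keeps roughly the top two thirds
  lysogeny:
    n_per_clade: 25
    prevalence:
      cladeA: {famA1: 0.8, famA2: 0.5, famB1: 0.05, famC1: 0.1}
      cladeB: {famA1: 0.1, famA2: 0.1, famB1: 0.7, famC1: 0.1}
      cladeC: {famA1: 0.1, famA2: 0.1, famB1: 0.05, famC1: 0.6}
  metagenome:
    samples: {S01: tongue, S02: tongue, S03: buccal_mucosa, S04: buccal_mucosa}
    contigs_per_sample: 60
    contig_len: [2000, 3000]
    marker_len_aa: 120
    marker_divergence_aa: 0.0
    abundance: {famA1: 0.4, famA2: 0.3, famB1: 0.2, famC1: 0.1}

ordination:
  restarts: 8
  max_iter: 200
  dims: 2
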