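# Methods

`phagediv` implements a desk-scale, fully seeded version of a comparative-genomics
and metagenomics workflow for temperate phages of naturally competent
*Pasteurellaceae*-type hosts. This note documents the models, the parameters that
matter, the synthetic data the package is validated on, and the numerical choices
made where the design was genuinely open.

## Prophage inclusion filter

Prophage predictions arrive as annotations carrying a completeness score (0–150)
and an ORF count. The filter keeps annotations with score **strictly greater than
90** and ORF count **at least 40** (the ORF bound is inclusive because obviously
truncated prophage elements separate from complete ones around that count), and
drops records flagged as duplicates. Duplicate screening — in practice a manual
judgement about re-sequenced strains and colony variants — is automated as a
reproducible proxy: two prophages are duplicates when their Mash distance is at
most 0.001 *and* their hosts are the same species. Within each such group the
first record in identifier sort order is kept; a group can therefore never be
emptied. Only the distance-and-species rule is automated; subjective criteria
(same patient, colony variants) are out of scope.

## USS/GC profiling and the lysogenizer cutoff

Uptake signal sequences come in two dialects; the canonical 9-mer cores are
`AAGTGCGGT` (Hin) and `ACAAGCGGT` (Apl), taken from the DNA-uptake literature and
overridable in configuration in case of dialect variants. Counting is a pure
substring count in **both orientations** (forward plus reverse complement,
summed), overlaps allowed; the two cores are far from their own reverse
complements so no window is double-counted within one orientation. Windows
containing any non-ACGT character are excluded. The one-mismatch count uses
Hamming distance ≤ 1 and therefore **includes** the exact matches, which
guarantees the superset invariant `count_1mm >= count_exact`; the single-mismatch
profile is reported alongside the exact profile, not instead of it.

Frequencies are normalized per 1 Mb of unambiguous sequence: both the GC%
denominator and the per-Mb denominator count A/C/G/T bases only, so N-padding
cannot deflate densities. A genome is classified as lysogenizing a competent host
when either dialect's exact frequency reaches the cutoff, **inclusive**, default
100 per Mb (the source convention states the cutoff value but not the boundary
rule; inclusive was fixed here and is exercised by the tests).

In an i.i.d. background with GC fraction *g*, each 9-mer core with 4 A/T-class
and 5 G/C-class positions occurs by chance at rate
`2 * ((1-g)/2)^4 * (g/2)^5` per window (both orientations). At g = 0.40 that is
about 5.2 per Mb — far below the 100/Mb cutoff, which is why the classifier
separates cleanly. Planted-density recovery is judged against
`planted + expected background` with a tolerance of three Poisson standard
deviations `3 * sqrt(expected)`; using the combined expectation keeps the bound
well defined at density 0, where the naive `3 * sqrt(planted)` band would be
degenerate.

## Genome distances and clustering

**MinHash/Mash.** Sketches use canonical k-mers (lexicographic minimum of the
k-mer and its reverse complement), k = 21 and sketch size s = 1000 by default;
k-mers containing non-ACGT characters are skipped. The hash is a splitmix64
finalizer applied to the 2-bit-packed k-mer XORed with a fixed documented seed
(`0x9E2A77CB5A5BF3D1`); bit-compatibility with any external tool is explicitly
not a goal — the estimator contract is. The Jaccard estimate uses the merged
bottom-sketch rule (fraction of the s smallest union hashes present in both
sketches) and the distance is `d = -(1/k) * ln(2j/(1+j))`, with `j = 0` reported
as `d = 1.0` and d capped at 1.

**Fragment ANI.** A simplified fragment-based average nucleotide identity:
both genomes are cut into consecutive 1020-nt fragments; a fragment pair is
matched by the best shared-12-mer-anchored ungapped diagonal; reciprocal best
pairs qualifying at ≥ 35% identity and ≥ 35% coverage are averaged. Seed
anchoring is what rejects unrelated sequence: random 1020-nt fragments share a
12-mer with probability ~10⁻³, so unrelated genome pairs come back *undefined*
rather than with a spurious identity (a global edit-distance identity would sit
near 50% for random DNA and never trip the 35% rule). The ungapped model matches
the substitution-only synthetic families; genomes with real indel structure
would need the thresholds revisited.

**Dotplot.** Exact forward-strand word matching at word length 10, returning
0-based match coordinates; reverse-strand matching is available behind a flag
but off by default.

**Clustering.** Real classification schemes combine whole-genome trees,
dotplots and curation; here clusters and superclusters are single-linkage
connected components of the Mash distance graph at two nested thresholds,
default ≤ 0.09 (cluster, genus-like; informed by observed within-cluster Mash
distances of 0–0.082 in real data) and ≤ 0.25 (supercluster). Nesting holds by
construction because the cluster graph is a subgraph of the supercluster graph.
Labels are assigned in order of each component's smallest member id so output is
deterministic. The coarser "main group" level (transposable / P2-like /
lambda-like) is gene-content based and is treated as a metadata label, not
computed.

## Marker screening

Cluster-diagnostic marker proteins are searched against six-frame translations
of metagenome contigs (plain codon translation, stops as `*`, trailing partial
codons dropped). The built-in aligner is a local affine-gap aligner under
BLOSUM62 (open −11, extend −1); for each marker-contig pair only the
best-scoring frame's hit is kept, and pairs below a raw score of 60 produce no
hit (random ~1-kb contigs score below this in ≥ 99% of trials). E-values follow
`K·m·n·exp(−λS)` with the gapped BLOSUM62 constants λ = 0.267, K = 0.041 and are
**approximate**: they are honest order-of-magnitude statements for the built-in
aligner, not calibrated tail probabilities. Externally produced 12/13-column
tabular hit files can be ingested instead and feed the same downstream scoring.

The **identity score** of a hit is the query-coverage fraction times the percent
identity — a 0–100 scale, so the retention threshold of 95 is meaningful (the
alternative reading, a product of two percentages on a 0–10000 scale, is
inconsistent with that threshold). Retention is inclusive at exactly 95. A
sample is positive for a phage cluster when at least one retained hit from any
of the cluster's markers survives both the E-value gate (default 1e-80, the
convention for a real translated search against a multi-gigabase database;
disable it with `None` when using the built-in aligner, whose search space is
orders of magnitude smaller) and the identity-score threshold. Supercluster
presence is the union over member clusters. Species presence from a relative
abundance table is strict: present iff abundance > 0.1%.

## Prevalence and richness statistics

Group-association tests decompose a k-group presence table into per-(cluster,
group) 2×2 tables (carrier vs non-carrier, group vs rest) and apply the
two-sided Fisher exact test with Bonferroni correction; the family size is an
explicit argument (default: all tests in the panel) so alternative conventions
remain testable, and stars are assigned at 0.05/0.01/0.001 on adjusted values.
Per-genome prophage counts are compared by one-way ANOVA with post hoc Tukey
HSD. Prevalence summaries report Wilson score intervals.

Rarefaction is individual-based over genomes, sampling without replacement: for
each n from 1 to G the number of distinct clusters present among n sampled
genomes is recorded; each replicate is one random ordering of the genomes, which
makes every replicate's curve non-decreasing by construction. Defaults are 10
replicates with a mandatory seed, and the 95% CI across replicates uses t
quantiles (the original spreadsheet convention being unspecified, t was chosen;
the same choice applies to other replicate-based CIs). The analytic expectation
`E[S_n] = Σ_i [1 − C(G−g_i, n)/C(G, n)]` is implemented alongside as the
closed-form check.

## Coevolution ordination

Entities are bacterial clades and phage clusters; an entity's profile is the
mean of its members' (GC%, Hin/Mb, Apl/Mb). Features are ΔGC (entity GC% minus
the dataset-minimum entity GC%, so the minimum-GC entity sits at 0), Hin and Apl
frequency, each standardized **per variable** so its maximum is 100. The
per-variable reading of "standardized by maximum" was chosen over a shared
maximum because the ordination fits a separate vector per variable; a column
whose maximum is 0 is left all-zero and flagged rather than divided.

Bray-Curtis dissimilarity `Σ|x−y| / Σ(x+y)` is computed on the feature rows
(all-zero pairs are 0 by convention). The nMDS minimizes Kruskal stress-1,
`sqrt(Σ(d−d̂)² / Σd²)`, alternating isotonic regression of configuration
distances on the dissimilarity rank order (primary tie approach: tied
dissimilarities are sub-ordered by current configuration distance, so ties
impose no constraint) with Guttman-transform majorization steps; disparities are
rescaled to the configuration's sum of squares each iteration to prevent
collapse. Defaults: 20 restarts, 300 iterations, tolerance 1e-7, mandatory
seed. The **first restart starts from the classical-MDS (PCoA) configuration**
and the rest from random Gaussians: pure random starts at small n are prone to
the classic nMDS degeneracy in which points collapse into coincident groups with
near-zero stress, and the metric start avoids it while random restarts still
explore. The per-iteration stress trace is retained and is non-increasing; the
best (lowest-stress) restart is reported. Axis orientation is arbitrary, so
coordinates are centered, rotated to principal axes and sign-fixed (first entity
non-negative on each axis) for reproducibility. Post hoc vectors give, per
variable, the Pearson correlations with the two axes (direction) and the
multiple correlation R of a linear regression on the coordinates (length);
zero-variance variables are flagged undefined.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of their spec, seed included; reruns are
bit-identical.

* **Genomes** are i.i.d. bases at a target GC with USS motifs planted at a
  per-Mb density: exactly `round(density × length/10⁶)` copies, placed
  non-overlapping by rejection sampling (retry cap 10⁴ — collisions are rare at
  the densities used, ≤ 1000/Mb with 9-nt motifs), each independently forward or
  reverse-complement, **overwriting** background bases so the length and hence
  the per-Mb denominator stay exact. Background chance hits of the cores are
  deliberately left in place and quantified rather than suppressed — a real
  profiler sees them too.
* **Phage families** derive members from a common ancestor by i.i.d.
  substitutions at rate r, uniform over the three alternative bases
  (Jukes–Cantor-like — the simplest model with the closed-form expected pairwise
  identity `(1−r)² + r²/3` recorded in the truth table).
* **Lysogeny tables** draw carriage Bernoulli per (clade, cluster) probability.
* **Metagenomes** are uniformly placed substrings of phage genomes sampled
  proportionally to abundance; truth labels mark contigs overlapping a marker
  interval by at least half the marker length. Marker genes are planted as
  reverse-translated proteins (random synonymous codons), optionally mutated at
  a controlled amino-acid divergence per phage variant to emulate a
  quasispecies.

Not emulated: gene content and codon structure, indels, rearrangements,
read-level sequencing error, assembly artifacts, and real phylogenetic
correlation structure. Passing tests therefore demonstrate that the statistics
and their thresholds behave as designed under their stated models — not that the
biological conclusions of any particular real dataset would be reproduced. The
real headline numbers of the motivating analyses (hundreds of prophages across
hundreds of downloaded genomes, cluster counts, a 0.83 Mash-vs-(1−ANI)
correlation, a 0.12 ordination stress) require those datasets and are
qualitative anchors here, mirrored by the synthetic analogues (e.g. the
benchmark's Mash-vs-(1−ANI) correlation is strongly positive, and the classifier
separates planted lysogenizers cleanly at 100/Mb).

## Benchmark problem sizes

The bundled benchmarks run on one CPU in roughly two minutes total: motif-count
oracle on 1000 random 10-kb sequences; density recovery on 1-Mb genomes at
{0, 50, 100, 400, 750}/Mb; classifier separation on 200 planted-density (400/Mb)
vs 2000 background 40-kb genomes; MinHash calibration on 100 50-kb family pairs
plus a 13-point rate grid; Mash-ANI coherence on 30 20-kb family pairs spanning
0–12% divergence; Fisher agreement on all 2×2 tables with margins ≤ 30 (reduced
by the 8-fold table symmetry, which both routes respect; the symmetry itself is
spot-checked) plus 2000 null tables; rarefaction on a 50-genome × 20-cluster
table at 1000 replicates; marker screening on 10 samples × 60 contigs from 6-kb
phage genomes with 150-aa markers (small genomes make full marker containment
overwhelmingly likely, so sample-level truth and detection coincide); and a
5-clade / 15-phage-cluster coevolution ordination. The end-to-end pipeline
fixture (3 clades, 4 families, 75-genome lysogeny table, 240 contigs) runs in
seconds and is compared byte-for-byte across reruns; the stage log is excluded
from that comparison because log lines are timestamped.

## Known limitations

* The fragment-ANI aligner is ungapped; indel-rich divergence would be
  underestimated or flagged undefined.
* Built-in E-values are approximate; real screening pipelines should import
  external tabular hits and keep the 1e-80 gate.
* Single-linkage threshold clustering is a reproducible surrogate for a curated
  multi-evidence classification; thresholds are configurable and should be
  re-examined per dataset.
* nMDS reports the best of finitely many restarts; stress is an upper bound on
  the global optimum.
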