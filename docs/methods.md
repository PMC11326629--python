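# Methods

This note documents the models, conventions and numerical choices behind
`collisim`, in the order data flows through the pipeline.

## The quantity being measured

Given a database of taxonomically labelled marker-gene sequences, the
pipeline asks: at a given identity threshold, how much of the database sits
in clusters that mix species? A *multi-species cluster* (MSC) is a cluster
whose members carry ≥ 2 distinct species labels. At 100% identity an MSC
means byte-identical (or contained) sequences with different species labels
— no classifier operating on that gene can separate them. At 95–99% it
means the species fall within commonly used species-proxy radii (gene
catalogs at 95%, OTU thresholds at 97/99%). Database growth is simulated by
subsampling: the statistics are computed on random subsets over a size
grid, and the growth of the number of sequences in MSCs with subset size is
summarized by a power-law exponent.

## Identity and the full-coverage rule

Two sequences are compared by aligning the shorter (*S*) end-to-end against
the longer (*L*) with free end gaps on *L* (semi-global alignment, so *S*
matches its best infix of *L*). With *d* the unit-cost edit distance of
that alignment,

    identity(S, L) = max(0, (|S| - d) / |S|).

Internal gaps thus count against the score exactly like mismatches, over
the fixed denominator |S|. This is the "shorter sequence must fully align
to the longer" convention with the shorter-length denominator, as in
CD-HIT's `-aS 1.0`-style coverage; identity is 1.0 exactly when *S* is a
substring of *L*. The alignment is computed with the Myers bit-vector
algorithm (edlib, `mode="HW"`), with a distance cap of
`floor(|S|·(1−t))` during clustering so hopeless pairs exit early. A
conservative q-gram screen (never rejecting a pair the alignment would
accept — property-tested) can pre-filter candidates; it only pays off for
long genes and is enabled by default for sequences ≥ 800 residues.
Sequences are opaque residue strings: nucleotide and protein families are
treated identically, and no alphabet validation is performed.

## Greedy clustering

The clusterer reimplements the CD-HIT greedy incremental contract, not its
internal heuristics:

* records are processed in a total order — length descending, ties broken
  by sequence then record id — so the output depends only on the input
  multiset (determinism and input-order invariance are tested);
* each record joins the **first** existing cluster (in creation order)
  whose representative it meets at ≥ threshold under the full-coverage
  rule, else founds a new cluster;
* representatives therefore have maximal length within their cluster, and
  no representative meets the threshold against an earlier representative.

At threshold 1.0 the comparison degenerates to exact containment and is
served by a fast path: representatives strictly longer than the record are
scanned with a substring test (they precede all equal-length ones in
creation order), and an equal-length representative can only be eligible if
identical, which a hash lookup resolves. A brute-force verifier
(`verify_clustering`) recomputes the partition, member-threshold,
representative-length and representative-maximality invariants with full
(uncapped) alignments and is run against the clusterer on random instances
in the test suite.

Exact replication of CD-HIT's outputs (word-size statistics, banding) is
explicitly not promised; the published greedy scheme is the model and the
contract above is what is guaranteed and tested.

## Synthetic databases

The generator emulates the structure the analysis depends on, with exact
bookkeeping (`GroundTruth`):

* **Taxonomy**: `n_genera` genera; species per genus and genomes per
  species given as fixed counts, uniform ranges, or explicit lists (lists
  allow one dominant species, as in deeply sampled pathogen genera —
  `listeria_like()` gives one genus, 34 species, and ~88.5% of genomes in
  the first species).
* **Families**: each `FamilySpec` has a mean length, length spread, and a
  per-genome copy number — a 16S-like family uses 1–9 copies per genome,
  protein-coding-like families are single-copy (≈ 40 such genes exist per
  real genome; each family here is generated independently).
* **Evolution**: per genus and family one random ancestral gene; species
  genes derive from it by independent per-site substitution at
  `inter_species_divergence` (expected substitutions/site; a hit site moves
  to one of the 3 other bases — a single-hit Jukes–Cantor-like model);
  genome copies derive from the species gene at
  `intra_species_divergence`. No indels: the analysis is identity-threshold
  based, and substitution-only evolution keeps expectations computable
  (two species' genes agree per site with probability (1−δ)² + δ²/3, which
  the tests verify by Monte-Carlo re-simulation).
* **Collisions**: with probability `collision_rate` per (species, family),
  the species' gene is replaced *verbatim* by a previously generated
  congener's gene before genome copies are drawn. Verbatim (rather than
  near-copy) planting makes the expected MSCs at 100% identity exactly
  enumerable from the ground truth — the basis of the recovery tests.
* **Defects**: `artifact_rate` corrupts a record's length to 15–40% or
  220–300% of the family mean (outside the length filter's band);
  `incomplete_rate` truncates the emitted lineage below the species rank.
  Both are recorded per record id.

One `numpy` PCG64 stream drives a `generate` call, consumed in a fixed
documented order (genera → families → species → genomes), so identical
config and seed give byte-identical FASTA output.

Defaults were chosen for testability and plausibility, not fitted to any
real database: inter-species divergence 0.10 (congeners clearly below the
95% radius for 300–1,500 nt genes), intra-species divergence 0.005, and a
collision rate of 0.05 (0.3 for the deeply-sampled-genus preset, which
yields a handful of colliding species pairs among 34 species). The real
divergence distributions of public references are unknown here; see
Limitations.

What the generator does **not** emulate: indel evolution, chimeras,
codon/GC structure, phylogenetically correlated divergence, sequencing
error, or mislabelled records. Passing tests therefore demonstrate the
correctness of the machinery on databases with known collision structure,
not the empirical collision rates of SILVA or GTDB.

## Subsampling

Subsets are drawn uniformly **without replacement over record instances**
(not unique sequences — the sources are non-deduplicated, so duplicates can
co-occur in a subset). A subset is reproducible from
`(master seed, family, size, replicate)` alone: the child seed is the first
8 bytes of the SHA-256 of that tuple reduced mod 2³¹, which is
platform-stable and makes subsets order-independent and parallelizable.
Sizes exceeding the family's record count are skipped with a warning.
Independent draws per size are the default; `nested=True` makes each
replicate's subsets prefixes of one permutation (monotone growth curves
with lower variance, at the cost of dependence across sizes) and is
documented as a deviation from independent subsets.

## Filters

* **Taxonomy**: removes records whose lineage is incomplete (all seven
  ranks required for SILVA-style lineages; genus+species for GTDB-style
  headers, which carry no higher ranks) or contains an organelle keyword
  (mitochondria/mitochondrion/chloroplast/plastid, case-insensitive, any
  rank). Keyword matching was chosen over curated accession lists to stay
  reproducible without external resources. Placeholder species labels
  ("uncultured …") are removable via an option, off by default, since how
  incompleteness was operationalized in practice is ambiguous.
* **Length**: per family, records below half or above twice the family's
  arithmetic mean length are removed. The mean is computed once on the
  pre-filter set; the filter does not iterate. A single pass is
  deterministic and sufficient when artifacts are far outside the band
  (tested with planted artifacts at ≥ 4× from the mean); re-applying the
  filter after extreme outliers are gone removes nothing further.

Filter conventions: species identity is the full species-rank string (the
binomial), never the epithet alone; genus is the genus rank (derived from
the binomial's first word for GTDB-style headers).

## Statistics

* `n_sequences_in_msc` counts **every** member of a multi-species cluster,
  including same-species duplicates — the non-deduplicated convention; this
  inflates counts relative to a unique-sequence convention and is the
  quantity the growth model fits.
* Percentages of species in MSCs use the species universe of the clustered
  subset, not of the full source database, matching per-size growth
  curves.
* Species-pair counts increment once per multi-species cluster per
  unordered pair (not per sequence pair), a scale-invariant convention.
* The genus-richness relation is computed on one designated clustering —
  by convention the largest database size — as the Pearson correlation
  between a genus' species richness in the subset and its species' MSC
  membership; it is reported undefined with < 3 species or zero variance.
* Replicates are aggregated per (marker, size, threshold) by the median
  (bootstrap-median convention), with mean and quartiles emitted alongside.

## Rate model

`Y = c·X^m` is fitted by OLS of log Y on log X (natural logs; *m* is
base-invariant, and scale equivariance — Y ↦ kY gives c ↦ kc with m
unchanged — is tested to machine precision). Points with Y = 0 are dropped
and counted rather than shifted by a pseudocount, which would inject an
arbitrary constant; a fit needs ≥ 2 positive points and X variation, else
it is reported undefined (NaN) without aborting sibling groups. The default
fits per-size medians across replicates; an all-points mode exists for
variance estimation. No weighting is applied.

Note that under pure subsampling of a *fixed* database with fixed colliding
species pairs, the expected number of colliding sequences grows roughly
linearly with subset size (m ≈ 1); super-linearity appears when rarer
colliding partners are absent from small subsets or when the colliding
fraction itself grows with size. The synthetic runs show both regimes
depending on how concentrated the planted collisions are.

## Problem sizes in the tests and acceptance script

The bundled experiments are scaled to desk size as the package's own study
conditions: the deeply-sampled-genus runs use 5,000 single-copy genes of
300 nt across 34 species (sizes 1,000–5,000 in steps of 1,000; 10 replicate
draws in the test suite, 5 in the acceptance script), the clustering
contract is verified on instances of up to 200 sequences of 50–500 nt, and
the identity primitive is checked exhaustively on 1,000 pairs of length
≤ 12 against an independent O(nm) dynamic program. The clusterer itself is
designed for much larger inputs (k-mer screening plus capped bit-vector
alignments; representatives held in memory), but no claim beyond the tested
sizes is made here.

## Known limitations

* Generator realism is structural, not parametric: divergences and
  collision rates are plausible choices, not estimates from SILVA/GTDB.
* The greedy first-eligible assignment (CD-HIT's fast-mode convention) can
  differ from best-match assignment near threshold boundaries; cluster
  *counts* are stable under the tested invariants but individual
  memberships are convention-dependent.
* Identity is edit-distance based; alignment-free identities (e.g. k-mer
  containment) or affine-gap scoring would shift values slightly near
  thresholds.
* `pairwise_identity` always returns a fraction: under the semi-global
  scheme the shorter sequence is always fully covered, so there is no
  separate "fails coverage" outcome.
* Gene families are generated independently; real marker genes share a
  genome phylogeny, so cross-family correlation of collisions
  (`multi_marker_species_fraction`) is weaker in synthetic data than in
  real databases.
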