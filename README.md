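# collisim

Simulation and quantification of **interspecies sequence collisions** in
growing marker-gene reference databases.

Marker genes — the 16S rRNA gene and the nearly universal single-copy
protein-coding genes — are widely used to assign species labels to reads,
genes and genomes. Their discriminative power, however, is a property of the
*database*, not just of the gene: as references accumulate sequences from
more organisms, genes from distinct species increasingly become identical or
near-identical ("collisions"), and species-level resolution erodes. This
package provides a tested pipeline for studying that erosion:

1. **Simulated database growth** — seeded random subsets of a marker-gene
   database over a size grid (e.g. 10,000–200,000 sequences in steps of
   10,000, or 1,000–5,000 for a single deeply sampled genus), with bootstrap
   replication.
2. **Greedy full-coverage clustering** — each simulated database is clustered
   at species-proxy identity thresholds (95%, 97%, 99%, 100%) with a
   CD-HIT-style greedy incremental clusterer that requires the shorter
   sequence to align end-to-end against the longer one. Identity between a
   shorter sequence *S* and a longer *L* is (|S| − d)/|S|, where *d* is the
   semi-global edit distance of *S* against the best infix of *L*.
3. **Multi-species cluster statistics** — a cluster containing ≥ 2 species is
   a *multi-species cluster* (MSC): no classifier can separate its species
   at that threshold. The package counts MSCs, the sequences and species
   inside them, species-pair co-occurrences, and the relation between a
   genus' species richness and its collision load.
4. **Power-law growth rate** — the number of sequences in MSCs, *Y*, is
   modelled against database size *X* as *Y = cX*^*m* by ordinary least
   squares in log–log space; the exponent *m* is the rate at which
   resolution is lost (*m* > 1 ⇒ super-linear).

Because real references (SILVA, GTDB, RefSeq assemblies) are far too large
to ship or rebuild in tests, the package includes a first-class **synthetic
database generator** with fully known taxonomy and *planted* verbatim
cross-species collisions, so every downstream stage can be validated against
exact ground truth.

## Worked example

```python
from collisim import (ClusterParams, SubsampleSpec, SyntheticConfig, fit_all,
                      generate, greedy_cluster, subsample, summarize)
from collisim.stats import stats_table
from collisim.synthetic import FamilySpec

# a deeply sampled genus: 34 species, 2,000 single-copy genes,
# one dominant species holding ~88.5% of the genomes
cfg = SyntheticConfig.listeria_like(
    n_species=34, n_genomes=2000, dominant_fraction=0.885,
    families=[FamilySpec("MG001", mean_length=300, length_sd=0.0, copy_number=1)],
    collision_rate=0.3, seed=42,
)
db, truth = generate(cfg)
print(f"{len(db)} sequences, {len(truth.species())} species, "
      f"{len(truth.collisions)} planted collisions")

ids = [r.record_id for r in db.records()]
seqs = db.sequences()
spec = SubsampleSpec(sizes=(500, 1000, 1500, 2000), n_replicates=5, seed=7)
rows = []
for sub in subsample(ids, spec, "MG001"):
    recs = [(rid, seqs[rid]) for rid in sub.record_ids]
    for t in (0.95, 1.0):
        clustering = greedy_cluster(recs, ClusterParams(t))
        rows.append(summarize(clustering, truth.record_species, marker_id="MG001",
                              replicate=sub.replicate, db_size=sub.size))
table = stats_table(rows)
for f in fit_all(table, on="median"):
    print(f"threshold {f.threshold:.2f}: m = {f.m:.3f}, c = {f.c:.3f}, R^2 = {f.r_squared:.4f}")
```

which prints:

```
2000 sequences, 34 species, 9 planted collisions
threshold 0.95: m = 1.093, c = 0.029, R^2 = 0.9999
threshold 1.00: m = 1.370, c = 0.002, R^2 = 0.9958
```

Nine planted verbatim collisions suffice to recruit sequences into
multi-species clusters at every threshold, and the recruitment grows at
least linearly with database size (*m* ≥ 1); at 100% identity growth is
super-linear here because the rarer colliding species are missing from the
smallest subsets. At size 2,000 and 100% identity this run finds a median of
8 multi-species clusters holding 53 sequences — identical sequences carrying
different species labels, which no sequence feature can separate.

## Command line

Every stage is also a subcommand of the `collisim` executable
(`generate`, `filter`, `subsample`, `cluster`, `stats`, `fit`, `run-all`);
`run-all` executes the whole workflow into a run directory of plain-text
artifacts (FASTA, TSV, CD-HIT-style `.clstr`) and is reproducible byte for
byte from its config and seed:

```sh
collisim run-all --synthetic-preset listeria --sizes "1000 2000 3000 4000 5000" \
    --replicates 100 --thresholds "0.95 0.97 0.99 1.0" --seed 1 --outdir runs/listeria
```

Real databases are ingested with `--input db.fasta --dialect silva|gtdb`
(SILVA-style seven-rank lineages or GTDB-style `marker=`/`s__` headers),
with the standard record filters: removal of incomplete or organellar
lineages, and of per-family length outliers (below half or above twice the
family's mean length).

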