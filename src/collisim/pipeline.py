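"""End-to-end analysis runs: database -> filters -> subsets -> clusterings
-> collision statistics -> power-law rate fits.

A run is described by a :class:`RunConfig` (serializable to YAML), takes
either a synthetic configuration or input FASTA files, and writes a run
directory of plain-text artifacts:

``config.yaml``            snapshot of the effective configuration
``database/<family>.fasta``  post-filter database, one file per family
``ground_truth.tsv``       planted collisions (synthetic inputs only)
``filter_report.tsv``      removals per filter, family and reason
``manifests.tsv``          subset membership (family, size, replicate, id)
``clusters/*.clstr``       final-size clusterings in CD-HIT-style text
``stats.tsv``              one row per (family, size, replicate, threshold)
``stats_aggregated.tsv``   replicate-aggregated statistics
``species_pairs.tsv``      species-pair co-occurrence in MSCs per threshold
``genus_richness.tsv``     per-species MSC membership vs genus richness
``genus_richness_correlation.tsv``  Pearson r per threshold
``rate_fits.tsv``          power-law (c, m) per family and threshold
``run.log``                stage-by-stage record counts

Re-running with the same config and seed reproduces every table byte for
byte: all randomness flows from the master seed through per-subset child
seeds, and the log carries no timestamps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import cluster as cl
from . import db_io, ratefit, stats, subsample, synthetic

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    # input: either a synthetic config or FASTA paths with a dialect
    synthetic_config: synthetic.SyntheticConfig | None = None
    input_paths: tuple[str, ...] = ()
    dialect: str = "silva"
    # filters
    apply_taxonomy_filter: bool = True
    require_all_ranks: bool = True
    apply_length_filter: bool = True
    # simulation grid
    sizes: tuple[int, ...] = (1000, 2000, 3000, 4000, 5000)
    n_replicates: int = 100
    nested: bool = False
    thresholds: tuple[float, ...] = (0.95, 0.97, 0.99, 1.0)
    # aggregation and reproducibility
    aggregate: str = "median"
    seed: int = 0
    write_clstr: bool = True

    def __post_init__(self) -> None:
        if self.synthetic_config is None and not self.input_paths:
            raise ValueError("config needs a synthetic_config or input_paths")
        if self.aggregate not in ("median", "mean"):
            raise ValueError("aggregate must be 'median' or 'mean'")
        self.sizes = tuple(int(s) for s in self.sizes)
        self.thresholds = tuple(float(t) for t in self.thresholds)

    def to_dict(self) -> dict:
        d: dict = {
            "dialect": self.dialect,
            "apply_taxonomy_filter": self.apply_taxonomy_filter,
            "require_all_ranks": self.require_all_ranks,
            "apply_length_filter": self.apply_length_filter,
            "sizes": list(self.sizes),
            "n_replicates": self.n_replicates,
            "nested": self.nested,
            "thresholds": list(self.thresholds),
            "aggregate": self.aggregate,
            "seed": self.seed,
            "write_clstr": self.write_clstr,
        }
        if self.input_paths:
            d["input_paths"] = list(self.input_paths)
        if self.synthetic_config is not None:
            sc = self.synthetic_config
            d["synthetic"] = {
                "n_genera": sc.n_genera,
                "species_per_genus": _spec_to_yaml(sc.species_per_genus),
                "genomes_per_species": _spec_to_yaml(sc.genomes_per_species),
                "families": [
                    {
                        "name": f.name,
                        "mean_length": f.mean_length,
                        "length_sd": f.length_sd,
                        "copy_number": list(f.copy_number)
                        if isinstance(f.copy_number, tuple)
                        else f.copy_number,
                    }
                    for f in sc.families
                ],
                "inter_species_divergence": sc.inter_species_divergence,
                "intra_species_divergence": sc.intra_species_divergence,
                "collision_rate": sc.collision_rate,
                "artifact_rate": sc.artifact_rate,
                "incomplete_rate": sc.incomplete_rate,
                "seed": sc.seed,
            }
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sc = None
        if "synthetic" in d:
            s = dict(d.pop("synthetic"))
            fams = [
                synthetic.FamilySpec(
                    name=f["name"],
                    mean_length=f.get("mean_length", 480),
                    length_sd=f.get("length_sd", 20.0),
                    copy_number=tuple(f["copy_number"])
                    if isinstance(f.get("copy_number", 1), list)
                    else f.get("copy_number", 1),
                )
                for f in s.pop("families", [])
            ] or synthetic.default_families(3)
            s["species_per_genus"] = _spec_from_yaml(s.get("species_per_genus", 4))
            s["genomes_per_species"] = _spec_from_yaml(s.get("genomes_per_species", 2))
            sc = synthetic.SyntheticConfig(families=fams, **s)
        d["input_paths"] = tuple(d.get("input_paths", ()))
        d["sizes"] = tuple(d.get("sizes", (1000, 2000, 3000, 4000, 5000)))
        d["thresholds"] = tuple(d.get("thresholds", (0.95, 0.97, 0.99, 1.0)))
        return cls(synthetic_config=sc, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _spec_to_yaml(spec):
    if isinstance(spec, tuple):
        return {"range": [int(spec[0]), int(spec[1])]}
    if isinstance(spec, int):
        return spec
    return [int(x) for x in spec]


def _spec_from_yaml(v):
    if isinstance(v, dict) and "range" in v:
        return (int(v["range"][0]), int(v["range"][1]))
    if isinstance(v, list):
        return [int(x) for x in v]
    return int(v)


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def info(self, msg: str) -> None:
        self.lines.append(msg)

    def flush(self) -> None:
        self.path.write_text("\n".join(self.lines) + "\n")


def _load_database(config: RunConfig, log: _RunLog, outdir: Path) -> db_io.MarkerDatabase:
    if config.synthetic_config is not None:
        db, truth = synthetic.generate(config.synthetic_config)
        truth.to_tsv(outdir / "ground_truth.tsv")
        log.info(
            f"generate: {len(db)} records, {len(db.families)} families, "
            f"{len(truth.species())} species, {len(truth.collisions)} planted collisions"
        )
        return db
    db = db_io.MarkerDatabase(provenance=["merged inputs"])
    for p in config.input_paths:
        part = db_io.parse_fasta(p, dialect=config.dialect)
        for rec in part.records():
            db.add(rec)
        db.parse_issues.extend(part.parse_issues)
        db.provenance.extend(part.provenance)
    log.info(
        f"parse: {len(db)} records, {len(db.families)} families, "
        f"{len(db.parse_issues)} header issues"
    )
    return db


def run(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the full analysis and write all artifacts into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _RunLog(outdir / "run.log")
    config.to_yaml(outdir / "config.yaml")

    db = _load_database(config, log, outdir)

    reports = []
    if config.apply_taxonomy_filter:
        db, rep = db_io.filter_taxonomy(db, require_all_ranks=config.require_all_ranks)
        reports.append(rep)
        log.info(f"filter_taxonomy: removed {rep.n_removed}, retained {len(db)}")
    if config.apply_length_filter:
        db, rep = db_io.filter_length(db)
        reports.append(rep)
        log.info(f"filter_length: removed {rep.n_removed}, retained {len(db)}")
    if reports:
        pd.concat([r.to_frame() for r in reports], ignore_index=True).to_csv(
            outdir / "filter_report.tsv", sep="\t", index=False
        )
    db_io.write_fasta(db, outdir / "database", dialect=config.dialect)

    species_of = db.species_labels()
    genus_of = db.genus_of_species()
    seq_of = db.sequences()

    spec = subsample.SubsampleSpec(
        sizes=config.sizes,
        n_replicates=config.n_replicates,
        seed=config.seed,
        nested=config.nested,
    )
    clusters_dir = outdir / "clusters"
    if config.write_clstr:
        clusters_dir.mkdir(exist_ok=True)

    all_stats: list[stats.CollisionStats] = []
    pair_inputs: dict[float, list] = {t: [] for t in config.thresholds}
    richness_rows: list[pd.DataFrame] = []
    corr_rows: list[dict] = []
    all_subsets: list[subsample.Subset] = []

    for family, recs in db.families.items():
        ids = [r.record_id for r in recs]
        largest = max((s for s in spec.sizes if s <= len(ids)), default=None)
        subsets = list(subsample.subsample(ids, spec, family=family))
        all_subsets.extend(subsets)
        log.info(f"subsample: family {family}: {len(subsets)} subsets from {len(ids)} records")
        for sub in subsets:
            records = [(rid, seq_of[rid]) for rid in sub.record_ids]
            for t in config.thresholds:
                clustering = cl.greedy_cluster(records, cl.ClusterParams(identity_threshold=t))
                all_stats.append(
                    stats.summarize(
                        clustering,
                        species_of,
                        marker_id=family,
                        replicate=sub.replicate,
                        db_size=sub.size,
                    )
                )
                is_final = largest is not None and sub.size == largest
                if is_final:
                    sub_species = {rid: species_of[rid] for rid in sub.record_ids}
                    pair_inputs[t].append((clustering, sub_species))
                    if sub.replicate == 0:
                        df, corr = stats.genus_richness_relation(
                            clustering, sub_species, genus_of
                        )
                        df = df.assign(marker_id=family, threshold=t)
                        richness_rows.append(df)
                        corr_rows.append(
                            {
                                "marker_id": family,
                                "threshold": t,
                                "pearson_r": float("nan") if corr is None else corr,
                                "n_points": len(df),
                            }
                        )
                        if config.write_clstr:
                            cl.write_clstr(
                                clustering,
                                seq_of,
                                clusters_dir / f"{family}_t{t:.2f}_size{sub.size}.clstr",
                            )

    subsample.write_manifest(all_subsets, outdir / "manifests.tsv")

    table = stats.stats_table(all_stats)
    table.to_csv(outdir / "stats.tsv", sep="\t", index=False)
    stats.aggregate_replicates(table, how=config.aggregate).to_csv(
        outdir / "stats_aggregated.tsv", sep="\t", index=False
    )

    pair_frames = []
    for t in config.thresholds:
        df = stats.species_pair_counts(pair_inputs[t])
        if not df.empty:
            df.insert(0, "threshold", t)
            pair_frames.append(df)
    pairs = (
        pd.concat(pair_frames, ignore_index=True)
        if pair_frames
        else pd.DataFrame(columns=["threshold", "species_a", "species_b", "n_cooccurrences"])
    )
    pairs.to_csv(outdir / "species_pairs.tsv", sep="\t", index=False)

    rich = (
        pd.concat(richness_rows, ignore_index=True)
        if richness_rows
        else pd.DataFrame(
            columns=["species", "genus", "genus_richness", "n_msc_of_species", "marker_id", "threshold"]
        )
    )
    rich.to_csv(outdir / "genus_richness.tsv", sep="\t", index=False)
    pd.DataFrame(corr_rows, columns=["marker_id", "threshold", "pearson_r", "n_points"]).to_csv(
        outdir / "genus_richness_correlation.tsv", sep="\t", index=False
    )

    fits = ratefit.fit_all(table, on="median")
    ratefit.rate_table(fits).to_csv(outdir / "rate_fits.tsv", sep="\t", index=False)

    log.info(f"stats: {len(table)} rows; rate fits: {len(fits)}")
    log.flush()
    return outdir
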