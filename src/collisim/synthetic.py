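"""Synthetic marker-gene databases with fully known collision structure.

Public 16S/marker-gene references are far too large to rebuild in tests,
so this module generates databases that emulate their salient structure
with complete ground truth: many species spread over genera of varying
richness, per-genome gene copies (a multi-copy 16S-like family with 1-9
copies per genome, single-copy protein-coding-like families), tight
intra-species similarity, inter-species divergence that can dip below
clustering thresholds, *planted verbatim cross-species duplicates*
(interspecies collisions), length-corrupted artifact records, and
non-deduplicated output.

Sequence evolution is a single-hit Jukes-Cantor-like model: each genus
carries one random ancestral gene per family; each species' gene derives
from the ancestor by independent per-site substitution (to one of the
three other bases) at ``inter_species_divergence``; each genome copy
derives from the species gene at ``intra_species_divergence``.  There are
no indels except artifact length corruption, since the downstream
analysis is identity-threshold based.

With probability ``collision_rate`` a species' gene for a family is
replaced *verbatim* by the gene of a previously generated congener
before genome copies are drawn; every planted collision is recorded in
the :class:`GroundTruth`, which makes the expected multi-species
clusters at 100% identity exactly enumerable.

A single RNG stream drives each ``generate`` call, consumed in a fixed,
documented order (genera -> families -> species -> genomes), so the same
config and seed reproduce the database byte for byte.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .db_io import MarkerDatabase, MarkerSequence, TaxonomyLineage

__all__ = [
    "FamilySpec",
    "SyntheticConfig",
    "PlantedCollision",
    "GroundTruth",
    "generate",
    "default_families",
    "skewed_genome_counts",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

CountSpec = int | tuple[int, int] | Sequence[int]


@dataclass(frozen=True)
class FamilySpec:
    """One marker-gene family: name, nucleotide length model, copy number.

    ``copy_number`` is either a fixed per-genome count or an inclusive
    ``(lo, hi)`` range sampled uniformly per genome (1-9 models a
    multi-copy 16S-like gene; 1 models universal single-copy markers).
    """

    name: str
    mean_length: int = 480
    length_sd: float = 20.0
    copy_number: int | tuple[int, int] = 1

    def __post_init__(self) -> None:
        if self.mean_length < 1:
            raise ValueError("mean_length must be >= 1")
        lo, hi = self._copy_range()
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid copy_number {self.copy_number!r}")

    def _copy_range(self) -> tuple[int, int]:
        if isinstance(self.copy_number, int):
            return self.copy_number, self.copy_number
        lo, hi = self.copy_number
        return int(lo), int(hi)


def default_families(n: int, include_16s: bool = True) -> list[FamilySpec]:
    """A 16S-like multi-copy family (1-9 copies per genome, ~1,500 nt)
    followed by single-copy protein-coding-like families (~40 per genome
    in a real genome; here one family each, ~480 nt)."""
    fams: list[FamilySpec] = []
    if include_16s and n >= 1:
        fams.append(FamilySpec("16S", mean_length=1500, length_sd=30.0, copy_number=(1, 9)))
    while len(fams) < n:
        i = len(fams) + (0 if include_16s else 1)
        fams.append(FamilySpec(f"MG{i:03d}", mean_length=480, length_sd=20.0, copy_number=1))
    return fams


def skewed_genome_counts(n_species: int, n_genomes: int, dominant_fraction: float = 0.885) -> list[int]:
    """Heavy-skew genome allocation: the first species receives
    ``dominant_fraction`` of all genomes (as in deeply sampled pathogen
    genera, where one species dominates the assemblies), the remainder is
    split as evenly as possible with at least one genome per species."""
    if n_species < 1 or n_genomes < n_species:
        raise ValueError("need at least one genome per species")
    dom = max(1, min(n_genomes - (n_species - 1), round(dominant_fraction * n_genomes)))
    rest = n_genomes - dom
    base, extra = divmod(rest, n_species - 1) if n_species > 1 else (0, 0)
    counts = [dom] + [base + (1 if i < extra else 0) for i in range(n_species - 1)]
    return counts


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of one synthetic database.

    ``species_per_genus`` / ``genomes_per_species`` are count specs: a
    fixed int, an inclusive ``(lo, hi)`` range sampled uniformly, or an
    explicit per-genus / per-species list (lists allow heavy skew such as
    one dominant species).  Divergences are expected substitutions per
    site; ``collision_rate`` is the per-(species, family) probability of
    a verbatim cross-species copy; ``artifact_rate`` the per-record
    probability of length corruption outside the [half-mean, twice-mean]
    band; ``incomplete_rate`` the per-record probability of emitting a
    truncated (species-free) lineage.
    """

    n_genera: int = 5
    species_per_genus: CountSpec = (2, 8)
    genomes_per_species: CountSpec = (1, 6)
    families: Sequence[FamilySpec] = field(default_factory=lambda: default_families(3))
    inter_species_divergence: float = 0.10
    intra_species_divergence: float = 0.005
    collision_rate: float = 0.05
    artifact_rate: float = 0.0
    incomplete_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genera < 1:
            raise ValueError("n_genera must be >= 1")
        if not self.families:
            raise ValueError("at least one marker family is required")
        if len({f.name for f in self.families}) != len(self.families):
            raise ValueError("family names must be unique")
        for name, rate in (
            ("collision_rate", self.collision_rate),
            ("artifact_rate", self.artifact_rate),
            ("incomplete_rate", self.incomplete_rate),
        ):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        for name, div in (
            ("inter_species_divergence", self.inter_species_divergence),
            ("intra_species_divergence", self.intra_species_divergence),
        ):
            if not (0.0 <= div < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        _validate_count_spec(self.species_per_genus, "species_per_genus")
        _validate_count_spec(self.genomes_per_species, "genomes_per_species")

    @classmethod
    def listeria_like(
        cls,
        n_species: int = 34,
        n_genomes: int = 5014,
        dominant_fraction: float = 0.885,
        families: Sequence[FamilySpec] | None = None,
        inter_species_divergence: float = 0.15,
        intra_species_divergence: float = 0.003,
        collision_rate: float = 0.3,
        seed: int = 0,
    ) -> "SyntheticConfig":
        """A deeply sampled single genus: one genus, many genomes, one
        dominant species holding most of them."""
        return cls(
            n_genera=1,
            species_per_genus=n_species,
            genomes_per_species=skewed_genome_counts(n_species, n_genomes, dominant_fraction),
            families=families if families is not None else default_families(3),
            inter_species_divergence=inter_species_divergence,
            intra_species_divergence=intra_species_divergence,
            collision_rate=collision_rate,
            seed=seed,
        )


def _validate_count_spec(spec: CountSpec, name: str) -> None:
    if isinstance(spec, int):
        if spec < 1:
            raise ValueError(f"{name} must be >= 1")
    elif isinstance(spec, tuple) and len(spec) == 2:
        lo, hi = spec
        if lo < 1 or hi < lo:
            raise ValueError(f"{name} range invalid: {spec!r}")
    else:
        counts = list(spec)
        if not counts or any(int(c) < 1 for c in counts):
            raise ValueError(f"{name} list must be non-empty positive counts")


def _resolve_counts(spec: CountSpec, n: int, rng: np.random.Generator) -> list[int]:
    if isinstance(spec, int):
        return [spec] * n
    if isinstance(spec, tuple) and len(spec) == 2:
        lo, hi = spec
        return [int(x) for x in rng.integers(int(lo), int(hi) + 1, size=n)]
    counts = [int(c) for c in spec]
    if len(counts) < n:
        raise ValueError(f"count list of length {len(counts)} shorter than required {n}")
    return counts[:n]


@dataclass(frozen=True)
class PlantedCollision:
    """One planted verbatim copy: ``species_dst`` received the gene of its
    congener ``species_src`` for ``family``."""

    species_src: str
    species_dst: str
    family: str


@dataclass
class GroundTruth:
    """Complete bookkeeping of a generated database."""

    collisions: list[PlantedCollision] = field(default_factory=list)
    genus_of_species: dict[str, str] = field(default_factory=dict)
    record_species: dict[str, str] = field(default_factory=dict)
    record_family: dict[str, str] = field(default_factory=dict)
    artifact_records: set[str] = field(default_factory=set)
    incomplete_records: set[str] = field(default_factory=set)

    @property
    def n_records(self) -> int:
        return len(self.record_species)

    def species(self) -> set[str]:
        return set(self.genus_of_species)

    def records_of(self, species: str, family: str) -> list[str]:
        return [
            rid
            for rid, sp in self.record_species.items()
            if sp == species and self.record_family[rid] == family
        ]

    def collision_pair_counts(self) -> Counter:
        """(species_a, species_b, family) -> number of planted events, with
        the species pair canonically sorted."""
        c: Counter = Counter()
        for col in self.collisions:
            a, b = sorted((col.species_src, col.species_dst))
            c[(a, b, col.family)] += 1
        return c

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"species_a": a, "species_b": b, "family": fam, "n_planted": n}
            for (a, b, fam), n in sorted(self.collision_pair_counts().items())
        ]
        return pd.DataFrame(rows, columns=["species_a", "species_b", "family", "n_planted"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _random_gene(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _mutate(gene: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution at ``rate``; a hit site moves to one of the
    three other bases uniformly (single-hit Jukes-Cantor-like)."""
    out = gene.copy()
    if rate <= 0.0:
        return out
    hits = rng.random(gene.size) < rate
    n = int(hits.sum())
    if n:
        out[hits] = (out[hits] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    return out


def _to_str(gene: np.ndarray) -> str:
    return bytes(_BASES[gene]).decode("ascii")


def _corrupt_length(gene: np.ndarray, mean_length: int, rng: np.random.Generator) -> np.ndarray:
    """Force a record's length outside [mean/2, 2*mean]: truncate to
    15-40% of the family mean or tile to 220-300% of it."""
    if rng.random() < 0.5:
        new_len = max(1, int(round(mean_length * rng.uniform(0.15, 0.40))))
        return gene[:new_len] if new_len <= gene.size else np.tile(gene, 2)[:new_len]
    new_len = int(round(mean_length * rng.uniform(2.2, 3.0)))
    reps = int(np.ceil(new_len / gene.size))
    return np.tile(gene, reps)[:new_len]


def _lineage_for(genus_idx: int, genus: str, species: str, truncate: bool) -> TaxonomyLineage:
    ranks = (
        "Bacteria",
        f"Phylum{genus_idx % 7:02d}",
        f"Class{genus_idx % 11:02d}",
        f"Order{genus_idx % 13:02d}",
        f"Family{genus_idx:03d}",
        genus,
        species,
    )
    if truncate:
        return TaxonomyLineage.from_labels(ranks[:2])
    return TaxonomyLineage.from_labels(ranks)


def generate(config: SyntheticConfig) -> tuple[MarkerDatabase, GroundTruth]:
    """Generate a synthetic marker-gene database and its ground truth.

    Draw order (one RNG stream, reproducible from ``config.seed``): per
    genus, first the family ancestors (each: length, then residues), then
    per species its per-family gene (collision coin, substitutions), then
    per genome the per-family copy numbers, copies (substitutions),
    artifact and header-truncation coins.
    """
    rng = np.random.default_rng(config.seed)
    db = MarkerDatabase(provenance=[f"synthetic(seed={config.seed})"])
    truth = GroundTruth()

    species_counts = _resolve_counts(config.species_per_genus, config.n_genera, rng)
    genome_counter = 0

    for gi in range(config.n_genera):
        genus = f"Genus{gi:03d}"
        n_species = species_counts[gi]
        genome_counts = _resolve_counts(config.genomes_per_species, n_species, rng)

        ancestors: dict[str, np.ndarray] = {}
        for fam in config.families:
            length = max(1, int(round(rng.normal(fam.mean_length, fam.length_sd))))
            ancestors[fam.name] = _random_gene(length, rng)

        # species gene per family, generated species by species so that a
        # collision can copy any previously generated congener's gene
        species_genes: list[dict[str, np.ndarray]] = []
        species_names: list[str] = []
        for si in range(n_species):
            species = f"{genus} sp{si:03d}"
            species_names.append(species)
            truth.genus_of_species[species] = genus
            genes: dict[str, np.ndarray] = {}
            for fam in config.families:
                gene = _mutate(ancestors[fam.name], config.inter_species_divergence, rng)
                if si > 0 and rng.random() < config.collision_rate:
                    donor = int(rng.integers(0, si))
                    gene = species_genes[donor][fam.name].copy()
                    truth.collisions.append(
                        PlantedCollision(species_names[donor], species, fam.name)
                    )
                genes[fam.name] = gene
            species_genes.append(genes)

            for _ in range(genome_counts[si]):
                genome_id = f"G{genome_counter:06d}"
                genome_counter += 1
                for fam in config.families:
                    lo, hi = fam._copy_range()
                    n_copies = int(rng.integers(lo, hi + 1)) if hi > lo else lo
                    for ci in range(n_copies):
                        copy = _mutate(genes[fam.name], config.intra_species_divergence, rng)
                        rid = f"{genome_id}|{fam.name}|{ci}"
                        is_artifact = config.artifact_rate > 0 and rng.random() < config.artifact_rate
                        if is_artifact:
                            copy = _corrupt_length(copy, fam.mean_length, rng)
                            truth.artifact_records.add(rid)
                        truncate = (
                            config.incomplete_rate > 0 and rng.random() < config.incomplete_rate
                        )
                        if truncate:
                            truth.incomplete_records.add(rid)
                        lineage = _lineage_for(gi, genus, species, truncate)
                        db.add(
                            MarkerSequence(
                                record_id=rid,
                                marker_id=fam.name,
                                lineage=lineage,
                                sequence=_to_str(copy),
                                genome_id=genome_id,
                            )
                        )
                        truth.record_species[rid] = species
                        truth.record_family[rid] = fam.name
    return db, truth
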