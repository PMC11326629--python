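"""Reading and writing taxonomy-bearing marker-gene FASTA databases.

Reference databases of marker genes (16S rRNA, universal single-copy
protein-coding genes) ship as multi-FASTA files whose headers carry the
taxonomic lineage of the source organism.  Two header dialects are
supported:

* ``silva`` -- ``"<id> Domain;Phylum;Class;Order;Family;Genus;Genus epithet"``,
  a seven-rank semicolon-separated lineage whose last rank is the species
  binomial (the genus is embedded in the species label);
* ``gtdb``  -- ``"<id> marker=<family> s__Genus epithet"``, a marker-gene
  record tagged with its gene family and a species label only;
* ``generic`` -- the SILVA form when the description contains semicolons,
  otherwise a record without taxonomy.

Databases are *not* deduplicated: identical sequences from the same or
different organisms are kept as distinct records, mirroring how public
marker-gene references are distributed.

Two record filters are provided:

* :func:`filter_taxonomy` removes records with incomplete lineages and
  records originating from organellar (mitochondrial / plastid) genomes;
* :func:`filter_length` removes per-family length outliers, i.e. records
  shorter than half or longer than twice the family's mean length, with
  the mean computed once on the unfiltered family.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
DIALECTS = ("silva", "gtdb", "generic")

#: substrings (lower-case) that mark an organellar lineage at any rank
ORGANELLE_KEYWORDS = ("mitochondria", "mitochondrion", "chloroplast", "plastid")

#: species-rank labels that are placeholders rather than real binomials
PLACEHOLDER_PATTERNS = ("uncultured", "unidentified", "unknown", "metagenome")

_WS = re.compile(r"\s+")


class FastaFormatError(ValueError):
    """Raised when a FASTA file is structurally malformed."""


def _normalize(label: str) -> str:
    return _WS.sub(" ", label).strip()


@dataclass(frozen=True)
class TaxonomyLineage:
    """An ordered domain-to-species lineage; missing ranks are ``None``."""

    ranks: tuple[str | None, ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != len(RANKS):
            raise ValueError(f"lineage must have {len(RANKS)} ranks, got {len(self.ranks)}")
        norm = tuple((_normalize(r) or None) if r is not None else None for r in self.ranks)
        object.__setattr__(self, "ranks", norm)

    @classmethod
    def empty(cls) -> "TaxonomyLineage":
        return cls((None,) * len(RANKS))

    @classmethod
    def from_labels(cls, labels: Iterable[str | None]) -> "TaxonomyLineage":
        labels = list(labels)
        labels += [None] * (len(RANKS) - len(labels))
        return cls(tuple(labels[: len(RANKS)]))

    def rank(self, name: str) -> str | None:
        return self.ranks[RANKS.index(name)]

    @property
    def species(self) -> str | None:
        return self.ranks[6]

    @property
    def genus(self) -> str | None:
        return self.ranks[5]

    @property
    def complete(self) -> bool:
        """True iff all seven ranks are present and non-empty."""
        return all(r is not None for r in self.ranks)

    @property
    def species_resolved(self) -> bool:
        """True iff genus and species are present (the GTDB-dialect notion
        of a usable label, where higher ranks are not carried in headers)."""
        return self.genus is not None and self.species is not None

    def is_organelle(self) -> bool:
        for r in self.ranks:
            if r is None:
                continue
            low = r.lower()
            if any(k in low for k in ORGANELLE_KEYWORDS):
                return True
        return False

    def has_placeholder_species(self) -> bool:
        sp = self.species
        if sp is None:
            return False
        low = sp.lower()
        return any(p in low for p in PLACEHOLDER_PATTERNS)

    def format(self) -> str:
        """SILVA-style semicolon join of the present ranks (prefix only)."""
        out: list[str] = []
        for r in self.ranks:
            if r is None:
                break
            out.append(r)
        return ";".join(out)


@dataclass(frozen=True)
class MarkerSequence:
    """One taxonomically labelled gene sequence from one genome."""

    record_id: str
    marker_id: str
    lineage: TaxonomyLineage
    sequence: str
    genome_id: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.record_id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def species(self) -> str | None:
        return self.lineage.species

    @property
    def genus(self) -> str | None:
        return self.lineage.genus

    def header(self, dialect: str = "silva") -> str:
        """Format the FASTA description line for ``dialect``; parsing the
        result back yields an equivalent record (round-trip)."""
        if dialect == "silva" or dialect == "generic":
            lin = self.lineage.format()
            return f"{self.record_id} {lin}" if lin else self.record_id
        if dialect == "gtdb":
            sp = self.species or ""
            return f"{self.record_id} marker={self.marker_id} s__{sp}".rstrip()
        raise ValueError(f"unknown dialect {dialect!r}")


@dataclass
class MarkerDatabase:
    """A non-deduplicated record collection partitioned by marker family."""

    families: dict[str, list[MarkerSequence]] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)
    parse_issues: list[tuple[str, str]] = field(default_factory=list)
    _ids: set[str] = field(default_factory=set, repr=False)

    def add(self, rec: MarkerSequence) -> None:
        if rec.record_id in self._ids:
            raise ValueError(f"duplicate record id {rec.record_id!r}")
        self._ids.add(rec.record_id)
        self.families.setdefault(rec.marker_id, []).append(rec)

    def records(self) -> Iterator[MarkerSequence]:
        for fam in self.families.values():
            yield from fam

    def __len__(self) -> int:
        return sum(len(v) for v in self.families.values())

    @property
    def n_records(self) -> int:
        return len(self)

    def species(self) -> set[str]:
        return {r.species for r in self.records() if r.species is not None}

    def species_labels(self) -> dict[str, str]:
        """record_id -> species for all records with a species label."""
        return {r.record_id: r.species for r in self.records() if r.species is not None}

    def genus_of_species(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for r in self.records():
            if r.species is not None and r.genus is not None:
                out[r.species] = r.genus
        return out

    def sequences(self) -> dict[str, str]:
        return {r.record_id: r.sequence for r in self.records()}


# ---------------------------------------------------------------------------
# header parsing


def _parse_silva_header(header: str) -> tuple[str, TaxonomyLineage, str | None]:
    parts = header.split(None, 1)
    rid = parts[0]
    if len(parts) == 1 or ";" not in parts[1]:
        return rid, TaxonomyLineage.empty(), "no semicolon-separated lineage"
    labels = [p for p in parts[1].split(";")]
    issue = None
    if len(labels) > len(RANKS):
        issue = f"{len(labels)} lineage fields, expected at most {len(RANKS)}"
        labels = labels[: len(RANKS)]
    return rid, TaxonomyLineage.from_labels(labels), issue


_GTDB_SPECIES = re.compile(r"\bs__(.*)$")
_GTDB_MARKER = re.compile(r"\bmarker=(\S+)")


def _parse_gtdb_header(header: str) -> tuple[str, str | None, TaxonomyLineage, str | None]:
    rid = header.split(None, 1)[0]
    m = _GTDB_MARKER.search(header)
    marker = m.group(1) if m else None
    s = _GTDB_SPECIES.search(header)
    if not s or not _normalize(s.group(1)):
        return rid, marker, TaxonomyLineage.empty(), "no s__ species field"
    species = _normalize(s.group(1))
    genus = species.split(" ", 1)[0]
    lineage = TaxonomyLineage.from_labels([None] * 5 + [genus, species])
    return rid, marker, lineage, None


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def parse_fasta(
    path: str | Path,
    dialect: str = "silva",
    default_marker: str = "16S",
) -> MarkerDatabase:
    """Parse a (optionally gzipped) multi-FASTA file into a :class:`MarkerDatabase`.

    Records whose header cannot be parsed under the dialect are retained with
    an empty lineage and listed in ``db.parse_issues`` rather than dropped.

    Parameters
    ----------
    dialect:
        ``silva`` (seven-rank lineage), ``gtdb`` (``marker=`` tag plus
        ``s__`` species label) or ``generic``.
    default_marker:
        Family label assigned to records whose header carries none
        (SILVA-style 16S databases are single-family files).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    db = MarkerDatabase(provenance=[f"parsed {path.name} (dialect={dialect})"])
    with _open_text(path) as fh:
        # SimpleFastaParser silently skips a preamble; reject it explicitly.
        pos = fh.tell()
        lineno = 0
        for line in fh:
            lineno += 1
            if line.strip():
                if not line.startswith(">"):
                    raise FastaFormatError(
                        f"{path}: line {lineno}: expected '>' header, got {line.strip()[:40]!r}"
                    )
                break
        fh.seek(pos)
        n = 0
        for header, seq in SimpleFastaParser(fh):
            n += 1
            seq = seq.upper()
            if not seq:
                raise FastaFormatError(f"{path}: record {n} ({header.split()[0]!r}) has an empty sequence")
            if dialect == "gtdb":
                rid, marker, lineage, issue = _parse_gtdb_header(header)
                marker = marker or default_marker
            else:
                rid, lineage, issue = _parse_silva_header(header)
                if dialect == "silva" and issue == "no semicolon-separated lineage":
                    pass  # reported below; generic treats it as taxonomy-free
                elif dialect == "generic":
                    issue = None
                marker = default_marker
            if issue:
                db.parse_issues.append((rid, issue))
            db.add(MarkerSequence(record_id=rid, marker_id=marker, lineage=lineage, sequence=seq))
    return db


def write_fasta(
    db: MarkerDatabase,
    directory: str | Path,
    dialect: str = "silva",
    line_width: int = 0,
) -> list[Path]:
    """Write one multi-FASTA per marker family into ``directory``.

    Returns the written paths in family order.  ``line_width`` of 0 keeps
    each sequence on a single line.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for fam, recs in db.families.items():
        p = directory / f"{fam}.fasta"
        with open(p, "w") as fh:
            for r in recs:
                fh.write(f">{r.header(dialect)}\n")
                if line_width and line_width > 0:
                    for i in range(0, len(r.sequence), line_width):
                        fh.write(r.sequence[i : i + line_width] + "\n")
                else:
                    fh.write(r.sequence + "\n")
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# filters


@dataclass
class FilterReport:
    """Per-family, per-reason account of removed records."""

    filter_name: str
    removed: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def record(self, family: str, reason: str, record_id: str) -> None:
        self.removed.setdefault((family, reason), []).append(record_id)

    @property
    def n_removed(self) -> int:
        return sum(len(v) for v in self.removed.values())

    def removed_ids(self) -> set[str]:
        return {rid for ids in self.removed.values() for rid in ids}

    def counts(self) -> dict[str, int]:
        """Total removed per reason, across families."""
        out: dict[str, int] = {}
        for (_, reason), ids in self.removed.items():
            out[reason] = out.get(reason, 0) + len(ids)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"filter": self.filter_name, "marker_id": fam, "reason": reason, "n_removed": len(ids)}
            for (fam, reason), ids in sorted(self.removed.items())
        ]
        return pd.DataFrame(rows, columns=["filter", "marker_id", "reason", "n_removed"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _rebuild(db: MarkerDatabase, keep: set[str], note: str) -> MarkerDatabase:
    out = MarkerDatabase(provenance=db.provenance + [note])
    for fam, recs in db.families.items():
        kept = [r for r in recs if r.record_id in keep]
        if kept:
            out.families[fam] = kept
            out._ids.update(r.record_id for r in kept)
    return out


def filter_taxonomy(
    db: MarkerDatabase,
    require_all_ranks: bool = True,
    drop_placeholders: bool = False,
) -> tuple[MarkerDatabase, FilterReport]:
    """Remove records with incomplete taxonomy or organellar origin.

    ``require_all_ranks=True`` demands all seven ranks (appropriate for the
    SILVA dialect); with ``False`` only genus and species are required,
    which is the strongest check the GTDB header dialect supports.
    ``drop_placeholders`` additionally removes species labels such as
    "uncultured bacterium" that name no real species (off by default).
    """
    report = FilterReport("taxonomy")
    keep: set[str] = set()
    for fam, recs in db.families.items():
        for r in recs:
            complete = r.lineage.complete if require_all_ranks else r.lineage.species_resolved
            if not complete:
                report.record(fam, "incomplete_lineage", r.record_id)
            elif r.lineage.is_organelle():
                report.record(fam, "organelle", r.record_id)
            elif drop_placeholders and r.lineage.has_placeholder_species():
                report.record(fam, "placeholder_species", r.record_id)
            else:
                keep.add(r.record_id)
    return _rebuild(db, keep, f"taxonomy filter removed {report.n_removed}"), report


def filter_length(db: MarkerDatabase) -> tuple[MarkerDatabase, FilterReport]:
    """Remove per-family length outliers: records below half or above twice
    the family's mean length.  The mean is computed once on the pre-filter
    record set of each family; the filter does not iterate.
    """
    report = FilterReport("length")
    keep: set[str] = set()
    for fam, recs in db.families.items():
        mean = sum(len(r) for r in recs) / len(recs)
        lo, hi = mean / 2.0, mean * 2.0
        for r in recs:
            if lo <= len(r) <= hi:
                keep.add(r.record_id)
            else:
                report.record(fam, "length_outlier", r.record_id)
    return _rebuild(db, keep, f"length filter removed {report.n_removed}"), report
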