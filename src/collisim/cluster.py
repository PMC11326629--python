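"""Greedy incremental identity clustering with a full-coverage rule.

The clusterer follows the CD-HIT greedy scheme: records are sorted
longest-first and each record, in turn, either joins the first existing
cluster whose representative it matches at or above the identity
threshold, or founds a new cluster with itself as representative.

Identity between a shorter sequence ``S`` and a longer one ``L`` uses the
*full-coverage* rule: every residue of S must be aligned against L (end
gaps on L are free, so S aligns to the best-matching infix of L), and

    identity(S, L) = (|S| - d) / |S|

where ``d`` is the unit-cost edit distance of S against that best infix.
Internal gaps therefore count against the score exactly like mismatches,
with the shorter length as the fixed denominator.  At threshold 1.0 the
rule reduces to exact substring containment and is computed by a fast
path without alignment.

The alignment itself is delegated to the Myers bit-vector implementation
in :mod:`edlib` (semi-global, ``mode="HW"``); the greedy scheme, the
candidate screen and the invariant verifier are implemented here.
Sequences are treated as opaque residue strings, so nucleotide and
protein families are clustered identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib

__all__ = [
    "ClusterParams",
    "Cluster",
    "Clustering",
    "pairwise_identity",
    "max_edit_distance",
    "greedy_cluster",
    "verify_clustering",
    "VerificationReport",
    "write_clstr",
    "write_cluster_tsv",
]


@dataclass(frozen=True)
class ClusterParams:
    """Parameters of one clustering run.

    ``identity_threshold`` is a fraction in (0, 1]; the classical
    species-proxy settings are 0.95, 0.97, 0.99 and 1.0.  The coverage
    rule (shorter sequence fully aligned to the longer) is fixed.
    ``prefilter_min_length`` enables a q-gram candidate screen for
    sequences at least that long; the screen is conservative (it never
    rejects a pair the alignment would accept) and only pays off for
    long genes such as full-length 16S.
    """

    identity_threshold: float
    prefilter_min_length: int = 800
    qgram: int = 8

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_threshold <= 1.0):
            raise ValueError(f"identity threshold must be in (0, 1], got {self.identity_threshold}")


def max_edit_distance(length: int, threshold: float) -> int:
    """Largest edit distance compatible with ``identity >= threshold`` for a
    query of ``length`` residues (identity = (length - d) / length)."""
    return int(math.floor(length * (1.0 - threshold) + 1e-9))


def _hw_distance(query: str, target: str, k: int = -1) -> int:
    """Semi-global unit-cost edit distance of ``query`` against the best
    infix of ``target``; -1 if it exceeds ``k`` (when k >= 0)."""
    return edlib.align(query, target, mode="HW", task="distance", k=k)["editDistance"]


def pairwise_identity(a: str, b: str) -> float:
    """Full-coverage identity between two sequences.

    The shorter sequence is aligned end-to-end against the longer one with
    free end gaps on the longer; identity is ``(|S| - d) / |S|`` clamped
    at 0, with ``d`` the optimal semi-global edit distance.  Returns 1.0
    exactly when the shorter sequence is a substring of the longer.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    s, l = (a, b) if len(a) <= len(b) else (b, a)
    d = _hw_distance(s, l)
    return max(0.0, (len(s) - d) / len(s))


def _qgram_positions(seq: str, q: int) -> list[str]:
    return [seq[i : i + q] for i in range(len(seq) - q + 1)]


def _screen_passes(qgrams: list[str], rep_qgrams: set[str], k: int, q: int) -> bool:
    """q-gram lemma screen: if the edit distance to some infix of the
    representative is <= k, at least ``len(qgrams) - q*k`` of the query's
    q-gram positions must occur in the representative.  Conservative: a
    True result is required for, but does not imply, a match."""
    needed = len(qgrams) - q * k
    if needed <= 0:
        return True
    hits = 0
    budget = len(qgrams)
    for i, g in enumerate(qgrams):
        if g in rep_qgrams:
            hits += 1
            if hits >= needed:
                return True
        if hits + (budget - i - 1) < needed:
            return False
    return False


@dataclass
class Cluster:
    """One representative-anchored cluster; the representative is a member."""

    representative_id: str
    member_ids: list[str]

    @property
    def n_sequences(self) -> int:
        return len(self.member_ids)

    def species_set(self, species_of: Mapping[str, str]) -> set[str]:
        return {species_of[m] for m in self.member_ids}


@dataclass
class Clustering:
    """A partition of a record set into clusters at one identity threshold."""

    clusters: list[Cluster]
    threshold: float
    n_records: int

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def member_ids(self) -> list[str]:
        return [m for c in self.clusters for m in c.member_ids]


RecordLike = Sequence  # (record_id, sequence) pairs or objects with those attrs


def _normalize_records(records: Iterable) -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = []
    for r in records:
        if hasattr(r, "record_id"):
            out.append((r.record_id, r.sequence))
        else:
            rid, seq = r
            out.append((str(rid), str(seq)))
    if not out:
        raise ValueError("cannot cluster an empty record set")
    seen: set[str] = set()
    for rid, seq in out:
        if not seq:
            raise ValueError(f"record {rid!r} has an empty sequence")
        if rid in seen:
            raise ValueError(f"duplicate record id {rid!r}")
        seen.add(rid)
    return out


def sort_records(records: Iterable) -> list[tuple[str, str]]:
    """Total processing order: length descending, then sequence, then id.

    The order is a function of the record multiset alone, which makes the
    greedy clustering deterministic and independent of input order.
    """
    return sorted(_normalize_records(records), key=lambda t: (-len(t[1]), t[1], t[0]))


class _LiveCluster:
    __slots__ = ("rep_id", "rep_seq", "members", "qgrams")

    def __init__(self, rep_id: str, rep_seq: str):
        self.rep_id = rep_id
        self.rep_seq = rep_seq
        self.members = [rep_id]
        self.qgrams: set[str] | None = None


def greedy_cluster(records: Iterable, params: ClusterParams) -> Clustering:
    """Cluster records greedily at ``params.identity_threshold``.

    Records are processed longest-first (ties broken by sequence then id);
    each joins the first cluster, in creation order, whose representative
    it matches under the full-coverage identity rule, else founds a new
    cluster.  Representatives therefore have maximal length within their
    cluster and no representative matches any earlier representative.
    """
    items = sort_records(records)
    t = params.identity_threshold
    clusters: list[_LiveCluster] = []

    if t >= 1.0:
        # Exact containment: eligible clusters have a representative that is
        # strictly longer (substring scan, in creation order) or identical
        # (hash lookup; at most one such representative can exist).
        exact: dict[str, _LiveCluster] = {}
        for rid, seq in items:
            ls = len(seq)
            target = None
            for cl in clusters:
                if len(cl.rep_seq) <= ls:
                    break  # representatives are in non-increasing length order
                if seq in cl.rep_seq:
                    target = cl
                    break
            if target is None:
                target = exact.get(seq)
            if target is None:
                cl = _LiveCluster(rid, seq)
                clusters.append(cl)
                exact[seq] = cl
            else:
                target.members.append(rid)
        return Clustering([Cluster(c.rep_id, c.members) for c in clusters], t, len(items))

    q = params.qgram
    for rid, seq in items:
        ls = len(seq)
        k = max_edit_distance(ls, t)
        screen = ls >= params.prefilter_min_length and ls >= 2 * q
        qgrams = _qgram_positions(seq, q) if screen else None
        target = None
        for cl in clusters:
            if qgrams is not None:
                if cl.qgrams is None:
                    cl.qgrams = set(_qgram_positions(cl.rep_seq, q))
                if not _screen_passes(qgrams, cl.qgrams, k, q):
                    continue
            if _hw_distance(seq, cl.rep_seq, k=k) != -1:
                target = cl
                break
        if target is None:
            clusters.append(_LiveCluster(rid, seq))
        else:
            target.members.append(rid)
    return Clustering([Cluster(c.rep_id, c.members) for c in clusters], t, len(items))


# ---------------------------------------------------------------------------
# brute-force contract verification


@dataclass
class VerificationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def verify_clustering(
    clustering: Clustering,
    records: Iterable,
    params: ClusterParams | None = None,
) -> VerificationReport:
    """Recompute the clustering contract by brute force.

    Checks, against the full pairwise identity (no screening shortcuts):

    * partition -- every input record appears in exactly one cluster;
    * representative length -- each representative is maximal in its cluster;
    * member threshold -- every member meets the identity threshold with
      full coverage against its representative;
    * representative maximality -- no representative meets the threshold
      against any earlier representative.

    Violations are reported, not raised.
    """
    t = params.identity_threshold if params is not None else clustering.threshold
    seqs = dict(_normalize_records(records))
    rep = VerificationReport()

    members = clustering.member_ids()
    if len(members) != len(set(members)):
        rep.violations.append("partition: duplicate member ids across clusters")
    missing = set(seqs) - set(members)
    extra = set(members) - set(seqs)
    if missing:
        rep.violations.append(f"partition: {len(missing)} input records unclustered")
    if extra:
        rep.violations.append(f"partition: {len(extra)} members not in the input")

    def meets(shorter: str, longer: str) -> bool:
        d = _hw_distance(shorter, longer)
        return d <= max_edit_distance(len(shorter), t)

    for ci, cl in enumerate(clustering.clusters):
        if cl.representative_id not in seqs:
            continue
        rseq = seqs[cl.representative_id]
        if cl.representative_id not in cl.member_ids:
            rep.violations.append(f"cluster {ci}: representative not among members")
        for m in cl.member_ids:
            if m not in seqs:
                continue
            mseq = seqs[m]
            if len(mseq) > len(rseq):
                rep.violations.append(
                    f"cluster {ci}: member {m} longer than representative {cl.representative_id}"
                )
            elif m != cl.representative_id and not meets(mseq, rseq):
                rep.violations.append(
                    f"cluster {ci}: member {m} below threshold against representative"
                )
    for ci in range(len(clustering.clusters)):
        ri = clustering.clusters[ci].representative_id
        if ri not in seqs:
            continue
        for cj in range(ci):
            rj = clustering.clusters[cj].representative_id
            if rj not in seqs:
                continue
            a, b = seqs[ri], seqs[rj]
            s, l = (a, b) if len(a) <= len(b) else (b, a)
            if meets(s, l):
                rep.violations.append(
                    f"maximality: representative {ri} meets threshold against earlier {rj}"
                )
    return rep


# ---------------------------------------------------------------------------
# output formats


def write_clstr(
    clustering: Clustering,
    sequences: Mapping[str, str],
    path: str | Path,
    unit: str = "nt",
) -> None:
    """Write a CD-HIT ``.clstr``-style listing: one ``>Cluster N`` stanza per
    cluster, members with length and id, the representative starred, other
    members annotated with their identity to the representative."""
    with open(path, "w") as fh:
        for ci, cl in enumerate(clustering.clusters):
            fh.write(f">Cluster {ci}\n")
            rseq = sequences[cl.representative_id]
            for mi, m in enumerate(cl.member_ids):
                mseq = sequences[m]
                if m == cl.representative_id:
                    fh.write(f"{mi}\t{len(mseq)}{unit}, >{m}... *\n")
                else:
                    ident = pairwise_identity(mseq, rseq) * 100.0
                    fh.write(f"{mi}\t{len(mseq)}{unit}, >{m}... at {ident:.2f}%\n")


def write_cluster_tsv(
    clustering: Clustering,
    path: str | Path,
    species_of: Mapping[str, str] | None = None,
) -> None:
    import pandas as pd

    rows = []
    for ci, cl in enumerate(clustering.clusters):
        for m in cl.member_ids:
            rows.append(
                {
                    "cluster_id": ci,
                    "record_id": m,
                    "is_representative": int(m == cl.representative_id),
                    "species": species_of.get(m, "") if species_of else "",
                }
            )
    pd.DataFrame(rows, columns=["cluster_id", "record_id", "is_representative", "species"]).to_csv(
        path, sep="\t", index=False
    )
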