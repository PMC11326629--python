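"""Multi-species cluster statistics.

A *multi-species cluster* (MSC) is a cluster whose members carry at
least two distinct species labels; it is the unit of taxonomic
ambiguity: a classifier cannot tell the co-clustered species apart at
that identity threshold.  This module turns clusterings into the
summary statistics of the analysis:

* per-clustering counts (clusters, MSCs, sequences in MSCs, species in
  MSCs and the percentage thereof);
* species-pair co-occurrence counts across MSCs (which species collide
  with which);
* the relation between a genus' species richness and how many MSCs its
  species belong to;
* the fraction of species that are MSC members in at least ``k`` of
  several marker families.

Counting conventions: duplicate sequences from the same species count
individually in ``n_sequences_in_msc`` (the source databases are not
deduplicated); the species universe for percentages is the species
present in the clustered subset, not the full source database; a
species pair is counted once per multi-species cluster it co-occurs in,
regardless of how many sequences each species contributes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cluster import Clustering

__all__ = [
    "CollisionStats",
    "summarize",
    "species_pair_counts",
    "genus_richness_relation",
    "multi_marker_species_fraction",
    "stats_table",
    "aggregate_replicates",
]

STATS_COLUMNS = [
    "marker_id",
    "db_size",
    "replicate",
    "threshold",
    "n_clusters",
    "n_multi_species_clusters",
    "n_sequences_in_msc",
    "n_species_total",
    "n_species_in_msc",
    "pct_species_in_msc",
]


@dataclass(frozen=True)
class CollisionStats:
    """Collision summary of one clustering (one marker, size, replicate,
    threshold)."""

    marker_id: str
    db_size: int
    replicate: int
    threshold: float
    n_clusters: int
    n_multi_species_clusters: int
    n_sequences_in_msc: int
    n_species_total: int
    n_species_in_msc: int

    @property
    def pct_species_in_msc(self) -> float:
        if self.n_species_total == 0:
            return 0.0
        return 100.0 * self.n_species_in_msc / self.n_species_total


def _cluster_species(clustering: Clustering, species_of: Mapping[str, str]) -> list[set[str]]:
    out = []
    for cl in clustering.clusters:
        try:
            out.append({species_of[m] for m in cl.member_ids})
        except KeyError as e:
            raise ValueError(f"record {e.args[0]!r} has no species label") from None
    return out


def summarize(
    clustering: Clustering,
    species_of: Mapping[str, str],
    marker_id: str = "",
    replicate: int = 0,
    db_size: int | None = None,
) -> CollisionStats:
    """Count clusters, multi-species clusters, sequences and species in
    multi-species clusters for one clustering.

    Every member of a multi-species cluster counts toward
    ``n_sequences_in_msc``, including same-species duplicates.
    """
    per_cluster = _cluster_species(clustering, species_of)
    all_species = set().union(*per_cluster) if per_cluster else set()
    msc = [
        (cl, sp) for cl, sp in zip(clustering.clusters, per_cluster) if len(sp) >= 2
    ]
    species_in_msc = set().union(*(sp for _, sp in msc)) if msc else set()
    return CollisionStats(
        marker_id=marker_id,
        db_size=db_size if db_size is not None else clustering.n_records,
        replicate=replicate,
        threshold=clustering.threshold,
        n_clusters=clustering.n_clusters,
        n_multi_species_clusters=len(msc),
        n_sequences_in_msc=sum(cl.n_sequences for cl, _ in msc),
        n_species_total=len(all_species),
        n_species_in_msc=len(species_in_msc),
    )


def species_pair_counts(
    clusterings: Iterable[tuple[Clustering, Mapping[str, str]]],
) -> pd.DataFrame:
    """Count how often unordered species pairs co-occur in multi-species
    clusters, aggregated over the given clusterings.

    Each multi-species cluster contributes one count to every unordered
    pair of species it contains.  Returns a frame with columns
    ``species_a``, ``species_b``, ``n_cooccurrences`` sorted by
    descending count (ties alphabetically).
    """
    counts: Counter = Counter()
    for clustering, species_of in clusterings:
        for sp in _cluster_species(clustering, species_of):
            if len(sp) >= 2:
                for a, b in combinations(sorted(sp), 2):
                    counts[(a, b)] += 1
    rows = [
        {"species_a": a, "species_b": b, "n_cooccurrences": n}
        for (a, b), n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["species_a", "species_b", "n_cooccurrences"])


def genus_richness_relation(
    clustering: Clustering,
    species_of: Mapping[str, str],
    genus_of: Mapping[str, str],
) -> tuple[pd.DataFrame, float | None]:
    """Relate each species' multi-species-cluster membership to the species
    richness of its genus within the clustered subset.

    Returns one row per species (``species``, ``genus``,
    ``genus_richness``, ``n_msc_of_species``) plus the Pearson
    correlation between richness and MSC membership, or ``None`` when
    fewer than three species are present or either variable has zero
    variance.  Intended for the final (largest) simulated database, where
    sampling noise is smallest.
    """
    per_cluster = _cluster_species(clustering, species_of)
    universe = sorted(set().union(*per_cluster)) if per_cluster else []
    msc_membership: Counter = Counter()
    for sp in per_cluster:
        if len(sp) >= 2:
            for s in sp:
                msc_membership[s] += 1
    richness: Counter = Counter()
    for s in universe:
        g = genus_of.get(s)
        if g is None:
            raise ValueError(f"species {s!r} has no genus label")
        richness[g] += 1
    rows = [
        {
            "species": s,
            "genus": genus_of[s],
            "genus_richness": richness[genus_of[s]],
            "n_msc_of_species": msc_membership.get(s, 0),
        }
        for s in universe
    ]
    df = pd.DataFrame(rows, columns=["species", "genus", "genus_richness", "n_msc_of_species"])
    corr: float | None = None
    if len(df) >= 3:
        x = df["genus_richness"].to_numpy(float)
        y = df["n_msc_of_species"].to_numpy(float)
        if np.ptp(x) > 0 and np.ptp(y) > 0:
            corr = float(sps.pearsonr(x, y).statistic)
    return df, corr


def multi_marker_species_fraction(
    per_marker: Mapping[str, tuple[Clustering, Mapping[str, str]]],
    k: int,
) -> float:
    """Percentage of species that sit in at least one multi-species cluster
    in at least ``k`` marker families (e.g. 50 of the 120 families).

    The species universe is the union over the given families'
    clusterings.
    """
    if k < 1 or k > len(per_marker):
        raise ValueError(f"k must be in [1, {len(per_marker)}], got {k}")
    universe: set[str] = set()
    hits: Counter = Counter()
    for clustering, species_of in per_marker.values():
        per_cluster = _cluster_species(clustering, species_of)
        universe.update(*per_cluster)
        in_msc = set().union(*(sp for sp in per_cluster if len(sp) >= 2)) if per_cluster else set()
        for s in in_msc:
            hits[s] += 1
    if not universe:
        return 0.0
    n = sum(1 for s in universe if hits.get(s, 0) >= k)
    return 100.0 * n / len(universe)


def stats_table(stats: Sequence[CollisionStats]) -> pd.DataFrame:
    rows = [
        {
            "marker_id": s.marker_id,
            "db_size": s.db_size,
            "replicate": s.replicate,
            "threshold": s.threshold,
            "n_clusters": s.n_clusters,
            "n_multi_species_clusters": s.n_multi_species_clusters,
            "n_sequences_in_msc": s.n_sequences_in_msc,
            "n_species_total": s.n_species_total,
            "n_species_in_msc": s.n_species_in_msc,
            "pct_species_in_msc": s.pct_species_in_msc,
        }
        for s in stats
    ]
    return pd.DataFrame(rows, columns=STATS_COLUMNS)


def aggregate_replicates(table: pd.DataFrame, how: str = "median") -> pd.DataFrame:
    """Aggregate replicate rows per (marker, size, threshold); the default
    median matches how bootstrap experiments are usually reported, mean
    and quartiles are emitted alongside for the key count."""
    if how not in ("median", "mean"):
        raise ValueError("how must be 'median' or 'mean'")
    value_cols = [
        "n_clusters",
        "n_multi_species_clusters",
        "n_sequences_in_msc",
        "n_species_total",
        "n_species_in_msc",
        "pct_species_in_msc",
    ]
    g = table.groupby(["marker_id", "threshold", "db_size"], as_index=False)
    agg = g[value_cols].median() if how == "median" else g[value_cols].mean()
    extra = g["n_sequences_in_msc"].agg(
        n_seq_in_msc_mean="mean",
        n_seq_in_msc_q25=lambda s: s.quantile(0.25),
        n_seq_in_msc_q75=lambda s: s.quantile(0.75),
        n_replicates="count",
    )
    return agg.merge(extra, on=["marker_id", "threshold", "db_size"]).sort_values(
        ["marker_id", "threshold", "db_size"], ignore_index=True
    )
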