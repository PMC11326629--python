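"""Multi-species cluster statistics."""

import numpy as np
import pytest

from collisim.cluster import Cluster, ClusterParams, Clustering, greedy_cluster
from collisim.stats import (
    aggregate_replicates,
    genus_richness_relation,
    multi_marker_species_fraction,
    species_pair_counts,
    stats_table,
    summarize,
)
from collisim.synthetic import FamilySpec, SyntheticConfig, generate


def clustering_of(groups, threshold=1.0):
    """Build a clustering from [[member ids...], ...]; first member is rep."""
    clusters = [Cluster(g[0], list(g)) for g in groups]
    return Clustering(clusters, threshold, sum(len(g) for g in groups))


class TestSummarize:
    def test_single_species_clusters_are_not_collisions(self):
        c = clustering_of([["a1", "a2"], ["b1"]])
        s = summarize(c, {"a1": "A", "a2": "A", "b1": "B"})
        assert (s.n_clusters, s.n_multi_species_clusters, s.n_sequences_in_msc) == (2, 0, 0)
        assert s.pct_species_in_msc == 0.0

    def test_direct_counting_with_duplicates(self):
        c = clustering_of([["a1", "b1"], ["a2"], ["c1", "c2", "d1"]])
        labels = {"a1": "A", "b1": "B", "a2": "A", "c1": "C", "c2": "C", "d1": "D"}
        s = summarize(c, labels)
        assert s.n_multi_species_clusters == 2
        assert s.n_sequences_in_msc == 5  # both C duplicates count individually
        assert s.n_species_in_msc == 4 and s.n_species_total == 4
        assert s.pct_species_in_msc == 100.0

    def test_unlabeled_record_is_an_error(self):
        c = clustering_of([["a1"]])
        with pytest.raises(ValueError, match="no species label"):
            summarize(c, {})

    def test_member_counts_conserve_db_size(self, rng, make_dna):
        cfg = SyntheticConfig(n_genera=2, species_per_genus=3, genomes_per_species=2,
                              families=[FamilySpec("f", 200, 0.0, 1)], seed=2)
        db, truth = generate(cfg)
        recs = [(r.record_id, r.sequence) for r in db.records()]
        for t in (0.95, 1.0):
            c = greedy_cluster(recs, ClusterParams(t))
            s = summarize(c, truth.record_species)
            assert sum(cl.n_sequences for cl in c.clusters) == s.db_size == len(recs)

    def test_planted_collisions_recovered_exactly_at_100(self):
        """With zero intra-species divergence and high inter-species
        divergence, the multi-species clusters at 100% identity are exactly
        the planted verbatim collisions, with exactly the planted group
        sizes."""
        cfg = SyntheticConfig(
            n_genera=4, species_per_genus=2, genomes_per_species=2,
            families=[FamilySpec("f", 400, 0.0, 1)],
            inter_species_divergence=0.25, intra_species_divergence=0.0,
            collision_rate=1.0, seed=6,
        )
        db, truth = generate(cfg)
        k = len(truth.collisions)
        assert k == 4  # one per genus: second species copies the first
        recs = [(r.record_id, r.sequence) for r in db.records()]
        c = greedy_cluster(recs, ClusterParams(1.0))
        s = summarize(c, truth.record_species)
        assert s.n_multi_species_clusters == k
        expected_seqs = sum(
            len(truth.records_of(col.species_src, col.family))
            + len(truth.records_of(col.species_dst, col.family))
            for col in truth.collisions
        )
        assert s.n_sequences_in_msc == expected_seqs


class TestSpeciesPairs:
    def test_triple_cluster_yields_three_pairs(self):
        c = clustering_of([["a", "b", "c"]])
        df = species_pair_counts([(c, {"a": "A", "b": "B", "c": "C"})])
        assert set(map(tuple, df.values)) == {("A", "B", 1), ("A", "C", 1), ("B", "C", 1)}

    def test_counts_accumulate_across_clusterings(self):
        c1 = clustering_of([["a", "b"]])
        c2 = clustering_of([["a2", "b2"]])
        labels = {"a": "A", "b": "B", "a2": "A", "b2": "B"}
        df = species_pair_counts([(c1, labels), (c2, labels)])
        assert df.iloc[0].tolist() == ["A", "B", 2]

    def test_pair_counted_once_per_cluster_not_per_sequence_pair(self):
        c = clustering_of([["a1", "a2", "b1", "b2"]])
        df = species_pair_counts([(c, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})])
        assert df.iloc[0]["n_cooccurrences"] == 1

    def test_planted_pairs_dominate_at_100(self):
        cfg = SyntheticConfig(
            n_genera=3, species_per_genus=3, genomes_per_species=3,
            families=[FamilySpec("f", 300, 0.0, 1)],
            inter_species_divergence=0.3, intra_species_divergence=0.0,
            collision_rate=0.8, seed=12,
        )
        db, truth = generate(cfg)
        recs = [(r.record_id, r.sequence) for r in db.records()]
        c = greedy_cluster(recs, ClusterParams(1.0))
        df = species_pair_counts([(c, truth.record_species)])
        planted = {(a, b) for (a, b, _f), _n in truth.collision_pair_counts().items()}
        observed = {(r.species_a, r.species_b) for r in df.itertuples()}
        assert planted and planted <= observed


class TestGenusRichness:
    def test_all_singletons_have_undefined_correlation(self):
        c = clustering_of([["a"], ["b"], ["c"]])
        labels = {"a": "A", "b": "B", "c": "C"}
        genus = {"A": "G1", "B": "G1", "C": "G2"}
        df, corr = genus_richness_relation(c, labels, genus)
        assert (df["n_msc_of_species"] == 0).all()
        assert corr is None  # zero variance in the response

    def test_collisions_concentrated_in_rich_genus(self):
        # rich genus G1 (3 species) collides; poor genus G2 (1 species) cannot
        c = clustering_of([["a", "b"], ["b2", "c"], ["d"]])
        labels = {"a": "A", "b": "B", "b2": "B", "c": "C", "d": "D"}
        genus = {"A": "G1", "B": "G1", "C": "G1", "D": "G2"}
        df, corr = genus_richness_relation(c, labels, genus)
        by_sp = df.set_index("species")
        assert by_sp.loc["D", "n_msc_of_species"] == 0
        assert by_sp.loc["B", "n_msc_of_species"] == 2
        assert by_sp.loc["A", "genus_richness"] == 3
        assert corr is not None and corr > 0

    def test_richness_collision_correlation_positive_by_construction(self):
        """When planted collision pressure scales with genus size, species of
        rich genera accumulate more multi-species clusters."""
        cfg = SyntheticConfig(
            n_genera=4, species_per_genus=[2, 4, 8, 12], genomes_per_species=2,
            families=[FamilySpec("f", 300, 0.0, 1)],
            inter_species_divergence=0.3, intra_species_divergence=0.0,
            collision_rate=0.5, seed=19,
        )
        db, truth = generate(cfg)
        recs = [(r.record_id, r.sequence) for r in db.records()]
        c = greedy_cluster(recs, ClusterParams(1.0))
        _, corr = genus_richness_relation(c, truth.record_species, truth.genus_of_species)
        assert corr is not None and corr > 0


class TestMultiMarkerFraction:
    def _family(self, msc_species, all_species):
        groups = []
        if msc_species:
            groups.append([f"{s}_1" for s in msc_species])
        groups += [[f"{s}_solo"] for s in all_species]
        labels = {m: m.rsplit("_", 1)[0] for g in groups for m in g}
        return clustering_of(groups), labels

    def test_k1_single_family_reduces_to_pct_species_in_msc(self):
        fam, labels = self._family(["A", "B"], ["A", "B", "C", "D"])
        pct = multi_marker_species_fraction({"f1": (fam, labels)}, k=1)
        assert pct == summarize(fam, labels).pct_species_in_msc == 50.0

    def test_threshold_logic_over_families(self):
        fams = {
            "f1": self._family(["X", "Y"], ["X", "Y", "Z"]),
            "f2": self._family(["X", "Y"], ["X", "Y", "Z"]),
            "f3": self._family(["X", "Z"], ["X", "Y", "Z"]),
        }
        assert multi_marker_species_fraction(fams, k=3) == pytest.approx(100 / 3)
        assert multi_marker_species_fraction(fams, k=2) == pytest.approx(200 / 3)
        with pytest.raises(ValueError):
            multi_marker_species_fraction(fams, k=4)


class TestAggregation:
    def test_monotone_in_planted_collision_count(self):
        """Sequences in multi-species clusters never decrease as the planted
        collision rate rises, all else (seed, structure) fixed."""
        counts = []
        for rate in (0.0, 0.3, 0.6, 1.0):
            cfg = SyntheticConfig(
                n_genera=3, species_per_genus=4, genomes_per_species=2,
                families=[FamilySpec("f", 250, 0.0, 1)],
                inter_species_divergence=0.3, intra_species_divergence=0.0,
                collision_rate=rate, seed=77,
            )
            db, truth = generate(cfg)
            recs = [(r.record_id, r.sequence) for r in db.records()]
            c = greedy_cluster(recs, ClusterParams(1.0))
            counts.append(summarize(c, truth.record_species).n_sequences_in_msc)
        assert counts == sorted(counts)
        assert counts[-1] > counts[0]

    def test_aggregate_replicates_median_and_mean(self):
        rows = []
        for rep, n in enumerate([10, 20, 60]):
            c = clustering_of([[f"x{i}" for i in range(2)]])
            s = summarize(c, {"x0": "A", "x1": "B"}, marker_id="f", replicate=rep, db_size=100)
            rows.append(s)
        table = stats_table(rows).assign(n_sequences_in_msc=[10, 20, 60])
        med = aggregate_replicates(table, how="median")
        assert med["n_sequences_in_msc"].iloc[0] == 20
        assert med["n_seq_in_msc_mean"].iloc[0] == pytest.approx(30)
        assert med["n_replicates"].iloc[0] == 3
        with pytest.raises(ValueError):
            aggregate_replicates(table, how="mode")


class TestThresholdOrdering:
    def test_loose_thresholds_catch_at_least_as_many_species(self):
        """With inter-species divergence graded just below the loosest
        threshold (~2% substitutions), congeneric species co-cluster at 95%
        but not at 100%: the replicate-mean percentage of species in
        multi-species clusters is non-increasing in the threshold."""
        from collisim.cluster import ClusterParams, greedy_cluster

        pcts = {0.95: [], 1.0: []}
        for seed in range(5):
            cfg = SyntheticConfig(
                n_genera=3, species_per_genus=3, genomes_per_species=2,
                families=[FamilySpec("f", 300, 0.0, 1)],
                inter_species_divergence=0.02, intra_species_divergence=0.0,
                collision_rate=0.0, seed=100 + seed,
            )
            db, truth = generate(cfg)
            recs = [(r.record_id, r.sequence) for r in db.records()]
            for t in pcts:
                s = summarize(greedy_cluster(recs, ClusterParams(t)), truth.record_species)
                pcts[t].append(s.pct_species_in_msc)
        import numpy as np

        assert np.mean(pcts[0.95]) >= np.mean(pcts[1.0])
        assert np.mean(pcts[0.95]) > 0  # the graded divergence does merge species
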