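"""Top-hit assignment, homology edges, cluster consolidation and censuses."""

import math

import numpy as np
import pytest

from homeoclust.cluster import (GeneCluster, HomologyEdge, TopHitAssignment,
                                assign_top_hits, build_edges, consolidate,
                                family_census, go_tally, ortholog_candidates,
                                strip_isoform, summarize)
from homeoclust.seqio import HitRecord, ThresholdConfig, ValidationError

from _oracles import transitive_closure_clusters

T = ThresholdConfig()


def hit(q, s, e, bits=500.0, alen=100):
    return HitRecord(query_id=q, subject_id=s, percent_identity=95.0,
                     alignment_length=alen, mismatches=5, gap_opens=0,
                     q_start=1, q_end=alen, s_start=1, s_end=alen,
                     evalue=e, bit_score=bits)


def assign(contig, gene, e=1e-50, bits=500.0, cov=0.9):
    return TopHitAssignment(contig_id=contig, subject_gene_id=gene,
                            evalue=e, bit_score=bits, coverage=cov)


class TestAssignTopHits:
    def test_cutoff_filters(self):
        hits = [hit("c1", "G1", 1e-50), hit("c2", "G2", 1e-3), hit("c3", "G3", 1e-30)]
        out = assign_top_hits(hits, T, {"c1": 100, "c2": 100, "c3": 100})
        assert [a.contig_id for a in out] == ["c1", "c3"]

    def test_best_subject_wins(self):
        hits = [hit("c1", "G1", 1e-7), hit("c1", "G2", 1e-50)]
        (a,) = assign_top_hits(hits, T, {"c1": 100})
        assert a.subject_gene_id == "G2"

    def test_no_hits(self):
        assert assign_top_hits([], T, {}) == []

    def test_missing_query_length_rejected(self):
        with pytest.raises(ValidationError, match="c1"):
            assign_top_hits([hit("c1", "G1", 1e-50)], T, {})

    def test_coverage_from_orf_length(self):
        (a,) = assign_top_hits([hit("c1", "G1", 1e-50, alen=60)], T, {"c1": 120})
        assert a.coverage == pytest.approx(0.5)

    def test_isoform_suffix_stripped(self):
        (a,) = assign_top_hits([hit("c1", "AT1G01010.2", 1e-50)], T, {"c1": 100})
        assert a.subject_gene_id == "AT1G01010"

    def test_strip_isoform_rule(self):
        assert strip_isoform("AT1G01010.12") == "AT1G01010"
        assert strip_isoform("G0001") == "G0001"
        assert strip_isoform("AT1G01010.12", pattern=None) == "AT1G01010.12"


class TestBuildEdges:
    def test_same_bin_edge(self):
        a = [assign("c1", "G1"), assign("c2", "G1")]
        edges = build_edges(a, {frozenset(("c1", "c2")): 1e-120}, T)
        assert len(edges) == 1 and edges[0].evalue == 1e-120

    def test_orientation_minimum_rule(self):
        # the pair E is min over orientations; a callable supplies it directly
        a = [assign("c1", "G1"), assign("c2", "G1")]
        edges = build_edges(a, lambda x, y: min(1e-90, 1e-110), T)
        assert len(edges) == 1

    def test_cutoff_strict(self):
        a = [assign("c1", "G1"), assign("c2", "G1")]
        assert build_edges(a, lambda x, y: 1e-100, T) == []
        assert len(build_edges(a, lambda x, y: 0.99e-100, T)) == 1

    def test_cross_bin_forbidden(self):
        a = [assign("c1", "G1"), assign("c2", "G2")]
        assert build_edges(a, lambda x, y: 0.0, T) == []

    def test_missing_pair_value_rejected(self):
        a = [assign("c1", "G1"), assign("c2", "G1")]
        with pytest.raises(ValidationError, match="c1"):
            build_edges(a, {}, T)

    def test_no_self_edges(self):
        with pytest.raises(ValidationError):
            HomologyEdge("c1", "c1", 1e-120)


class TestConsolidate:
    def test_components_within_bins(self):
        a = [assign(c, "G1") for c in ("c1", "c2", "c3")] + [assign("c4", "G2")]
        edges = [HomologyEdge("c1", "c2", 1e-120), HomologyEdge("c2", "c3", 1e-120)]
        clusters = consolidate(a, edges)
        parts = {c.member_contig_ids for c in clusters}
        assert parts == {frozenset({"c1", "c2", "c3"}), frozenset({"c4"})}

    def test_edgeless_limit_all_singletons(self):
        a = [assign(c, "G1") for c in ("c1", "c2", "c3")]
        clusters = consolidate(a, [])
        assert len(clusters) == 3
        assert all(len(c.member_contig_ids) == 1 for c in clusters)

    def test_dxs_like_family_shape(self):
        """12 contigs of one enzyme family split across 4 subject genes give
        4 clusters (the family-splitting behaviour on synthetic fixtures)."""
        a, edges = [], []
        for g in range(4):
            members = [f"dxs{g}_{i}" for i in range(3)]
            a += [assign(m, f"GDXS{g}") for m in members]
            edges += [HomologyEdge(members[0], members[1], 1e-150),
                      HomologyEdge(members[1], members[2], 1e-150)]
        clusters = consolidate(a, edges)
        assert len(clusters) == 4
        assert sum(len(c.member_contig_ids) for c in clusters) == 12

    def test_representative_minimal_evalue_then_bits_then_name(self):
        a = [assign("c1", "G1", e=1e-50, bits=400), assign("c2", "G1", e=1e-80, bits=300),
             assign("c3", "G1", e=1e-80, bits=350)]
        edges = [HomologyEdge("c1", "c2", 1e-120), HomologyEdge("c2", "c3", 1e-120)]
        (c,) = consolidate(a, edges)
        assert c.representative_contig_id == "c3"  # lowest E, then higher bits

    def test_deterministic_ids_and_permutation_invariance(self):
        rng = np.random.default_rng(0)
        a = [assign(f"c{i}", f"G{i % 3}") for i in range(12)]
        edges = [HomologyEdge(f"c{i}", f"c{i + 3}", 1e-150) for i in range(6)]
        base = consolidate(a, edges)
        for _ in range(5):
            pa = list(a)
            pe = list(edges)
            rng.shuffle(pa)
            rng.shuffle(pe)
            again = consolidate(pa, pe)
            assert [(c.cluster_id, c.member_contig_ids) for c in again] == \
                   [(c.cluster_id, c.member_contig_ids) for c in base]

    def test_matches_bruteforce_closure_on_random_instances(self):
        """Partition equals exhaustive transitive closure on random instances."""
        rng = np.random.default_rng(1)
        for trial in range(200):
            n = int(rng.integers(2, 50))
            contigs = [f"c{i}" for i in range(n)]
            bins = {c: f"G{rng.integers(0, max(1, n // 4))}" for c in contigs}
            a = [assign(c, bins[c]) for c in contigs]
            edges = []
            edge_set = set()
            for _ in range(int(rng.integers(0, 2 * n))):
                i, j = rng.integers(0, n, size=2)
                x, y = contigs[i], contigs[j]
                if x != y and bins[x] == bins[y] and frozenset((x, y)) not in edge_set:
                    edge_set.add(frozenset((x, y)))
                    edges.append(HomologyEdge(x, y, 1e-150))
            ours = {c.member_contig_ids for c in consolidate(a, edges)}
            oracle = transitive_closure_clusters(bins, edge_set)
            assert ours == oracle, trial

    def test_partition_property(self):
        rng = np.random.default_rng(2)
        contigs = [f"c{i}" for i in range(30)]
        a = [assign(c, f"G{rng.integers(0, 5)}") for c in contigs]
        bins = {x.contig_id: x.subject_gene_id for x in a}
        edges = [HomologyEdge(x, y, 1e-150)
                 for x in contigs for y in contigs
                 if x < y and bins[x] == bins[y] and rng.random() < 0.2]
        clusters = consolidate(a, edges)
        seen = [m for c in clusters for m in c.member_contig_ids]
        assert sorted(seen) == sorted(contigs)  # disjoint and covering

    def test_edge_monotonicity(self):
        """Adding an edge never increases the cluster count; removing one
        never decreases it."""
        rng = np.random.default_rng(3)
        contigs = [f"c{i}" for i in range(20)]
        a = [assign(c, f"G{rng.integers(0, 3)}") for c in contigs]
        bins = {x.contig_id: x.subject_gene_id for x in a}
        candidates = [(x, y) for x in contigs for y in contigs
                      if x < y and bins[x] == bins[y]]
        rng.shuffle(candidates)
        edges = []
        prev = len(consolidate(a, edges))
        for x, y in candidates[:15]:
            edges.append(HomologyEdge(x, y, 1e-150))
            cur = len(consolidate(a, edges))
            assert cur <= prev
            prev = cur

    def test_cross_bin_edge_rejected(self):
        a = [assign("c1", "G1"), assign("c2", "G2")]
        with pytest.raises(ValidationError):
            consolidate(a, [HomologyEdge("c1", "c2", 1e-150)])


class TestOrthologCandidates:
    def test_boundary_semantics(self):
        kept = ortholog_candidates([assign("c1", "G1", e=1e-50, bits=200, cov=0.5)], T)
        assert len(kept) == 1
        dropped = ortholog_candidates([assign("c1", "G1", e=1e-50, bits=150, cov=0.5)], T)
        assert dropped == []  # score must be strictly > 150
        assert len(ortholog_candidates([assign("c1", "G1", bits=151, cov=0.5)], T)) == 1
        assert ortholog_candidates([assign("c1", "G1", bits=200, cov=0.19)], T) == []
        assert len(ortholog_candidates([assign("c1", "G1", bits=200, cov=0.20)], T)) == 1


class TestSummaries:
    def make_clusters(self, sizes_per_gene):
        clusters = []
        i = 0
        for g, sizes in sizes_per_gene.items():
            for k, size in enumerate(sizes, 1):
                members = frozenset(f"c{i + j}" for j in range(size))
                i += size
                clusters.append(GeneCluster(cluster_id=f"{g}.{k}", subject_gene_id=g,
                                            member_contig_ids=members,
                                            representative_contig_id=min(members)))
        return clusters

    def test_ratio_one_third(self):
        clusters = self.make_clusters({"G1": [3], "G2": [3], "G3": [3]})
        s = summarize(clusters, n_contigs_total=12)
        assert s.n_assigned == 9 and s.n_clusters == 3
        assert s.cluster_ratio == pytest.approx(1 / 3)
        assert s.n_subject_genes == 3

    def test_zero_clusters_sentinel(self):
        s = summarize([], n_contigs_total=5)
        assert math.isnan(s.cluster_ratio) and s.n_clusters == 0

    def test_count_ordering_invariant(self):
        clusters = self.make_clusters({"G1": [2, 1], "G2": [4]})
        s = summarize(clusters, 10)
        assert s.n_subject_genes <= s.n_clusters <= s.n_assigned

    def test_family_census_tps_like_shape(self):
        """46 contigs in 30 components labelled TPS count as (46, 30)."""
        sizes = [2] * 16 + [1] * 14  # 46 contigs, 30 clusters
        clusters = self.make_clusters({f"GT{i}": [s] for i, s in enumerate(sizes)})
        table = {f"GT{i}": "TPS" for i in range(30)}
        census = family_census(clusters, table)
        assert census["TPS"] == (46, 30)

    def test_family_census_unassigned(self):
        clusters = self.make_clusters({"G1": [1]})
        assert family_census(clusters, {}) == {"unassigned": (1, 1)}


class TestGoTally:
    def test_incidence_arithmetic(self):
        a = [assign("c1", "g1"), assign("c2", "g2")]
        table = {"g1": {"cellular_component": ["nucleus"]},
                 "g2": {"cellular_component": ["nucleus", "chloroplast"]}}
        out = go_tally(a, table)
        assert out["cellular_component"]["nucleus"] == pytest.approx(2 / 3)
        assert out["cellular_component"]["chloroplast"] == pytest.approx(1 / 3)

    def test_fractions_sum_to_one(self):
        a = [assign(f"c{i}", f"g{i % 3}") for i in range(9)]
        table = {"g0": {"molecular_function": ["kinase", "binding"]},
                 "g1": {"molecular_function": ["binding"]}}
        out = go_tally(a, table)
        assert sum(out["molecular_function"].values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_assignments(self):
        assert go_tally([], {"g": {"ns": ["x"]}}) == {"ns": {}}

    def test_unannotated_genes_are_unknown(self):
        out = go_tally([assign("c1", "gX")], {"g1": {"biological_process": ["growth"]}})
        assert out["biological_process"]["unknown"] == pytest.approx(1.0)
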