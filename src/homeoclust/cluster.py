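"""Gene-cluster consolidation of polyploid transcriptome contigs.

A *gene cluster* is a set of contigs that (a) share the same best reference
top-hit gene at E < 1e-5 and (b) are connected by pairwise translated
homology edges at E < 1e-100 (single linkage: membership only requires high
homology to at least one other member, so clusters are the connected
components of the edge graph within each top-hit bin). In an allohexaploid
the three homeologous copies of a gene are expected to collapse into one
cluster, so the number of clusters approximates the number of underlying
genes — roughly one third of the number of annotated contigs.
"""

from __future__ import annotations

import math
import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx

from homeoclust.seqio import HitRecord, ThresholdConfig, ValidationError

_ISOFORM_SUFFIX = re.compile(r"\.\d+$")


def strip_isoform(subject_id: str, pattern: re.Pattern | None = _ISOFORM_SUFFIX) -> str:
    """Collapse an isoform identifier to its gene/locus identifier.

    Default rule strips one trailing ``.<digits>`` suffix (the common
    locus.isoform convention); pass ``pattern=None`` to disable.
    """
    if pattern is None:
        return subject_id
    return pattern.sub("", subject_id)


@dataclass(frozen=True)
class TopHitAssignment:
    """A contig's best reference gene under the annotation cutoff."""

    contig_id: str
    subject_gene_id: str
    evalue: float
    bit_score: float
    coverage: float

    def __post_init__(self):
        if not (0 < self.coverage <= 1):
            raise ValidationError(f"coverage out of (0,1] for {self.contig_id}")


@dataclass(frozen=True)
class HomologyEdge:
    """An unordered within-bin contig pair with edge-qualifying homology."""

    contig_a: str
    contig_b: str
    evalue: float

    def __post_init__(self):
        if self.contig_a == self.contig_b:
            raise ValidationError(f"self-edge on {self.contig_a}")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.contig_a, self.contig_b))


@dataclass(frozen=True)
class GeneCluster:
    """A reference-gene-binned connected component of contigs."""

    cluster_id: str
    subject_gene_id: str
    member_contig_ids: frozenset
    representative_contig_id: str

    def __post_init__(self):
        if not self.member_contig_ids:
            raise ValidationError(f"cluster {self.cluster_id} has no members")
        if self.representative_contig_id not in self.member_contig_ids:
            raise ValidationError(f"representative not a member in {self.cluster_id}")


@dataclass(frozen=True)
class ClusterSummary:
    n_contigs_total: int
    n_assigned: int
    n_clusters: int
    n_subject_genes: int
    cluster_ratio: float  # NaN when nothing was assigned

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def assign_top_hits(hits: Sequence[HitRecord], thresholds: ThresholdConfig,
                    query_lengths: Mapping[str, int],
                    isoform_pattern: re.Pattern | None = _ISOFORM_SUFFIX
                    ) -> list[TopHitAssignment]:
    """Pick each contig's top hit (strict E cutoff) at gene/locus granularity.

    ``query_lengths`` maps each query id to the residue length of its
    translated query (the longest ORF); coverage is
    alignment_length / query ORF length, capped at 1 for gapped alignments
    longer than the query.
    """
    from homeoclust.homology import top_hit

    for h in hits:
        if h.query_id not in query_lengths:
            raise ValidationError(f"query {h.query_id!r} missing from query_lengths")
    winners = top_hit(hits, thresholds.tophit_evalue_max)
    out = []
    for contig_id in sorted(winners):
        h = winners[contig_id]
        coverage = min(1.0, h.alignment_length / query_lengths[contig_id])
        out.append(TopHitAssignment(
            contig_id=contig_id,
            subject_gene_id=strip_isoform(h.subject_id, isoform_pattern),
            evalue=h.evalue, bit_score=h.bit_score, coverage=coverage))
    return out


def build_edges(assignments: Sequence[TopHitAssignment],
                pair_evalue: Callable[[str, str], float] | Mapping,
                thresholds: ThresholdConfig) -> list[HomologyEdge]:
    """Homology edges between same-bin contig pairs at E < edge cutoff.

    ``pair_evalue`` is either a callable ``(contig_a, contig_b) -> E``
    expected to already return the minimum over the two query/subject
    orientations, or a mapping keyed by frozenset pairs (missing same-bin
    pairs raise). Cross-bin edges are never formed; each unordered pair
    appears at most once.
    """
    bins: dict[str, list[str]] = defaultdict(list)
    for a in assignments:
        bins[a.subject_gene_id].append(a.contig_id)
    lookup: Callable[[str, str], float]
    if callable(pair_evalue):
        lookup = pair_evalue
    else:
        table = pair_evalue

        def lookup(x: str, y: str) -> float:
            key = frozenset((x, y))
            if key not in table:
                raise ValidationError(f"pair E-value missing for {sorted(key)}")
            return table[key]

    edges = []
    for gene in sorted(bins):
        members = sorted(bins[gene])
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                e = lookup(a, b)
                if e < thresholds.edge_evalue_max:
                    edges.append(HomologyEdge(contig_a=a, contig_b=b, evalue=e))
    return edges


def consolidate(assignments: Sequence[TopHitAssignment],
                edges: Sequence[HomologyEdge]) -> list[GeneCluster]:
    """Connected components of the edge graph within each top-hit bin.

    Isolated assigned contigs become singleton clusters. The representative
    is the member with the minimal top-hit E-value (ties: highest bit score,
    then lexicographically smallest contig id). Cluster ids are
    ``<gene>.<ordinal>`` with ordinals assigned by each component's smallest
    member id, so the output is deterministic and input-order independent.
    """
    by_contig = {a.contig_id: a for a in assignments}
    if len(by_contig) != len(assignments):
        raise ValidationError("duplicate contig in assignments")
    graph = nx.Graph()
    graph.add_nodes_from(by_contig)
    for e in edges:
        if e.contig_a not in by_contig or e.contig_b not in by_contig:
            raise ValidationError(f"edge endpoint not assigned: {e.contig_a}/{e.contig_b}")
        if by_contig[e.contig_a].subject_gene_id != by_contig[e.contig_b].subject_gene_id:
            raise ValidationError(f"cross-bin edge {e.contig_a}/{e.contig_b}")
        graph.add_edge(e.contig_a, e.contig_b)
    per_gene: dict[str, list[frozenset]] = defaultdict(list)
    for component in nx.connected_components(graph):
        gene = by_contig[next(iter(component))].subject_gene_id
        per_gene[gene].append(frozenset(component))
    clusters = []
    for gene in sorted(per_gene):
        components = sorted(per_gene[gene], key=min)
        for ordinal, members in enumerate(components, start=1):
            rep = min(members, key=lambda c: (by_contig[c].evalue, -by_contig[c].bit_score, c))
            clusters.append(GeneCluster(
                cluster_id=f"{gene}.{ordinal}", subject_gene_id=gene,
                member_contig_ids=members, representative_contig_id=rep))
    return clusters


def ortholog_candidates(assignments: Sequence[TopHitAssignment],
                        thresholds: ThresholdConfig) -> list[TopHitAssignment]:
    """Assignments strong enough for phylogenetic/ortholog analysis.

    Keeps E < tophit cutoff AND bit score strictly > the score threshold
    (150 itself fails) AND coverage >= the coverage floor (0.20 itself
    passes).
    """
    return [a for a in assignments
            if a.evalue < thresholds.tophit_evalue_max
            and a.bit_score > thresholds.ortholog_score_min
            and a.coverage >= thresholds.ortholog_coverage_min]


def summarize(clusters: Sequence[GeneCluster], n_contigs_total: int) -> ClusterSummary:
    """Cluster census: counts and the clusters-per-assigned-contig ratio."""
    n_assigned = sum(len(c.member_contig_ids) for c in clusters)
    n_clusters = len(clusters)
    n_genes = len({c.subject_gene_id for c in clusters})
    ratio = n_clusters / n_assigned if n_assigned else math.nan
    return ClusterSummary(n_contigs_total=n_contigs_total, n_assigned=n_assigned,
                          n_clusters=n_clusters, n_subject_genes=n_genes,
                          cluster_ratio=ratio)


def family_census(clusters: Sequence[GeneCluster],
                  family_table: Mapping[str, str]) -> dict[str, tuple[int, int]]:
    """Per-family (n_contigs, n_clusters); genes absent from the table count
    under "unassigned"."""
    contigs: dict[str, int] = defaultdict(int)
    ncl: dict[str, int] = defaultdict(int)
    for c in clusters:
        family = family_table.get(c.subject_gene_id, "unassigned")
        contigs[family] += len(c.member_contig_ids)
        ncl[family] += 1
    return {fam: (contigs[fam], ncl[fam]) for fam in sorted(contigs)}


def go_tally(assignments: Sequence[TopHitAssignment],
             go_table: Mapping[str, Mapping[str, Iterable[str]]]
             ) -> dict[str, dict[str, float]]:
    """GO-slim category proportions per namespace over assignment incidences.

    ``go_table`` maps gene -> namespace -> categories. Each
    (assignment, category) incidence counts once; fractions within a
    namespace sum to 1. Genes missing from the table contribute an "unknown"
    incidence to every namespace seen in the table (or to all three standard
    namespaces when the table is empty).
    """
    namespaces = sorted({ns for gene in go_table.values() for ns in gene}) or [
        "biological_process", "cellular_component", "molecular_function"]
    counts: dict[str, dict[str, int]] = {ns: defaultdict(int) for ns in namespaces}
    for a in assignments:
        entry = go_table.get(a.subject_gene_id)
        for ns in namespaces:
            cats = list(entry.get(ns, [])) if entry is not None else []
            if not cats:
                counts[ns]["unknown"] += 1
            else:
                for cat in cats:
                    counts[ns][cat] += 1
    out: dict[str, dict[str, float]] = {}
    for ns in namespaces:
        total = sum(counts[ns].values())
        out[ns] = ({cat: c / total for cat, c in sorted(counts[ns].items())}
                   if total else {})
    return out
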