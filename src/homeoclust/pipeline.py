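"""End-to-end orchestration: trim -> ORFs -> search -> cluster -> evaluate.

The analytic path is deterministic given inputs and configuration (the only
randomness in the package lives in the simulator and the bootstrap, both
seeded). Every run emits a manifest with the configuration snapshot, a
config hash, and per-stage record counts so that stage bookkeeping is
reconcilable, in the spirit of a read-filtering summary table.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from homeoclust import __version__
from homeoclust.cluster import (TopHitAssignment, assign_top_hits, build_edges,
                                consolidate, summarize)
from homeoclust.homology import (KmerIndex, ScoringScheme, contig_pair_homology,
                                 search_translated_query)
from homeoclust.orf import DEFAULT_MIN_AA, longest_orf
from homeoclust.seqio import (SequenceRecord, ThresholdConfig, write_clusters,
                              write_tabular_hits)

logger = logging.getLogger("homeoclust")


def config_hash(thresholds: ThresholdConfig, scheme: ScoringScheme,
                min_orf_aa: int) -> str:
    payload = json.dumps({**asdict(thresholds), **asdict(scheme),
                          "min_orf_aa": min_orf_aa}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    clusters: list
    summary: Mapping
    manifest: Mapping
    assignments: list[TopHitAssignment]
    hits: list


def run_pipeline(contigs: Sequence[SequenceRecord],
                 proteins: Sequence[SequenceRecord],
                 thresholds: ThresholdConfig = ThresholdConfig(),
                 scheme: ScoringScheme = ScoringScheme(),
                 min_orf_aa: int = DEFAULT_MIN_AA,
                 exhaustive: bool = False,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Cluster assembled contigs against a reference proteome.

    Stages: longest-ORF extraction per contig; translated search of every
    contig against the proteome (k-mer seeded unless ``exhaustive``); strict
    top-hit assignment; within-bin pairwise translated homology edges at the
    stringent edge cutoff (minimum E over the two query/subject
    orientations); connected-component consolidation. When ``out_dir`` is
    given, writes clusters.tsv, hits.tsv, summary.json and manifest.json.
    """
    contigs = list(contigs)
    proteins = list(proteins)
    stage_counts: dict[str, int] = {"contigs_in": len(contigs), "proteins_in": len(proteins)}
    if contigs and not proteins:
        raise ValueError("protein database must be non-empty")

    orfs = {}
    for c in contigs:
        orf = longest_orf(c, min_orf_aa)
        if orf is not None:
            orfs[c.id] = orf
    stage_counts["contigs_with_orf"] = len(orfs)
    logger.info("stage=orf contigs=%d with_orf=%d", len(contigs), len(orfs))

    index = KmerIndex(proteins) if proteins and not exhaustive else None
    hits = []
    for c in contigs:
        if c.id not in orfs:
            continue
        hits.extend(search_translated_query(
            c, proteins, scheme, min_orf_aa, exhaustive=exhaustive, index=index))
    stage_counts["hits"] = len(hits)
    logger.info("stage=search hits=%d", len(hits))

    query_lengths = {cid: len(orf.peptide) for cid, orf in orfs.items()}
    assignments = assign_top_hits(hits, thresholds, query_lengths)
    stage_counts["assigned_contigs"] = len(assignments)
    logger.info("stage=tophit assigned=%d", len(assignments))

    by_id = {c.id: c for c in contigs}

    def pair_e(a: str, b: str) -> float:
        e_ab = contig_pair_homology(orfs[a], by_id[b], scheme)
        e_ba = contig_pair_homology(orfs[b], by_id[a], scheme)
        return min(e_ab, e_ba)

    edges = build_edges(assignments, pair_e, thresholds)
    stage_counts["edges"] = len(edges)
    logger.info("stage=edges edges=%d", len(edges))

    clusters = consolidate(assignments, edges)
    stage_counts["clusters"] = len(clusters)
    summary = summarize(clusters, n_contigs_total=len(contigs)).to_dict()
    logger.info("stage=cluster clusters=%d ratio=%s", len(clusters),
                summary["cluster_ratio"])

    # reconciliation: nothing silently dropped between stages
    assert stage_counts["assigned_contigs"] == summary["n_assigned"]
    assert stage_counts["contigs_with_orf"] <= stage_counts["contigs_in"]

    manifest = {
        "version": __version__,
        "config": {**asdict(thresholds), **asdict(scheme), "min_orf_aa": min_orf_aa,
                   "exhaustive": exhaustive},
        "config_hash": config_hash(thresholds, scheme, min_orf_aa),
        "stage_counts": stage_counts,
        "unassigned_contigs": len(contigs) - len(assignments),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_clusters(out_dir / "clusters.tsv", clusters)
        write_tabular_hits(out_dir / "hits.tsv", hits)
        (out_dir / "summary.json").write_text(_dump(summary))
        (out_dir / "manifest.json").write_text(_dump(manifest))
        manifest["output_dir"] = str(out_dir)
    return PipelineResult(clusters=clusters, summary=summary, manifest=manifest,
                          assignments=assignments, hits=hits)


def _sanitize(obj):
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    return obj


def _dump(obj) -> str:
    return json.dumps(_sanitize(obj), indent=2, sort_keys=True) + "\n"
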