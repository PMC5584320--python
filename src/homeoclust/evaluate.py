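"""Score recovered gene clusters against simulator ground truth.

All metrics are pair-counting metrics over the same contig universe:
precision/recall over unordered co-clustered pairs, and the adjusted Rand
index (agreement corrected for chance) computed from the contingency table
of the two partitions. Contigs the pipeline left unclustered (no top hit)
are treated as singletons so the universes stay comparable; their count is
reported separately so assignment failures stay visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from homeoclust.seqio import ValidationError


@dataclass(frozen=True)
class RecoveryReport:
    n_true_genes: int
    n_clusters: int
    pair_precision: float
    pair_recall: float
    adjusted_rand: float
    gene_count_error: float
    n_unassigned: int = 0

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _check_universe(truth: Mapping[str, str], predicted: Mapping[str, str]) -> None:
    if set(truth) != set(predicted):
        diff = sorted(set(truth) ^ set(predicted))
        raise ValidationError(f"contig universes differ; symmetric difference: {diff[:20]}"
                              + (" ..." if len(diff) > 20 else ""))


def _contingency(truth: Mapping[str, str], predicted: Mapping[str, str]) -> np.ndarray:
    keys = sorted(truth)
    t = pd.Categorical([truth[k] for k in keys])
    p = pd.Categorical([predicted[k] for k in keys])
    return pd.crosstab(t, p).to_numpy()


def _comb2(x: np.ndarray) -> np.ndarray:
    return x * (x - 1) / 2.0


def pair_metrics(truth: Mapping[str, str], predicted: Mapping[str, str]
                 ) -> tuple[float, float]:
    """Pairwise precision and recall of a predicted partition.

    Over all unordered contig pairs: precision = fraction of co-clustered
    pairs that are truly same-gene; recall = fraction of same-gene pairs
    recovered as co-clustered. Either is 1.0 by convention when its
    denominator is empty (no co-clustered / no same-gene pairs).
    """
    _check_universe(truth, predicted)
    m = _contingency(truth, predicted)
    together_true = _comb2(m.sum(axis=1)).sum()
    together_pred = _comb2(m.sum(axis=0)).sum()
    together_both = _comb2(m).sum()
    precision = together_both / together_pred if together_pred else 1.0
    recall = together_both / together_true if together_true else 1.0
    return float(precision), float(recall)


def adjusted_rand(truth: Mapping[str, str], predicted: Mapping[str, str]) -> float:
    """Adjusted Rand index: (Index - Expected) / (Max - Expected).

    Computed from the contingency table of the two partitions. Returns NaN
    for fewer than two contigs (undefined), and 1.0 when both partitions are
    identical degenerate partitions (all-singletons or all-together), the
    conventional limit.
    """
    _check_universe(truth, predicted)
    if len(truth) < 2:
        return math.nan
    m = _contingency(truth, predicted)
    n = m.sum()
    index = _comb2(m).sum()
    a = _comb2(m.sum(axis=1)).sum()
    b = _comb2(m.sum(axis=0)).sum()
    total = _comb2(np.array(n, dtype=float))
    expected = a * b / total
    maximum = (a + b) / 2.0
    if maximum == expected:
        return 1.0
    return float((index - expected) / (maximum - expected))


def score_recovery(truth: Mapping[str, str], clusters: Sequence,
                   universe: Sequence[str] | None = None) -> RecoveryReport:
    """Full recovery report for a clustering against ground-truth gene labels.

    ``truth`` maps contig -> true gene; ``clusters`` are
    :class:`~homeoclust.cluster.GeneCluster` objects. Contigs in the truth
    universe missing from every cluster are scored as singletons and counted
    in ``n_unassigned``. ``gene_count_error`` compares the number of clusters
    (including those singletons) with the number of true genes.
    """
    predicted: dict[str, str] = {}
    for c in clusters:
        for contig in c.member_contig_ids:
            if contig in predicted:
                raise ValidationError(f"contig {contig} appears in two clusters")
            predicted[contig] = c.cluster_id
    unknown = [c for c in predicted if c not in truth]
    if unknown:
        raise ValidationError(f"clustered contigs missing from truth: {sorted(unknown)[:10]}")
    n_unassigned = 0
    for contig in truth:
        if contig not in predicted:
            predicted[contig] = f"__singleton__{contig}"
            n_unassigned += 1
    precision, recall = pair_metrics(truth, predicted)
    ari = adjusted_rand(truth, predicted)
    n_true = len(set(truth.values()))
    n_clusters = len(set(predicted.values()))
    return RecoveryReport(
        n_true_genes=n_true, n_clusters=n_clusters,
        pair_precision=precision, pair_recall=recall, adjusted_rand=ari,
        gene_count_error=abs(n_clusters - n_true) / n_true if n_true else math.nan,
        n_unassigned=n_unassigned)
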