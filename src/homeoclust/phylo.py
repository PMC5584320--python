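"""Neighbor-joining phylogenies with bootstrap support from protein alignments.

Distances default to the p-distance with pairwise deletion (only columns
where neither sequence is gapped are compared); an optional Kimura protein
correction is available. Trees follow the Saitou-Nei agglomeration with the
usual Q-criterion and branch-length formulas, deterministic lowest-index
tie-breaks, and negative branch lengths clamped to zero with the deficit
moved to the sibling edge. Bootstrap support is the percentage of
column-resampled replicate trees containing each internal bipartition of the
full-data tree, annotated as integer internal-node labels in the newick
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skbio import TreeNode

from homeoclust.seqio import SequenceRecord, ValidationError


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(d)):
            raise ValidationError("distance matrix entries must be finite")
        if not np.allclose(d, d.T):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        if (d < 0).any():
            raise ValidationError("distances must be non-negative")

    @property
    def size(self) -> int:
        return len(self.labels)


def _check_alignment(records: Sequence[SequenceRecord]) -> int:
    lengths = {len(r) for r in records}
    if len(lengths) != 1:
        raise ValidationError("aligned records must all have the same length")
    (length,) = lengths
    if length < 1:
        raise ValidationError("alignment must have at least one column")
    return length


def p_distance(alignment: Sequence[SequenceRecord], kimura: bool = False) -> DistanceMatrix:
    """Pairwise protein distances under pairwise deletion.

    d[i][j] = mismatches / compared columns over columns where neither
    sequence has a gap ('-' or '.'). With ``kimura=True`` the Kimura protein
    correction -ln(1 - p - p^2/5) is applied. A pair with zero comparable
    columns is an error naming the pair.
    """
    _check_alignment(alignment)
    chars = np.array([list(r.residues) for r in alignment])
    gap = (chars == "-") | (chars == ".")
    n = len(alignment)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            comparable = int(ok.sum())
            if comparable == 0:
                raise ValidationError(
                    f"no comparable columns between {alignment[i].id!r} and {alignment[j].id!r}")
            p = float((chars[i, ok] != chars[j, ok]).sum()) / comparable
            if kimura:
                arg = 1.0 - p - 0.2 * p * p
                if arg <= 0:
                    raise ValidationError(
                        f"Kimura correction undefined at p={p:.3f} for "
                        f"{alignment[i].id!r} vs {alignment[j].id!r}")
                p = -math.log(arg)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(labels=tuple(r.id for r in alignment), d=d)


def nj(matrix: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (Saitou-Nei) from a distance matrix.

    Agglomerates by minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j with the
    lowest-index pair breaking Q ties; the final three lineages are joined at
    an unrooted trifurcation with closed-form terminal branch lengths.
    Negative branch lengths are clamped to zero and the deficit added to the
    sibling edge so leaf-to-leaf path lengths are preserved.
    """
    if matrix.size < 3:
        raise ValidationError("neighbor joining requires at least 3 taxa")
    d = matrix.d.copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in matrix.labels]
    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)  # row-major => lowest index pair
        if i > j:
            i, j = j, i
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length, b.length = li, lj
        parent.extend([a, b])
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([
            np.hstack([d[np.ix_(keep, keep)], new_row[keep][:, None]]),
            np.hstack([new_row[keep], [0.0]]),
        ])
        nodes = [nodes[k] for k in keep] + [parent]
    # final unrooted trifurcation: closed-form terminal branches
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    la, lb, lc = _clamp_triple(la, lb, lc)
    root = TreeNode()
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = length
        root.append(node)
    return root


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def _clamp_triple(la: float, lb: float, lc: float) -> tuple[float, float, float]:
    vals = [la, lb, lc]
    for i in range(3):
        if vals[i] < 0:
            deficit = vals[i] / 2.0
            vals[i] = 0.0
            for j in range(3):
                if j != i:
                    vals[j] = vals[j] + deficit
    return tuple(max(v, 0.0) for v in vals)


def _bipartitions(tree: TreeNode, labels: frozenset) -> dict[frozenset, TreeNode]:
    """Internal-edge bipartitions as canonical leaf sets.

    Each internal edge is represented by the side of the split NOT containing
    the alphabetically first label, making the representation root-invariant.
    """
    anchor = min(labels)
    out: dict[frozenset, TreeNode] = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(labels - side) < 2:
            continue  # trivial split
        if anchor in side:
            side = labels - side
        out[side] = node
    return out


def bootstrap_support(alignment: Sequence[SequenceRecord], replicates: int = 1000,
                      rng_seed: int = 0, kimura: bool = False) -> TreeNode:
    """NJ tree of the full alignment with bootstrap supports on internal nodes.

    Columns are resampled with replacement ``replicates`` times; support is
    the integer percentage of replicate trees containing each internal
    bipartition of the full-data tree, stored as the internal node name (and
    therefore serialized as internal newick labels). Reproducible under
    ``rng_seed``.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    length = _check_alignment(alignment)
    if length < 2:
        raise ValidationError("alignment must have at least 2 columns")
    labels = frozenset(r.id for r in alignment)
    full = nj(p_distance(alignment, kimura=kimura))
    target = _bipartitions(full, labels)
    counts = {side: 0 for side in target}
    rng = np.random.default_rng(rng_seed)
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        resampled = [
            SequenceRecord(id=r.id, residues="".join(r.residues[c] for c in cols),
                           alphabet=r.alphabet)
            for r in alignment
        ]
        try:
            rep_tree = nj(p_distance(resampled, kimura=kimura))
        except ValidationError:
            continue  # replicate with an all-gap pair carries no signal
        rep_sides = set(_bipartitions(rep_tree, labels))
        for side in counts:
            if side in rep_sides:
                counts[side] += 1
    for side, node in target.items():
        node.name = str(round(100.0 * counts[side] / replicates))
    return full
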