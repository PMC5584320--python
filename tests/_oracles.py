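"""Independent reference implementations used only as test oracles.

Everything here is deliberately naive (quadratic DP, exhaustive enumeration,
explicit pair counting) and shares no code with the package paths it checks.
"""

from __future__ import annotations

from itertools import combinations

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def score_pair(a: str, b: str) -> int:
    if a == "X" or b == "X":
        return 0
    return int(_B62[a, b])


def sw_reference(a: str, b: str, gap_open: int = 11, gap_ext: int = 1) -> int:
    """Plain O(n*m) affine-gap Smith-Waterman, score only.

    A gap of length k costs gap_open + (k-1)*gap_ext.
    """
    la, lb = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (lb + 1) for _ in range(la + 1)]
    E = [[NEG] * (lb + 1) for _ in range(la + 1)]
    F = [[NEG] * (lb + 1) for _ in range(la + 1)]
    best = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_ext)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_ext)
            H[i][j] = max(0.0, H[i - 1][j - 1] + score_pair(a[i - 1], b[j - 1]),
                          E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


def longest_orf_bruteforce(nt: str) -> int:
    """Length (aa) of the longest stop-free codon window over all 6 frames."""
    from Bio.Seq import Seq

    best = 0
    for seq in (nt, str(Seq(nt).reverse_complement())):
        for offset in range(3):
            frame = seq[offset:]
            frame = frame[: len(frame) - len(frame) % 3]
            pep = str(Seq(frame).translate())
            for run in pep.split("*"):
                best = max(best, len(run))
    return best


def transitive_closure_clusters(bins: dict[str, str],
                                edges: set[frozenset]) -> set[frozenset]:
    """Brute-force single-linkage closure within top-hit bins.

    ``bins`` maps contig -> gene; edges between different bins are ignored
    (the real path refuses them, the oracle simply drops them). Repeatedly
    merges any two groups connected by an edge until a fixed point.
    """
    groups = [{c} for c in bins]
    changed = True
    while changed:
        changed = False
        for i, j in combinations(range(len(groups)), 2):
            gi, gj = groups[i], groups[j]
            if any(frozenset((x, y)) in edges and bins[x] == bins[y]
                   for x in gi for y in gj):
                groups[i] = gi | gj
                del groups[j]
                changed = True
                break
    return {frozenset(g) for g in groups}


def pair_counts(truth: dict[str, str], pred: dict[str, str]) -> tuple[int, int, int, int]:
    """(both, truth-only, pred-only, neither) unordered-pair agreement counts."""
    both = t_only = p_only = neither = 0
    for x, y in combinations(sorted(truth), 2):
        same_t = truth[x] == truth[y]
        same_p = pred[x] == pred[y]
        if same_t and same_p:
            both += 1
        elif same_t:
            t_only += 1
        elif same_p:
            p_only += 1
        else:
            neither += 1
    return both, t_only, p_only, neither


def random_additive_matrix(rng, n_taxa: int = 8):
    """A random binary tree and the exact leaf-to-leaf path-length matrix.

    Returns (labels, matrix, splits) where splits is the set of non-trivial
    bipartitions, each canonicalized as the side not containing labels[0].
    """
    import numpy as np

    labels = [f"T{i}" for i in range(n_taxa)]
    # grow a tree as a list of (children of each internal node); simulate by
    # successively joining random cluster pairs, recording member sets
    clusters = [{lab} for lab in labels]
    dist = np.zeros((n_taxa, n_taxa))
    # track per-leaf depth from its current cluster root
    depth = {lab: 0.0 for lab in labels}
    splits = set()
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        bi = float(rng.uniform(0.05, 1.0))
        bj = float(rng.uniform(0.05, 1.0))
        ci, cj = clusters[i], clusters[j]
        for x in ci:
            for y in cj:
                xi = labels.index(x)
                yi = labels.index(y)
                dd = depth[x] + bi + depth[y] + bj
                dist[xi, yi] = dist[yi, xi] = dd
        for x in ci:
            depth[x] += bi
        for y in cj:
            depth[y] += bj
        merged = ci | cj
        if 2 <= len(merged) <= n_taxa - 2:
            side = merged if labels[0] not in merged else set(labels) - merged
            splits.add(frozenset(side))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return labels, dist, splits
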