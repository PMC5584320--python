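"""Local protein alignment with affine gaps and Karlin-Altschul statistics.

Three search modes mirror the translated-search roles of the original
workflow: protein vs protein (:func:`local_align`), translated contig query
vs a protein database (:func:`search_translated_query`, the BLASTX role) and
protein query vs a translated contig (:func:`contig_pair_homology`, the
TBLASTN role used for within-cluster homology edges).

Statistics: raw Smith-Waterman scores S are normalized to bits
S' = (lambda*S - ln K)/ln 2 and E-values are E = m*n*2^(-S') over search
space m*n, without finite-size correction. The default lambda=0.267, K=0.041
are the published gapped BLOSUM62/11/1 values; every cutoff is applied as a
strict "<".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from homeoclust._sw import sw_align, sw_score
from homeoclust.orf import OpenReadingFrame, find_orfs, translate_frame, FRAMES
from homeoclust.seqio import HitRecord, SequenceRecord, normalize_residues, PROTEIN

LN2 = math.log(2.0)

# alphabet for kernel encoding; X is a wildcard scoring 0 against everything
_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}
_X_INDEX = _AA_INDEX["X"]

SEED_KMER = 5


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and Karlin-Altschul parameters."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lambda_: float = 0.267
    K: float = 0.041

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if not self.lambda_ > 0:
            raise ValueError("lambda_ must be positive")
        if not (0 < self.K < 1):
            raise ValueError("K must lie in (0, 1)")

    @property
    def matrix(self) -> np.ndarray:
        return _encoded_matrix(self.matrix_name)


@lru_cache(maxsize=4)
def _encoded_matrix(name: str) -> np.ndarray:
    src = substitution_matrices.load(name)
    n = len(_ALPHABET)
    m = np.zeros((n, n), dtype=np.int64)
    for i, a in enumerate(_ALPHABET):
        for j, b in enumerate(_ALPHABET):
            if a == "X" or b == "X":
                m[i, j] = 0  # wildcard residues are score-neutral
            else:
                m[i, j] = int(src[a, b])
    return m


def encode_peptide(peptide: str) -> np.ndarray:
    """Encode a protein string as kernel indices; unknowns map to X."""
    peptide = normalize_residues(peptide, PROTEIN)
    if "*" in peptide:
        raise ValueError("stop symbols are not alignable; split segments at stops")
    return np.fromiter((_AA_INDEX.get(aa, _X_INDEX) for aa in peptide),
                       dtype=np.int8, count=len(peptide))


@dataclass(frozen=True)
class AlignmentResult:
    """One optimal local alignment with its score statistics.

    Coordinates are 1-based inclusive; all-zero coordinates denote an empty
    alignment (raw score 0). ``evalue`` is computed over the m*n search space
    of the two aligned sequences themselves; database searches re-derive E
    over the database search space.
    """

    raw_score: int
    bits: float
    evalue: float
    q_start: int = 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0
    n_identical: int = 0
    alignment_length: int = 0
    mismatches: int = 0
    gap_opens: int = 0

    def __post_init__(self):
        if self.raw_score < 0:
            raise ValueError("local alignment score cannot be negative")
        if self.n_identical > self.alignment_length:
            raise ValueError("n_identical cannot exceed alignment_length")


def to_bits(raw: float, scheme: ScoringScheme) -> float:
    """Normalized bit score S' = (lambda*S - ln K) / ln 2."""
    if raw < 0:
        raise ValueError("raw score must be non-negative")
    return (scheme.lambda_ * raw - math.log(scheme.K)) / LN2


def evalue(bits: float, m: int, n: int) -> float:
    """Expected hit count E = m * n * 2^(-bits) over search space m x n."""
    if m < 1 or n < 1:
        raise ValueError("search-space dimensions must be >= 1")
    return float(m) * float(n) * math.exp(-bits * LN2)


def local_align(a: str, b: str, scheme: ScoringScheme = ScoringScheme()) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment of two protein strings.

    The opening penalty is charged on the first residue of a gap and the
    extension penalty on each additional one. Empty input yields score 0 and
    an empty alignment. The reported alignment ends at the first optimal cell
    in row-major (query-major) order; the traceback prefers substitutions
    over gaps.
    """
    ea, eb = encode_peptide(a), encode_peptide(b)
    if ea.size == 0 or eb.size == 0:
        return AlignmentResult(raw_score=0, bits=to_bits(0, scheme),
                               evalue=evalue(to_bits(0, scheme), max(ea.size, 1), max(eb.size, 1)))
    score, qs, qe, ss, se, ident, cols, mism, gaps = sw_align(
        ea, eb, scheme.matrix, scheme.gap_open, scheme.gap_extend)
    bits = to_bits(score, scheme)
    return AlignmentResult(raw_score=int(score), bits=bits,
                           evalue=evalue(bits, ea.size, eb.size),
                           q_start=qs, q_end=qe, s_start=ss, s_end=se,
                           n_identical=ident, alignment_length=cols,
                           mismatches=mism, gap_opens=gaps)


def local_score(a: np.ndarray, b: np.ndarray, scheme: ScoringScheme) -> int:
    """Score-only kernel entry point for pre-encoded sequences."""
    if a.size == 0 or b.size == 0:
        return 0
    return int(sw_score(a, b, scheme.matrix, scheme.gap_open, scheme.gap_extend))


# ---------------------------------------------------------------------------
# k-mer seeded fast path

def _kmers(encoded: np.ndarray, k: int = SEED_KMER) -> set[bytes]:
    data = encoded.tobytes()
    return {data[i:i + k] for i in range(len(data) - k + 1)}


class KmerIndex:
    """Inverted exact k-mer index over a protein database.

    The fast path aligns a query against exactly those subjects sharing at
    least one k-mer; every alignment that is run uses the full DP, so any
    reported hit carries the exact optimal score. Pairs without a shared
    k-mer are skipped (they cannot reach the stringent cutoffs used here for
    realistic residue identities).
    """

    def __init__(self, proteins: Sequence[SequenceRecord], k: int = SEED_KMER):
        self.k = k
        self.encoded = {p.id: encode_peptide(p.residues) for p in proteins}
        self.index: dict[bytes, list[str]] = {}
        for pid, enc in self.encoded.items():
            for kmer in _kmers(enc, k):
                self.index.setdefault(kmer, []).append(pid)

    def candidates(self, query: np.ndarray) -> list[str]:
        hits: set[str] = set()
        for kmer in _kmers(query, self.k):
            ids = self.index.get(kmer)
            if ids:
                hits.update(ids)
        return sorted(hits)


# ---------------------------------------------------------------------------
# search modes

def search_translated_query(contig: SequenceRecord,
                            proteins: Sequence[SequenceRecord],
                            scheme: ScoringScheme = ScoringScheme(),
                            min_orf_aa: int = 30,
                            exhaustive: bool = False,
                            index: KmerIndex | None = None) -> list[HitRecord]:
    """Align every qualifying ORF of a nucleotide contig to a protein database.

    All six frames are scanned for stop-free ORFs of length >= ``min_orf_aa``;
    per (contig, subject) only the best alignment (lowest E, then highest
    bits) is reported. Query coordinates in the returned hits refer to the
    ORF peptide that produced the hit. The search space is
    m = ORF length, n = total database residues.
    """
    if not proteins:
        raise ValueError("protein database must be non-empty")
    orfs = find_orfs(contig, min_orf_aa)
    if not orfs:
        return []
    if index is None and not exhaustive:
        index = KmerIndex(proteins, SEED_KMER)
    n_db = sum(len(p) for p in proteins)
    encoded = index.encoded if index is not None else {p.id: encode_peptide(p.residues) for p in proteins}
    best: dict[str, tuple] = {}
    for orf in orfs:
        q = encode_peptide(orf.peptide)
        subject_ids = [p.id for p in proteins] if exhaustive else index.candidates(q)
        for sid in subject_ids:
            score = local_score(q, encoded[sid], scheme)
            if score <= 0:
                continue
            bits = to_bits(score, scheme)
            e = evalue(bits, q.size, n_db)
            key = (e, -bits)
            if sid not in best or key < best[sid][0]:
                best[sid] = (key, orf, score)
    hits = []
    for sid in sorted(best):
        (e, neg_bits), orf, score = best[sid]
        q = encode_peptide(orf.peptide)
        s, qs, qe, ss, se, ident, cols, mism, gaps = sw_align(
            q, encoded[sid], scheme.matrix, scheme.gap_open, scheme.gap_extend)
        hits.append(HitRecord(
            query_id=contig.id, subject_id=sid,
            percent_identity=100.0 * ident / cols if cols else 0.0,
            alignment_length=cols, mismatches=mism, gap_opens=gaps,
            q_start=qs, q_end=qe, s_start=ss, s_end=se,
            evalue=e, bit_score=-neg_bits))
    return hits


def translated_segments(contig: SequenceRecord, min_aa: int = 10) -> list[str]:
    """Stop-free peptide segments from all six frame translations of a contig."""
    segments = []
    for frame in FRAMES:
        pep = translate_frame(contig.residues, frame)
        for part in pep.split("*"):
            if len(part) >= min_aa:
                segments.append(part)
    return segments


def contig_pair_homology(query_orf: OpenReadingFrame,
                         subject_contig: SequenceRecord,
                         scheme: ScoringScheme = ScoringScheme(),
                         min_segment_aa: int = 10) -> float:
    """Best E-value of an ORF peptide against a translated contig.

    The subject's six frame translations are split at stops into stop-free
    segments; the minimum E over segments is returned with search space
    m = peptide length, n = subject length in residues (nt/3). A subject
    shorter than one codon yields +inf (no edge possible).
    """
    n_subject = len(subject_contig) // 3
    if n_subject < 1:
        return math.inf
    q = encode_peptide(query_orf.peptide)
    best_score = 0
    for segment in translated_segments(subject_contig, min_segment_aa):
        s = local_score(q, encode_peptide(segment), scheme)
        if s > best_score:
            best_score = s
    if best_score == 0:
        return math.inf
    return evalue(to_bits(best_score, scheme), q.size, n_subject)


def top_hit(hits: Iterable[HitRecord], cutoff: float) -> dict[str, HitRecord]:
    """Best hit per query below the E-value cutoff (strict inequality).

    Ties on E break by highest bit score, then lexicographically smallest
    subject id. Queries with no qualifying hit are absent from the result.
    """
    winners: dict[str, HitRecord] = {}
    for h in hits:
        cur = winners.get(h.query_id)
        if cur is None or (h.evalue, -h.bit_score, h.subject_id) < (cur.evalue, -cur.bit_score, cur.subject_id):
            winners[h.query_id] = h
    return {q: h for q, h in winners.items() if h.evalue < cutoff}
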