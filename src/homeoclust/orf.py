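"""Six-frame translation and longest-ORF extraction.

An ORF here is a stop-to-stop stretch: a start codon is NOT required, because
EST contigs are frequently 5'-truncated and requiring ATG would discard valid
homeolog fragments. Sequence ends count as stops, so ORFs may abut contig
termini. The longest qualifying ORF across all six frames is the translated
query used by the downstream homology search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from Bio.Data.CodonTable import standard_dna_table

from homeoclust.seqio import SequenceRecord, normalize_residues, NUCLEOTIDE

FRAMES = (1, 2, 3, -1, -2, -3)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"

DEFAULT_MIN_AA = 30


@dataclass(frozen=True)
class OpenReadingFrame:
    """A stop-free translated stretch of a contig.

    ``nt_start``/``nt_end`` are 0-based half-open coordinates on the forward
    strand of the contig regardless of frame sign; ``peptide`` carries no stop
    symbol and satisfies nt_end - nt_start == 3 * len(peptide).
    """

    contig_id: str
    frame: int
    nt_start: int
    nt_end: int
    peptide: str

    def __post_init__(self):
        if self.frame not in FRAMES:
            raise ValueError(f"invalid frame {self.frame}")
        if self.nt_end - self.nt_start != 3 * len(self.peptide):
            raise ValueError("ORF coordinates inconsistent with peptide length")
        if "*" in self.peptide:
            raise ValueError("ORF peptide must not contain a stop symbol")


def reverse_complement(nt: str) -> str:
    """Watson-Crick reverse complement; symbols outside ACGTN become N first."""
    nt = normalize_residues(nt, NUCLEOTIDE)
    return nt.translate(_COMPLEMENT)[::-1]


def translate_frame(nt: str, frame: int) -> str:
    """Translate one frame under the standard genetic code, stops as '*'.

    ``frame`` is one of +1/+2/+3 (forward, offset frame-1) or -1/-2/-3 (same
    offsets on the reverse complement). A trailing partial codon is dropped.
    Codons containing N translate to the unambiguous residue if every
    expansion agrees (including all-stop, which yields '*'), otherwise to 'X'.
    """
    if frame not in FRAMES:
        raise ValueError(f"invalid frame {frame}")
    nt = normalize_residues(nt, NUCLEOTIDE)
    if frame < 0:
        nt = reverse_complement(nt)
    offset = abs(frame) - 1
    out = []
    for i in range(offset, len(nt) - 2, 3):
        out.append(_translate_codon(nt[i:i + 3]))
    return "".join(out)


def _translate_codon(codon: str) -> str:
    aa = _CODON_TABLE.get(codon)
    if aa is not None:
        return aa
    # ambiguity: expand N positions; unambiguous only if all expansions agree
    expansions = [""]
    for c in codon:
        opts = "ACGT" if c == "N" else c
        expansions = [e + o for e in expansions for o in opts]
    aas = {_CODON_TABLE[e] for e in expansions}
    return aas.pop() if len(aas) == 1 else "X"


def _stop_free_runs(peptide: str) -> Iterator[tuple[int, int]]:
    """Yield (start, end) half-open codon-index runs between stops."""
    start = 0
    for i, aa in enumerate(peptide):
        if aa == "*":
            if i > start:
                yield start, i
            start = i + 1
    if len(peptide) > start:
        yield start, len(peptide)


def find_orfs(contig: SequenceRecord, min_aa: int = DEFAULT_MIN_AA) -> list[OpenReadingFrame]:
    """All stop-to-stop ORFs of length >= ``min_aa`` in all six frames.

    Ordered by frame (+1,+2,+3,-1,-2,-3) then 5'-most position in that frame.
    """
    if contig.alphabet != NUCLEOTIDE:
        raise ValueError("find_orfs requires a nucleotide record")
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    n = len(contig.residues)
    orfs: list[OpenReadingFrame] = []
    for frame in FRAMES:
        pep = translate_frame(contig.residues, frame)
        offset = abs(frame) - 1
        for a, b in _stop_free_runs(pep):
            if b - a < min_aa:
                continue
            # coordinates on the translated strand, then mapped to forward
            s = offset + 3 * a
            e = offset + 3 * b
            if frame < 0:
                s, e = n - e, n - s
            orfs.append(OpenReadingFrame(contig_id=contig.id, frame=frame,
                                         nt_start=s, nt_end=e, peptide=pep[a:b]))
    return orfs


def longest_orf(contig: SequenceRecord, min_aa: int = DEFAULT_MIN_AA) -> OpenReadingFrame | None:
    """The longest stop-free stretch over all six frames, or None.

    Length ties are broken by lexicographically smallest peptide (which makes
    the result strand-symmetric), then by frame order +1,+2,+3,-1,-2,-3, then
    by the 5'-most position within the frame's own reading direction.
    """
    best = None
    best_key = None
    for orf in find_orfs(contig, min_aa):
        key = (-len(orf.peptide), orf.peptide)
        if best is None or key < best_key:
            best, best_key = orf, key
    return best
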