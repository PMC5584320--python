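"""Read cleanup: adapter removal, poly-T/poly-A tail trimming, length filter.

EST libraries built from oligo-dT-primed cDNA carry PCR-primer adapters at the
read termini, a poly-T signal on the 5' side of reverse-read sequences and a
poly-A signal on the 3' side. Cleanup removes the best terminal adapter
occurrence (interior occurrences are biological sequence and untouched), then
the terminal homopolymer runs, then drops reads shorter than the minimum
length (default 40 bp; length exactly 40 passes).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from homeoclust.seqio import SequenceRecord

# The two library PCR primers printed with the original protocol; adapter sets
# are a user input, these ship as the default.
DEFAULT_ADAPTERS = (
    "AAGCAGTGGTATCAACGCAGAGT",   # 5' PCR primer
    "ATTCTAGAGGCCGAGGCGGCCGAC",  # 3' PCR primer 2
)

DEFAULT_MIN_POLY_RUN = 10
DEFAULT_MAX_INTERRUPTS = 1


@dataclass(frozen=True)
class TrimReport:
    """Stage bookkeeping for a cleanup run (mirrors a filtering summary table)."""

    n_input: int = 0
    n_adapter_trimmed: int = 0
    n_polyt_trimmed: int = 0
    n_polya_trimmed: int = 0
    n_too_short: int = 0
    n_passed: int = 0

    def __post_init__(self):
        counts = (self.n_input, self.n_adapter_trimmed, self.n_polyt_trimmed,
                  self.n_polya_trimmed, self.n_too_short, self.n_passed)
        if any(c < 0 for c in counts):
            raise ValueError("trim report counts must be non-negative")
        if self.n_passed + self.n_too_short != self.n_input:
            raise ValueError("n_passed + n_too_short must equal n_input")

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_adapter(seq: SequenceRecord, adapters: Sequence[str],
                 max_mismatch_rate: float = 0.0) -> SequenceRecord:
    """Remove the best terminal occurrence of each adapter.

    For every adapter the terminal windows (one adapter length deep at either
    end) are scanned for a full occurrence with at most
    ``floor(rate * len(adapter))`` mismatches; the occurrence and everything
    outward of it is removed. Interior occurrences are untouched. The best
    occurrence per side is the one with the fewest mismatches, ties resolved
    toward removing more sequence. Idempotent on already-trimmed input.
    """
    if not adapters or any(not a for a in adapters):
        raise ValueError("adapters must be non-empty strings")
    if not (0 <= max_mismatch_rate < 0.5):
        raise ValueError("max_mismatch_rate must be in [0, 0.5)")
    residues = seq.residues
    for adapter in adapters:
        adapter = adapter.upper()
        la = len(adapter)
        allowed = int(max_mismatch_rate * la)
        for side in ("five_prime", "three_prime"):
            n = len(residues)
            # terminal = within one adapter length of an end; when the two
            # windows overlap an occurrence belongs to the side whose
            # removal discards less sequence
            best = None  # (mismatches, -cut) so min() prefers deeper cuts on ties
            for s in range(0, n - la + 1):
                in5 = s < la
                in3 = s + la > n - la
                if not (in5 or in3):
                    continue
                cut5, cut3 = s + la, n - s
                if in5 and in3:
                    occ_side = "five_prime" if cut5 <= cut3 else "three_prime"
                else:
                    occ_side = "five_prime" if in5 else "three_prime"
                if occ_side != side:
                    continue
                mm = _mismatches(adapter, residues[s:s + la])
                if mm <= allowed:
                    cand = (mm, -(cut5 if side == "five_prime" else cut3))
                    if best is None or cand < best:
                        best = cand
            if best is not None:
                cut = -best[1]
                residues = residues[cut:] if side == "five_prime" else residues[:n - cut]
    if residues == seq.residues:
        return seq
    return replace(seq, residues=residues) if residues else _empty(seq)


def _empty(seq: SequenceRecord) -> SequenceRecord:
    # bypass the non-empty invariant deliberately: caller filters empties out
    out = SequenceRecord(id=seq.id, residues="N", description=seq.description,
                         alphabet=seq.alphabet)
    object.__setattr__(out, "residues", "")
    return out


def terminal_run_length(residues: str, base: str, from_start: bool,
                        max_interrupts: int) -> int:
    """Length of the maximal terminal run of ``base``.

    Up to ``max_interrupts`` non-matching bases are tolerated inside the run,
    never two consecutively, and the run always ends on a matching base.
    """
    s = residues if from_start else residues[::-1]
    interrupts = 0
    last_match = 0
    i = 0
    while i < len(s):
        if s[i] == base:
            last_match = i + 1
            i += 1
        elif (interrupts < max_interrupts and i + 1 < len(s) and s[i + 1] == base
              and i > 0):  # an interrupt must be interior and followed by base
            interrupts += 1
            i += 1
        else:
            break
    return last_match


def trim_homopolymer(seq: SequenceRecord, base: str, side: str,
                     min_run: int = DEFAULT_MIN_POLY_RUN,
                     max_interrupts: int = DEFAULT_MAX_INTERRUPTS) -> SequenceRecord:
    """Remove a terminal poly-A/poly-T run of length >= ``min_run``.

    ``side`` is ``"five_prime"`` or ``"three_prime"``. The run may contain up
    to ``max_interrupts`` non-matching bases (never two consecutive). Below
    ``min_run`` the sequence is returned unchanged.
    """
    if base not in ("A", "T"):
        raise ValueError("base must be 'A' or 'T'")
    if side not in ("five_prime", "three_prime"):
        raise ValueError("side must be 'five_prime' or 'three_prime'")
    if min_run < 4:
        raise ValueError("min_run must be >= 4")
    run = terminal_run_length(seq.residues, base, side == "five_prime", max_interrupts)
    if run < min_run:
        return seq
    residues = seq.residues[run:] if side == "five_prime" else seq.residues[:-run]
    return replace(seq, residues=residues) if residues else _empty(seq)


def length_filter(records: Iterable[SequenceRecord], min_len: int = 40,
                  partial_report: TrimReport | None = None
                  ) -> tuple[list[SequenceRecord], TrimReport]:
    """Drop records shorter than ``min_len`` bases (length == min_len passes)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    records = list(records)
    passed = [r for r in records if len(r) >= min_len]
    base = partial_report.to_dict() if partial_report else {}
    base.update(n_input=len(records), n_too_short=len(records) - len(passed),
                n_passed=len(passed))
    return passed, TrimReport(**base)


def clean_records(records: Iterable[SequenceRecord],
                  adapters: Sequence[str] = DEFAULT_ADAPTERS,
                  max_mismatch_rate: float = 0.1,
                  min_poly_run: int = DEFAULT_MIN_POLY_RUN,
                  max_interrupts: int = DEFAULT_MAX_INTERRUPTS,
                  min_len: int = 40) -> tuple[list[SequenceRecord], TrimReport]:
    """Full cleanup: adapters, then 5' poly-T, then 3' poly-A, then length filter."""
    records = list(records)
    n_adapter = n_polyt = n_polya = 0
    cleaned = []
    for rec in records:
        adapter_hit = polyt_hit = polya_hit = False
        current = rec
        # iterate to a fixed point: removing a poly-tail can expose a
        # previously interior adapter occurrence at the new terminus
        while current.residues:
            t = trim_adapter(current, adapters, max_mismatch_rate)
            adapter_hit |= len(t) != len(current)
            rec2 = trim_homopolymer(t, "T", "five_prime", min_poly_run, max_interrupts) if t.residues else t
            polyt_hit |= len(rec2) != len(t)
            rec3 = trim_homopolymer(rec2, "A", "three_prime", min_poly_run, max_interrupts) if rec2.residues else rec2
            polya_hit |= len(rec3) != len(rec2)
            if len(rec3) == len(current):
                break
            current = rec3
        else:
            rec3 = current
        n_adapter += adapter_hit
        n_polyt += polyt_hit
        n_polya += polya_hit
        cleaned.append(rec3)
    partial = TrimReport(n_input=0, n_adapter_trimmed=n_adapter,
                         n_polyt_trimmed=n_polyt, n_polya_trimmed=n_polya,
                         n_too_short=0, n_passed=0)
    return length_filter(cleaned, min_len, partial)
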