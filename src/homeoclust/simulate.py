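"""Synthetic allopolyploid transcriptome generator with ground truth.

Emulates the data regime of a normalized EST assembly from an allohexaploid:
each gene exists as three homeologous copies (one per subgenome) with low
mutual divergence, gene families are mutually unrelated (high divergence),
contigs may be full-length or 5'/3' fragments (mirroring full-length and
end-purified library types), some homeologs are missing, and the reference
proteome is a diverged outgroup translation of each gene's ancestor.

The substitution model is nucleotide Jukes-Cantor applied independently per
branch (the per-site probability of an observed change over branch length d
substitutions/site is 3/4*(1-exp(-4d/3))), with frame-preserving codon
indels. Codons that would become stops have their substitution event redrawn
conditional on a non-stop outcome so the intended ORF structure survives.
Homeolog similarity, not sequencing realism, is what downstream tests need,
so read-level error models are deliberately out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from homeoclust.seqio import SequenceRecord, NUCLEOTIDE, PROTEIN
from homeoclust.orf import translate_frame

FRAGMENT_TYPES = ("full", "five_prime", "three_prime")

_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)
# codon index c0*16 + c1*4 + c2 with A,C,G,T = 0..3
_STOP_CODES = frozenset((48, 50, 56))  # TAA, TAG, TGA
_SENSE_CODES = np.array([c for c in range(64) if c not in _STOP_CODES])


def _decode(arr: np.ndarray) -> str:
    return _LETTERS[arr].tobytes().decode()


def _codon_codes(arr: np.ndarray) -> np.ndarray:
    c = arr.reshape(-1, 3)
    return c[:, 0] * 16 + c[:, 1] * 4 + c[:, 2]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated transcriptome.

    Divergences are branch lengths in substitutions/site: each homeolog
    diverges ``homeolog_divergence`` from the gene's ancestral CDS and the
    reference protein derives from the ancestor at ``reference_divergence``.
    ``fragment_profile`` gives the (full-length, 5'-fragment, 3'-fragment)
    proportions; fragments cover at least ``min_fragment_cov`` of the CDS.
    Gene families are mutually unrelated random sequences, i.e. generated at
    divergence saturation, which satisfies any ``family_divergence`` >= 0.5.
    """

    n_genes: int = 200
    n_subgenomes: int = 3
    homeolog_divergence: float = 0.03
    family_divergence: float = 0.5
    reference_divergence: float = 0.15
    fragment_profile: tuple[float, float, float] = (0.5, 0.25, 0.25)
    missing_homeolog_prob: float = 0.1
    indel_rate: float = 0.001
    cds_length_range: tuple[int, int] = (150, 500)
    min_fragment_cov: float = 0.4
    utr_length_range: tuple[int, int] = (20, 60)
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_subgenomes < 1:
            raise ValueError("n_genes and n_subgenomes must be >= 1")
        for name in ("homeolog_divergence", "reference_divergence", "indel_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.family_divergence < 0.5:
            raise ValueError("family_divergence below 0.5 is not modelled; "
                             "gene families are generated at saturation")
        if not (0 <= self.missing_homeolog_prob <= 1):
            raise ValueError("missing_homeolog_prob must be a probability")
        if abs(sum(self.fragment_profile) - 1.0) > 1e-9 or min(self.fragment_profile) < 0:
            raise ValueError("fragment_profile proportions must be >= 0 and sum to 1")
        lo, hi = self.cds_length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid cds_length_range")
        if not (0 < self.min_fragment_cov <= 1):
            raise ValueError("min_fragment_cov must be in (0, 1]")


@dataclass(frozen=True)
class TruthEntry:
    gene_id: str
    subgenome: int
    fragment_type: str


@dataclass(frozen=True)
class GroundTruth:
    """Per-contig simulation labels for recovery scoring."""

    entries: Mapping[str, TruthEntry]

    def gene_labels(self) -> dict[str, str]:
        return {cid: e.gene_id for cid, e in self.entries.items()}

    def __len__(self) -> int:
        return len(self.entries)


def expected_identity(d: float) -> float:
    """Expected nucleotide identity of two sequences each diverged d from a
    common ancestor under Jukes-Cantor: 1 - 3/4*(1 - exp(-8d/3))."""
    if d < 0:
        raise ValueError("divergence must be >= 0")
    return 1.0 - 0.75 * (1.0 - math.exp(-8.0 * d / 3.0))


def _jc_substitution_prob(d: float) -> float:
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def _mutate_jc(ancestor: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """One Jukes-Cantor branch over a codon-aligned CDS (values 0..3).

    Which sites mutate is drawn once (Bernoulli with the JC change
    probability) and never revisited; when a mutated codon lands on a stop,
    only the *target* nucleotides of its mutated sites are redrawn until the
    codon is sense again. This keeps the per-site substitution probability
    exactly at the JC value — the stop exclusion only reweights which of the
    three alternative targets is chosen.
    """
    out = ancestor.copy()
    if d == 0:
        return out
    p = _jc_substitution_prob(d)
    mask = rng.random(len(ancestor)) < p
    out[mask] = (ancestor[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
    todo = np.flatnonzero(np.isin(_codon_codes(out), tuple(_STOP_CODES)))
    while todo.size:
        for ci in todo:
            sites = [3 * ci + k for k in range(3) if mask[3 * ci + k]]
            # ancestor codons are sense, so a stop implies >= 1 mutated site
            for s in sites:
                out[s] = (ancestor[s] + rng.integers(1, 4)) % 4
        codes = _codon_codes(out)[todo]
        todo = todo[np.isin(codes, tuple(_STOP_CODES))]
    return out


def _random_cds(n_codons: int, rng: np.random.Generator) -> np.ndarray:
    codes = _SENSE_CODES[rng.integers(0, len(_SENSE_CODES), size=n_codons)]
    arr = np.empty(3 * n_codons, dtype=np.int64)
    arr[0::3] = codes // 16
    arr[1::3] = (codes // 4) % 4
    arr[2::3] = codes % 4
    arr[:3] = (0, 3, 2)  # ATG start codon
    return arr


def _apply_indels(cds: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Frame-preserving single-codon indels at ``rate`` events per site."""
    if rate <= 0:
        return cds
    n_events = rng.binomial(len(cds), rate)
    out = cds
    for _ in range(n_events):
        n_codons = len(out) // 3
        if n_codons <= 2:
            break
        pos = int(rng.integers(1, n_codons))  # never disturb the start codon
        if rng.random() < 0.5:
            out = np.concatenate([out[:3 * pos], out[3 * (pos + 1):]])
        else:
            code = int(_SENSE_CODES[rng.integers(0, len(_SENSE_CODES))])
            ins = np.array([code // 16, (code // 4) % 4, code % 4], dtype=out.dtype)
            out = np.concatenate([out[:3 * pos], ins, out[3 * pos:]])
    return out


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return _decode(rng.integers(0, 4, size=n)) if n else ""


def simulate_transcriptome(config: SimConfig
                           ) -> tuple[list[SequenceRecord], list[SequenceRecord], GroundTruth]:
    """Generate (contigs, reference proteins, ground truth).

    Fully reproducible under ``config.seed``. Per gene: a random ancestral
    CDS (uniform sense codons, ATG start, terminal stop appended on
    emission), one reference protein, and one contig per surviving homeolog.
    Fragment extents are drawn uniformly in [min_fragment_cov, 1] of the CDS
    length; every contig gets independent random UTR padding (full-length
    contigs on both sides, fragments only on their intact end).
    """
    rng = np.random.default_rng(config.seed)
    contigs: list[SequenceRecord] = []
    proteins: list[SequenceRecord] = []
    truth: dict[str, TruthEntry] = {}
    width = max(4, len(str(config.n_genes)))
    stop = np.array([3, 0, 0], dtype=np.int64)  # TAA
    for g in range(1, config.n_genes + 1):
        gene_id = f"G{g:0{width}d}"
        n_codons = int(rng.integers(config.cds_length_range[0],
                                    config.cds_length_range[1] + 1))
        ancestor = _random_cds(n_codons, rng)
        ref = _mutate_jc(ancestor, config.reference_divergence, rng)
        ref_aa = translate_frame(_decode(ref), 1)
        proteins.append(SequenceRecord(id=f"R{gene_id}", residues=ref_aa,
                                       description=f"reference protein of {gene_id}",
                                       alphabet=PROTEIN))
        for sg in range(1, config.n_subgenomes + 1):
            # all draws happen regardless of dropout to keep the random
            # stream aligned across missing_homeolog_prob settings
            dropped = rng.random() < config.missing_homeolog_prob
            homeolog = _mutate_jc(ancestor, config.homeolog_divergence, rng)
            homeolog = _apply_indels(homeolog, config.indel_rate, rng)
            ftype = FRAGMENT_TYPES[int(rng.choice(3, p=config.fragment_profile))]
            cov = float(rng.uniform(config.min_fragment_cov, 1.0))
            utr5 = _random_nt(rng, int(rng.integers(config.utr_length_range[0],
                                                    config.utr_length_range[1] + 1)))
            utr3 = _random_nt(rng, int(rng.integers(config.utr_length_range[0],
                                                    config.utr_length_range[1] + 1)))
            if dropped:
                continue
            cds = _decode(np.concatenate([homeolog, stop]))
            keep = max(3, int(round(cov * len(cds))))
            if ftype == "full":
                residues = utr5 + cds + utr3
            elif ftype == "five_prime":
                residues = utr5 + cds[:keep]
            else:
                residues = cds[-keep:] + utr3
            contig_id = f"{gene_id}_sg{sg}"
            contigs.append(SequenceRecord(id=contig_id, residues=residues,
                                          description=f"{ftype} homeolog",
                                          alphabet=NUCLEOTIDE))
            truth[contig_id] = TruthEntry(gene_id=gene_id, subgenome=sg,
                                          fragment_type=ftype)
    return contigs, proteins, GroundTruth(entries=truth)


def write_truth(path, truth: GroundTruth) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tgene_id\tsubgenome\tfragment_type\n")
        for cid in sorted(truth.entries):
            e = truth.entries[cid]
            fh.write(f"{cid}\t{e.gene_id}\t{e.subgenome}\t{e.fragment_type}\n")


def read_truth(path) -> GroundTruth:
    entries: dict[str, TruthEntry] = {}
    with open(path) as fh:
        fh.readline()  # header
        for line in fh:
            cid, gene, sg, ftype = line.rstrip("\n").split("\t")
            entries[cid] = TruthEntry(gene_id=gene, subgenome=int(sg), fragment_type=ftype)
    return GroundTruth(entries=entries)
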