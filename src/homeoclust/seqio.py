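"""Sequence, hit-table and cluster-table I/O plus the central threshold config.

All coordinates stored in :class:`HitRecord` are 1-based inclusive (the
12-column tabular-hit convention); everything internal to the package slices
0-based half-open. Conversion happens only where hits are built or consumed.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import yaml
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from Bio.Seq import Seq as _BioSeq

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

# '-' and '.' are preserved so aligned sequences round-trip
_NT_CANON = set("ACGTN-.")
_AA_CANON = set("ACDEFGHIKLMNPQRSTVWYX*-.")


class ValidationError(ValueError):
    """Raised when an input file or record violates a documented contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """One nucleotide or protein sequence.

    Residues are upper-case; unknown nucleotide symbols are normalized to N,
    unknown amino-acid symbols to X.
    """

    id: str
    residues: str
    description: str = ""
    alphabet: str = NUCLEOTIDE

    def __post_init__(self):
        if not self.id:
            raise ValidationError("sequence id must be non-empty")
        if self.alphabet not in (NUCLEOTIDE, PROTEIN):
            raise ValidationError(f"unknown alphabet {self.alphabet!r}")
        object.__setattr__(self, "residues", normalize_residues(self.residues, self.alphabet))

    def __len__(self) -> int:
        return len(self.residues)


def normalize_residues(residues: str, alphabet: str) -> str:
    s = residues.upper()
    if alphabet == NUCLEOTIDE:
        s = s.replace("U", "T")
        if not _NT_CANON.issuperset(s):
            s = "".join(c if c in _NT_CANON else "N" for c in s)
    else:
        if not _AA_CANON.issuperset(s):
            s = "".join(c if c in _AA_CANON else "X" for c in s)
    return s


@dataclass(frozen=True)
class HitRecord:
    """One pairwise homology hit in 12-column tabular form.

    ``q_start``/``q_end``/``s_start``/``s_end`` are 1-based inclusive.
    For translated-query searches the query coordinates refer to the query
    ORF peptide, not the underlying nucleotide contig.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self):
        if self.evalue < 0:
            raise ValidationError(f"negative evalue for {self.query_id}/{self.subject_id}")
        if self.alignment_length < 1:
            raise ValidationError(f"alignment_length < 1 for {self.query_id}/{self.subject_id}")
        if self.q_start < 1 or self.s_start < 1:
            raise ValidationError(f"coordinates must be 1-based for {self.query_id}/{self.subject_id}")


@dataclass(frozen=True)
class ThresholdConfig:
    """Every numeric threshold of the pipeline in one place.

    Defaults follow the published workflow: top hits at E < 1e-5 (strict),
    within-cluster homology edges at E < 1e-100 (strict), ortholog candidates
    at bit score > 150 and alignment coverage >= 20% of the query ORF, reads
    shorter than 40 bp discarded, 1000 bootstrap replicates. The "1e-5" and
    "1e-100" cutoffs are applied as strict inequalities (written "<1.0e-5" /
    "<1.0e-100" at the source).
    """

    tophit_evalue_max: float = 1e-5
    edge_evalue_max: float = 1e-100
    ortholog_score_min: float = 150.0
    ortholog_coverage_min: float = 0.20
    min_read_length: int = 40
    bootstrap_replicates: int = 1000

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ValidationError(f"threshold {f.name} must be strictly positive, got {v!r}")
        if not (0 < self.ortholog_coverage_min <= 1):
            raise ValidationError("ortholog_coverage_min must be in (0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "ThresholdConfig":
        """Load thresholds from a YAML mapping or plain ``key = value`` lines."""
        text = Path(path).read_text()
        data = None
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError:
            pass
        if not isinstance(data, dict):
            data = {}
            for ln in text.splitlines():
                ln = ln.split("#", 1)[0].strip()
                if not ln:
                    continue
                if "=" not in ln:
                    raise ValidationError(f"cannot parse config line {ln!r}")
                k, v = (x.strip() for x in ln.split("=", 1))
                data[k] = v
        return cls.from_mapping(data)

    @classmethod
    def from_mapping(cls, data: dict) -> "ThresholdConfig":
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for k, v in data.items():
            if k not in known:
                raise ValidationError(f"unknown threshold key {k!r}")
            kwargs[k] = int(v) if k in ("min_read_length", "bootstrap_replicates") else float(v)
        return cls(**kwargs)

    def override(self, **kwargs) -> "ThresholdConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, alphabet: str = NUCLEOTIDE) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Order is preserved, wrapped lines are concatenated, case is normalized to
    upper. The id is the header token before the first whitespace; the rest of
    the header becomes the description. Duplicate ids raise
    :class:`ValidationError`; an empty file yields an empty list with a warning.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq), description=desc, alphabet=alphabet))
    if not records:
        warnings.warn(f"no sequences found in {path}", stacklevel=2)
    return records


def write_fasta(path: str | Path, records: Iterable[SequenceRecord], width: int = 70) -> None:
    bio = (
        _BioSeqRecord(_BioSeq(r.residues), id=r.id, description=r.description)
        for r in records
    )
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# 12-column tabular hit tables

_HIT_FIELDS = (
    ("query_id", str), ("subject_id", str), ("percent_identity", float),
    ("alignment_length", int), ("mismatches", int), ("gap_opens", int),
    ("q_start", int), ("q_end", int), ("s_start", int), ("s_end", int),
    ("evalue", float), ("bit_score", float),
)


def read_tabular_hits(path: str | Path) -> list[HitRecord]:
    """Parse a 12-column tab-separated hit table (standard column order).

    Row order is preserved. A row with the wrong column count or an
    unparsable number raises :class:`ValidationError` naming the line.
    """
    hits: list[HitRecord] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 12:
                raise ValidationError(f"{path}:{lineno}: expected 12 columns, found {len(row)}")
            kwargs = {}
            for (name, typ), value in zip(_HIT_FIELDS, row):
                try:
                    kwargs[name] = typ(value)
                except ValueError as exc:
                    raise ValidationError(f"{path}:{lineno}: bad value {value!r} for {name}") from exc
            hits.append(HitRecord(**kwargs))
    return hits


def write_tabular_hits(path: str | Path, hits: Iterable[HitRecord]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for h in hits:
            w.writerow([
                h.query_id, h.subject_id, f"{h.percent_identity:.2f}",
                h.alignment_length, h.mismatches, h.gap_opens,
                h.q_start, h.q_end, h.s_start, h.s_end,
                f"{h.evalue:.3g}", f"{h.bit_score:.1f}",
            ])


# ---------------------------------------------------------------------------
# Cluster tables

_CLUSTER_HEADER = ["cluster_id", "subject_gene_id", "contig_id", "is_representative"]


def write_clusters(path: str | Path, clusters: Sequence) -> None:
    """Write gene clusters as TSV, one row per member contig.

    Deterministic ordering: by cluster_id, then contig_id. Exactly one member
    per cluster carries is_representative = 1.
    """
    ids = [c.cluster_id for c in clusters]
    if len(set(ids)) != len(ids):
        raise ValidationError("cluster ids are not unique")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_CLUSTER_HEADER)
        for c in sorted(clusters, key=lambda c: c.cluster_id):
            for contig in sorted(c.member_contig_ids):
                w.writerow([c.cluster_id, c.subject_gene_id, contig,
                            1 if contig == c.representative_contig_id else 0])


def read_clusters(path: str | Path) -> list:
    """Read a cluster TSV back into :class:`~homeoclust.cluster.GeneCluster`."""
    from homeoclust.cluster import GeneCluster

    rows: dict[str, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _CLUSTER_HEADER:
            raise ValidationError(f"{path}: unexpected header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != 4:
                raise ValidationError(f"{path}:{lineno}: expected 4 columns")
            cid, gene, contig, rep = row
            d = rows.setdefault(cid, {"gene": gene, "members": set(), "rep": None})
            if d["gene"] != gene:
                raise ValidationError(f"{path}:{lineno}: cluster {cid} maps to multiple genes")
            d["members"].add(contig)
            if rep == "1":
                d["rep"] = contig
    out = []
    for cid, d in sorted(rows.items()):
        if d["rep"] is None:
            raise ValidationError(f"{path}: cluster {cid} has no representative")
        out.append(GeneCluster(cluster_id=cid, subject_gene_id=d["gene"],
                               member_contig_ids=frozenset(d["members"]),
                               representative_contig_id=d["rep"]))
    return out
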