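"""Sequences, annotations and coordinate conventions for mitochondrial genomes.

The central container is :class:`MitoGenome`: a set of contigs (possibly a
single closed circle, possibly several fragments, as is common for repeat-rich
copepod mitogenomes) plus strand-aware gene features.  All coordinates are
0-based half-open internally; GFF3 on disk is 1-based inclusive.  Features may
span the origin of a circular contig, encoded on disk as ``start > end`` with a
``circular_wrap=true`` attribute (a documented dialect -- GFF3 has no native
way to express a wrapping interval).

Translation uses NCBI genetic codes through Biopython's codon tables; the
default is table 5 (invertebrate mitochondrial), under which AGA/AGG encode
serine and TGA encodes tryptophan.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import gffutils.feature

from .errors import InputError

DNA_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


class FeatureKind(str, Enum):
    CDS = "CDS"
    rRNA = "rRNA"
    tRNA = "tRNA"


class StopStatus(str, Enum):
    """Completeness of a CDS terminator.

    Animal mitochondrial CDS frequently end in a bare T or TA that is
    completed to a TAA stop by polyadenylation of the transcript; such genes
    have nucleotide lengths not divisible by three.
    """

    complete = "complete"
    partial_TA = "partial_TA"
    partial_T = "partial_T"
    no_stop = "no_stop"
    not_applicable = "not_applicable"


@dataclass(frozen=True)
class Contig:
    id: str
    seq: str
    circular: bool = False

    def __post_init__(self):
        if not self.seq:
            raise InputError(f"contig {self.id!r}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise InputError(
                f"contig {self.id!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene.  ``start``/``end`` are 0-based half-open on the
    forward strand; ``wrap=True`` marks a feature crossing the origin of a
    circular contig (then ``start > end`` and the feature is the tail of the
    contig followed by its head)."""

    gene_name: str
    kind: FeatureKind
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    stop_status: StopStatus = StopStatus.not_applicable
    wrap: bool = False

    def __post_init__(self):
        if self.strand not in "+-":
            raise InputError(f"{self.gene_name}: strand must be + or -")
        if not self.wrap and not (0 <= self.start < self.end):
            raise InputError(
                f"{self.gene_name}: bad interval [{self.start},{self.end})"
            )
        if self.kind is FeatureKind.CDS and self.stop_status is StopStatus.not_applicable:
            object.__setattr__(self, "stop_status", StopStatus.complete)

    def length(self, contig_len: int | None = None) -> int:
        if not self.wrap:
            return self.end - self.start
        if contig_len is None:
            raise InputError(f"{self.gene_name}: wrap feature needs contig length")
        return contig_len - self.start + self.end


@dataclass
class MitoGenome:
    species: str
    contigs: list[Contig]
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise InputError("duplicate contig ids")
        for f in self.features:
            if f.contig_id not in set(ids):
                raise InputError(
                    f"feature {f.gene_name}: unknown contig {f.contig_id!r}"
                )
        cds_keys = [
            (f.contig_id, f.start, f.end, f.strand)
            for f in self.features
            if f.kind is FeatureKind.CDS
        ]
        if len(set(cds_keys)) != len(cds_keys):
            raise InputError("duplicate CDS feature coordinates")

    def contig(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise InputError(f"no contig {contig_id!r}")

    def features_of(self, *kinds: FeatureKind) -> list[GeneFeature]:
        if not kinds:
            return list(self.features)
        return [f for f in self.features if f.kind in kinds]

    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)


@dataclass(frozen=True)
class GeneticCode:
    """An NCBI translation table: codon -> one-letter amino acid, plus the
    stop-codon set."""

    table_id: int
    forward: dict
    stops: frozenset

    @classmethod
    def from_table_id(cls, table_id: int = 5) -> "GeneticCode":
        t = CodonTable.unambiguous_dna_by_id[table_id]
        return cls(
            table_id=table_id,
            forward=dict(t.forward_table),
            stops=frozenset(t.stop_codons),
        )


INVERTEBRATE_MITO = GeneticCode.from_table_id(5)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[Contig]:
    """Read a (multi-)FASTA into contigs.  Sequences are uppercased, U
    replaced by T; a record is flagged circular when the word ``circular``
    appears in its description."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    text = path.read_text()
    if not text.strip():
        raise InputError(f"{path}: empty FASTA file")
    if not text.lstrip().startswith(">"):
        raise InputError(f"{path}: line 1: expected '>' header")
    contigs = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        circular = "circular" in rec.description.lower().split()
        contigs.append(Contig(id=rec.id, seq=seq, circular=circular))
    if not contigs:
        raise InputError(f"{path}: no FASTA records")
    return contigs


def write_fasta(contigs: Iterable[Contig], path) -> None:
    """Write contigs as 60-column wrapped FASTA, tagging circular ones."""
    records = []
    for c in contigs:
        desc = "circular" if c.circular else ""
        records.append(SeqRecord(Seq(c.seq), id=c.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3

_KIND_BY_TYPE = {k.value: k for k in FeatureKind}


def read_features(path, genome: MitoGenome | Sequence[Contig]) -> list[GeneFeature]:
    """Read gene features from a GFF3 file.

    1-based inclusive coordinates are converted to 0-based half-open.  The
    gene name comes from the ``gene`` attribute, falling back to ``Name``.
    ``start > end`` together with a ``circular_wrap=true`` attribute encodes
    an origin-spanning feature on a circular contig.
    """
    contigs = genome.contigs if isinstance(genome, MitoGenome) else list(genome)
    by_id = {c.id: c for c in contigs}
    feats: list[GeneFeature] = []
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            gf = gffutils.feature.feature_from_line(line)
        except Exception as exc:  # gffutils raises assorted types
            raise InputError(f"{path}: line {lineno}: {exc}") from exc
        if gf.featuretype not in _KIND_BY_TYPE:
            continue
        contig = by_id.get(gf.seqid)
        if contig is None:
            raise InputError(f"{path}: line {lineno}: unknown seqid {gf.seqid!r}")
        attrs = {k: v[0] for k, v in gf.attributes.items() if v}
        name = attrs.get("gene") or attrs.get("Name")
        if not name:
            raise InputError(f"{path}: line {lineno}: no gene/Name attribute")
        wrap = attrs.get("circular_wrap", "").lower() == "true"
        start1, end1 = gf.start, gf.end
        if wrap:
            if not contig.circular:
                raise InputError(
                    f"{path}: line {lineno}: wrap feature on linear contig"
                )
            start, end = start1 - 1, end1  # tail start, head end
        else:
            if end1 < start1:
                raise InputError(
                    f"{path}: line {lineno}: end < start without circular_wrap"
                )
            start, end = start1 - 1, end1
            if end > len(contig):
                raise InputError(f"{path}: line {lineno}: feature beyond contig end")
        kind = _KIND_BY_TYPE[gf.featuretype]
        status = StopStatus(attrs["stop_status"]) if "stop_status" in attrs else (
            StopStatus.complete if kind is FeatureKind.CDS else StopStatus.not_applicable
        )
        feats.append(
            GeneFeature(
                gene_name=name,
                kind=kind,
                contig_id=gf.seqid,
                start=start,
                end=end,
                strand=gf.strand if gf.strand in "+-" else "+",
                stop_status=status,
                wrap=wrap,
            )
        )
    return feats


def write_features(features: Iterable[GeneFeature], path, source: str = "mitocomp") -> None:
    """Write features as GFF3 (1-based inclusive; wrap dialect documented in
    :func:`read_features`)."""
    lines = ["##gff-version 3"]
    for f in features:
        attrs = [f"gene={f.gene_name}"]
        if f.kind is FeatureKind.CDS:
            attrs.append(f"stop_status={f.stop_status.value}")
        if f.wrap:
            attrs.append("circular_wrap=true")
        lines.append(
            "\t".join(
                [
                    f.contig_id,
                    source,
                    f.kind.value,
                    str(f.start + 1),
                    str(f.end),
                    ".",
                    f.strand,
                    ".",
                    ";".join(attrs),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Sequence extraction and translation

def extract_gene_seq(genome: MitoGenome, feature: GeneFeature) -> str:
    """Gene sequence in its sense (transcribed) orientation.

    Forward-strand slice of the contig; minus-strand features are reverse
    complemented; origin-spanning features concatenate contig tail + head.
    """
    contig = genome.contig(feature.contig_id)
    s = contig.seq
    if feature.wrap:
        if not contig.circular:
            raise InputError(f"{feature.gene_name}: wrap feature on linear contig")
        raw = s[feature.start:] + s[: feature.end]
    else:
        if feature.end > len(s):
            raise InputError(f"{feature.gene_name}: out of range on {contig.id}")
        raw = s[feature.start : feature.end]
    return revcomp(raw) if feature.strand == "-" else raw


class InternalStopError(InputError):
    def __init__(self, codon_index: int, codon: str):
        super().__init__(f"internal stop codon {codon} at codon index {codon_index}")
        self.codon_index = codon_index
        self.codon = codon


def translate(cds_seq: str, code: GeneticCode = INVERTEBRATE_MITO,
              internal_stop: str = "raise") -> str:
    """Translate an in-frame CDS.

    Trailing 1-2 nt (an incomplete stop) are ignored and a terminal stop codon
    is excluded from the chain.  Codons with ambiguous bases give ``X``.  An
    internal stop raises :class:`InternalStopError` by default; with
    ``internal_stop='mask'`` it is emitted as ``?`` instead (useful on
    simulated divergent sequences, where substitutions can create stops).
    """
    if len(cds_seq) < 3:
        raise InputError("CDS shorter than one codon")
    if internal_stop not in ("raise", "mask"):
        raise ValueError("internal_stop must be 'raise' or 'mask'")
    n_codons = len(cds_seq) // 3
    chain = []
    for i in range(n_codons):
        codon = cds_seq[3 * i : 3 * i + 3].upper()
        if codon in code.stops:
            if i == n_codons - 1:
                break
            if internal_stop == "mask":
                chain.append("?")
                continue
            raise InternalStopError(i, codon)
        aa = code.forward.get(codon)
        chain.append(aa if aa is not None else "X")
    return "".join(chain)


def genome_from_files(fasta_path, gff_path, species: str = "") -> MitoGenome:
    """Convenience loader: FASTA + GFF3 -> annotated genome."""
    contigs = read_fasta(fasta_path)
    genome = MitoGenome(species=species or Path(fasta_path).stem, contigs=contigs)
    genome.features = read_features(gff_path, genome)
    return MitoGenome(species=genome.species, contigs=contigs, features=genome.features)
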