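"""Codon-level accounting: stop-codon completeness, amino-acid chain lengths,
four-fold degenerate sites and the GC skew at those neutral positions.

The accounting rule for animal mitochondrial CDS: a gene with a complete
TAA/TAG terminator encodes nt_length/3 - 1 residues (the stop codon is not a
residue); a gene whose stop is completed by polyadenylation (length mod 3 in
{1, 2}, ending in T or TA) encodes floor(nt_length/3) residues.

Four-fold degeneracy is judged from the codon family alone: a third position
counts as neutral iff the four completions of its first two bases all encode
one amino acid.  Under the invertebrate mitochondrial code (table 5) the
families are TCN, CTN, CCN, CGN, ACN, GTN, GCN, GGN and AGN -- AGN qualifies
because AGA/AGG encode serine in this code.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

from .errors import InputError
from .genome_io import (
    FeatureKind,
    GeneFeature,
    GeneticCode,
    INVERTEBRATE_MITO,
    MitoGenome,
    StopStatus,
    extract_gene_seq,
)
from .composition import gc_skew


@dataclass(frozen=True)
class CdsRecord:
    gene_name: str
    species: str
    nt_length: int
    aa_length: int
    stop_status: StopStatus


@dataclass(frozen=True)
class NeutralSiteSet:
    gene_name: str
    positions: tuple  # third-codon-position indices, each == 2 (mod 3)
    counts: dict      # base -> count at those positions, sense strand


def classify_stop(cds_seq: str) -> StopStatus:
    """Stop-codon completeness of a CDS from its sequence alone."""
    if len(cds_seq) < 3:
        raise InputError("CDS shorter than one codon")
    seq = cds_seq.upper()
    rem = len(seq) % 3
    if rem == 0 and seq[-3:] in ("TAA", "TAG"):
        return StopStatus.complete
    if rem == 2 and seq[-2:] == "TA":
        return StopStatus.partial_TA
    if rem == 1 and seq[-1] == "T":
        return StopStatus.partial_T
    return StopStatus.no_stop


def aa_chain_length(nt_length: int, stop_status: StopStatus) -> int:
    """Residue count from nucleotide length under the stop-codon rule."""
    if nt_length < 3:
        raise InputError("nt_length < 3")
    if stop_status is StopStatus.complete:
        if nt_length % 3:
            raise InputError(
                f"complete stop but nt_length {nt_length} not divisible by 3"
            )
        return nt_length // 3 - 1
    if stop_status in (StopStatus.partial_TA, StopStatus.partial_T):
        return nt_length // 3
    raise InputError(f"cannot derive chain length for status {stop_status}")


def infer_stop_status(nt_length: int) -> StopStatus:
    """Status implied by length alone (used when only printed bp values are
    available): divisible by three -> complete, else the matching partial."""
    rem = nt_length % 3
    if rem == 0:
        return StopStatus.complete
    return StopStatus.partial_T if rem == 1 else StopStatus.partial_TA


def fourfold_families(code: GeneticCode = INVERTEBRATE_MITO) -> frozenset:
    """Two-base prefixes whose four codon completions encode one amino acid."""
    fams = []
    for b1 in "TCAG":
        for b2 in "TCAG":
            aas = set()
            ok = True
            for b3 in "TCAG":
                codon = b1 + b2 + b3
                if codon in code.stops:
                    ok = False
                    break
                aas.add(code.forward[codon])
            if ok and len(aas) == 1:
                fams.append(b1 + b2)
    return frozenset(fams)


def fourfold_positions(cds_seq: str, code: GeneticCode = INVERTEBRATE_MITO,
                       gene_name: str = "") -> NeutralSiteSet:
    """Third-codon positions in four-fold degenerate families.

    A trailing partial codon (incomplete stop) is ignored with a warning.
    """
    seq = cds_seq.upper()
    if len(seq) % 3:
        warnings.warn(
            f"{gene_name or 'CDS'}: length {len(seq)} not divisible by 3; "
            "trailing partial codon ignored"
        )
    fams = fourfold_families(code)
    positions = []
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    for i in range(len(seq) // 3):
        codon = seq[3 * i : 3 * i + 3]
        if codon[:2] in fams:
            positions.append(3 * i + 2)
            if codon[2] in counts:
                counts[codon[2]] += 1
    return NeutralSiteSet(gene_name=gene_name, positions=tuple(positions),
                          counts=counts)


def neutral_site_gc_skew(genome: MitoGenome, feature: GeneFeature,
                         code: GeneticCode = INVERTEBRATE_MITO) -> float:
    """GC skew at four-fold degenerate third positions of a CDS, computed on
    the sense strand (so the sign reflects the gene's native orientation)."""
    if feature.kind is not FeatureKind.CDS:
        raise InputError(f"{feature.gene_name}: not a CDS")
    sense = extract_gene_seq(genome, feature)
    sites = fourfold_positions(sense, code, gene_name=feature.gene_name)
    bases = "".join(sense[p] for p in sites.positions)
    return gc_skew(bases)


def ortholog_rsd(lengths) -> float:
    """Relative standard deviation of ortholog lengths, percent.

    Sample (n-1 denominator) standard deviation over the mean, times 100,
    rounded half-up to two decimals (the convention of the printed table:
    population SD would give 0.35 instead of 0.41 for the atp6 row).
    """
    vals = list(lengths)
    if len(vals) < 2:
        raise InputError("RSD needs at least two values")
    mean = statistics.fmean(vals)
    if mean == 0:
        raise InputError("zero mean")
    sd = statistics.stdev(vals)
    rsd = sd / mean * 100.0
    return float(Decimal(repr(rsd)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def incomplete_stop_census(table) -> int:
    """Number of CDS records with an incomplete stop codon (nt length not
    divisible by three)."""
    return sum(1 for rec in table if rec.nt_length % 3 != 0)


def records_from_lengths(lengths_by_species: dict) -> list[CdsRecord]:
    """Build CdsRecords from a {species: {gene: bp}} table of printed
    lengths, inferring stop status and chain length from bp alone."""
    records = []
    for species, genes in lengths_by_species.items():
        for gene, bp in genes.items():
            status = infer_stop_status(bp)
            records.append(
                CdsRecord(
                    gene_name=gene,
                    species=species,
                    nt_length=bp,
                    aa_length=aa_chain_length(bp, status),
                    stop_status=status,
                )
            )
    return records
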