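"""Synthetic annotated mitogenomes with planted, machine-checkable truth.

The generator emulates the structure of large, repeat-rich calanoid copepod
mitogenomes: a circular molecule with 13 protein-coding genes (realistic
lengths, a configurable subset ending in polyadenylation-completed stops),
2 rRNAs, 22 tRNAs, long non-AT-rich non-coding regions carrying tandem TATA
arrays, terminal inverted repeats (palindromes), an overall AT content around
58%, and optionally a rearranged / diverged partner genome plus error-free
read sets at known coverage.

Everything is deterministic given the seed: a single NumPy generator is
seeded once per call and consumed in a fixed documented order (gene parts,
then spacers, then non-coding regions, then assembly).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError
from .genome_io import (
    Contig,
    FeatureKind,
    GeneFeature,
    MitoGenome,
    StopStatus,
    revcomp,
)
from .gene_order import (
    RearrangementEvent,
    SignedGeneOrder,
    apply_events,
)
from . import reference_tables

# Roster of genes with realistic default lengths (CDS lengths follow the
# published Calanus glacialis values; rRNAs use the reported 1125/656 bp).
CDS_LENGTHS = dict(reference_tables.CDS_LENGTHS_BP["C_glacialis"])
RRNA_LENGTHS = {"rrnL": 1125, "rrnS": 656}
TRNA_NAMES = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
    "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
)
TRNA_LENGTH = 66

#: Default ancestral signed circular order (the pancrustacean-like ground
#: pattern), anchored on cox1.
ANCESTRAL_ORDER = (
    "cox1", "trnL2", "cox2", "trnK", "trnD", "atp8", "atp6", "cox3",
    "trnG", "nd3", "trnA", "trnR", "trnN", "trnS1", "trnE", "-trnF",
    "-nd5", "-trnH", "-nd4", "-nd4l", "trnT", "-trnP", "nd6", "cytb",
    "trnS2", "-nd1", "-trnL1", "-rrnL", "-trnV", "-rrnS", "trnI",
    "-trnQ", "trnM", "nd2", "trnW", "-trnC", "-trnY",
)

_TERMINAL_NCR_LEN = 300
_BASES = np.array(list("ATGC"))


@dataclass(frozen=True)
class SimConfig:
    seed: int
    n_cds: int = 13
    n_trna: int = 22
    n_rrna: int = 2
    ncr_lengths: tuple = (800, 1500, 2500)
    at_content: float = 0.583
    tata_units: int = 8
    palindrome_len: int = 15
    divergence_p: float = 0.0
    planted_events: tuple = ()
    read_coverage: float = 50.0
    read_len: int = 150
    incomplete_stop_genes: tuple = ("cytb", "nd1", "nd5")
    species: str = "synthetic"

    def __post_init__(self):
        if self.seed is None:
            raise InputError("seed is mandatory")
        if not (0.0 <= self.at_content <= 1.0):
            raise InputError("at_content must be in [0, 1]")
        if not (0.0 <= self.divergence_p <= 0.75):
            raise InputError("divergence_p must be in [0, 0.75]")
        if not (1 <= self.n_cds <= 13 and 0 <= self.n_trna <= 22
                and 0 <= self.n_rrna <= 2):
            raise InputError("gene counts exceed the available roster")
        if self.ncr_lengths and min(self.ncr_lengths) < 4 * self.tata_units + 10:
            raise InputError(
                "infeasible config: shortest NCR cannot hold the TATA array"
            )
        if _TERMINAL_NCR_LEN < 2 * self.palindrome_len + 30:
            raise InputError(
                "infeasible config: terminal NCR cannot hold the palindrome"
            )


@dataclass
class SimTruth:
    ancestral_order: tuple
    events: tuple
    emitted_order: tuple
    genome_length: int
    tata_arrays: list = field(default_factory=list)   # (start, end, unit, copies)
    palindromes: list = field(default_factory=list)   # (pos_a, pos_b, length)
    realized_divergence: dict = field(default_factory=dict)
    n_substitutions: int = 0

    def to_json(self, path=None) -> str:
        d = asdict(self)
        d["events"] = [
            {"kind": e.kind, "start": e.start, "end": e.end, "dest": e.dest}
            for e in self.events
        ]
        text = json.dumps(d, indent=2, default=list)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _roster(config: SimConfig) -> dict:
    """gene -> (kind, length) for the configured subset of the roster."""
    roster = {}
    for name in list(CDS_LENGTHS)[: config.n_cds]:
        roster[name] = (FeatureKind.CDS, CDS_LENGTHS[name])
    for name in list(RRNA_LENGTHS)[: config.n_rrna]:
        roster[name] = (FeatureKind.rRNA, RRNA_LENGTHS[name])
    for name in TRNA_NAMES[: config.n_trna]:
        roster[name] = (FeatureKind.tRNA, TRNA_LENGTH)
    return roster


def ancestral_gene_order(config: SimConfig) -> SignedGeneOrder:
    roster = _roster(config)
    labels = tuple(l for l in ANCESTRAL_ORDER if l.lstrip("-") in roster)
    if "cox1" not in roster:
        raise InputError("the roster must include the cox1 anchor")
    return SignedGeneOrder(labels)


def _rand_seq(rng, n: int, at: float) -> str:
    p = [at / 2, at / 2, (1 - at) / 2, (1 - at) / 2]
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _cds_seq(rng, length: int, status: StopStatus, at: float,
             stops=("TAA", "TAG")) -> str:
    if status is StopStatus.complete:
        if length % 3:
            raise InputError("complete CDS length must be divisible by 3")
        n_body, tail = length // 3 - 2, "TAA"
    elif status is StopStatus.partial_TA:
        if length % 3 != 2:
            raise InputError("partial_TA CDS length must be 2 mod 3")
        n_body, tail = (length - 5) // 3, "TA"
    elif status is StopStatus.partial_T:
        if length % 3 != 1:
            raise InputError("partial_T CDS length must be 1 mod 3")
        n_body, tail = (length - 4) // 3, "T"
    else:
        raise InputError(f"cannot build CDS with status {status}")
    if n_body < 0:
        raise InputError("CDS too short")
    codons = []
    while len(codons) < n_body:
        chunk = _rand_seq(rng, 3 * (n_body - len(codons)), at)
        for i in range(0, len(chunk), 3):
            codon = chunk[i : i + 3]
            if codon not in stops:
                codons.append(codon)
    return "ATG" + "".join(codons) + tail


def _status_for(config: SimConfig, gene: str, length: int) -> StopStatus:
    if gene in config.incomplete_stop_genes:
        rem = length % 3
        if rem == 1:
            return StopStatus.partial_T
        if rem == 2:
            return StopStatus.partial_TA
        raise InputError(
            f"{gene}: length {length} divisible by 3 cannot carry an "
            "incomplete stop"
        )
    if length % 3:
        raise InputError(f"{gene}: length {length} needs an incomplete stop")
    return StopStatus.complete


def _gene_parts(rng, config: SimConfig) -> dict:
    """gene -> (kind, sense-strand sequence, stop status); fixed rng order
    (roster iteration order)."""
    parts = {}
    for gene, (kind, length) in _roster(config).items():
        if kind is FeatureKind.CDS:
            status = _status_for(config, gene, length)
            seq = _cds_seq(rng, length, status, config.at_content)
        else:
            status = StopStatus.not_applicable
            # rRNAs are the most AT-rich segments of real mitogenomes
            at = min(1.0, config.at_content + (0.10 if kind is FeatureKind.rRNA else 0.0))
            seq = _rand_seq(rng, length, at)
        parts[gene] = (kind, seq, status)
    return parts


def _ncr_with_tata(rng, length: int, tata_units: int, at: float):
    """NCR sequence carrying a TATA tandem array with G/C guard bases so the
    planted coordinates are exactly recoverable; returns (seq, (start, end,
    unit, copies)) with coordinates local to the NCR."""
    array = "TATA" * tata_units
    pad_total = length - len(array) - 2
    left = pad_total // 2
    right = pad_total - left
    seq = _rand_seq(rng, left, at) + "C" + array + "G" + _rand_seq(rng, right, at)
    start = left + 1
    return seq, (start, start + len(array), "AT", len(array) / 2)


def _terminal_ncr(rng, config: SimConfig, at: float):
    """300 bp NCR holding an inverted repeat (arm, spacer, revcomp arm);
    returns (seq, (pos_a, pos_b, length)) with local coordinates."""
    plen = config.palindrome_len
    arm = _rand_seq(rng, plen, at)
    spacer = _rand_seq(rng, 10, at)
    pad_total = _TERMINAL_NCR_LEN - (2 * plen + len(spacer))
    left = pad_total // 2
    right = pad_total - left
    seq = (_rand_seq(rng, left, at) + arm + spacer + revcomp(arm)
           + _rand_seq(rng, right, at))
    return seq, (left, left + plen + len(spacer), plen)


def _assemble(rng, config: SimConfig, order: SignedGeneOrder, parts: dict,
              spacers: list, ncrs: list, head, tail,
              contig_id: str = "mt1"):
    """Concatenate head NCR, genes (with spacers and internal NCRs at fixed
    slots) and tail NCR into one circular annotated contig."""
    n_genes = len(order.labels)
    n_ncr = len(ncrs)
    ncr_slots = {}
    for j in range(n_ncr):  # internal NCRs at evenly spaced gene slots
        ncr_slots[(j + 1) * n_genes // (n_ncr + 1)] = j
    if len(ncr_slots) != n_ncr:
        raise InputError("infeasible config: more NCRs than gene slots")
    pieces = []
    features = []
    truth_tatas = []
    truth_pals = []
    pos = 0

    def push(s):
        nonlocal pos
        pieces.append(s)
        pos += len(s)

    head_seq, (pa, pb, plen) = head
    truth_pals.append((pa, pb, plen))
    push(head_seq)
    for gi, label in enumerate(order.labels):
        if gi in ncr_slots:
            ncr_seq, (ts, te, unit, copies) = ncrs[ncr_slots[gi]]
            truth_tatas.append((pos + ts, pos + te, unit, copies))
            push(ncr_seq)
        push(spacers[gi])
        gene = label.lstrip("-")
        kind, seq, status = parts[gene]
        strand = "-" if label.startswith("-") else "+"
        placed = revcomp(seq) if strand == "-" else seq
        features.append(
            GeneFeature(
                gene_name=gene,
                kind=kind,
                contig_id=contig_id,
                start=pos,
                end=pos + len(placed),
                strand=strand,
                stop_status=status,
            )
        )
        push(placed)
    tail_seq, (pa, pb, plen) = tail
    truth_pals.append((pos + pa, pos + pb, plen))
    push(tail_seq)
    contig = Contig(id=contig_id, seq="".join(pieces), circular=True)
    return contig, features, truth_tatas, truth_pals


def simulate_genome(config: SimConfig):
    """One annotated circular mitogenome plus its planted truth.

    The emitted gene order is the ancestral order with
    ``config.planted_events`` applied; replaying the truth's event list on
    the truth's ancestral order reproduces the emitted order exactly.
    """
    rng = np.random.default_rng(config.seed)
    ancestral = ancestral_gene_order(config)
    emitted = apply_events(ancestral, config.planted_events)
    parts = _gene_parts(rng, config)
    spacers = [_rand_seq(rng, int(rng.integers(5, 21)), config.at_content)
               for _ in emitted.labels]
    ncrs = [_ncr_with_tata(rng, L, config.tata_units, config.at_content)
            for L in config.ncr_lengths]
    head = _terminal_ncr(rng, config, config.at_content)
    tail = _terminal_ncr(rng, config, config.at_content)
    contig, features, tatas, pals = _assemble(
        rng, config, emitted, parts, spacers, ncrs, head, tail
    )
    # tail palindrome truth uses absolute coordinates already
    genome = MitoGenome(species=config.species, contigs=[contig],
                        features=features)
    truth = SimTruth(
        ancestral_order=ancestral.labels,
        events=tuple(config.planted_events),
        emitted_order=emitted.labels,
        genome_length=len(contig),
        tata_arrays=tatas,
        palindromes=pals,
    )
    return genome, truth


def simulate_pair(config: SimConfig):
    """Two genomes sharing gene/NCR content: A carries the ancestral order;
    B carries the rearranged order (``planted_events``) and is then diverged
    at ``divergence_p``.  Returns (genome_a, genome_b, truth) where the truth
    records the events, realized per-gene divergence and total substitution
    count."""
    rng = np.random.default_rng(config.seed)
    ancestral = ancestral_gene_order(config)
    emitted = apply_events(ancestral, config.planted_events)
    parts = _gene_parts(rng, config)
    spacers = [_rand_seq(rng, int(rng.integers(5, 21)), config.at_content)
               for _ in ancestral.labels]
    ncrs = [_ncr_with_tata(rng, L, config.tata_units, config.at_content)
            for L in config.ncr_lengths]
    head = _terminal_ncr(rng, config, config.at_content)
    tail = _terminal_ncr(rng, config, config.at_content)
    contig_a, feats_a, tatas, pals = _assemble(
        rng, config, ancestral, parts, spacers, ncrs, head, tail, "mtA"
    )
    contig_b, feats_b, _, _ = _assemble(
        rng, config, emitted, parts, spacers, ncrs, head, tail, "mtB"
    )
    genome_a = MitoGenome(species=config.species + "_A",
                          contigs=[contig_a], features=feats_a)
    genome_b = MitoGenome(species=config.species + "_B",
                          contigs=[contig_b], features=feats_b)
    div_seed = int(np.random.default_rng(config.seed).integers(0, 2**31 - 1))
    genome_b, n_subs = diverge_pair(genome_b, config.divergence_p, div_seed)
    from .genome_io import extract_gene_seq

    realized = {}
    feats_by_name = {f.gene_name: f for f in feats_b}
    for fa in feats_a:
        fb = feats_by_name.get(fa.gene_name)
        if fb is None:
            continue
        sa = extract_gene_seq(genome_a, fa)
        sb = extract_gene_seq(genome_b, fb)
        if len(sa) == len(sb):
            realized[fa.gene_name] = sum(
                1 for x, y in zip(sa, sb) if x != y
            ) / len(sa)
    truth = SimTruth(
        ancestral_order=ancestral.labels,
        events=tuple(config.planted_events),
        emitted_order=emitted.labels,
        genome_length=len(contig_a),
        tata_arrays=tatas,
        palindromes=pals,
        realized_divergence=realized,
        n_substitutions=n_subs,
    )
    return genome_a, genome_b, truth


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_INDEX_BASE = np.array(list("ACGT"))


def diverge_pair(genome: MitoGenome, p: float, seed: int):
    """Independently substitute each site with probability p, choosing
    uniformly among the three alternative bases (Jukes-Cantor-like).
    Annotations are carried over unchanged; returns (new genome, realized
    substitution count).  N sites are never substituted."""
    if not (0.0 <= p <= 0.75):
        raise InputError("p must be in [0, 0.75]")
    rng = np.random.default_rng(seed)
    new_contigs = []
    realized = 0
    for c in genome.contigs:
        arr = np.frombuffer(c.seq.encode(), dtype=np.uint8).copy()
        idx = np.full(arr.shape, -1, dtype=np.int8)
        for b, i in _BASE_INDEX.items():
            idx[arr == ord(b)] = i
        hit = (rng.random(arr.shape) < p) & (idx >= 0)
        shifts = rng.integers(1, 4, size=arr.shape)
        new_idx = (idx + shifts) % 4
        out = arr.copy()
        sub = np.frombuffer("".join(_INDEX_BASE[new_idx[hit]]).encode(),
                            dtype=np.uint8) if hit.any() else np.array([], dtype=np.uint8)
        out[hit] = sub
        realized += int(hit.sum())
        new_contigs.append(Contig(id=c.id, seq=out.tobytes().decode(),
                                  circular=c.circular))
    return (
        MitoGenome(species=genome.species, contigs=new_contigs,
                   features=list(genome.features)),
        realized,
    )


def simulate_reads(genome: MitoGenome, coverage: float, read_len: int,
                   seed: int) -> list:
    """Error-free reads uniform over the genome at the requested expected
    depth.  Circular contigs are sampled across the origin; linear contigs
    from positions [0, L - read_len].  Deterministic given seed."""
    if coverage <= 0:
        raise InputError("coverage must be positive")
    rng = np.random.default_rng(seed)
    records = []
    ridx = 0
    for c in genome.contigs:
        L = len(c)
        if read_len > L:
            raise InputError(f"read_len {read_len} exceeds contig {c.id} ({L} bp)")
        n_reads = int(round(coverage * L / read_len))
        doubled = c.seq + c.seq[: read_len] if c.circular else c.seq
        max_start = L if c.circular else L - read_len + 1
        starts = rng.integers(0, max_start, size=n_reads)
        flip = rng.random(n_reads) < 0.5
        for s, fl in zip(starts, flip):
            seq = doubled[s : s + read_len]
            if fl:
                seq = revcomp(seq)
            rec = SeqRecord(Seq(seq), id=f"{c.id}_read{ridx}", description="")
            rec.letter_annotations["phred_quality"] = [40] * read_len
            records.append(rec)
            ridx += 1
    return records
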