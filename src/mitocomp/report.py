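"""Per-genome and pairwise comparison reports.

These builders aggregate the analysis modules into the summary surfaces a
mitogenome paper reports -- contig lengths and their sum, base composition
and strand asymmetry, the per-gene CDS table (bp, aa, stop status), the tRNA
census including duplicates, the NCR inventory with repeat content, per-gene
and concatenated p-distances, gene-order distances and event scenarios.  All
numbers come from module operations; the report layer only sums and formats.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field, asdict

from . import codon, composition, distances, gene_order, repeats
from .errors import InputError, NotFoundWithinBound
from .genome_io import (
    FeatureKind,
    MitoGenome,
    extract_gene_seq,
    translate,
)

log = logging.getLogger("mitocomp")


@dataclass
class GenomeReport:
    species: str
    contig_lengths: dict
    total_length: int
    composition: dict
    strand_weight_diff_percent: float
    cds_table: list          # rows: gene, bp, aa, stop_status, strand
    trna_census: dict        # gene -> count (duplicates show as > 1)
    ncr_inventory: list      # rows: contig, start, end, length, n_tandem_arrays
    warnings: list = field(default_factory=list)

    def to_dict(self):
        return asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class ComparisonReport:
    pair: tuple
    shared_genes: list
    dropped_genes: list
    per_gene_p: dict          # gene -> {p, se, n_sites}
    concatenated_aa: dict
    rsd_table: dict           # gene -> RSD% of aa chain lengths
    breakpoint_distance: dict # with/without tRNA
    event_scenario: dict
    dotplot_summary: dict
    rrna_window_profile: dict
    seed: int
    warnings: list = field(default_factory=list)

    def to_dict(self):
        return asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, default=list)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _ncr_intervals(genome: MitoGenome, min_len: int = 100):
    """Unannotated stretches per contig (ignoring origin wrap-around)."""
    out = []
    for c in genome.contigs:
        feats = sorted(
            (f for f in genome.features if f.contig_id == c.id and not f.wrap),
            key=lambda f: f.start,
        )
        pos = 0
        for f in feats:
            if f.start - pos >= min_len:
                out.append((c.id, pos, f.start))
            pos = max(pos, f.end)
        if len(c) - pos >= min_len:
            out.append((c.id, pos, len(c)))
    return out


def build_genome_report(genome: MitoGenome, ncr_min_len: int = 100,
                        tandem_min_copies: float = 5) -> GenomeReport:
    warnings_ = []
    if not genome.features:
        warnings_.append("W001 no annotations: sequence statistics only")
    comp = composition.base_summary(genome)
    weight = composition.strand_weight_diff(
        "".join(c.seq for c in genome.contigs)
    )
    cds_rows = []
    for f in genome.features_of(FeatureKind.CDS):
        seq = extract_gene_seq(genome, f)
        status = codon.classify_stop(seq)
        if status != f.stop_status:
            warnings_.append(
                f"W002 {f.gene_name}: annotated stop_status "
                f"{f.stop_status.value} conflicts with sequence "
                f"({status.value}); sequence wins"
            )
        try:
            aa = codon.aa_chain_length(len(seq), status)
        except InputError:
            aa = None
            warnings_.append(f"W003 {f.gene_name}: no stop codon found")
        cds_rows.append(
            {
                "gene": f.gene_name,
                "bp": len(seq),
                "aa": aa,
                "stop_status": status.value,
                "strand": f.strand,
            }
        )
    cds_rows.sort(key=lambda r: r["gene"])
    trna = Counter(
        f.gene_name for f in genome.features_of(FeatureKind.tRNA)
    )
    ncr_rows = []
    for contig_id, start, end in _ncr_intervals(genome, ncr_min_len):
        seq = genome.contig(contig_id).seq[start:end]
        arrays = repeats.find_tandem_arrays(
            seq, min_copies=tandem_min_copies
        )
        ncr_rows.append(
            {
                "contig": contig_id,
                "start": start,
                "end": end,
                "length": end - start,
                "n_tandem_arrays": len(arrays),
            }
        )
    return GenomeReport(
        species=genome.species,
        contig_lengths={c.id: len(c) for c in genome.contigs},
        total_length=genome.total_length(),
        composition=comp,
        strand_weight_diff_percent=weight,
        cds_table=cds_rows,
        trna_census=dict(sorted(trna.items())),
        ncr_inventory=ncr_rows,
        warnings=warnings_,
    )


def build_comparison_report(genome_a: MitoGenome, genome_b: MitoGenome,
                            seed: int = 0, replicates: int = 1000,
                            max_events: int = 4,
                            window: int = 300, step: int = 10) -> ComparisonReport:
    warnings_ = []
    feats_a = {f.gene_name: f for f in genome_a.features}
    feats_b = {f.gene_name: f for f in genome_b.features}
    shared = sorted(set(feats_a) & set(feats_b))
    dropped = sorted(set(feats_a) ^ set(feats_b))
    if not shared:
        raise InputError("no shared genes between the two genomes")
    if dropped:
        warnings_.append(
            "W010 comparison restricted to shared genes; dropped: "
            + ",".join(dropped)
        )

    per_gene = {}
    aa_blocks = []
    aa_lengths = {}
    rrna_profile = {}
    for gene in shared:
        fa, fb = feats_a[gene], feats_b[gene]
        if fa.kind is FeatureKind.tRNA:
            continue
        sa = extract_gene_seq(genome_a, fa)
        sb = extract_gene_seq(genome_b, fb)
        block = distances.global_align(
            sa, sb, labels=(genome_a.species, genome_b.species)
        )
        block = distances.complete_deletion(block)
        est = distances.p_distance(
            block, genome_a.species, genome_b.species,
            replicates=replicates, seed=seed,
        )
        per_gene[gene] = {"p": est.p, "se": est.se, "n_sites": est.n_sites,
                          "kind": fa.kind.value}
        if fa.kind is FeatureKind.CDS:
            pa = translate(sa, internal_stop="mask")
            pb = translate(sb, internal_stop="mask")
            aa_blocks.append(
                distances.global_align(
                    pa, pb, labels=(genome_a.species, genome_b.species)
                )
            )
            aa_lengths[gene] = codon.ortholog_rsd(
                [len(pa.replace("?", "")), len(pb.replace("?", ""))]
            )
        if fa.kind is FeatureKind.rRNA and gene not in rrna_profile:
            nt_block = distances.global_align(
                sa, sb, labels=(genome_a.species, genome_b.species)
            )
            if nt_block.n_cols >= window:
                prof = distances.sliding_window_distance(
                    nt_block, width=window, step=step
                )
                rrna_profile[gene] = {
                    "centers": [float(x) for x in prof["centers"]],
                    "p": [float(x) for x in prof["p"]],
                }

    concat = distances.concat_genes(aa_blocks) if aa_blocks else None
    if concat is not None:
        concat = distances.complete_deletion(concat)
        est = distances.p_distance(
            concat, genome_a.species, genome_b.species,
            replicates=replicates, seed=seed,
        )
        concat_d = {"p": est.p, "se": est.se, "n_sites": est.n_sites,
                    "replicates": est.replicates}
    else:
        concat_d = {}

    # gene order
    bp_d = {}
    scenario = {}
    for flag, key in ((True, "with_trna"), (False, "without_trna")):
        try:
            oa = gene_order.extract_order(genome_a, include_trna=flag)
            ob = gene_order.extract_order(genome_b, include_trna=flag)
        except InputError as exc:
            warnings_.append(f"W011 gene order ({key}): {exc}")
            continue
        ra, rb, dropped_go = gene_order.restrict_to_shared(oa, ob)
        bp_d[key] = gene_order.breakpoint_distance(ra, rb)
        if key == "without_trna":
            try:
                events = gene_order.infer_events(ra, rb, max_events=max_events)
                scenario = {
                    "n_events": len(events),
                    "events": [
                        {"kind": e.kind, "start": e.start, "end": e.end,
                         "dest": e.dest}
                        for e in events
                    ],
                }
            except NotFoundWithinBound as exc:
                scenario = {"n_events": None,
                            "status": f"not found within {exc.bound} events"}

    seq_a = "".join(c.seq for c in genome_a.contigs)
    seq_b = "".join(c.seq for c in genome_b.contigs)
    matches = repeats.dotplot_matches(seq_a, seq_b, word=11)
    dp = {
        "n_forward": sum(1 for m in matches if m.orientation == "forward"),
        "n_reverse": sum(1 for m in matches if m.orientation == "reverse"),
        "longest": max((m.length for m in matches), default=0),
    }

    return ComparisonReport(
        pair=(genome_a.species, genome_b.species),
        shared_genes=shared,
        dropped_genes=dropped,
        per_gene_p=per_gene,
        concatenated_aa=concat_d,
        rsd_table=aa_lengths,
        breakpoint_distance=bp_d,
        event_scenario=scenario,
        dotplot_summary=dp,
        rrna_window_profile=rrna_profile,
        seed=seed,
        warnings=warnings_,
    )
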