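"""Read-level genome characterization: canonical k-mer histograms, k-mer
genome-size estimation, per-read GC distribution, and the picogram<->bp and
coverage-ratio utilities used when relating sequencing yield to genome size.

Counting is exact and in-memory (desk scale: up to a few tens of millions of
k-mers).  Canonical counting takes the lexicographic minimum of each k-mer
and its reverse complement so the histogram is strand-independent.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .genome_io import revcomp

#: bp per picogram of double-stranded DNA (0.978e9; from the standard
#: relationship genome size [bp] = mass [pg] x 0.978e9).
BP_PER_PG = 0.978e9


@dataclass
class KmerHistogram:
    k: int
    counts: dict  # multiplicity -> number of distinct canonical k-mers
    total_kmers: int

    def __post_init__(self):
        check = sum(m * c for m, c in self.counts.items())
        if check != self.total_kmers:
            raise InputError("histogram total inconsistent with counts")


@dataclass(frozen=True)
class GenomeSizeEstimate:
    status: str  # "estimated" | "no_nontrivial_maximum"
    peak_multiplicity: int | None = None
    size_bp: float | None = None


def _read_seqs(reads):
    for r in reads:
        if isinstance(r, str):
            yield r.upper()
        else:  # Bio.SeqRecord or anything with .seq
            yield str(r.seq).upper()


def kmer_histogram(reads, k: int = 21) -> KmerHistogram:
    """Exact canonical k-mer frequency histogram of a read set.

    k must be odd (so no k-mer is its own reverse complement) and at most
    31; genome-scale work uses k around 21, but small odd k is accepted for
    exact hand-checkable counting.  K-mers containing N are skipped.
    """
    if k % 2 == 0 or not (3 <= k <= 31):
        raise InputError("k must be odd and within [3, 31]")
    counts: Counter = Counter()
    total = 0
    any_read = False
    for seq in _read_seqs(reads):
        any_read = True
        if k >= len(seq):
            raise InputError(f"k={k} exceeds read length {len(seq)}")
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            rc = revcomp(kmer)
            counts[min(kmer, rc)] += 1
            total += 1
    if not any_read:
        raise InputError("no reads")
    hist = Counter(counts.values())
    return KmerHistogram(k=k, counts=dict(hist), total_kmers=total)


def estimate_genome_size(hist: KmerHistogram,
                         min_multiplicity: int = 4) -> GenomeSizeEstimate:
    """Haploid genome size from the k-mer histogram coverage peak.

    The histogram is smoothed with a 3-bin moving average; the candidate
    peaks are interior local maxima at multiplicity >= min_multiplicity
    (which excludes the low-copy/error slope near multiplicity 1).  If no
    such maximum exists -- e.g. a monotonically decreasing histogram, the
    signature of a genome too large/repeat-rich for the available coverage
    -- the status is ``no_nontrivial_maximum``.  Otherwise
    size = total_kmers / peak_multiplicity.
    """
    if not hist.counts:
        raise InputError("empty histogram")
    max_m = max(hist.counts)
    arr = np.zeros(max_m + 2)
    for m, c in hist.counts.items():
        arr[m] = c
    sm = np.convolve(arr, np.ones(3) / 3, mode="same")
    best = None
    for m in range(max(2, min_multiplicity), max_m + 1):
        if sm[m] > sm[m - 1] and sm[m] > sm[m + 1]:
            if best is None or sm[m] > sm[best]:
                best = m
    if best is None:
        return GenomeSizeEstimate(status="no_nontrivial_maximum")
    return GenomeSizeEstimate(
        status="estimated",
        peak_multiplicity=best,
        size_bp=hist.total_kmers / best,
    )


def read_gc_distribution(reads, bins: int = 50):
    """Per-read GC-fraction histogram, normalized to relative frequency.

    Returns (bin_edges, freqs) with freqs summing to 1; N bases are excluded
    from each read's GC fraction, and all-N reads are dropped.
    """
    fracs = []
    for seq in _read_seqs(reads):
        gc = seq.count("G") + seq.count("C")
        valid = len(seq) - seq.count("N")
        if valid:
            fracs.append(gc / valid)
    if not fracs:
        raise InputError("no reads with unambiguous bases")
    counts, edges = np.histogram(fracs, bins=bins, range=(0.0, 1.0))
    return edges, counts / counts.sum()


def pg_to_bp(picograms: float) -> float:
    """Convert a DNA mass in picograms to base pairs (0.978e9 bp/pg)."""
    if picograms < 0:
        raise InputError("negative DNA mass")
    return picograms * BP_PER_PG


def coverage_ratio(mean_cov_a: float, mean_cov_b: float):
    """Copy-ratio between two loci/species from mean coverages.

    Returns (raw, rounded-to-1-decimal).
    """
    if mean_cov_a <= 0 or mean_cov_b <= 0:
        raise InputError("coverages must be positive")
    raw = mean_cov_a / mean_cov_b
    return raw, round(raw, 1)


def write_histogram_tsv(hist: KmerHistogram, path) -> None:
    with open(path, "w") as fh:
        fh.write("multiplicity\tdistinct_kmers\n")
        for m in sorted(hist.counts):
            fh.write(f"{m}\t{hist.counts[m]}\n")


def read_histogram_tsv(path, k: int = 21) -> KmerHistogram:
    counts = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("multiplicity"):
            raise InputError(f"{path}: not a histogram TSV")
        for line in fh:
            m, c = line.split()
            counts[int(m)] = int(c)
    total = sum(m * c for m, c in counts.items())
    return KmerHistogram(k=k, counts=counts, total_kmers=total)
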