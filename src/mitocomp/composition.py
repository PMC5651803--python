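"""Compositional statistics: AT/GC skew, GC content, strand asymmetry.

Skews are the classical strand-asymmetry indices

    AT skew = (A - T) / (A + T)        GC skew = (G - C) / (G + C)

computed over a whole sequence, per gene, or in sliding windows.  Both are
undefined (NaN, never 0) when the denominator is zero.  N bases are excluded
from every count.  "Heavy" strand is defined operationally as the strand with
the greater G+T content.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .genome_io import MitoGenome, Contig, revcomp

UNDEFINED = math.nan

#: Average residue masses of the four deoxynucleotide monophosphates, g/mol,
#: as incorporated in a DNA chain.  Used for the strand molecular-weight
#: asymmetry; configurable because average vs monoisotopic conventions differ.
RESIDUE_MASS = {"A": 313.21, "C": 289.18, "G": 329.21, "T": 304.20}


@dataclass(frozen=True)
class WindowSpec:
    width: int = 300
    step: int = 10
    wrap: bool = True

    def __post_init__(self):
        if self.width < 1 or self.step < 1:
            raise InputError("window width and step must be >= 1")


@dataclass
class SkewProfile:
    contig_id: str
    centers: np.ndarray
    at_skew: np.ndarray
    gc_skew: np.ndarray
    gc_content: np.ndarray

    def to_rows(self):
        for i in range(len(self.centers)):
            yield (self.contig_id, float(self.centers[i]), float(self.at_skew[i]),
                   float(self.gc_skew[i]), float(self.gc_content[i]))


def _counts(seq: str):
    return (seq.count("A"), seq.count("C"), seq.count("G"), seq.count("T"))


def at_skew(seq: str) -> float:
    a, _, _, t = _counts(seq.upper())
    return (a - t) / (a + t) if a + t else UNDEFINED


def gc_skew(seq: str) -> float:
    _, c, g, _ = _counts(seq.upper())
    return (g - c) / (g + c) if g + c else UNDEFINED


def sliding_composition(contig: Contig, spec: WindowSpec | None = None) -> SkewProfile:
    """Windowed AT skew, GC skew and GC content along a contig.

    Windows start at position 0 and advance by ``spec.step``; on circular
    contigs (``spec.wrap``) they cross the origin, giving ceil(L/step)
    windows; on linear contigs floor((L-width)/step)+1 windows.
    """
    spec = spec or WindowSpec(wrap=contig.circular)
    L = len(contig)
    w = spec.width
    if not spec.wrap and w > L:
        raise InputError(f"window {w} longer than linear contig {contig.id} ({L} bp)")
    seq = contig.seq if not spec.wrap else contig.seq + contig.seq[: w]
    starts = (range(0, L - w + 1, spec.step) if not spec.wrap
              else range(0, L, spec.step))
    centers, ats, gcs, gcc = [], [], [], []
    for s in starts:
        win = seq[s : s + w]
        a, c, g, t = _counts(win)
        centers.append((s + w / 2) % L if spec.wrap else s + w / 2)
        ats.append((a - t) / (a + t) if a + t else UNDEFINED)
        gcs.append((g - c) / (g + c) if g + c else UNDEFINED)
        total = a + c + g + t
        gcc.append((g + c) / total if total else UNDEFINED)
    return SkewProfile(contig.id, np.array(centers), np.array(ats),
                       np.array(gcs), np.array(gcc))


def base_summary(genome: MitoGenome | Contig | str) -> dict:
    """Whole-genome base composition over all contigs concatenated.

    Returns AT%, GC% (of non-N bases), G+T% of the forward and reverse
    strands, the heavy-strand G+T% (heavy = strand with larger G+T;
    ties resolved to forward), and the total length.
    """
    if isinstance(genome, MitoGenome):
        seq = "".join(c.seq for c in genome.contigs)
    elif isinstance(genome, Contig):
        seq = genome.seq
    else:
        seq = str(genome).upper()
    a, c, g, t = _counts(seq)
    n_valid = a + c + g + t
    if n_valid == 0:
        raise InputError("no unambiguous bases")
    gt_fwd = 100.0 * (g + t) / n_valid
    gt_rev = 100.0 * (c + a) / n_valid  # G+T of reverse strand = C+A of forward
    heavy = "forward" if gt_fwd >= gt_rev else "reverse"
    return {
        "length": len(seq),
        "at_percent": 100.0 * (a + t) / n_valid,
        "gc_percent": 100.0 * (g + c) / n_valid,
        "gt_percent_forward": gt_fwd,
        "gt_percent_reverse": gt_rev,
        "heavy_strand": heavy,
        "gt_percent_heavy": max(gt_fwd, gt_rev),
    }


def strand_weight_diff(seq: str, masses: dict | None = None) -> float:
    """Relative molecular-weight difference between the two strands, percent.

    |W_fwd - W_rev| / mean(W_fwd, W_rev) * 100, with per-residue masses from
    ``masses`` (default :data:`RESIDUE_MASS`).  N bases are excluded from
    both strands, with a warning.
    """
    if not seq:
        raise InputError("empty sequence")
    masses = masses or RESIDUE_MASS
    seq = seq.upper()
    if "N" in seq:
        warnings.warn("N bases excluded from strand weight computation")
        seq = seq.replace("N", "")
        if not seq:
            raise InputError("no unambiguous bases")
    a, c, g, t = _counts(seq)
    w_fwd = a * masses["A"] + c * masses["C"] + g * masses["G"] + t * masses["T"]
    # complement strand has A<->T, C<->G counts
    w_rev = t * masses["A"] + g * masses["C"] + c * masses["G"] + a * masses["T"]
    return abs(w_fwd - w_rev) / ((w_fwd + w_rev) / 2) * 100.0


def write_profile_tsv(profiles, path) -> None:
    """TSV with columns contig, center, at_skew, gc_skew, gc_content."""
    with open(path, "w") as fh:
        fh.write("contig\tcenter\tat_skew\tgc_skew\tgc_content\n")
        for prof in profiles:
            for row in prof.to_rows():
                fh.write("{}\t{:.1f}\t{:.6g}\t{:.6g}\t{:.6g}\n".format(*row))
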