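"""Uncorrected p-distances with complete deletion and bootstrap standard
errors, over nucleotide or amino-acid alignments.

The estimator is deliberately model-free: p = (number of differing sites) /
(number of sites kept after complete deletion), where complete deletion drops
every alignment column containing a gap ``-`` or missing-data ``?`` symbol in
any row.  Standard errors come from a site (column) bootstrap, 1000
replicates by default.  A linear-gap Needleman-Wunsch aligner is included as
plumbing for building the pairwise alignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from .errors import InputError

GAP_CHARS = frozenset("-?")


@dataclass
class AlignmentBlock:
    """Gap-aware alignment: equal-length rows keyed by labels."""

    labels: tuple
    rows: tuple

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.rows = tuple(self.rows)
        if len(self.labels) != len(self.rows):
            raise InputError("labels/rows length mismatch")
        if not self.rows:
            raise InputError("empty alignment block")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise InputError("alignment rows differ in length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def row(self, label: str) -> str:
        try:
            return self.rows[self.labels.index(label)]
        except ValueError:
            raise InputError(f"no row labelled {label!r}")

    def kept_columns(self) -> list:
        """Columns free of gaps and missing data in every row."""
        return [
            j
            for j in range(self.n_cols)
            if all(r[j] not in GAP_CHARS for r in self.rows)
        ]


@dataclass(frozen=True)
class DistanceEstimate:
    p: float
    se: float
    n_sites: int
    replicates: int
    seed: int | None


def global_align(seq_a: str, seq_b: str, match: float = 1.0,
                 mismatch: float = -1.0, gap: float = -2.0,
                 labels=("A", "B")) -> AlignmentBlock:
    """Optimal global (Needleman-Wunsch) alignment under a linear gap score.

    Uses Biopython's PairwiseAligner; of the co-optimal alignments the
    aligner's first (deterministic) traceback is returned.
    """
    if not seq_a or not seq_b:
        raise InputError("cannot align empty sequences")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aln = aligner.align(seq_a, seq_b)[0]
    return AlignmentBlock(labels=tuple(labels), rows=(str(aln[0]), str(aln[1])))


def align_score(seq_a: str, seq_b: str, match: float = 1.0,
                mismatch: float = -1.0, gap: float = -2.0) -> float:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return float(aligner.score(seq_a, seq_b))


def complete_deletion(block: AlignmentBlock) -> AlignmentBlock:
    """Drop every column with a gap or missing symbol in any row."""
    kept = block.kept_columns()
    if not kept:
        raise InputError("complete deletion removed every column")
    rows = tuple("".join(r[j] for j in kept) for r in block.rows)
    return AlignmentBlock(labels=block.labels, rows=rows)


def p_distance(block: AlignmentBlock, row_a: str, row_b: str,
               replicates: int = 1000, seed: int | None = None) -> DistanceEstimate:
    """Uncorrected p-distance between two rows, with bootstrap SE.

    Requires a gap-free block (apply :func:`complete_deletion` first).  The
    bootstrap resamples columns with replacement; the SE is the sample
    standard deviation of the replicate p values.  Deterministic given seed.
    """
    a, b = block.row(row_a), block.row(row_b)
    if any(ch in GAP_CHARS for ch in a + b):
        raise InputError("p_distance requires complete deletion first")
    n = len(a)
    if n == 0:
        raise InputError("zero sites")
    mism = np.frombuffer(a.encode(), dtype=np.uint8) != np.frombuffer(
        b.encode(), dtype=np.uint8
    )
    p = float(mism.mean())
    if replicates < 1:
        return DistanceEstimate(p, 0.0, n, 0, seed)
    rng = np.random.default_rng(seed)
    reps = np.empty(replicates)
    chunk = max(1, min(replicates, 2_000_000 // n))
    done = 0
    while done < replicates:
        m = min(chunk, replicates - done)
        idx = rng.integers(0, n, size=(m, n))
        reps[done : done + m] = mism[idx].mean(axis=1)
        done += m
    se = float(reps.std(ddof=1)) if replicates > 1 else 0.0
    return DistanceEstimate(p, se, n, replicates, seed)


def concat_genes(per_gene_blocks) -> AlignmentBlock:
    """Column-wise concatenation of per-gene blocks, in the order given.

    All blocks must carry the same label set; rows are concatenated
    label-wise (so the gene order of the input list is the documented,
    caller-fixed concatenation order).
    """
    blocks = list(per_gene_blocks)
    if not blocks:
        raise InputError("no blocks to concatenate")
    labels = tuple(sorted(blocks[0].labels))
    for blk in blocks:
        if tuple(sorted(blk.labels)) != labels:
            raise InputError("blocks carry different label sets")
    rows = tuple(
        "".join(blk.row(lab) for blk in blocks) for lab in labels
    )
    return AlignmentBlock(labels=labels, rows=rows)


def sliding_window_distance(block: AlignmentBlock, width: int = 300,
                            step: int = 10) -> dict:
    """Windowed p-distance along a two-row alignment.

    Windows are [s, s+width) in alignment coordinates, s = 0, step, ...;
    within each window only columns free of gaps/missing data count.  A
    window with zero kept sites is NaN.  Returns dict with ``centers``,
    ``p`` and ``n_sites`` arrays.
    """
    if len(block.rows) != 2:
        raise InputError("sliding_window_distance needs a two-row block")
    L = block.n_cols
    if width > L:
        raise InputError(f"window {width} longer than alignment ({L})")
    a, b = block.rows
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    gap_codes = np.array([ord("-"), ord("?")], dtype=np.uint8)
    ok = ~(np.isin(aa, gap_codes) | np.isin(bb, gap_codes))
    mism = (aa != bb) & ok
    cs_ok = np.concatenate([[0], np.cumsum(ok)])
    cs_mm = np.concatenate([[0], np.cumsum(mism)])
    starts = np.arange(0, L - width + 1, step)
    kept = cs_ok[starts + width] - cs_ok[starts]
    diff = cs_mm[starts + width] - cs_mm[starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(kept > 0, diff / np.maximum(kept, 1), np.nan)
    return {"centers": starts + width / 2, "p": p, "n_sites": kept}


def write_distance_json(est: DistanceEstimate, path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(
            {
                "p": est.p,
                "se": est.se,
                "n_sites": est.n_sites,
                "replicates": est.replicates,
                "seed": est.seed,
            },
            fh,
            indent=2,
        )
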