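"""Repeat profiling for non-coding regions: tandem microsatellite-like
arrays, terminal inverted repeats (palindromes), and word-based dotplot
match extraction.

All detectors are exact (no mismatch tolerance in the dotplot; optional
bounded mismatches when extending inverted repeats), matching the word-based
dotplot methodology classically used for mitogenome comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InputError
from .genome_io import Contig, revcomp


@dataclass(frozen=True)
class TandemArray:
    contig_id: str
    start: int
    end: int
    unit: str      # canonical (lexicographically smallest) rotation
    copies: float  # may be fractional (trailing partial unit >= half counted)

    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PalindromeMatch:
    """Two substrings of one terminal window that are reverse complements."""

    contig_id: str
    terminus: str  # "start" or "end"
    pos_a: int     # absolute coordinates on the contig
    pos_b: int
    length: int


@dataclass(frozen=True)
class DotplotMatch:
    pos_a: int
    pos_b: int
    length: int
    orientation: str  # "forward" or "reverse"


def canonical_rotation(unit: str) -> str:
    """Lexicographically smallest rotation of a repeat unit."""
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _is_primitive(unit: str) -> bool:
    """True unless the unit is itself a repetition of a shorter string."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def find_tandem_arrays(seq: str, max_unit: int = 6, min_copies: float = 3,
                       contig_id: str = "") -> list:
    """Maximal, non-extendable tandem arrays with unit length <= max_unit.

    Scans each unit length u for maximal runs where seq[i] == seq[i+u]; a
    run of r matching positions spans r+u bases, i.e. (r+u)/u copies.  Units
    are reported in canonical rotation; non-primitive units (multiples of a
    shorter period) are skipped, so one locus is reported once.  A trailing
    partial copy counts when it reaches at least half a unit (which the
    fractional copy number reflects).
    """
    seq = seq.upper()
    n = len(seq)
    out = []
    for u in range(1, max_unit + 1):
        i = 0
        while i + u < n:
            if seq[i] != seq[i + u]:
                i += 1
                continue
            j = i
            while j + u < n and seq[j] == seq[j + u]:
                j += 1
            # matches at [i, j); array spans [i, j + u)
            span = (j - i) + u
            copies = span / u
            unit = seq[i : i + u]
            if copies >= min_copies and _is_primitive(unit):
                # trim trailing partial copy below half a unit
                partial = span % u
                end = i + span
                if partial and partial * 2 < u:
                    end -= partial
                    copies = (end - i) / u
                if copies >= min_copies:
                    out.append(
                        TandemArray(
                            contig_id=contig_id,
                            start=i,
                            end=end,
                            unit=canonical_rotation(unit),
                            copies=copies,
                        )
                    )
            i = j + 1
    out.sort(key=lambda t: (t.start, t.end, t.unit))
    return out


def find_terminal_palindromes(contig: Contig, window: int = 500,
                              min_len: int = 10, max_mismatch: int = 0) -> list:
    """Inverted repeats within each terminal window of a contig.

    Reports maximal substring pairs (S at pos_a, revcomp(S) at pos_b > pos_a)
    of length >= min_len inside the first and last ``window`` bases.  Seeds
    of length min_len are hash-matched exactly and extended greedily,
    tolerating up to ``max_mismatch`` mismatches during extension.
    """
    if len(contig) < window:
        raise InputError(f"contig {contig.id} shorter than window {window}")
    results = []
    for terminus, offset in (("start", 0), ("end", len(contig) - window)):
        w = contig.seq[offset : offset + window]
        if min_len > window:
            continue
        results.extend(
            _inverted_repeats_in_window(w, min_len, max_mismatch, contig.id,
                                        terminus, offset)
        )
    return results


def _inverted_repeats_in_window(w, min_len, max_mismatch, contig_id,
                                terminus, offset):
    seeds = {}
    for i in range(len(w) - min_len + 1):
        seeds.setdefault(w[i : i + min_len], []).append(i)
    found = set()
    for i in range(len(w) - min_len + 1):
        probe = revcomp(w[i : i + min_len])
        for j in seeds.get(probe, ()):  # w[j:j+min_len] == revcomp(seed at i)
            if j < i + min_len:  # keep arm order and non-overlap
                continue
            found.add(_extend_inverted(w, i, j, min_len, max_mismatch))
    out = [
        PalindromeMatch(contig_id, terminus, offset + a, offset + b, length)
        for a, b, length in sorted(found)
    ]
    return _drop_contained(out)


def _extend_inverted(w, i, j, seed_len, max_mismatch):
    """Extend the inverted-repeat seed (arm1 = w[i:i+L], arm2 = w[j:j+L] =
    revcomp(arm1)) maximally, keeping the arms non-overlapping."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    a0, a1 = i, i + seed_len          # arm 1: [a0, a1)
    b0, b1 = j, j + seed_len          # arm 2: [b0, b1)
    mm = 0
    # inward: arm1 grows right, arm2 grows left
    while a1 + 1 <= b0 - 1:
        if comp.get(w[a1]) != w[b0 - 1]:
            mm += 1
            if mm > max_mismatch:
                break
        a1 += 1
        b0 -= 1
    # outward: arm1 grows left, arm2 grows right
    while a0 > 0 and b1 < len(w):
        if comp.get(w[a0 - 1]) != w[b1]:
            mm += 1
            if mm > max_mismatch:
                break
        a0 -= 1
        b1 += 1
    return a0, b0, a1 - a0


def _drop_contained(matches):
    out = []
    for m in matches:
        contained = any(
            o is not m
            and o.pos_a <= m.pos_a
            and o.pos_b + o.length >= m.pos_b + m.length
            and o.length >= m.length
            for o in matches
        )
        if not contained:
            out.append(m)
    return out


def dotplot_matches(seq_a: str, seq_b: str, word: int = 11, step: int = 1) -> list:
    """Exact word matches between two sequences, merged into maximal
    diagonals, in forward and reverse-complement orientation.

    Coordinates are 0-based starts in each original sequence; for reverse
    matches ``pos_b`` is the start in B of the segment whose reverse
    complement matches A at ``pos_a``.
    """
    if word < 4:
        raise InputError("word size must be >= 4")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    out = []
    out.extend(_merged_diagonals(seq_a, seq_b, word, step, "forward"))
    rc_b = revcomp(seq_b)
    for m in _merged_diagonals(seq_a, rc_b, word, step, "reverse"):
        pos_b = len(seq_b) - m.pos_b - m.length
        out.append(DotplotMatch(m.pos_a, pos_b, m.length, "reverse"))
    out.sort(key=lambda m: (m.orientation, m.pos_a, m.pos_b))
    return out


def _merged_diagonals(a, b, word, step, orientation):
    index = {}
    for j in range(0, len(b) - word + 1):
        index.setdefault(b[j : j + word], []).append(j)
    hits_by_diag = {}
    for i in range(0, len(a) - word + 1, step):
        for j in index.get(a[i : i + word], ()):
            hits_by_diag.setdefault(j - i, []).append(i)
    out = []
    for diag, starts in hits_by_diag.items():
        starts.sort()
        run_start = prev = starts[0]
        for i in starts[1:]:
            if i <= prev + word:  # overlapping/adjacent words: same segment
                prev = i
            else:
                out.append(DotplotMatch(run_start, run_start + diag,
                                        prev + word - run_start, orientation))
                run_start = prev = i
        out.append(DotplotMatch(run_start, run_start + diag,
                                prev + word - run_start, orientation))
    return out


def rescan(seq: str, array: TandemArray) -> bool:
    """Literal re-check that a reported array really tiles its slice."""
    piece = seq[array.start : array.end].upper()
    u = len(array.unit)
    if not piece:
        return False
    phase = piece[:u]
    if canonical_rotation(phase) != array.unit:
        return False
    tiled = (phase * (len(piece) // u + 1))[: len(piece)]
    return piece == tiled
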