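"""Signed circular gene orders and rearrangement-event inference.

A mitochondrial gene order is a signed circular permutation of gene labels
(sign = transcription strand).  Orders are normalized by rotating (and, if
needed, flipping the whole circle) so that an anchor gene -- cox1 by default,
the most conserved mitochondrial marker -- comes first with positive sign.
Two genomes that differ only by rotation or by which strand was sequenced
therefore normalize to the same order.

Rearrangement events are the three classes used in gene-order studies of
mitogenomes: block transpositions, block reversals (inversions) and reverse
transpositions (a block moved and inverted).  Each event breaks at most three
signed adjacencies, so ceil(breakpoint_distance / 3) lower-bounds the number
of events separating two orders; the bound drives an iterative-deepening
search (:func:`infer_events`).  :func:`bfs_min_events` is an exact
bidirectional breadth-first oracle for small instances, used to certify the
heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Iterable, Sequence

from .errors import InputError, NotFoundWithinBound
from .genome_io import FeatureKind, MitoGenome

FRAGMENT_MARKER_PREFIX = "__frag"


def flip(label: str) -> str:
    return label[1:] if label.startswith("-") else "-" + label


def base_name(label: str) -> str:
    return label.lstrip("-")


@dataclass(frozen=True)
class SignedGeneOrder:
    """Signed circular gene order; ``-`` prefix marks reverse-strand genes."""

    labels: tuple
    anchor: str = "cox1"

    def __post_init__(self):
        names = [base_name(l) for l in self.labels]
        if len(set(names)) != len(names):
            raise InputError("gene labels not unique (up to sign)")

    def normalized(self) -> "SignedGeneOrder":
        return SignedGeneOrder(
            normalize_labels(self.labels, self.anchor), self.anchor
        )

    def gene_set(self) -> frozenset:
        return frozenset(base_name(l) for l in self.labels)

    def __len__(self):
        return len(self.labels)


def normalize_labels(labels: Sequence[str], anchor: str = "cox1") -> tuple:
    """Rotate/flip a signed circular order so ``anchor`` is first and +."""
    labels = tuple(labels)
    names = [base_name(l) for l in labels]
    try:
        i = names.index(anchor)
    except ValueError:
        raise InputError(f"anchor gene {anchor!r} absent from order")
    if labels[i].startswith("-"):
        labels = tuple(flip(l) for l in reversed(labels))
        i = len(labels) - 1 - i
    return labels[i:] + labels[:i]


@dataclass(frozen=True)
class RearrangementEvent:
    """One rearrangement on a normalized order.

    ``start``/``end`` delimit the moved/reversed block as a half-open index
    interval in the current linear representation (anchor fixed at index 0,
    so blocks live in [1, n)).  For (reverse) transpositions ``dest`` is the
    insertion index in the list after block removal.
    """

    kind: str  # transposition | reversal | reverse_transposition
    start: int
    end: int
    dest: int | None = None

    def __post_init__(self):
        if self.kind not in ("transposition", "reversal", "reverse_transposition"):
            raise InputError(f"unknown event kind {self.kind!r}")
        if self.kind != "reversal" and self.dest is None:
            raise InputError(f"{self.kind} needs a destination index")

    def inverse(self) -> "RearrangementEvent":
        if self.kind == "reversal":
            return self
        b = self.end - self.start
        return RearrangementEvent(self.kind, self.dest, self.dest + b, self.start)

    def sort_key(self):
        return (self.kind, self.start, self.end, -1 if self.dest is None else self.dest)


def apply_event(labels: tuple, event: RearrangementEvent) -> tuple:
    n = len(labels)
    s, e = event.start, event.end
    if not (0 < s < e <= n):
        raise InputError(f"block [{s},{e}) out of range (n={n}, anchor at 0)")
    block = labels[s:e]
    if event.kind == "reversal":
        rev = tuple(flip(l) for l in reversed(block))
        return labels[:s] + rev + labels[e:]
    rest = labels[:s] + labels[e:]
    d = event.dest
    if not (0 <= d <= len(rest)):
        raise InputError(f"destination {d} out of range")
    if event.kind == "reverse_transposition":
        block = tuple(flip(l) for l in reversed(block))
    return rest[:d] + block + rest[d:]


def apply_events(order: SignedGeneOrder,
                 events: Iterable[RearrangementEvent]) -> SignedGeneOrder:
    labels = tuple(order.labels)
    for ev in events:
        labels = apply_event(labels, ev)
    return SignedGeneOrder(labels, order.anchor)


# ---------------------------------------------------------------------------
# Extraction from annotated genomes

def extract_order(genome: MitoGenome, include_trna: bool = True,
                  anchor: str = "cox1",
                  fragment_markers: bool = True) -> SignedGeneOrder:
    """Signed gene order from an annotated genome.

    Genes are listed in forward-coordinate order per contig (origin-wrapping
    features sort by their start, i.e. last); multi-contig genomes are
    concatenated in declared contig order with a fragmentation marker token
    between contigs.  The result is normalized on ``anchor``.
    """
    labels = []
    multi = len(genome.contigs) > 1
    for ci, contig in enumerate(genome.contigs):
        feats = [f for f in genome.features if f.contig_id == contig.id]
        if not include_trna:
            feats = [f for f in feats if f.kind is not FeatureKind.tRNA]
        feats.sort(key=lambda f: (f.start, f.end))
        for f in feats:
            labels.append(f.gene_name if f.strand == "+" else "-" + f.gene_name)
        if multi and fragment_markers and ci < len(genome.contigs) - 1:
            labels.append(f"{FRAGMENT_MARKER_PREFIX}{ci}")
    return SignedGeneOrder(tuple(labels), anchor).normalized()


def restrict_to_shared(a: SignedGeneOrder, b: SignedGeneOrder):
    """Drop fragmentation markers and genes not present in both orders;
    returns the restricted pair plus the list of dropped gene names."""
    def genes(o):
        return {base_name(l) for l in o.labels
                if not base_name(l).startswith(FRAGMENT_MARKER_PREFIX)}

    shared = genes(a) & genes(b)
    dropped = sorted((genes(a) | genes(b)) - shared)
    ra = tuple(l for l in a.labels if base_name(l) in shared)
    rb = tuple(l for l in b.labels if base_name(l) in shared)
    return (SignedGeneOrder(ra, a.anchor).normalized(),
            SignedGeneOrder(rb, b.anchor).normalized(), dropped)


# ---------------------------------------------------------------------------
# Distances

def _adjacencies(labels: Sequence[str]) -> set:
    n = len(labels)
    return {(labels[i], labels[(i + 1) % n]) for i in range(n)}


def breakpoint_distance(a: SignedGeneOrder | Sequence[str],
                        b: SignedGeneOrder | Sequence[str]) -> int:
    """Signed circular breakpoint distance: adjacencies of A absent from B.

    An adjacency (x, y) is present in B if B contains (x, y) or its
    reading-direction mirror (-y, -x).
    """
    la = a.labels if isinstance(a, SignedGeneOrder) else tuple(a)
    lb = b.labels if isinstance(b, SignedGeneOrder) else tuple(b)
    if {base_name(l) for l in la} != {base_name(l) for l in lb}:
        raise InputError("gene-order comparison requires identical label sets")
    adj_b = _adjacencies(lb)
    missing = 0
    for x, y in _adjacencies(la):
        if (x, y) not in adj_b and (flip(y), flip(x)) not in adj_b:
            missing += 1
    return missing


def _bp(la: tuple, lb: tuple) -> int:
    adj_b = _adjacencies(lb)
    return sum(
        1
        for x, y in _adjacencies(la)
        if (x, y) not in adj_b and (flip(y), flip(x)) not in adj_b
    )


# ---------------------------------------------------------------------------
# Event enumeration (anchor fixed at index 0)

def enumerate_events(n: int):
    """All distinct single events on a normalized order of n genes.

    Blocks exclude the anchor position 0; on a circle this loses no
    generality (an operation on a block containing the anchor equals an
    operation on its complement).  Identity moves and transpositions whose
    destination reproduces the reversal are skipped.  Deterministic
    lexicographic enumeration order.
    """
    events = []
    for s in range(1, n):
        for e in range(s + 1, n + 1):
            events.append(RearrangementEvent("reversal", s, e))
            b = e - s
            for d in range(1, n - b + 1):
                if d != s:
                    events.append(RearrangementEvent("transposition", s, e, d))
                    events.append(
                        RearrangementEvent("reverse_transposition", s, e, d)
                    )
    events.sort(key=RearrangementEvent.sort_key)
    return events


def _neighbors(labels: tuple, events):
    for ev in events:
        yield ev, apply_event(labels, ev)


# ---------------------------------------------------------------------------
# Exact oracle: bidirectional BFS

def bfs_min_events(a: SignedGeneOrder, b: SignedGeneOrder, cap: int = 4) -> int:
    """Exact minimum event count by bidirectional BFS; -1 if > cap.

    Guarded to small instances (<= 10 genes, cap <= 4): the event graph has
    hundreds of neighbors per state.  Valid because every event class is
    closed under inversion.
    """
    na = a.normalized().labels
    nb = b.normalized().labels
    if a.gene_set() != b.gene_set():
        raise InputError("gene-order comparison requires identical label sets")
    n = len(na)
    if n > 10 or cap > 4:
        raise InputError("bfs_min_events is an exact small-instance oracle: "
                         "needs <= 10 genes and cap <= 4")
    if na == nb:
        return 0
    events = enumerate_events(n)
    dist_a = {na: 0}
    dist_b = {nb: 0}
    frontier_a, frontier_b = [na], [nb]
    depth_a = depth_b = 0
    while depth_a + depth_b < cap:
        # expand the smaller frontier
        if len(frontier_a) <= len(frontier_b):
            frontier, dist, other, here_depth = frontier_a, dist_a, dist_b, depth_a
        else:
            frontier, dist, other, here_depth = frontier_b, dist_b, dist_a, depth_b
        new_frontier = []
        for state in frontier:
            for _, nxt in _neighbors(state, events):
                if nxt not in dist:
                    dist[nxt] = here_depth + 1
                    new_frontier.append(nxt)
        best = None
        for state in new_frontier:
            if state in other:
                d = here_depth + 1 + other[state]
                best = d if best is None else min(best, d)
        if frontier is frontier_a:
            frontier_a, depth_a = new_frontier, here_depth + 1
        else:
            frontier_b, depth_b = new_frontier, here_depth + 1
        if best is not None and best <= cap:
            return best
        if not new_frontier:
            break
    return -1


# ---------------------------------------------------------------------------
# Heuristic search: iterative deepening with breakpoint pruning

def infer_events(a: SignedGeneOrder, b: SignedGeneOrder,
                 max_events: int = 4) -> list:
    """Shortest event sequence turning order A into order B.

    Iterative-deepening depth-first search over the three event classes,
    pruned by the breakpoint lower bound (each event changes at most three
    adjacencies).  Ties are broken by fewest events, then by lexicographic
    event encoding.  The returned solution is replay-checked before being
    returned.  Raises :class:`NotFoundWithinBound` when no sequence of at
    most ``max_events`` events exists (or is found).
    """
    na = a.normalized().labels
    nb = b.normalized().labels
    if a.gene_set() != b.gene_set():
        raise InputError("gene-order comparison requires identical label sets")
    events = enumerate_events(len(na))

    def dfs(cur: tuple, remaining: int):
        if cur == nb:
            return []
        if remaining == 0:
            return None
        if ceil(_bp(cur, nb) / 3) > remaining:
            return None
        for ev in events:
            nxt = apply_event(cur, ev)
            if nxt == cur:
                continue
            sub = dfs(nxt, remaining - 1)
            if sub is not None:
                return [ev] + sub
        return None

    for depth in range(0, max_events + 1):
        if ceil(_bp(na, nb) / 3) > depth:
            continue
        sol = dfs(na, depth)
        if sol is not None:
            # hard postcondition: replaying the events reproduces B exactly
            check = na
            for ev in sol:
                check = apply_event(check, ev)
            assert check == nb, "event replay failed to reproduce target order"
            return sol
    raise NotFoundWithinBound(
        f"no event scenario within {max_events} events", max_events
    )


# ---------------------------------------------------------------------------
# Four-taxon parsimony scenario

@dataclass
class ParsimonyScenario:
    internal_orders: dict
    edge_events: dict
    total_events: int


def _ball(labels: tuple, radius: int, events) -> dict:
    """All normalized orders within ``radius`` events, with distances."""
    dist = {labels: 0}
    frontier = [labels]
    for r in range(1, radius + 1):
        nxt_frontier = []
        for state in frontier:
            for _, nxt in _neighbors(state, events):
                if nxt not in dist:
                    dist[nxt] = r
                    nxt_frontier.append(nxt)
        frontier = nxt_frontier
    return dist


def parsimony_scenario(orders: dict, topology=None, k: int = 2,
                       max_pair_candidates: int = 16) -> ParsimonyScenario:
    """Most-parsimonious two-internal-node scenario for four gene orders.

    ``orders`` maps four taxon names to SignedGeneOrders; ``topology`` is a
    nested pair such as (("A","B"),("C","D")) naming the cherries.  Candidate
    internal orders are the intersections of event-balls around each cherry's
    leaves, grown from radius 0 up to ``k``; the (X, Y) pair minimizing the
    total event count over the five edges wins.  Raises
    :class:`NotFoundWithinBound` if no candidates exist within ``k``.
    """
    if len(orders) != 4:
        raise InputError("parsimony_scenario expects exactly four orders")
    taxa = sorted(orders)
    if topology is None:
        topology = ((taxa[0], taxa[1]), (taxa[2], taxa[3]))
    (l1, l2), (l3, l4) = topology
    norm = {t: orders[t].normalized().labels for t in orders}
    gs = {frozenset(base_name(x) for x in v) for v in norm.values()}
    if len(gs) != 1:
        raise InputError("all four orders must share one gene set")
    n = len(norm[l1])
    events = enumerate_events(n)
    anchor = next(iter(orders.values())).anchor

    def candidates(u, v):
        for r in range(0, k + 1):
            bu = _ball(norm[u], r, events)
            bv = _ball(norm[v], r, events)
            inter = set(bu) & set(bv)
            if inter:
                cands = sorted(inter, key=lambda s: (bu[s] + bv[s], s))
                return [(s, bu[s], bv[s]) for s in cands[:max_pair_candidates]]
        return []

    cand_x = candidates(l1, l2)
    cand_y = candidates(l3, l4)
    if not cand_x or not cand_y:
        raise NotFoundWithinBound(f"no internal-node candidates within {k} events", k)

    best = None
    for x, dx1, dx2 in cand_x:
        for y, dy3, dy4 in cand_y:
            leaf_sum = dx1 + dx2 + dy3 + dy4
            lower = leaf_sum + (0 if x == y else ceil(_bp(x, y) / 3))
            if best is not None and lower >= best[0][0]:
                continue
            ox = SignedGeneOrder(x, anchor)
            oy = SignedGeneOrder(y, anchor)
            if x == y:
                mid = []
            else:
                try:
                    mid = infer_events(ox, oy, max_events=k + 1)
                except NotFoundWithinBound:
                    continue
            total = leaf_sum + len(mid)
            key = (total, x, y)
            if best is None or key < best[0]:
                best = (key, x, y, mid, (dx1, dx2, dy3, dy4))
    if best is None:
        raise NotFoundWithinBound(f"no scenario within bound {k}", k)
    _, x, y, mid, (dx1, dx2, dy3, dy4) = best
    ox = SignedGeneOrder(x, anchor)
    oy = SignedGeneOrder(y, anchor)
    edge_events = {
        (l1, "X"): infer_events(SignedGeneOrder(norm[l1], anchor), ox, k),
        (l2, "X"): infer_events(SignedGeneOrder(norm[l2], anchor), ox, k),
        (l3, "Y"): infer_events(SignedGeneOrder(norm[l3], anchor), oy, k),
        (l4, "Y"): infer_events(SignedGeneOrder(norm[l4], anchor), oy, k),
        ("X", "Y"): mid,
    }
    total = sum(len(v) for v in edge_events.values())
    return ParsimonyScenario(
        internal_orders={"X": ox, "Y": oy},
        edge_events=edge_events,
        total_events=total,
    )


# ---------------------------------------------------------------------------
# Plain-text interchange (one genome per line, comma-separated signed tokens)

def write_orders(orders: dict, path) -> None:
    with open(path, "w") as fh:
        for name, order in orders.items():
            fh.write(name + "\t" + ",".join(order.labels) + "\n")


def read_orders(path, anchor: str = "cox1") -> dict:
    out = {}
    for line in open(path):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, _, rest = line.partition("\t")
        if not rest:
            raise InputError(f"malformed gene-order line: {line!r}")
        out[name] = SignedGeneOrder(tuple(rest.split(",")), anchor)
    return out
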