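"""Rearrangement events and pathway inference between gene orders.

Mitogenome gene orders evolve through a small set of event kinds:

* transposition (T) — a contiguous block moves, strands unchanged;
* inversion (I) — a block is reversed in place, strands flipped;
* inverse transposition (IT) — a block moves *and* flips strand;
* tandem duplication random loss (TDRL) — a segment is duplicated in
  tandem and one copy of every redundant gene is subsequently lost, which
  can relocate many non-adjacent genes in a single move without touching
  strands.

Because the loss step keeps each survivor at its position inside the first
or the second tandem copy, a one-TDRL product is always the genes retained
in copy 1, in source order, followed by the genes retained in copy 2, in
source order.  Written as ranks in the source, the target is therefore one
TDRL away exactly when its rank sequence is a concatenation of at most two
strictly ascending runs, and the minimum number of TDRL moves is
ceil(log2 r) where r is the number of maximal ascending runs (each move
can at most double the number of runs that can be merged away).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .gene_order import (
    Element,
    GeneOrder,
    GeneOrderError,
    GeneSetMismatchError,
)

EVENT_KINDS = ("transposition", "inversion", "inverse_transposition", "tdrl",
               "duplication", "loss", "partial_random_loss")

# tie-break order among event kinds for equal-length alternatives
_KIND_RANK = {"transposition": 0, "inversion": 1, "inverse_transposition": 2,
              "tdrl": 3, "duplication": 4, "partial_random_loss": 5, "loss": 6}


class StrandMismatchError(GeneOrderError):
    def __init__(self, genes):
        self.genes = list(genes)
        super().__init__(
            f"TDRL cannot flip strands; strand differs for: {self.genes}")


@dataclass(frozen=True)
class RearrangementEvent:
    """A typed edit on a linearized gene order.

    ``source_position`` and ``target_position`` index into the pre-event
    order. ``tdrl_partition`` holds the (copy-1, copy-2) kept-gene sets for
    TDRL events; ``moved_block`` lists the rendered names of moved genes.
    """

    kind: str
    moved_block: tuple[str, ...] = ()
    source_position: int = 0
    target_position: int = 0
    tdrl_window: tuple[int, int] | None = None
    tdrl_partition: tuple[frozenset[str], frozenset[str]] | None = None

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")

    def describe(self) -> str:
        if self.kind == "tdrl":
            c1 = ",".join(sorted(self.tdrl_partition[0]))
            c2 = ",".join(sorted(self.tdrl_partition[1]))
            return (f"TDRL over window {self.tdrl_window}: copy 1 retains "
                    f"[{c1}], copy 2 retains [{c2}]")
        block = ",".join(self.moved_block)
        return (f"{self.kind} of [{block}] from position "
                f"{self.source_position} to {self.target_position}")


@dataclass
class Pathway:
    """An ordered event list mapping a source order onto a target order."""

    events: list[RearrangementEvent]
    source: GeneOrder
    target: GeneOrder
    predicted_isps: list[tuple[str, str]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.events)

    def narrative(self) -> str:
        if not self.events:
            return "identical orders; no event required"
        lines = [f"step {i + 1}: {ev.describe()}"
                 for i, ev in enumerate(self.events)]
        if self.predicted_isps:
            lines.append("predicted rearrangement-associated spacers: " +
                         ", ".join(f"ISP {u}-{d}" for u, d in self.predicted_isps))
        return "\n".join(lines)


# --------------------------------------------------------------------------
# Event application (replay)
# --------------------------------------------------------------------------

def apply_event(order: GeneOrder, event: RearrangementEvent) -> GeneOrder:
    """Apply a single event to a linearized order; pure replay on elements."""
    elems = list(order.elements)
    k = event.kind
    if k == "tdrl":
        i, j = event.tdrl_window
        if not (0 <= i < j <= len(elems)):
            raise GeneOrderError(
                f"tdrl window {event.tdrl_window} outside order of "
                f"{len(elems)} elements")
        win = elems[i:j]
        set1, set2 = event.tdrl_partition
        names = _rendered(order)[i:j]
        if set(names) != (set1 | set2) or (set1 & set2):
            raise GeneOrderError(
                "tdrl partition does not partition the window gene set")
        c1 = [e for e, nm in zip(win, names) if nm in set1]
        c2 = [e for e, nm in zip(win, names) if nm not in set1]
        new = elems[:i] + c1 + c2 + elems[j:]
    elif k in ("transposition", "inverse_transposition", "inversion"):
        i, L = event.source_position, len(event.moved_block)
        block = elems[i:i + L]
        if k == "inversion":
            new = elems[:i] + _flip(block) + elems[i + L:]
        else:
            if k == "inverse_transposition":
                block = _flip(block)
            rest = elems[:i] + elems[i + L:]
            t = event.target_position
            new = rest[:t] + block + rest[t:]
    else:
        raise GeneOrderError(f"apply_event does not replay kind {k!r}")
    return replace(order, elements=tuple(new), name=None)


def apply_pathway(order: GeneOrder, pathway: Pathway) -> GeneOrder:
    for ev in pathway.events:
        order = apply_event(order, ev)
    return order


def _flip(block: list[Element]) -> list[Element]:
    return [(lab, "+" if s == "-" else "-") for lab, s in reversed(block)]


def _rendered(order: GeneOrder) -> list[str]:
    return order.rendered()


def _check_same_genes(a: GeneOrder, b: GeneOrder) -> None:
    sa, sb = sorted(a.rendered()), sorted(b.rendered())
    if sa != sb:
        raise GeneSetMismatchError(set(sa) - set(sb), set(sb) - set(sa))


# --------------------------------------------------------------------------
# Single-event detection
# --------------------------------------------------------------------------

def _signature(order: GeneOrder) -> tuple:
    return order.signature()


def detect_single_event(a: GeneOrder, b: GeneOrder) -> RearrangementEvent | None:
    """Smallest single T/I/IT event mapping ``a`` onto ``b``, or ``None``.

    Candidate events are enumerated from the aligned difference region
    (identical prefixes/suffixes are never part of the moved block is *not*
    assumed — the full event space is searched), each verified by replay.
    Ties are broken by smallest moved block, then leftmost source, then
    T < I < IT.
    """
    _check_same_genes(a, b)
    names = a.rendered()
    ea = list(zip(names, (s for _, s in a.elements)))
    eb = list(zip(b.rendered(), (s for _, s in b.elements)))
    if ea == eb:
        return None
    n = len(ea)

    def flipped(block):
        return [(nm, "+" if s == "-" else "-") for nm, s in reversed(block)]

    # search in increasing block size: the first size with a verified event
    # wins; within a size, leftmost source then T < I < IT
    for L in range(1, n):
        best = None
        for i in range(0, n - L + 1):
            block = ea[i:i + L]
            fblock = flipped(block)
            rest = ea[:i] + ea[i + L:]
            if ea[:i] + fblock + ea[i + L:] == eb:
                cand = (i, _KIND_RANK["inversion"],
                        RearrangementEvent("inversion",
                                           tuple(names[i:i + L]), i, i))
                if best is None or cand[:2] < best[:2]:
                    best = cand
            for t in range(0, n - L + 1):
                if t == i:
                    continue
                for blk, kind in ((block, "transposition"),
                                  (fblock, "inverse_transposition")):
                    if rest[:t] + blk + rest[t:] == eb:
                        cand = (i, _KIND_RANK[kind],
                                RearrangementEvent(kind,
                                                   tuple(names[i:i + L]), i, t))
                        if best is None or cand[:2] < best[:2]:
                            best = cand
        if best is not None:
            return best[2]
    return None


# --------------------------------------------------------------------------
# TDRL reachability and distance
# --------------------------------------------------------------------------

def _ranks(a: GeneOrder, b: GeneOrder) -> list[int]:
    """Positions of b's genes in a (requires identical strand vectors)."""
    _check_same_genes(a, b)
    sa = {nm: s for nm, s in zip(a.rendered(), (s for _, s in a.elements))}
    bad = [nm for nm, (_, s) in zip(b.rendered(), b.elements) if sa[nm] != s]
    if bad:
        raise StrandMismatchError(bad)
    pos = {nm: i for i, nm in enumerate(a.rendered())}
    return [pos[nm] for nm in b.rendered()]


def _ascending_runs(ranks: list[int]) -> list[list[int]]:
    """Maximal strictly ascending runs of the rank sequence."""
    runs: list[list[int]] = []
    for r in ranks:
        if runs and runs[-1][-1] < r:
            runs[-1].append(r)
        else:
            runs.append([r])
    return runs


def tdrl_reachable(a: GeneOrder, b: GeneOrder,
                   segment: tuple[int, int] | None = None
                   ) -> tuple[bool, tuple[frozenset[str], frozenset[str]] | None]:
    """Is ``b`` one TDRL move away from ``a`` (identity included)?

    True iff the rank sequence of ``b`` in ``a`` is a concatenation of at
    most two strictly ascending runs; the witness partition names the genes
    retained in the first and second tandem copy (verified by replay in the
    property suite against exhaustive enumeration of one-TDRL products).
    With ``segment=(i, j)`` the move is restricted to that window of ``a``
    (genes outside must be fixed).
    """
    ranks = _ranks(a, b)
    if segment is not None:
        i, j = segment
        for k, r in enumerate(ranks):
            if not (i <= r < j) and k != r:
                return False, None
        runs = _ascending_runs([r for r in ranks if i <= r < j])
    else:
        runs = _ascending_runs(ranks)
    if len(runs) > 2:
        return False, None
    names_a = a.rendered()
    set1 = frozenset(names_a[r] for r in runs[0])
    set2 = frozenset(names_a[r] for r in runs[1]) if len(runs) > 1 else frozenset()
    return True, (set1, set2)


def minimal_tdrl_event(a: GeneOrder, b: GeneOrder) -> RearrangementEvent | None:
    """The one-TDRL event over the *smallest* window mapping a onto b.

    The window is the minimal contiguous region outside which every gene is
    already in place; restricting the duplication to it matters when the
    event is replayed on sequence: only genes inside the window leave
    pseudogene remnants.  Returns ``None`` for identical orders; raises
    :class:`GeneOrderError` if no single TDRL suffices.
    """
    ranks = _ranks(a, b)
    moved = [k for k, r in enumerate(ranks) if r != k]
    if not moved:
        return None
    lo, hi = min(moved), max(moved) + 1
    ok, part = tdrl_reachable(a, b, segment=(lo, hi))
    if not ok:
        raise GeneOrderError("target is not one TDRL away from source")
    names = a.rendered()
    return RearrangementEvent("tdrl", tuple(names[lo:hi]), lo, lo,
                              tdrl_window=(lo, hi), tdrl_partition=part)


def min_tdrl_steps(a: GeneOrder, b: GeneOrder) -> int:
    """Minimum number of TDRL moves from ``a`` to ``b``: ceil(log2 r) with
    r the number of maximal strictly ascending runs of b's ranks in a."""
    ranks = _ranks(a, b)
    r = len(_ascending_runs(ranks))
    return 0 if r <= 1 else math.ceil(math.log2(r))


# --------------------------------------------------------------------------
# Pathway search
# --------------------------------------------------------------------------

DEFAULT_KINDS = frozenset({"transposition", "inversion",
                           "inverse_transposition", "tdrl"})


@dataclass
class PathwaySearchResult:
    pathways: list[Pathway]
    found: bool
    bound: int

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self):
        return len(self.pathways)


def _single_events(order: GeneOrder, kinds: frozenset[str],
                   tdrl_max_window: int) -> list[RearrangementEvent]:
    n = len(order)
    names = order.rendered()
    out = []
    for L in range(1, n):
        for i in range(0, n - L + 1):
            block = tuple(names[i:i + L])
            if "inversion" in kinds:
                out.append(RearrangementEvent("inversion", block, i, i))
            for t in range(0, n - L + 1):
                if t == i:
                    continue
                if "transposition" in kinds:
                    out.append(RearrangementEvent("transposition", block, i, t))
                if "inverse_transposition" in kinds:
                    out.append(
                        RearrangementEvent("inverse_transposition", block, i, t))
    if "tdrl" in kinds:
        for w in range(2, min(tdrl_max_window, n) + 1):
            for i in range(0, n - w + 1):
                win = names[i:i + w]
                for mask in range(1, (1 << w) - 1):
                    set1 = frozenset(win[k] for k in range(w) if mask >> k & 1)
                    out.append(RearrangementEvent(
                        "tdrl", tuple(win), i, i, tdrl_window=(i, i + w),
                        tdrl_partition=(set1, frozenset(win) - set1)))
    return out


def infer_pathways(a: GeneOrder, b: GeneOrder, max_events: int = 2,
                   allowed_kinds: frozenset[str] = DEFAULT_KINDS,
                   max_pathways: int = 10,
                   tdrl_max_window: int = 6) -> PathwaySearchResult:
    """Breadth-first enumeration of minimal event pathways from a to b.

    ``max_events`` is capped at 3 (combinatorial guard).  TDRL successors
    are enumerated exhaustively only over windows up to ``tdrl_max_window``;
    in addition, an unrestricted whole-order TDRL is always tried as the
    *closing* move of a pathway via the rank-splitting reachability test, so
    one-TDRL transformations of any width are found.  Every returned pathway
    is verified by replay.  An exhausted bound returns ``found=False``
    rather than raising.
    """
    if max_events > 3:
        raise GeneOrderError("max_events is capped at 3")
    _check_same_genes(a, b)
    target = _signature(b)

    def closing_tdrl(cur: GeneOrder) -> RearrangementEvent | None:
        if "tdrl" not in allowed_kinds:
            return None
        try:
            ok, part = tdrl_reachable(cur, b)
        except StrandMismatchError:
            return None
        if not ok or _signature(cur) == target:
            return None
        return RearrangementEvent("tdrl", tuple(cur.rendered()), 0, 0,
                                  tdrl_window=(0, len(cur)),
                                  tdrl_partition=part)

    if _signature(a) == target:
        return PathwaySearchResult([Pathway([], a, b)], True, max_events)

    frontier: list[tuple[GeneOrder, list[RearrangementEvent]]] = [(a, [])]
    seen = {_signature(a)}
    for depth in range(1, max_events + 1):
        hits: list[list[RearrangementEvent]] = []
        nxt = []
        for cur, evs in frontier:
            ev = closing_tdrl(cur)
            if ev is not None:
                hits.append(evs + [ev])
                if len(hits) >= max_pathways:
                    break
            for cand in _single_events(cur, allowed_kinds, tdrl_max_window):
                new = apply_event(cur, cand)
                sig = _signature(new)
                if sig == target:
                    hits.append(evs + [cand])
                    if len(hits) >= max_pathways:
                        break
                elif depth < max_events and sig not in seen:
                    seen.add(sig)
                    nxt.append((new, evs + [cand]))
            if len(hits) >= max_pathways:
                break
        if hits:
            pathways = []
            for evs in _dedupe(hits)[:max_pathways]:
                p = Pathway(list(evs), a, b,
                            predicted_isps=_predict_isps(a, evs))
                assert _signature(apply_pathway(a, p)) == target
                pathways.append(p)
            pathways.sort(key=_pathway_key)
            return PathwaySearchResult(pathways, True, max_events)
        frontier = nxt
    return PathwaySearchResult([], False, max_events)


def _dedupe(hits):
    seen, out = set(), []
    for evs in hits:
        key = tuple((e.kind, e.moved_block, e.source_position,
                     e.target_position, e.tdrl_partition) for e in evs)
        if key not in seen:
            seen.add(key)
            out.append(evs)
    return out


def _pathway_key(p: Pathway):
    moved = sum(len(e.moved_block) if e.kind != "tdrl"
                else len(e.tdrl_partition[0]) for e in p.events)
    left = min((e.source_position for e in p.events), default=0)
    kinds = tuple(_KIND_RANK[e.kind] for e in p.events)
    return (p.length, moved, left, kinds)


def _predict_isps(a: GeneOrder, events) -> list[tuple[str, str]]:
    """Spacer positions a pathway creates: junctions flanking each moved
    block in the pre-event order (the 'orange dot' convention)."""
    names = a.rendered()
    n = len(names)
    isps = []
    for ev in events:
        if ev.kind == "tdrl":
            i, j = ev.tdrl_window
            edges = [i, j - 1]
        else:
            i = ev.source_position
            edges = [i, i + len(ev.moved_block) - 1]
        for e in edges:
            isps.append((names[e - 1] if e > 0 else names[-1],
                         names[(e + 1) % n]))
    # unique, order-preserving
    seen, out = set(), []
    for pair in isps:
        if pair not in seen:
            seen.add(pair)
            out.append(pair)
    return out


# --------------------------------------------------------------------------
# Duplication-bearing arrangements (2FFGO / 4QGO style narratives)
# --------------------------------------------------------------------------

def explain_duplication_pathway(record) -> Pathway:
    """Pathway hypothesis for an arrangement with duplicated genes.

    Two mechanisms are recognized from copy strands, adjacency and spacer
    repeat structure:

    * two copies on opposite strands at distant positions -> duplication of
      the in-situ copy followed by inverse transposition of the other (the
      copy overlapping a neighbour gene is deemed in situ, since moving it
      would have disrupted that neighbour);
    * three or more tandem copies with near-identical upstream spacers ->
      one tandem duplication of a larger segment, a partial random loss
      shaping the first spacer, then iterated tandem duplication of the
      (spacer + gene) unit.

    ``record`` is a :class:`~mitorearr.annotation.MitogenomeRecord`; a
    duplicate-free record yields an empty pathway.
    """
    from .annotation import extract_isps, gene_order_of

    order = gene_order_of(record)
    counts = order.multiplicity()
    dup_names = [nm for nm, c in counts.items() if c > 1]
    if not dup_names:
        return Pathway([], order, order)

    names = order.rendered()
    elems = order.elements
    events: list[RearrangementEvent] = []
    isps = {f"ISP {s.upstream}-{s.downstream}": s for s in extract_isps(record)}

    for nm in dup_names:
        idxs = [i for i, (lab, _) in enumerate(elems) if lab.name == nm]
        strands = {elems[i][1] for i in idxs}
        tandem = all(b - a == 1 for a, b in zip(idxs, idxs[1:]))
        if len(idxs) == 2 and len(strands) == 2 and not tandem:
            # opposite-strand distant copy: duplication + inverse transposition
            in_situ, mover = _resolve_mover(record, order, idxs)
            events.append(RearrangementEvent(
                "duplication", (names[in_situ],), in_situ, in_situ + 1))
            events.append(RearrangementEvent(
                "inverse_transposition", (names[mover],), in_situ + 1, mover))
        elif len(idxs) >= 3 and tandem and len(strands) == 1:
            # iterated tandem duplication of (spacer + gene) after one
            # partial random loss, supported by identical inter-copy spacers
            first = idxs[0]
            seg = tuple(names[first:idxs[-1] + 1])
            events.append(RearrangementEvent(
                "duplication", seg[:1], first, first + 1))
            events.append(RearrangementEvent(
                "partial_random_loss", seg[:1], first, first + 1))
            for k in range(1, len(idxs) - 1):
                events.append(RearrangementEvent(
                    "duplication", (names[idxs[k]],), idxs[k], idxs[k] + 1))
        else:
            events.append(RearrangementEvent(
                "duplication", (names[idxs[0]],), idxs[0], idxs[1]))
    return Pathway(events, order, order,
                   predicted_isps=[(s.upstream, s.downstream)
                                   for s in isps.values()])


def _resolve_mover(record, order: GeneOrder, idxs: list[int]) -> tuple[int, int]:
    """Decide which of two opposite-strand copies moved: the copy that
    overlaps an adjacent gene is in situ (its displacement would have
    disrupted the neighbour); fall back to the copy at the plesiomorphic
    MIQGO-neighbourhood position."""
    from .annotation import extract_isps

    overlaps = {(s.upstream, s.downstream)
                for s in extract_isps(record) if s.length < 0}
    names = order.rendered()
    n = len(names)
    for i in idxs:
        nm = names[i]
        if any(nm in pair for pair in overlaps):
            other = idxs[1] if i == idxs[0] else idxs[0]
            return i, other
    return idxs[1], idxs[0]
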