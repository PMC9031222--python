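"""Independent brute-force oracles used to validate the implementation.

Each oracle takes the slow, obviously-correct route (exhaustive subset
testing, full enumeration of move products, breadth-first search, quadratic
dynamic programming, exhaustive labelling) and is kept independent of the
code paths it checks.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations


# ---- common intervals ------------------------------------------------------

def brute_force_common_intervals(a: list, b: list) -> set[frozenset]:
    """All subsets of size 2..n contiguous in both orders, by testing every
    subset for contiguity."""
    n = len(a)
    pos_a = {g: i for i, g in enumerate(a)}
    pos_b = {g: i for i, g in enumerate(b)}
    out = set()
    for size in range(2, n + 1):
        for combo in combinations(a, size):
            pa = sorted(pos_a[g] for g in combo)
            pb = sorted(pos_b[g] for g in combo)
            if pa[-1] - pa[0] == size - 1 and pb[-1] - pb[0] == size - 1:
                out.add(frozenset(combo))
    return out


# ---- TDRL ------------------------------------------------------------------

def one_tdrl_products(order: tuple) -> set[tuple]:
    """Every distinct order reachable by one tandem-duplication-random-loss
    move: for every window and every kept-in-copy-1 subset, copy-1 genes in
    order followed by copy-2 genes in order."""
    n = len(order)
    out = set()
    for i in range(n):
        for j in range(i + 2, n + 1):
            win = order[i:j]
            w = len(win)
            for mask in range(1 << w):
                c1 = tuple(win[k] for k in range(w) if mask >> k & 1)
                c2 = tuple(win[k] for k in range(w) if not mask >> k & 1)
                out.add(order[:i] + c1 + c2 + order[j:])
    return out


def bfs_tdrl_distances(start: tuple, max_depth: int = 4) -> dict[tuple, int]:
    """Shortest TDRL-move path length from ``start`` to every reachable
    order within ``max_depth`` moves."""
    dist = {start: 0}
    frontier = deque([start])
    while frontier:
        cur = frontier.popleft()
        if dist[cur] >= max_depth:
            continue
        for nxt in one_tdrl_products(cur):
            if nxt not in dist:
                dist[nxt] = dist[cur] + 1
                frontier.append(nxt)
    return dist


# ---- single events ---------------------------------------------------------

def all_single_event_products(elems: tuple) -> set[tuple]:
    """Orders reachable by one transposition, inversion or inverse
    transposition of any contiguous block.  ``elems`` is a tuple of
    (name, strand) pairs."""
    def flip(block):
        return tuple((nm, "+" if s == "-" else "-") for nm, s in reversed(block))

    n = len(elems)
    out = set()
    for L in range(1, n):
        for i in range(0, n - L + 1):
            block = elems[i:i + L]
            out.add(elems[:i] + flip(block) + elems[i + L:])  # inversion
            rest = elems[:i] + elems[i + L:]
            for t in range(0, n - L + 1):
                if t == i:
                    continue
                out.add(rest[:t] + block + rest[t:])
                out.add(rest[:t] + flip(block) + rest[t:])
    out.discard(elems)
    return out


# ---- longest common substring ----------------------------------------------

def dp_longest_common_substring(a: str, b: str) -> int:
    """Classic O(|a||b|) dynamic program; returns the length only."""
    best = 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


# ---- parsimony -------------------------------------------------------------

def exhaustive_parsimony_score(tree, tip_states: dict[str, str],
                               states: list[str]) -> int:
    """Minimum number of state changes over all internal labellings."""
    from itertools import product

    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    best = None
    for combo in product(states, repeat=len(internal)):
        assign = dict(zip((id(nd) for nd in internal), combo))

        def state_of(nd):
            if nd.is_leaf():
                return tip_states[nd.taxon.label]
            return assign[id(nd)]

        changes = 0
        for nd in tree.preorder_node_iter():
            for child in nd.child_nodes():
                if state_of(nd) != state_of(child):
                    changes += 1
        if best is None or changes < best:
            best = changes
    return best
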