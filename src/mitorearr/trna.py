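"""tRNA cloverleaf structure against templates and character evolution.

Metazoan mitochondrial tRNAs fold into a cloverleaf: acceptor stem (ac,
7 bp), DHU arm (dh, up to 4 bp — absent in serine-AGN tRNAs), anticodon
arm (an, 5 bp with the anticodon at the centre of a 7-nt loop) and TΨC arm
(tp, up to 5 bp), plus a short variable region and an unpaired 3' tail.
Stems are indexed from the stem base outward, so an5 is the anticodon-stem
pair adjacent to the loop and tp1 the TΨC pair at the stem base.

A sequence "folds" to a template when enough of the template's paired
positions form Watson–Crick or G·U couples (80% by default) — an
operational stand-in for manual secondary-structure vetting.  Stem-pair
differences between two structures of the same template are classified as
identical, hemi-compensatory (one side changed, pairing kept),
fully compensatory (both sides changed, both pairs Watson–Crick) or
destabilizing.  Character states (anticodon type, gene copy number) are
mapped onto a given phylogeny by Fitch or Wagner parsimony; trees are
always inputs, never inferred from the tRNAs themselves.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import dendropy

from .gene_order import GeneOrderError

WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "T"), ("T", "G")}
VALID_PAIRS = WC_PAIRS | WOBBLE_PAIRS

FOLD_THRESHOLD = 0.8
MIN_TRNA_LEN, MAX_TRNA_LEN = 55, 95

STEM_NAMES = ("ac", "dh", "an", "tp")


class TRNAError(GeneOrderError):
    pass


# --------------------------------------------------------------------------
# Templates
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TRNATemplate:
    """Cloverleaf layout: region lengths fixed, pairs derived from them."""

    name: str
    family: str  # amino-acid identity; "S1" marks the serine-AGN family
    ac: int = 7
    dh: int = 4
    an: int = 5
    tp: int = 5
    dh_loop: int = 7
    an_loop: int = 7
    tp_loop: int = 7
    sp1: int = 2  # between acceptor stem and DHU arm
    sp2: int = 1  # between DHU arm and anticodon arm
    var: int = 4  # variable region
    tail: int = 4  # unpaired discriminator + NCC tail
    anticodon_default: str = "NNN"

    @property
    def length(self) -> int:
        return (2 * (self.ac + self.dh + self.an + self.tp)
                + self.dh_loop + self.an_loop + self.tp_loop
                + self.sp1 + self.sp2 + self.var + self.tail)

    def regions(self) -> dict[str, tuple[int, int]]:
        """Half-open [start, end) spans of each region, 0-based."""
        spans = {}
        pos = 0
        for nm, ln in (("ac5", self.ac), ("sp1", self.sp1), ("dh5", self.dh),
                       ("dh_loop", self.dh_loop), ("dh3", self.dh),
                       ("sp2", self.sp2), ("an5", self.an),
                       ("an_loop", self.an_loop), ("an3", self.an),
                       ("var", self.var), ("tp5", self.tp),
                       ("tp_loop", self.tp_loop), ("tp3", self.tp),
                       ("ac3", self.ac), ("tail", self.tail)):
            spans[nm] = (pos, pos + ln)
            pos += ln
        return spans

    def stem_pairs(self) -> dict[str, list[tuple[int, int]]]:
        """Paired 0-based index tuples per stem, numbered base -> loop."""
        r = self.regions()
        pairs: dict[str, list[tuple[int, int]]] = {}
        for stem, five, three in (("ac", "ac5", "ac3"), ("dh", "dh5", "dh3"),
                                  ("an", "an5", "an3"), ("tp", "tp5", "tp3")):
            (f0, f1), (t0, t1) = r[five], r[three]
            L = f1 - f0
            pairs[stem] = [(f0 + i, t1 - 1 - i) for i in range(L)]
        return pairs

    @property
    def anticodon_span(self) -> tuple[int, int]:
        lo, hi = self.regions()["an_loop"]
        mid = (lo + hi) // 2
        return (mid - 1, mid + 2)


_template_cache: dict[str, TRNATemplate] | None = None


def templates() -> dict[str, TRNATemplate]:
    """Shipped templates: a standard cloverleaf, the DHU-armless serine-AGN
    (trnS1) layout, and trnM/trnF presets."""
    global _template_cache
    if _template_cache is None:
        text = (resources.files("mitorearr")
                .joinpath("data/trna/templates.tsv").read_text())
        _template_cache = {}
        header = None
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                continue
            row = dict(zip(header, parts))
            _template_cache[row["name"]] = TRNATemplate(
                name=row["name"], family=row["family"],
                ac=int(row["ac"]), dh=int(row["dh"]), an=int(row["an"]),
                tp=int(row["tp"]), dh_loop=int(row["dh_loop"]),
                an_loop=int(row["an_loop"]), tp_loop=int(row["tp_loop"]),
                sp1=int(row["sp1"]), sp2=int(row["sp2"]),
                var=int(row["var"]), tail=int(row["tail"]),
                anticodon_default=row["anticodon_default"])
    return _template_cache


# --------------------------------------------------------------------------
# Folding
# --------------------------------------------------------------------------

@dataclass
class TRNAStructure:
    sequence: str
    template: TRNATemplate
    stems: dict[str, list[tuple[int, int]]]

    @property
    def anticodon(self) -> str:
        lo, hi = self.template.anticodon_span
        return self.sequence[lo:hi]

    def pair(self, stem: str, i: int) -> tuple[str, str]:
        """Nucleotide couple at 1-based pair ``i`` of ``stem`` (base->loop)."""
        p5, p3 = self.stems[stem][i - 1]
        return self.sequence[p5], self.sequence[p3]


@dataclass
class FoldOutcome:
    structure: TRNAStructure | None
    violated: list[tuple[str, int]]  # (stem, 1-based pair index)
    fraction_valid: float

    @property
    def ok(self) -> bool:
        return self.structure is not None


def fold_to_template(seq: str, template: TRNATemplate,
                     threshold: float = FOLD_THRESHOLD) -> FoldOutcome:
    """Check a sequence against a cloverleaf template.

    Deterministic and idempotent: stems sit at the template's fixed
    positions (anchored so the anticodon triplet falls at the loop centre);
    nucleotides beyond the template length are an unpaired 3' extension and
    never affect acceptance.  The structure is accepted iff at least
    ``threshold`` of the template pairs are Watson–Crick or G·U; on failure
    the violated pairs are listed.
    """
    if not (MIN_TRNA_LEN <= len(seq) <= MAX_TRNA_LEN):
        raise TRNAError(
            f"sequence length {len(seq)} outside {MIN_TRNA_LEN}..{MAX_TRNA_LEN}")
    core = template.length - template.tail
    if len(seq) < core:
        raise TRNAError(
            f"sequence of {len(seq)} nt shorter than the {core}-nt paired "
            f"core of template {template.name!r}")
    s = seq.upper().replace("U", "T")
    pairs = template.stem_pairs()
    violated = []
    total = 0
    for stem, plist in pairs.items():
        for i, (p5, p3) in enumerate(plist, start=1):
            total += 1
            if (s[p5], s[p3]) not in VALID_PAIRS:
                violated.append((stem, i))
    frac = 1.0 - len(violated) / total if total else 0.0
    if frac >= threshold:
        return FoldOutcome(TRNAStructure(s, template, pairs), violated, frac)
    return FoldOutcome(None, violated, frac)


# --------------------------------------------------------------------------
# Anticodon typing and stem-pair comparison
# --------------------------------------------------------------------------

S1_TYPES = ("GCT", "ACT", "TCT")


@dataclass(frozen=True)
class AnticodonType:
    triplet: str
    label: str | None  # GCT/ACT/TCT for the serine-AGN family, else None


def anticodon_type(struct: TRNAStructure) -> AnticodonType:
    """Anticodon triplet, labelled for serine-AGN (trnS1) templates.

    GCT is the plesiomorphic lepidopteran condition; ACT and TCT arise
    repeatedly in parallel.
    """
    tri = struct.anticodon
    if any(ch not in "ACGT" for ch in tri):
        raise TRNAError(f"anticodon {tri!r} contains ambiguity codes")
    if struct.template.family == "S1":
        if tri not in S1_TYPES:
            return AnticodonType(tri, None)
        return AnticodonType(tri, tri)
    return AnticodonType(tri, None)


PAIR_CLASSES = ("identical", "hemi", "fully_compensatory", "destabilizing")


@dataclass(frozen=True)
class StemPairChange:
    stem: str
    index: int  # 1-based from the stem base
    pair1: tuple[str, str]
    pair2: tuple[str, str]
    kind: str


def compare_stem_pairs(s1: TRNAStructure, s2: TRNAStructure
                       ) -> list[StemPairChange]:
    """Classify every stem position between two same-template structures.

    fully_compensatory: both nucleotides changed and both couples are
    Watson–Crick (e.g. an5 A–T vs G–C, tp1 A–T vs T–A); hemi: one side
    changed with pairing (G·U allowed) preserved; destabilizing otherwise.
    """
    if s1.template != s2.template:
        raise TRNAError("structures use different templates")
    out = []
    for stem in STEM_NAMES:
        for i in range(1, len(s1.stems[stem]) + 1):
            p1, p2 = s1.pair(stem, i), s2.pair(stem, i)
            if p1 == p2:
                kind = "identical"
            elif p1[0] != p2[0] and p1[1] != p2[1]:
                kind = ("fully_compensatory"
                        if p1 in WC_PAIRS and p2 in WC_PAIRS
                        else "destabilizing")
            else:  # exactly one side changed
                kind = ("hemi" if p1 in VALID_PAIRS and p2 in VALID_PAIRS
                        else "destabilizing")
            out.append(StemPairChange(stem, i, p1, p2, kind))
    return out


# --------------------------------------------------------------------------
# Parsimony mapping on a given phylogeny
# --------------------------------------------------------------------------

@dataclass
class CharacterStateMap:
    tree: dendropy.Tree
    tip_states: dict[str, frozenset]
    ancestral_states: dict[str, frozenset]
    min_changes: int


def _check_tips(tree: dendropy.Tree, tip_states: Mapping) -> None:
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = tips - set(tip_states)
    if missing:
        raise TRNAError(f"tips missing a state: {sorted(missing)}")


def _node_key(node: dendropy.Node, counter: itertools.count) -> str:
    if node.taxon is not None:
        return node.taxon.label
    if node.label:
        return node.label
    key = f"node{next(counter)}"
    node.label = key
    return key


def fitch_map(tree: dendropy.Tree, tip_states: Mapping[str, Sequence]
              ) -> CharacterStateMap:
    """Fitch parsimony on a rooted tree, multistate, unordered.

    The bottom-up pass intersects child state sets where possible (a union
    costs one change); the top-down pass resolves ancestral sets against
    each parent.  ``min_changes`` is the parsimony score of the returned
    labelling, which is optimal for binary trees.
    """
    _check_tips(tree, tip_states)
    counter = itertools.count(1)
    down: dict[dendropy.Node, frozenset] = {}
    changes = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            down[node] = frozenset(tip_states[node.taxon.label])
            if not down[node]:
                raise TRNAError(f"empty state set for tip {node.taxon.label}")
        else:
            kids = [down[c] for c in node.child_nodes()]
            inter = frozenset.intersection(*kids)
            if inter:
                down[node] = inter
            else:
                down[node] = frozenset.union(*kids)
                changes += len(kids) - 1 if len(kids) > 2 else 1
    # top-down refinement
    anc: dict[str, frozenset] = {}
    root = tree.seed_node
    anc_states: dict[dendropy.Node, frozenset] = {root: down[root]}
    for node in tree.preorder_node_iter():
        if node is not root:
            inter = down[node] & anc_states[node.parent_node]
            anc_states[node] = inter if inter else down[node]
        anc[_node_key(node, counter)] = anc_states[node]
    return CharacterStateMap(tree, {k: frozenset(v) for k, v in tip_states.items()},
                             anc, changes)


def wagner_map(tree: dendropy.Tree, tip_states: Mapping[str, int],
               max_state: int | None = None) -> CharacterStateMap:
    """Ordered (Wagner) parsimony for an integer character such as gene
    copy number: a change between states i and j costs |i - j|, so each
    duplication or loss step costs one.  Sankoff dynamic programming with
    top-down backtracking; ancestral sets contain every state on some
    optimal labelling consistent with the chosen parent state."""
    _check_tips(tree, tip_states)
    states = sorted(set(tip_states.values()))
    hi = max(states) if max_state is None else max_state
    lo = min(states + [0])
    domain = list(range(lo, hi + 1))
    INF = float("inf")
    cost: dict[dendropy.Node, dict[int, float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = tip_states[node.taxon.label]
            cost[node] = {d: (0 if d == s else INF) for d in domain}
        else:
            cost[node] = {}
            for d in domain:
                tot = 0.0
                for c in node.child_nodes():
                    tot += min(cost[c][e] + abs(d - e) for e in domain)
                cost[node][d] = tot
    root = tree.seed_node
    best = min(cost[root].values())
    counter = itertools.count(1)
    anc: dict[str, frozenset] = {}
    choice: dict[dendropy.Node, int] = {}
    for node in tree.preorder_node_iter():
        if node is root:
            opts = [d for d in domain if cost[node][d] == best]
        else:
            p = choice[node.parent_node]
            score = min(cost[node][e] + abs(p - e) for e in domain)
            opts = [d for d in domain if cost[node][d] + abs(p - d) == score]
        choice[node] = min(opts)
        anc[_node_key(node, counter)] = frozenset(opts)
    return CharacterStateMap(tree, {k: frozenset([v]) for k, v in tip_states.items()},
                             anc, int(best))
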