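"""Signed circular mitochondrial gene orders and common-interval comparison.

The mitogenome of insects carries 37 genes (13 protein-coding, 22 tRNAs,
2 rRNAs) plus the control region, giving a 38-element vocabulary.  A gene
order is a signed circular arrangement over that vocabulary; comparisons are
done after linearizing both orders at a shared anchor gene (cox1 by default,
the convention used throughout the butterfly literature).

Two orders are compared through their *common intervals*: subsets of genes
that occur contiguously in both arrangements.  The shared-common-interval
(SCI) count, expressed as a percentage of the self-comparison count, is a
conservation score: identical orders score 100%, a single adjacent swap
barely dents it, and heavily rearranged orders drop far below.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from typing import Iterable, Sequence

# --------------------------------------------------------------------------
# Controlled vocabulary: 13 CDS + 22 tRNAs + 2 rRNAs + control region = 38
# --------------------------------------------------------------------------

CDS_GENES = (
    "cox1", "cox2", "cox3", "cob",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
    "atp6", "atp8",
)
TRNA_GENES = (
    "A", "C", "D", "E", "F", "G", "H", "I", "K", "L1", "L2",
    "M", "N", "P", "Q", "R", "S1", "S2", "T", "V", "W", "Y",
)
RRNA_GENES = ("rrnS", "rrnL")
CONTROL_REGION = "CoRe"

VOCABULARY = frozenset(CDS_GENES) | frozenset(TRNA_GENES) | frozenset(RRNA_GENES) | {CONTROL_REGION}
assert len(VOCABULARY) == 38

DEFAULT_ANCHOR = "cox1"

# Hotspot tRNA clusters of the butterfly mitogenome.
CLUSTER_ARNS1EF = frozenset({"A", "R", "N", "S1", "E", "F"})
CLUSTER_MIQ = frozenset({"M", "I", "Q"})


class GeneOrderError(ValueError):
    """Base class for gene-order level errors."""


class UnknownGeneNameError(GeneOrderError):
    def __init__(self, names: Sequence[str]):
        self.names = list(names)
        super().__init__(f"unrecognized gene name(s): {', '.join(self.names)}")


class AnchorError(GeneOrderError):
    pass


class GeneSetMismatchError(GeneOrderError):
    def __init__(self, only_a: Iterable[str], only_b: Iterable[str]):
        self.only_a = sorted(only_a)
        self.only_b = sorted(only_b)
        super().__init__(
            f"gene sets differ; only in first: {self.only_a or '-'}; "
            f"only in second: {self.only_b or '-'}"
        )


class IncompleteGeneSetError(GeneOrderError):
    def __init__(self, missing: Iterable[str]):
        self.missing = sorted(missing)
        super().__init__(f"incomplete gene set, missing: {self.missing}")


# --------------------------------------------------------------------------
# Labels
# --------------------------------------------------------------------------

_COPY_LETTERS = "abcdefghij"


@dataclass(frozen=True, order=True)
class GeneLabel:
    """A gene name from the controlled vocabulary plus a copy index.

    ``copy`` is 1 for the sole/first copy; duplicated copies are numbered in
    order of occurrence along the genome and rendered with letter suffixes
    (Qa, Qb, ...) when the arrangement carries more than one copy.
    """

    name: str
    copy: int = 1

    def __post_init__(self):
        if self.name not in VOCABULARY:
            raise UnknownGeneNameError([self.name])
        if self.copy < 1:
            raise GeneOrderError(f"copy index must be >= 1, got {self.copy}")

    def render(self, duplicated: bool = False) -> str:
        if duplicated or self.copy > 1:
            return f"{self.name}{_COPY_LETTERS[self.copy - 1]}"
        return self.name

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.render()


# --------------------------------------------------------------------------
# Gene name normalization
# --------------------------------------------------------------------------

_AA3_TO_1 = {
    "ala": "A", "cys": "C", "asp": "D", "glu": "E", "phe": "F",
    "gly": "G", "his": "H", "ile": "I", "lys": "K", "met": "M",
    "asn": "N", "pro": "P", "gln": "Q", "arg": "R", "thr": "T",
    "val": "V", "trp": "W", "tyr": "Y",
}

_SYNONYMS = {
    # protein-coding genes
    "co1": "cox1", "coi": "cox1", "coxi": "cox1", "cox1": "cox1",
    "co2": "cox2", "coii": "cox2", "coxii": "cox2", "cox2": "cox2",
    "co3": "cox3", "coiii": "cox3", "coxiii": "cox3", "cox3": "cox3",
    "cytb": "cob", "cob": "cob", "cb": "cob",
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4L", "nd5": "nad5", "nd6": "nad6",
    "nad1": "nad1", "nad2": "nad2", "nad3": "nad3", "nad4": "nad4",
    "nad4l": "nad4L", "nad5": "nad5", "nad6": "nad6",
    "atp6": "atp6", "atp8": "atp8", "atpase6": "atp6", "atpase8": "atp8",
    # rRNAs
    "rrns": "rrnS", "12s": "rrnS", "srrna": "rrnS", "s-rrna": "rrnS",
    "12srrna": "rrnS", "rrnl": "rrnL", "16s": "rrnL", "lrrna": "rrnL",
    "l-rrna": "rrnL", "16srrna": "rrnL",
    # control region
    "core": "CoRe", "dloop": "CoRe", "d-loop": "CoRe",
    "controlregion": "CoRe", "atrichregion": "CoRe", "a+trichregion": "CoRe",
    "cr": "CoRe",
}

_CODON_FAMILY = {
    # leucine / serine disambiguation by codon family
    "cun": "L1", "ctn": "L1", "uur": "L2", "ttr": "L2", "uua": "L2", "tta": "L2",
    "agn": "S1", "agc": "S1", "agy": "S1", "ucn": "S2", "tcn": "S2", "uga": "S2", "tga": "S2", "gct": "S1",
}

_TRNA_RE = re.compile(r"^(?:trna[-_ ]?|trn)(.+)$", re.IGNORECASE)


def _normalize_one(raw: str) -> str:
    """Map one free-text annotation name to its canonical base name."""
    token = raw.strip()
    key = re.sub(r"[\s_]+", "", token).lower()
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    # vocabulary names used verbatim (nad2, S1, CoRe, ...)
    if token in VOCABULARY:
        return token
    m = _TRNA_RE.match(token)
    body = m.group(1) if m else token
    # tRNA forms: "M", "trnM", "tRNA-Met", "tRNA-Ser(AGN)", "trnL1", "S1"
    body = body.strip()
    fam = re.search(r"\(([^)]+)\)", body)
    stem = re.sub(r"\([^)]*\)", "", body).strip().rstrip("-_ ")
    stem_l = stem.lower()
    if stem_l in _AA3_TO_1:
        base = _AA3_TO_1[stem_l]
    elif stem_l in ("leu", "ser"):
        base = None  # needs codon family
    elif stem in TRNA_GENES:
        return stem
    elif stem.upper() in ("L1", "L2", "S1", "S2"):
        return stem.upper()
    elif len(stem) == 1 and stem.upper() in TRNA_GENES:
        return stem.upper()
    else:
        raise UnknownGeneNameError([raw])
    if base is not None:
        return base
    if fam:
        famkey = fam.group(1).replace("-", "").lower()
        if famkey in _CODON_FAMILY:
            return _CODON_FAMILY[famkey]
    raise UnknownGeneNameError([raw])


def normalize_labels(raw_names: Sequence[str]) -> list[GeneLabel]:
    """Normalize free-text gene names to canonical labels.

    Names are processed in genome order; duplicated base names receive copy
    indices 1, 2, ... in order of occurrence.  Unrecognized names raise
    :class:`UnknownGeneNameError` listing every offender.
    """
    if not raw_names:
        raise GeneOrderError("empty annotation name list")
    bases, bad = [], []
    for raw in raw_names:
        try:
            bases.append(_normalize_one(raw))
        except UnknownGeneNameError:
            bad.append(raw)
    if bad:
        raise UnknownGeneNameError(bad)
    seen: dict[str, int] = {}
    labels = []
    for b in bases:
        seen[b] = seen.get(b, 0) + 1
        labels.append(GeneLabel(b, seen[b]))
    return labels


# --------------------------------------------------------------------------
# GeneOrder
# --------------------------------------------------------------------------

Element = tuple[GeneLabel, str]  # (label, strand '+'/'-')


@dataclass(frozen=True)
class GeneOrder:
    """An ordered signed arrangement of gene labels.

    ``topology`` is ``"circular"`` (rotation-equivalent) or ``"linearized"``
    (fixed start at ``anchor``).
    """

    elements: tuple[Element, ...]
    topology: str = "circular"
    anchor: str | None = None
    name: str | None = None
    provenance: str | None = None

    def __post_init__(self):
        for lab, strand in self.elements:
            if strand not in ("+", "-"):
                raise GeneOrderError(f"bad strand {strand!r} for {lab}")

    # -- basic views -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.elements)

    def base_names(self) -> list[str]:
        return [lab.name for lab, _ in self.elements]

    def multiplicity(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for lab, _ in self.elements:
            counts[lab.name] = counts.get(lab.name, 0) + 1
        return counts

    def has_duplicates(self) -> bool:
        return any(v > 1 for v in self.multiplicity().values())

    def signature(self) -> tuple[tuple[str, int, str], ...]:
        """Rotation-independent only after linearization: (name, copy, strand)."""
        return tuple((lab.name, lab.copy, s) for lab, s in self.elements)

    def rendered(self) -> list[str]:
        multi = {n for n, c in self.multiplicity().items() if c > 1}
        return [lab.render(lab.name in multi) for lab, _ in self.elements]

    def is_complete(self) -> bool:
        return set(self.base_names()) >= VOCABULARY

    # -- construction helpers ---------------------------------------------
    @classmethod
    def from_names(cls, names: Sequence[str], strands: Sequence[str] | None = None,
                   **kw) -> "GeneOrder":
        labels = normalize_labels(list(names))
        if strands is None:
            strands = ["+"] * len(labels)
        return cls(tuple(zip(labels, strands)), **kw)

    def rotate(self, k: int) -> "GeneOrder":
        k %= len(self.elements)
        return replace(self, elements=self.elements[k:] + self.elements[:k],
                       topology="circular", anchor=None)


def linearize(order: GeneOrder, anchor: str = DEFAULT_ANCHOR) -> GeneOrder:
    """Rotate a circular order to start at ``anchor``; idempotent.

    The anchor must occur exactly once.  Strands and cyclic succession are
    preserved; the result carries ``topology="linearized"``.
    """
    hits = [i for i, (lab, _) in enumerate(order.elements) if lab.name == anchor]
    if len(hits) != 1:
        raise AnchorError(
            f"anchor {anchor!r} occurs {len(hits)} times; need exactly one")
    i = hits[0]
    return replace(order, elements=order.elements[i:] + order.elements[:i],
                   topology="linearized", anchor=anchor)


# --------------------------------------------------------------------------
# Common intervals
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CommonIntervalSet:
    intervals: frozenset[frozenset[str]]
    n: int
    min_size: int = 2

    @property
    def count(self) -> int:
        return len(self.intervals)

    def self_count(self) -> int:
        """Common-interval count of an identical pair of this size."""
        return self.n * (self.n - 1) // 2


def _check_comparable(a: GeneOrder, b: GeneOrder) -> tuple[list[str], list[str]]:
    na, nb = a.base_names(), b.base_names()
    if len(set(na)) != len(na) or len(set(nb)) != len(nb):
        raise GeneOrderError(
            "orders contain duplicated base names; collapse duplicates first")
    if set(na) != set(nb):
        raise GeneSetMismatchError(set(na) - set(nb), set(nb) - set(na))
    return na, nb


def common_intervals(a: GeneOrder, b: GeneOrder) -> CommonIntervalSet:
    """All gene subsets of size 2..n contiguous in both linearized orders.

    Signs are ignored: intervals are unsigned element sets, following the
    counting convention of interval-based gene-order comparison tools.  Every
    common interval is necessarily a window of ``a``, so windows of ``a`` are
    enumerated and tested for contiguity in ``b`` via position ranks
    (O(n^2) incremental min/max, ample at n = 38).
    """
    na, nb = _check_comparable(a, b)
    pos_b = {g: i for i, g in enumerate(nb)}
    n = len(na)
    found = set()
    for i in range(n):
        lo = hi = pos_b[na[i]]
        for j in range(i + 1, n):
            p = pos_b[na[j]]
            lo, hi = min(lo, p), max(hi, p)
            if hi - lo == j - i:
                found.add(frozenset(na[i:j + 1]))
    return CommonIntervalSet(frozenset(found), n=n)


def round_half_up(x: float, digits: int = 0) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def sci_percentage(a: GeneOrder, b: GeneOrder, *, convention: str = "size2",
                   rounded: bool = True) -> float:
    """Shared-common-interval percentage of the self-comparison count.

    ``convention="size2"`` (default) counts unsigned intervals of size 2..n
    (denominator n(n-1)/2); ``convention="singleton"`` additionally counts
    the n singletons (denominator n(n+1)/2).  Reported values are rounded
    half-up to integer percent; pass ``rounded=False`` for the raw float.
    """
    cis = common_intervals(a, b)
    n = cis.n
    if convention == "size2":
        num, den = cis.count, n * (n - 1) // 2
    elif convention == "singleton":
        num, den = cis.count + n, n * (n + 1) // 2
    else:
        raise ValueError(f"unknown convention {convention!r}")
    pct = 100.0 * num / den
    return round_half_up(pct) if rounded else pct


# --------------------------------------------------------------------------
# Registry of named arrangements
# --------------------------------------------------------------------------

REGISTRY_NAMES = (
    "PanGO", "MIQGO", "IMQGO", "S1NGO", "ES1GO", "2NGO", "2S1EGO",
    "2S1GO", "2FFGO", "4QGO", "BemGO",
)

_REGISTRY_FILES = {name: f"{name.lower()}.tsv" for name in REGISTRY_NAMES}
_REGISTRY_FILES["BemGO"] = "bemgo_synthetic.tsv"

_registry_cache: dict[str, GeneOrder] | None = None


def read_order_file(text: str, name: str | None = None) -> GeneOrder:
    """Parse a plain-text order file: one 'gene<TAB>strand' line per gene,
    '#' comment lines allowed (a '# provenance:' line is kept as metadata)."""
    names, strands, prov = [], [], None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "provenance:" in line:
                prov = line.split("provenance:", 1)[1].strip()
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise GeneOrderError(f"bad order line: {line!r}")
        names.append(parts[0])
        strands.append("-" if parts[1].strip() in ("-", "−") else "+")
    order = GeneOrder.from_names(names, strands, topology="linearized",
                                 anchor=DEFAULT_ANCHOR, name=name,
                                 provenance=prov)
    return order


def write_order_file(order: GeneOrder) -> str:
    lines = []
    if order.provenance:
        lines.append(f"# provenance: {order.provenance}")
    for rendered, (_, strand) in zip(order.rendered(), order.elements):
        base = rendered.rstrip(_COPY_LETTERS) if rendered not in VOCABULARY else rendered
        lines.append(f"{base}\t{strand}")
    return "\n".join(lines) + "\n"


def registry() -> dict[str, GeneOrder]:
    """Named gene orders of the butterfly literature, linearized at cox1."""
    global _registry_cache
    if _registry_cache is None:
        _registry_cache = {}
        pkg = resources.files("mitorearr").joinpath("data/orders")
        for name, fn in _REGISTRY_FILES.items():
            text = pkg.joinpath(fn).read_text()
            _registry_cache[name] = read_order_file(text, name=name)
    return _registry_cache


def classify_arrangement(g: GeneOrder) -> tuple[str, str | None]:
    """Match a complete linearized order against the registry.

    Returns ``(name, None)`` on an exact match (element sequence including
    duplications and strands), else ``("novel", nearest)`` where ``nearest``
    is the registry entry with the highest SCI percentage after duplicate
    collapsing.
    """
    missing = VOCABULARY - set(g.base_names())
    if missing:
        raise IncompleteGeneSetError(missing)
    if g.topology != "linearized":
        g = linearize(g, DEFAULT_ANCHOR)
    sig = g.signature()
    for name, order in registry().items():
        if order.signature() == sig:
            return name, None
    flat = collapse_duplicates(g)
    best_name, best_sci = None, -1.0
    for name, order in registry().items():
        ref = collapse_duplicates(order)
        try:
            s = sci_percentage(flat, ref, rounded=False)
        except GeneOrderError:
            continue
        if s > best_sci:
            best_name, best_sci = name, s
    return "novel", best_name


def collapse_duplicates(g: GeneOrder, policy: str = "keep-plesiomorphic-position") -> GeneOrder:
    """Retain exactly one copy of each duplicated base name.

    Under the default policy the retained copy is the one whose immediate
    neighbours match its neighbours in MIQGO (the plesiomorphic butterfly
    order); ties and no-match fall back to the first copy.  ``policy=
    "keep-first"`` always keeps the first copy.
    """
    if not g.has_duplicates():
        return g
    if policy not in ("keep-plesiomorphic-position", "keep-first"):
        raise ValueError(f"unknown policy {policy!r}")
    counts = g.multiplicity()
    keep_idx: dict[str, int] = {}
    if policy == "keep-first":
        for i, (lab, _) in enumerate(g.elements):
            keep_idx.setdefault(lab.name, i)
    else:
        ref = registry()["MIQGO"].base_names() if g.name != "MIQGO" else None
        if ref is None:
            ref = g.base_names()
        nref = len(ref)
        neigh = {ref[i]: (ref[i - 1], ref[(i + 1) % nref]) for i in range(nref)}
        names = g.base_names()
        n = len(names)
        best: dict[str, tuple[int, int]] = {}  # name -> (-score, index)
        for i, nm in enumerate(names):
            if counts[nm] == 1:
                continue
            prev_, next_ = names[i - 1], names[(i + 1) % n]
            want = neigh.get(nm)
            score = 0
            if want is not None:
                score = (prev_ == want[0]) + (next_ == want[1])
            cand = (-score, i)
            if nm not in best or cand < best[nm]:
                best[nm] = cand
        keep_idx = {nm: i for nm, (_, i) in best.items()}
    out = []
    for i, (lab, strand) in enumerate(g.elements):
        if counts[lab.name] == 1 or keep_idx.get(lab.name) == i:
            out.append((GeneLabel(lab.name, 1), strand))
    return replace(g, elements=tuple(out),
                   provenance=(g.provenance or "") + f" [collapsed:{policy}]")
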