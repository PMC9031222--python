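"""Synthetic mitogenomes, scripted rearrangements and tRNA families.

The generator emulates the features of butterfly mitogenomes that the
analysis stages consume: ~15-kb circular AT-rich (default 80% A+T)
genomes carrying any named arrangement from the registry, with per-gene
lengths in the lepidopteran range, tRNA genes that fold to their
cloverleaf templates, and small intergenic spacers.  Scripted
rearrangement events rebuild the genome and plant decaying remnants of
the lost gene copies in the spacers the event creates, so the
spacer-homology stages have a known ground truth.  Background sequence is
i.i.d. at the configured AT bias — no codon structure, which is
sufficient for gene-order and spacer analyses.

Everything is deterministic under (config, seed); truth tables accompany
each generated dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import (
    GeneAnnotation,
    MitogenomeRecord,
    feature_type_of,
    gene_order_of,
    revcomp,
)
from .gene_order import (
    CONTROL_REGION,
    GeneOrder,
    GeneOrderError,
    TRNA_GENES,
    registry,
)
from .rearrangements import RearrangementEvent, apply_event
from .trna import TRNATemplate, templates

# typical lepidopteran gene lengths (bases); tRNAs fall back to their
# template length
DEFAULT_GENE_LENGTHS = {
    "cox1": 1531, "cox2": 688, "cox3": 789, "cob": 1149,
    "nad1": 936, "nad2": 1023, "nad3": 354, "nad4": 1341, "nad4L": 291,
    "nad5": 1734, "nad6": 531, "atp6": 678, "atp8": 162,
    "rrnS": 780, "rrnL": 1350, CONTROL_REGION: 350,
}

_BASES = np.array(list("ATGC"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    ``remnant_retention`` is the fraction of a lost gene copy that survives
    in the spacer left behind by a rearrangement; ``subst_rate`` the
    per-site substitution probability applied to such remnants (and to
    duplicated-copy divergence).
    """

    seed: int = 0
    arrangement: str = "MIQGO"
    genome_at_content: float = 0.80
    gene_lengths: dict = field(default_factory=dict)
    spacer_length_range: tuple[int, int] = (2, 8)
    remnant_retention: float = 0.5
    subst_rate: float = 0.10

    def __post_init__(self):
        if not (0.0 <= self.genome_at_content <= 1.0):
            raise GeneOrderError("genome_at_content must be in [0, 1]")
        if not (0.0 <= self.remnant_retention <= 1.0):
            raise GeneOrderError("remnant_retention must be in [0, 1]")
        if not (0.0 <= self.subst_rate <= 1.0):
            raise GeneOrderError("subst_rate must be in [0, 1]")


def _probs(at: float) -> np.ndarray:
    return np.array([at / 2, at / 2, (1 - at) / 2, (1 - at) / 2])


def random_seq(rng: np.random.Generator, n: int, at: float) -> str:
    return "".join(rng.choice(_BASES, size=n, p=_probs(at)))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        repl = rng.choice(_BASES, size=int(hit.sum()))
        # force a change where the draw equals the original
        same = repl == arr[hit]
        while same.any():
            repl[same] = rng.choice(_BASES, size=int(same.sum()))
            same = repl == arr[hit]
        arr[hit] = repl
    return "".join(arr)


# --------------------------------------------------------------------------
# tRNA sequence generation
# --------------------------------------------------------------------------

_WC = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]


def trna_template_for(gene: str) -> TRNATemplate:
    t = templates()
    return t.get(gene, t["standard"])


def generate_trna_sequence(template: TRNATemplate, rng: np.random.Generator,
                           at: float, anticodon: str | None = None) -> str:
    """A sequence that folds to the template: every stem pair Watson–Crick
    (AT-weighted), loops i.i.d. at the AT bias, requested anticodon set."""
    n = template.length
    seq = list(random_seq(rng, n, at))
    p_at = at  # weight of A-T/T-A pair types
    for plist in template.stem_pairs().values():
        for p5, p3 in plist:
            if rng.random() < p_at:
                pair = _WC[rng.integers(0, 2)]
            else:
                pair = _WC[2 + rng.integers(0, 2)]
            seq[p5], seq[p3] = pair
    tri = anticodon or template.anticodon_default
    if tri and "N" not in tri:
        lo, hi = template.anticodon_span
        seq[lo:hi] = list(tri)
    return "".join(seq)


# --------------------------------------------------------------------------
# Genome generation
# --------------------------------------------------------------------------

def _gene_length(cfg: SimConfig, gene: str) -> int:
    if gene in cfg.gene_lengths:
        return cfg.gene_lengths[gene]
    if gene in DEFAULT_GENE_LENGTHS:
        return DEFAULT_GENE_LENGTHS[gene]
    return trna_template_for(gene).length


def _gene_sequence(cfg: SimConfig, gene: str, rng: np.random.Generator) -> str:
    if gene in TRNA_GENES:
        tpl = trna_template_for(gene)
        want = _gene_length(cfg, gene)
        seq = generate_trna_sequence(tpl, rng, cfg.genome_at_content)
        if want > len(seq):
            seq += random_seq(rng, want - len(seq), cfg.genome_at_content)
        return seq[:max(want, tpl.length)] if want >= tpl.length else seq
    return random_seq(rng, _gene_length(cfg, gene), cfg.genome_at_content)


def generate_mitogenome(cfg: SimConfig) -> MitogenomeRecord:
    """A circular annotated genome carrying the requested arrangement.

    Gene sequences are generated once per base name, so duplicated copies
    start out identical (the condition observed for tandem tRNA
    multiplications); for arrangements with three or more tandem copies the
    inter-copy spacers are likewise identical, built as a mosaic of the
    downstream spacer, the control-region 3' end, the trnM 3' end and trnI
    — the repeat-unit structure that iterated tandem duplication produces.
    """
    reg = registry()
    if cfg.arrangement not in reg:
        raise GeneOrderError(f"unknown arrangement {cfg.arrangement!r}")
    order = reg[cfg.arrangement]
    rng = np.random.default_rng(cfg.seed)
    gene_seqs: dict[str, str] = {}
    for name in dict.fromkeys(order.base_names()):
        gene_seqs[name] = _gene_sequence(cfg, name, rng)

    # spacers per junction
    lo, hi = cfg.spacer_length_range
    elems = order.elements
    n = len(elems)
    spacers = [random_seq(rng, int(rng.integers(lo, hi + 1)), cfg.genome_at_content)
               for _ in range(n)]

    # tandem multi-copy genes get identical repeat-unit spacers (mosaic)
    counts = order.multiplicity()
    tandem_gene = None
    for nm, c in counts.items():
        idxs = [i for i, (lab, _) in enumerate(elems) if lab.name == nm]
        if c >= 3 and all(b - a == 1 for a, b in zip(idxs, idxs[1:])):
            tandem_gene = (nm, idxs)
    if tandem_gene is not None:
        nm, idxs = tandem_gene
        downstream_isp = spacers[idxs[-1]]  # spacer after the last copy
        unit = (mutate(rng, downstream_isp, cfg.subst_rate)
                + gene_seqs[CONTROL_REGION][-20:]
                + gene_seqs["M"][-20:]
                + gene_seqs["I"][-25:])
        for i in idxs[:-1]:
            spacers[i] = unit

    parts: list[str] = []
    anns: list[GeneAnnotation] = []
    pos = 1
    for i, (lab, strand) in enumerate(elems):
        gseq = gene_seqs[lab.name]
        placed = revcomp(gseq) if strand == "-" else gseq
        anns.append(GeneAnnotation(lab, pos, pos + len(placed) - 1, strand,
                                   feature_type_of(lab.name)))
        parts.append(placed)
        pos += len(placed)
        parts.append(spacers[i])
        pos += len(spacers[i])
    rec = MitogenomeRecord(
        id=f"SIM-{cfg.arrangement}-{cfg.seed}", sequence="".join(parts),
        annotations=anns,
        description=f"synthetic {cfg.arrangement} mitogenome (seed {cfg.seed})")
    rec.validate()
    return rec


# --------------------------------------------------------------------------
# Scripted rearrangement with planted remnants
# --------------------------------------------------------------------------

def apply_scripted_event(record: MitogenomeRecord, event: RearrangementEvent,
                         cfg: SimConfig) -> MitogenomeRecord:
    """Rebuild a genome after one rearrangement event, planting remnants.

    The gene order is updated by the event; spacers at rearrangement-
    associated positions receive ``remnant_retention`` of the lost copy's
    3' end, point-mutated at ``subst_rate`` (the decayed pseudogene the
    event leaves behind).  TDRL lays the two tandem copies out with the
    non-retained genes of each copy decayed in place; transpositions and
    inverse transpositions leave remnants of the moved block at its source
    junction; inversions flip the block in place without remnants.
    """
    order = gene_order_of(record)
    try:
        new_order = apply_event(order, event)
    except GeneOrderError as exc:
        raise GeneOrderError(
            f"event not applicable to {record.id}: {exc}") from exc
    rng = np.random.default_rng([cfg.seed, 917, len(record.sequence) % 9973])

    anns = sorted(record.annotations, key=lambda a: a.start)
    multi: dict[str, int] = {}
    for a in anns:
        multi[a.label.name] = multi.get(a.label.name, 0) + 1
    gene_seq = {a.label.render(False) if multi[a.label.name] == 1
                else a.label.render(True): record.feature_sequence(a)
                for a in anns}
    old_names = order.rendered()
    old_strand = {nm: s for nm, (_, s) in zip(old_names, order.elements)}

    def remnant(nm: str) -> str:
        if cfg.remnant_retention <= 0:
            return random_seq(rng, int(rng.integers(*cfg.spacer_length_range)),
                              cfg.genome_at_content)
        seq = gene_seq[nm]
        keep = max(1, round(cfg.remnant_retention * len(seq)))
        return mutate(rng, seq[-keep:], cfg.subst_rate)

    def spacer() -> str:
        lo, hi = cfg.spacer_length_range
        return random_seq(rng, int(rng.integers(lo, hi + 1)),
                          cfg.genome_at_content)

    # per-position extra sequence (remnants) inserted *before* each gene of
    # the new order, keyed by rendered name
    pre_insert: dict[str, str] = {}
    if event.kind == "tdrl":
        set1, set2 = event.tdrl_partition
        i, j = event.tdrl_window
        win = old_names[i:j]
        # copy 1: genes of set1 survive, set2 decay in place; copy 2 mirrors
        copy1 = [(nm, nm in set1) for nm in win]
        copy2 = [(nm, nm in set2) for nm in win]
        layout = copy1 + copy2
        # attach each remnant run to the next surviving gene
        pending = ""
        attached: dict[str, str] = {}
        for nm, alive in layout:
            if alive:
                attached[nm] = pending
                pending = ""
            else:
                pending += remnant(nm)
        tail = pending
        if tail:
            # remnants after the last survivor run into the next spacer
            after = old_names[j] if j < len(old_names) else old_names[0]
            attached[after] = attached.get(after, "") + tail
        pre_insert = {nm: s for nm, s in attached.items() if s}
    elif event.kind in ("transposition", "inverse_transposition"):
        # remnants of the moved block stay at the source junction, i.e.
        # before the gene that followed the block in the old order
        i, L = event.source_position, len(event.moved_block)
        follower = old_names[(i + L) % len(old_names)]
        pre_insert[follower] = "".join(remnant(nm) for nm in event.moved_block)

    parts: list[str] = []
    new_anns: list[GeneAnnotation] = []
    pos = 1
    for lab, strand in new_order.elements:
        nm = lab.render(multi.get(lab.name, 1) > 1)
        extra = pre_insert.get(nm, "")
        if extra:
            parts.append(extra)
            pos += len(extra)
        gseq = gene_seq[nm]
        placed = revcomp(gseq) if strand == "-" else gseq
        new_anns.append(GeneAnnotation(
            lab, pos, pos + len(placed) - 1, strand,
            feature_type_of(lab.name)))
        parts.append(placed)
        pos += len(placed)
        sp = spacer()
        parts.append(sp)
        pos += len(sp)
    rec = MitogenomeRecord(
        id=record.id + f"+{event.kind}", sequence="".join(parts),
        annotations=new_anns,
        description=record.description + f" after {event.kind}")
    rec.validate()
    return rec


# --------------------------------------------------------------------------
# tRNA families with truth tables
# --------------------------------------------------------------------------

def generate_trna_family(template: TRNATemplate, anticodons: list[str],
                         n_per_type: int, subst_rate: float, seed: int,
                         stem_overrides: dict | None = None,
                         at: float = 0.80
                         ) -> tuple[list[str], pd.DataFrame]:
    """Sequences folding to ``template`` with planted anticodons/stem pairs.

    One consensus is generated per anticodon type from a shared family
    ancestor; each of the ``n_per_type`` copies then diverges by
    ``subst_rate``: unpaired positions mutate freely, stem pairs are
    replaced by a random Watson–Crick couple on both sides (compensatory),
    so every output still folds.  ``stem_overrides`` maps an anticodon type
    to ``{(stem, index): (nt5, nt3)}`` planted couples (e.g. an5 G–C in one
    subgroup vs A–T in another).  Returns the sequences and a truth table
    (id, anticodon, planted pairs).
    """
    rng = np.random.default_rng(seed)
    ancestor = generate_trna_sequence(template, rng, at)
    pairs = template.stem_pairs()
    rows, seqs = [], []
    for tri in anticodons:
        cons = list(ancestor)
        lo, hi = template.anticodon_span
        cons[lo:hi] = list(tri)
        if stem_overrides and tri in stem_overrides:
            for (stem, idx), (x, y) in stem_overrides[tri].items():
                p5, p3 = pairs[stem][idx - 1]
                cons[p5], cons[p3] = x, y
        paired_idx = {p for plist in pairs.values() for pq in plist for p in pq}
        anticodon_idx = set(range(lo, hi))
        protected = anticodon_idx | (
            {p for (stem, idx) in (stem_overrides or {}).get(tri, {})
             for p in pairs[stem][idx - 1]})
        for k in range(n_per_type):
            seq = list(cons)
            if subst_rate > 0:
                for plist in pairs.values():
                    for p5, p3 in plist:
                        if p5 in protected or p3 in protected:
                            continue
                        if rng.random() < subst_rate:
                            seq[p5], seq[p3] = _WC[rng.integers(0, 4)]
                for p in range(len(seq)):
                    if p in paired_idx or p in protected:
                        continue
                    if rng.random() < subst_rate:
                        choices = [b for b in "ATGC" if b != seq[p]]
                        seq[p] = choices[rng.integers(0, 3)]
            sid = f"{template.name}-{tri}-{k + 1}"
            seqs.append("".join(seq))
            row = {"id": sid, "anticodon": tri}
            if stem_overrides and tri in stem_overrides:
                for (stem, idx), (x, y) in stem_overrides[tri].items():
                    row[f"{stem}{idx}"] = f"{x}-{y}"
            rows.append(row)
    return seqs, pd.DataFrame(rows)
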