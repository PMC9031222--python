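"""Annotated mitogenome records: I/O, gene orders, spacers, composition.

Coordinates are 1-based inclusive throughout (the GenBank dialect).  A
feature that wraps the circular origin keeps its genomic start and end and
is flagged ``wrap=True``; on GenBank output it is written as a join of the
two arcs.  By convention the plus strand is the strand encoding the
majority of genes; the reader asserts this orientation and flips the record
(reverse complement, remapped coordinates) if the input violates it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .gene_order import (
    CDS_GENES,
    CONTROL_REGION,
    DEFAULT_ANCHOR,
    GeneLabel,
    GeneOrder,
    GeneOrderError,
    RRNA_GENES,
    TRNA_GENES,
    normalize_labels,
    linearize,
)

FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "control_region")

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn",
                            "TGCAYRMKVBHDNtgcayrmkvbhdn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(GeneOrderError):
    pass


def feature_type_of(name: str) -> str:
    if name in CDS_GENES:
        return "CDS"
    if name in TRNA_GENES:
        return "tRNA"
    if name in RRNA_GENES:
        return "rRNA"
    return "control_region"


@dataclass(frozen=True)
class GeneAnnotation:
    label: GeneLabel
    start: int  # 1-based inclusive
    end: int
    strand: str
    feature_type: str
    wrap: bool = False

    def __post_init__(self):
        if not self.wrap and self.start > self.end:
            raise AnnotationError(
                f"{self.label}: start {self.start} > end {self.end} "
                "without wrap flag")

    def span(self, genome_length: int) -> int:
        if self.wrap:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1

    def end_abs(self, genome_length: int) -> int:
        """End coordinate unrolled past the origin for wrap features."""
        return self.end + genome_length if self.wrap else self.end


@dataclass
class MitogenomeRecord:
    id: str
    sequence: str  # plus strand, circular
    annotations: list[GeneAnnotation] = field(default_factory=list)
    description: str = ""
    flipped_to_majority_strand: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        for a in self.annotations:
            if not (1 <= a.start <= self.length and 1 <= a.end <= self.length):
                raise AnnotationError(
                    f"{a.label} at {a.start}..{a.end} outside 1..{self.length}")

    def feature_sequence(self, a: GeneAnnotation) -> str:
        """Gene sequence, reverse-complemented for minus-strand features."""
        if a.wrap:
            s = self.sequence[a.start - 1:] + self.sequence[:a.end]
        else:
            s = self.sequence[a.start - 1:a.end]
        return revcomp(s) if a.strand == "-" else s


# --------------------------------------------------------------------------
# GenBank / FASTA / gene-table I/O
# --------------------------------------------------------------------------

def _to_seqrecord(record: MitogenomeRecord) -> SeqRecord:
    sr = SeqRecord(Seq(record.sequence), id=record.id, name=record.id[:16],
                   description=record.description)
    sr.annotations["molecule_type"] = "DNA"
    sr.annotations["topology"] = "circular"
    L = record.length
    for a in record.annotations:
        strand = 1 if a.strand == "+" else -1
        if a.wrap:
            loc = CompoundLocation([
                FeatureLocation(a.start - 1, L, strand),
                FeatureLocation(0, a.end, strand)])
        else:
            loc = FeatureLocation(a.start - 1, a.end, strand)
        key = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
               "control_region": "misc_feature"}[a.feature_type]
        feat = SeqFeature(loc, type=key,
                          qualifiers={"gene": [a.label.name]})
        if a.feature_type == "control_region":
            feat.qualifiers["note"] = ["control region"]
        sr.features.append(feat)
    return sr


def write_genbank(record: MitogenomeRecord, handle_or_path) -> None:
    SeqIO.write([_to_seqrecord(record)], handle_or_path, "genbank")


def write_fasta(record: MitogenomeRecord, handle_or_path) -> None:
    SeqIO.write([_to_seqrecord(record)], handle_or_path, "fasta")


def _feature_name(feat: SeqFeature) -> str | None:
    for q in ("gene", "product", "note"):
        if q in feat.qualifiers:
            val = feat.qualifiers[q][0]
            if q == "note" and "control region" in val.lower():
                return CONTROL_REGION
            return val
    if feat.type in ("D-loop", "misc_feature"):
        return CONTROL_REGION
    return None


def read_genbank(handle_or_path) -> MitogenomeRecord:
    """Read one annotated mitogenome from a GenBank flat file.

    Gene names are normalized to the controlled vocabulary; records without
    features are accepted with an empty annotation list.  The record is
    flipped if the minority strand carries most genes.
    """
    try:
        sr = SeqIO.read(handle_or_path, "genbank")
    except ValueError as exc:
        raise AnnotationError(f"cannot parse GenBank input: {exc}") from exc
    L = len(sr.seq)
    raw = []
    for feat in sr.features:
        if feat.type not in ("CDS", "tRNA", "rRNA", "misc_feature", "D-loop",
                             "gene"):
            continue
        if feat.type == "gene":  # skip umbrella gene features
            continue
        name = _feature_name(feat)
        if name is None:
            continue
        parts = feat.location.parts
        strand = "+" if (feat.location.strand or 1) >= 0 else "-"
        if len(parts) == 2 and int(parts[0].end) == L and int(parts[1].start) == 0:
            start, end, wrap = int(parts[0].start) + 1, int(parts[1].end), True
        else:
            start, end, wrap = int(feat.location.start) + 1, int(feat.location.end), False
        raw.append((name, start, end, strand, wrap))
    raw.sort(key=lambda r: r[1])
    labels = normalize_labels([r[0] for r in raw]) if raw else []
    anns = [GeneAnnotation(lab, start, end, strand,
                           feature_type_of(lab.name), wrap)
            for lab, (_, start, end, strand, wrap) in zip(labels, raw)]
    rec = MitogenomeRecord(sr.id or "record", str(sr.seq).upper(), anns,
                           description=sr.description or "")
    rec.validate()
    return _ensure_majority_plus(rec)


def read_fasta(handle_or_path) -> MitogenomeRecord:
    sr = SeqIO.read(handle_or_path, "fasta")
    return MitogenomeRecord(sr.id, str(sr.seq).upper(),
                            description=sr.description)


def _ensure_majority_plus(rec: MitogenomeRecord) -> MitogenomeRecord:
    coding = [a for a in rec.annotations if a.feature_type != "control_region"]
    if not coding:
        return rec
    plus = sum(1 for a in coding if a.strand == "+")
    if plus * 2 >= len(coding):
        return rec
    L = rec.length
    flipped = []
    for a in rec.annotations:
        ns, ne = L - a.end + 1, L - a.start + 1
        if a.wrap:
            ns, ne = L - a.end + 1 - L, L - a.start + 1  # re-wrapped below
            ns = ns % L or L
        flipped.append(replace(a, start=min(ns, ne) if not a.wrap else ns,
                               end=max(ns, ne) if not a.wrap else ne,
                               strand="+" if a.strand == "-" else "-"))
    flipped.sort(key=lambda a: a.start)
    return MitogenomeRecord(rec.id, revcomp(rec.sequence), flipped,
                            rec.description, flipped_to_majority_strand=True)


def write_gene_table(record: MitogenomeRecord, path_or_handle) -> None:
    df = gene_table(record)
    df.to_csv(path_or_handle, sep="\t", index=False)


def gene_table(record: MitogenomeRecord) -> pd.DataFrame:
    order = sorted(record.annotations, key=lambda a: a.start)
    multi = {}
    for a in order:
        multi[a.label.name] = multi.get(a.label.name, 0) + 1
    return pd.DataFrame(
        [{"gene": a.label.render(multi[a.label.name] > 1),
          "start": a.start, "end": a.end, "strand": a.strand,
          "type": a.feature_type, "wrap": a.wrap} for a in order])


def read_gene_table(path_or_handle, sequence: str = "",
                    record_id: str = "table") -> MitogenomeRecord:
    df = pd.read_csv(path_or_handle, sep="\t")
    labels = normalize_labels([str(g) for g in df["gene"]])
    anns = [GeneAnnotation(lab, int(r.start), int(r.end), str(r.strand),
                           feature_type_of(lab.name),
                           bool(getattr(r, "wrap", False)))
            for lab, r in zip(labels, df.itertuples())]
    return MitogenomeRecord(record_id, sequence, anns)


# --------------------------------------------------------------------------
# Gene order and spacers
# --------------------------------------------------------------------------

def gene_order_of(record: MitogenomeRecord,
                  anchor: str = DEFAULT_ANCHOR) -> GeneOrder:
    """Derive the signed gene order of a record, linearized at ``anchor``."""
    if len(record.annotations) < 2:
        raise AnnotationError("need at least two annotations for a gene order")
    anns = sorted(record.annotations, key=lambda a: (a.start, a.end))
    for x, y in zip(anns, anns[1:]):
        if (x.start, x.end) == (y.start, y.end):
            raise AnnotationError(
                f"annotations {x.label} and {y.label} occupy the same span")
    labels = normalize_labels([a.label.name for a in anns])
    elements = tuple((lab, a.strand) for lab, a in zip(labels, anns))
    order = GeneOrder(elements, topology="circular", name=record.id)
    return linearize(order, anchor)


@dataclass(frozen=True)
class IntergenicSpacer:
    """Sequence between adjacent annotated genes on the circle.

    A negative ``length`` encodes an overlap of the two genes (empty
    sequence).  The conventional name is ``ISP upstream-downstream``.
    """

    upstream: str
    downstream: str
    sequence: str
    length: int

    @property
    def name(self) -> str:
        return f"ISP {self.upstream}-{self.downstream}"


def extract_isps(record: MitogenomeRecord, min_len: int = 1
                 ) -> list[IntergenicSpacer]:
    """All spacers of gap >= ``min_len`` plus every overlap (length < 0).

    One entry per adjacent annotation pair on the circle, including the
    wrap-around pair; zero-length gaps are omitted.
    """
    anns = sorted(record.annotations, key=lambda a: a.start)
    if not anns:
        return []
    L = record.length
    multi: dict[str, int] = {}
    for a in anns:
        multi[a.label.name] = multi.get(a.label.name, 0) + 1
    out = []
    for cur, nxt in zip(anns, anns[1:] + anns[:1]):
        end_abs = cur.end_abs(L)
        start_next = nxt.start + (L if nxt is anns[0] else 0)
        gap = start_next - end_abs - 1
        if 0 <= gap < min_len or (gap == 0):
            continue
        if gap > 0:
            s0 = end_abs % L  # 0-based start of spacer
            seq = (record.sequence * 2)[s0:s0 + gap]
        else:
            seq = ""
        out.append(IntergenicSpacer(
            cur.label.render(multi[cur.label.name] > 1),
            nxt.label.render(multi[nxt.label.name] > 1),
            seq, gap))
    return out


def spacer_table(spacers: Sequence[IntergenicSpacer]) -> pd.DataFrame:
    return pd.DataFrame([{"name": s.name, "upstream": s.upstream,
                          "downstream": s.downstream, "length": s.length,
                          "sequence": s.sequence} for s in spacers])


# --------------------------------------------------------------------------
# Composition statistics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SkewStats:
    """Strand-asymmetry and composition statistics of one sequence.

    AT-skew = (A - T)/(A + T); GC-skew = (G - C)/(G + C).  A component with
    zero denominator is ``None`` (undefined).  Ambiguity codes are excluded
    from all counts; contents are percentages of unambiguous bases.
    """

    at_skew: float | None
    gc_skew: float | None
    at_content: float
    gc_content: float
    length: int


def skews(sequence: str) -> SkewStats:
    if not sequence:
        raise AnnotationError("empty sequence")
    s = sequence.upper()
    a, t = s.count("A"), s.count("T")
    g, c = s.count("G"), s.count("C")
    unamb = a + t + g + c
    if unamb == 0:
        raise AnnotationError("sequence has no unambiguous nucleotides")
    return SkewStats(
        at_skew=(a - t) / (a + t) if a + t else None,
        gc_skew=(g - c) / (g + c) if g + c else None,
        at_content=100.0 * (a + t) / unamb,
        gc_content=100.0 * (g + c) / unamb,
        length=len(s),
    )


def summarize_dataset(records: Sequence[MitogenomeRecord]) -> pd.DataFrame:
    """Per-record length/composition table with mean, sd, min, max rows.

    The dispersion rows use the sample standard deviation (n - 1); with a
    single record the sd row is NaN.
    """
    if not records:
        raise AnnotationError("need at least one record")
    rows = {}
    for rec in records:
        st = skews(rec.sequence)
        rows[rec.id] = {"length": rec.length, "at_content": st.at_content,
                        "gc_content": st.gc_content,
                        "at_skew": st.at_skew if st.at_skew is not None else np.nan,
                        "gc_skew": st.gc_skew if st.gc_skew is not None else np.nan}
    df = pd.DataFrame.from_dict(rows, orient="index").astype(float)
    summary = pd.DataFrame({
        "mean": df.mean(), "sd": df.std(ddof=1),
        "min": df.min(), "max": df.max()}).T
    return pd.concat([df, summary])
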