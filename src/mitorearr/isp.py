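"""Origin hypotheses for intergenic spacers (ISPs).

Rearrangement events leave decaying copies of the displaced genes inside
the spacers they create.  This module tests candidate source genes for a
spacer by scanning every candidate segment of comparable length for its
identity to the spacer, profiles conservation across spacer alignments
under a majority rule, finds longest exact shared substrings, and
decomposes mosaic spacers into segments attributable to different sources.

A caution built into the reporting: on strongly AT-biased sequence, random
segments reach substantial identity, and short conserved motifs have many
counterparts scattered along the genome.  The scan therefore flags
near-tied hits (several distinct segments within two percentage points of
the best) — the signature of a spurious origin assignment — and can report
a composition-matched null band from shuffled queries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import Align

from .gene_order import GeneOrderError

ISP_SCAN_MIN_LEN = 15
NEAR_TIE_PP = 2.0


class ISPError(GeneOrderError):
    pass


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -2
    al.extend_gap_score = -1
    # the candidate window is padded: its unused overhang (query-row end
    # gaps) is not penalized
    try:
        al.open_end_deletion_score = 0
        al.extend_end_deletion_score = 0
    except AttributeError:  # older biopython naming
        al.query_end_open_gap_score = 0
        al.query_end_extend_gap_score = 0
    return al


def _seq_array(s: str) -> np.ndarray:
    return np.frombuffer(s.upper().encode(), dtype=np.uint8)


def _identity_profile(query: np.ndarray, candidate: np.ndarray) -> np.ndarray:
    """Ungapped percent identity of the query at every candidate offset."""
    w = len(query)
    if len(candidate) < w:
        return np.array([])
    windows = np.lib.stride_tricks.sliding_window_view(candidate, w)
    return 100.0 * (windows == query).mean(axis=1)


def _gapped_identity(query: str, segment: str, *,
                     denominator: str = "columns") -> tuple[float, int, int, int]:
    """Global-align query against a candidate segment.

    Returns (identity %, aligned columns, segment start offset, segment end
    offset) where offsets trim candidate end-gap columns.  ``denominator``
    is "columns" (gap columns counted, the default convention) or
    "ungapped" (matched+mismatched columns only).
    """
    al = _aligner()
    aln = al.align(segment, query)[0]
    tgt, qry = str(aln[0]), str(aln[1])
    # trim columns where the query has leading/trailing gaps (pad overhang)
    lead = len(qry) - len(qry.lstrip("-"))
    trail = len(qry) - len(qry.rstrip("-"))
    hi = len(qry) - trail
    tgt_c, qry_c = tgt[lead:hi], qry[lead:hi]
    matches = sum(1 for x, y in zip(tgt_c, qry_c) if x == y and x != "-")
    if denominator == "ungapped":
        cols = sum(1 for x, y in zip(tgt_c, qry_c) if x != "-" and y != "-")
    else:
        cols = len(tgt_c)
    identity = 100.0 * matches / cols if cols else 0.0
    seg_start = sum(1 for ch in tgt[:lead] if ch != "-")
    seg_used = sum(1 for ch in tgt_c if ch != "-")
    return identity, len(tgt_c), seg_start, seg_start + seg_used


@dataclass
class RemnantHit:
    """One candidate-segment match for a spacer query.

    ``segment_start``/``segment_end`` are 1-based inclusive positions in the
    candidate gene; identity is matched columns over aligned columns.
    """

    candidate_gene: str
    segment_start: int
    segment_end: int
    identity: float
    aligned_length: int
    rank: int = 0
    near_tie: bool = False


def segment_identity_scan(query: str, candidate: str, *,
                          candidate_name: str = "candidate",
                          length_tolerance: float = 0.2,
                          top_k: int = 5,
                          min_len: int = ISP_SCAN_MIN_LEN,
                          near_tie_pp: float = NEAR_TIE_PP,
                          denominator: str = "columns") -> list[RemnantHit]:
    """Best-identity candidate segments for a spacer query.

    The query is slid along the candidate at step 1 (ungapped profile),
    local maxima at least half a query length apart are refined by gapped
    global alignment against the window padded by ``length_tolerance`` of
    the query length (so the aligned segment may be up to that fraction
    shorter or longer than the query), and the top-``top_k`` hits are
    returned sorted by identity, hits within ``near_tie_pp`` percentage
    points of the best flagged as near ties.
    """
    if len(query) < min_len:
        raise ISPError(
            f"query of {len(query)} nt is below the scan minimum {min_len}")
    q, c = _seq_array(query), _seq_array(candidate)
    w = len(q)
    pad = max(1, round(length_tolerance * w))
    if len(c) < w:
        ident, cols, s0, s1 = _gapped_identity(query, candidate,
                                               denominator=denominator)
        hits = [RemnantHit(candidate_name, s0 + 1, s1, ident, cols)]
    else:
        profile = _identity_profile(q, c)
        order = np.argsort(profile)[::-1]
        peaks: list[int] = []
        for idx in order:
            if all(abs(int(idx) - p) >= max(w // 2, 1) for p in peaks):
                peaks.append(int(idx))
            if len(peaks) >= max(top_k, 3):
                break
        hits = []
        for p in peaks:
            lo, hi = max(0, p - pad), min(len(c), p + w + pad)
            ident, cols, s0, s1 = _gapped_identity(
                query, candidate[lo:hi], denominator=denominator)
            hits.append(RemnantHit(candidate_name, lo + s0 + 1, lo + s1,
                                   ident, cols))
    hits.sort(key=lambda h: (-h.identity, h.segment_start))
    # merge refined hits that converged onto the same segment
    merged: list[RemnantHit] = []
    for h in hits:
        if any(not (h.segment_end < m.segment_start or
                    h.segment_start > m.segment_end) and
               abs(h.identity - m.identity) < 1e-9 for m in merged):
            continue
        merged.append(h)
    merged = merged[:top_k]
    best = merged[0].identity if merged else 0.0
    for rank, h in enumerate(merged, start=1):
        h.rank = rank
        h.near_tie = (best - h.identity) < near_tie_pp
    return merged


def null_band(query: str, candidate: str, *, n_shuffles: int = 100,
              seed: int = 0, percentile: float = 95.0) -> float:
    """Composition-matched null: top scan identity of shuffled queries.

    Returns the requested percentile (default 95th) of the best hit
    identity over ``n_shuffles`` random shuffles of the query — the level a
    hit must clear before an origin claim means anything on biased
    composition.
    """
    rng = np.random.default_rng(seed)
    letters = np.array(list(query))
    tops = []
    for _ in range(n_shuffles):
        rng.shuffle(letters)
        hits = segment_identity_scan("".join(letters), candidate, top_k=1)
        tops.append(hits[0].identity if hits else 0.0)
    return float(np.percentile(tops, percentile))


# --------------------------------------------------------------------------
# Majority-rule conservation
# --------------------------------------------------------------------------

@dataclass
class ConservationProfile:
    """Per-column conservation of a gapped alignment under the >50% rule.

    A column is conserved iff its modal non-gap residue occurs in more than
    half of the non-gap rows *and* at least half of the rows are non-gap.
    ``percent_conserved`` is conserved columns over total columns.
    """

    column_counts: list[dict[str, int]]
    conserved_flags: list[bool]
    n_sequences: int

    @property
    def n_columns(self) -> int:
        return len(self.conserved_flags)

    @property
    def n_conserved(self) -> int:
        return sum(self.conserved_flags)

    @property
    def percent_conserved(self) -> float:
        return 100.0 * self.n_conserved / self.n_columns if self.n_columns else 0.0


def majority_conservation(rows: Sequence[str]) -> ConservationProfile:
    if len(rows) < 2:
        raise ISPError("need at least two aligned rows")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ISPError(f"unequal row lengths: {sorted(lengths)}")
    n = len(rows)
    counts_per_col: list[dict[str, int]] = []
    flags: list[bool] = []
    for col in zip(*[r.upper() for r in rows]):
        counts = Counter(ch for ch in col if ch not in "-.")
        nongap = sum(counts.values())
        if counts and nongap * 2 >= n:
            modal = counts.most_common(1)[0][1]
            flags.append(modal * 2 > nongap)
        else:
            flags.append(False)
        counts_per_col.append(dict(counts))
    return ConservationProfile(counts_per_col, flags, n)


# --------------------------------------------------------------------------
# Longest common substring
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LCSResult:
    substring: str
    length: int
    positions_a: tuple[int, ...]  # 0-based start positions of occurrence
    positions_b: tuple[int, ...]


def longest_common_substring(a: str, b: str) -> LCSResult:
    """Longest exact shared substring via a suffix automaton of ``a``.

    Ties are broken by the leftmost occurrence in ``a``; all occurrence
    positions in both inputs are reported.  Linear in |a| + |b|, unlike the
    quadratic dynamic-programming formulation used as an oracle in testing.
    """
    if not a or not b:
        raise ISPError("both sequences must be non-empty")
    # suffix automaton of a
    sa_next: list[dict[str, int]] = [{}]
    sa_link = [-1]
    sa_len = [0]
    last = 0
    for ch in a:
        cur = len(sa_next)
        sa_next.append({})
        sa_len.append(sa_len[last] + 1)
        sa_link.append(-1)
        p = last
        while p != -1 and ch not in sa_next[p]:
            sa_next[p][ch] = cur
            p = sa_link[p]
        if p == -1:
            sa_link[cur] = 0
        else:
            q = sa_next[p][ch]
            if sa_len[p] + 1 == sa_len[q]:
                sa_link[cur] = q
            else:
                clone = len(sa_next)
                sa_next.append(dict(sa_next[q]))
                sa_len.append(sa_len[p] + 1)
                sa_link.append(sa_link[q])
                while p != -1 and sa_next[p].get(ch) == q:
                    sa_next[p][ch] = clone
                    p = sa_link[p]
                sa_link[q] = clone
                sa_link[cur] = clone
        last = cur
    # walk b
    best_len, best_end_b, v, ln = 0, 0, 0, 0
    for i, ch in enumerate(b):
        while v and ch not in sa_next[v]:
            v = sa_link[v]
            ln = sa_len[v]
        if ch in sa_next[v]:
            v = sa_next[v][ch]
            ln += 1
        else:
            v, ln = 0, 0
        if ln > best_len:
            best_len, best_end_b = ln, i + 1
    if best_len == 0:
        return LCSResult("", 0, (), ())
    sub = b[best_end_b - best_len:best_end_b]
    # leftmost-in-a tie-break: among all longest shared substrings choose
    # the one whose first occurrence in a is leftmost
    occs_a = {}
    for s in _shared_substrings(a, b, best_len):
        occs_a[s] = a.find(s)
    if occs_a:
        sub = min(occs_a, key=lambda s: (occs_a[s], s))
    return LCSResult(sub, best_len, _all_positions(a, sub),
                     _all_positions(b, sub))


def _shared_substrings(a: str, b: str, L: int) -> set[str]:
    subs_a = {a[i:i + L] for i in range(len(a) - L + 1)}
    return {b[i:i + L] for i in range(len(b) - L + 1)} & subs_a


def _all_positions(s: str, sub: str) -> tuple[int, ...]:
    out, i = [], s.find(sub)
    while i != -1:
        out.append(i)
        i = s.find(sub, i + 1)
    return tuple(out)


# --------------------------------------------------------------------------
# Mosaic decomposition
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpacerSegment:
    spacer_start: int  # 1-based inclusive within the spacer
    spacer_end: int
    candidate_gene: str
    candidate_start: int
    candidate_end: int
    identity: float


def decompose_spacer(spacer_seq: str,
                     candidates: Sequence[tuple[str, str]], *,
                     identity_floor: float = 70.0,
                     window: int = 24, step: int = 8,
                     min_len: int = ISP_SCAN_MIN_LEN) -> list[SpacerSegment]:
    """Greedy tiling of a spacer by segments of different source genes.

    Windows of the spacer are assigned to the candidate with the highest
    ungapped identity (if above ``identity_floor``); runs of consecutive
    windows voting for the same candidate are merged and refined by gapped
    alignment.  Returns ordered, non-overlapping segment assignments; an
    empty list when nothing clears the floor.
    """
    if len(spacer_seq) < min_len:
        raise ISPError(
            f"spacer of {len(spacer_seq)} nt is below the scan minimum {min_len}")
    if not candidates:
        raise ISPError("need at least one candidate")
    arrs = {name: _seq_array(seq) for name, seq in candidates}
    seqs = dict(candidates)
    n = len(spacer_seq)
    w = min(window, n)
    votes = []  # (pos, best_name, best_identity)
    for pos in range(0, n - w + 1, step):
        qa = _seq_array(spacer_seq[pos:pos + w])
        best_name, best_id = None, -1.0
        for name, arr in arrs.items():
            prof = _identity_profile(qa, arr)
            if prof.size == 0:
                continue
            top = float(prof.max())
            if top > best_id:
                best_name, best_id = name, top
        if best_name is not None and best_id >= identity_floor:
            votes.append((pos, best_name))
    if not votes:
        return []
    # merge consecutive same-candidate votes into runs
    runs = []
    for pos, name in votes:
        if runs and runs[-1][2] == name and pos <= runs[-1][1] + step:
            runs[-1][1] = pos + w
        else:
            runs.append([pos, pos + w, name])
    # enforce a non-overlapping tiling: split boundary overlaps midway
    for prev, nxt in zip(runs, runs[1:]):
        if prev[1] > nxt[0]:
            mid = (prev[1] + nxt[0]) // 2
            prev[1], nxt[0] = mid, mid
    out = []
    for lo, hi, name in runs:
        frag = spacer_seq[lo:hi]
        ident, cols, s0, s1 = _gapped_identity(frag, seqs[name])
        if ident < identity_floor:
            continue
        out.append(SpacerSegment(lo + 1, hi, name, s0 + 1, s1, ident))
    return out


# --------------------------------------------------------------------------
# Hypothesis comparison
# --------------------------------------------------------------------------

@dataclass
class HypothesisResult:
    candidate_gene: str
    best_identity: float
    n_near_ties: int
    coverage: float  # aligned length of best hit / spacer length
    flag: str  # unique_top | multiple_near_ties | ambiguous
    hits: list[RemnantHit] = field(default_factory=list)
    null_p95: float | None = None


@dataclass
class HypothesisReport:
    spacer_name: str
    results: list[HypothesisResult]
    verdict: str = "inconclusive"

    @property
    def best(self) -> HypothesisResult:
        return max(self.results, key=lambda r: r.best_identity)


def hypothesis_report(spacer_seq: str,
                      hypotheses: Sequence[tuple[str, str]], *,
                      spacer_name: str = "spacer",
                      near_tie_pp: float = NEAR_TIE_PP,
                      null_shuffles: int = 0,
                      seed: int = 0) -> HypothesisReport:
    """Compare candidate origin genes for one spacer.

    For each hypothesis the scan's best identity, the number of near-tied
    distinct segments, and the alignment-length coverage are reported.
    Several near-tied segments flag ``multiple_near_ties`` — the pattern
    that undermines an origin claim, since a true pseudogene remnant has
    one orthologous segment, not many equally good ones; a single clear
    segment flags ``unique_top``.  With ``null_shuffles`` > 0 a
    shuffled-query null band is computed per hypothesis, and a hypothesis
    whose best hit does not clear its null band is flagged ``ambiguous``
    instead (on strongly biased composition every candidate aligns
    "somewhat well" to everything).

    The report's ``verdict`` names the winning candidate when one
    hypothesis has a unique top hit that leads the runner-up candidate by
    at least ``near_tie_pp`` percentage points and is not ambiguous;
    otherwise ``"inconclusive"``.
    """
    if len(hypotheses) < 2:
        raise ISPError("need at least two hypotheses to compare")
    results = []
    for name, seq in hypotheses:
        hits = segment_identity_scan(spacer_seq, seq, candidate_name=name,
                                     near_tie_pp=near_tie_pp)
        best = hits[0].identity if hits else 0.0
        ties = sum(1 for h in hits if h.near_tie)
        res = HypothesisResult(
            name, best, ties,
            coverage=(hits[0].aligned_length / len(spacer_seq)) if hits else 0.0,
            flag="unique_top" if ties <= 1 else "multiple_near_ties",
            hits=hits)
        if null_shuffles:
            res.null_p95 = null_band(spacer_seq, seq,
                                     n_shuffles=null_shuffles, seed=seed)
            if res.best_identity <= res.null_p95:
                res.flag = "ambiguous"
        results.append(res)
    ranked = sorted(results, key=lambda r: -r.best_identity)
    verdict = "inconclusive"
    if (ranked[0].flag == "unique_top"
            and ranked[0].best_identity - ranked[1].best_identity >= near_tie_pp):
        verdict = ranked[0].candidate_gene
    return HypothesisReport(spacer_name, results, verdict)
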