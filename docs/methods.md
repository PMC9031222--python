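# Methods

This note documents the models and procedures implemented in `mitorearr`,
the parameters that matter, the synthetic-data conditions under which the
package is validated, and the limitations of both.

## Gene orders and common intervals

A gene order is a signed circular arrangement over a fixed 38-element
vocabulary: 13 protein-coding genes, 22 tRNAs (one-letter codes, with
L1/L2 and S1/S2 distinguishing the leucine and serine isoacceptor codon
families), two rRNAs and the control region (`CoRe`).  Orders are
compared after linearization at a shared anchor, `cox1` by default
(configurable); linearization requires the anchor to occur exactly once
and is idempotent.

A *common interval* of two duplicate-free orders is a gene set contiguous
in both.  The counting convention is:

* unsigned element sets (strands carried on the order but ignored by the
  interval count — sign changes are the business of the event model);
* sizes 2..n, full interval included, singletons excluded;
* n = 38 with the control region included;
* SCI percentage = 100 · count / (n(n−1)/2), rounded half-up to integer
  for report tables (floats retained internally).

A singleton-inclusive convention (denominator n(n+1)/2) is selectable via
`convention="singleton"` and recorded in report metadata; the two round to
the same integer for all registry pairs.  Every common interval of a pair
is a window of the first order, so counting is O(n²) with incremental
min/max of positions — ample at n = 38; no interval-tree machinery is
needed or wanted here.

Duplicate-bearing orders are collapsed before interval counting.  The
default policy keeps, for each duplicated base name, the copy whose
immediate neighbours match its neighbourhood in MIQGO (the plesiomorphic
butterfly order) — e.g. the opposite-strand relocated trnF copy of 2FFGO
is discarded in favour of the in-situ copy — with ties and no-matches
falling back to the first copy.  A `keep-first` policy is selectable; the
applied policy is recorded in the output provenance.

### The arrangement registry

Eleven named orders ship as plain-text files (one `gene<TAB>strand` line
per element, linearized from cox1).  PanGO is the pancrustacean ancestral
order; MIQGO differs by the M–I–Q transposition; IMQGO, S1NGO and ES1GO
are single adjacent-block transpositions of MIQGO; 2NGO, 2S1EGO, 2S1GO,
4QGO carry extra tandem tRNA copies; 2FFGO carries a second trnF on the
opposite strand between trnR and trnN (the published description of this
arrangement places the second copy there in its summary table, while the
running text says "between trnR and trnS1"; the table placement is used).

**BemGO is synthetic.**  The heavily rearranged *Bematistes* order is
published only as a figure we could not transcribe.  The shipped
`bemgo_synthetic.tsv` was constructed by scripted search: starting from
MIQGO, apply one inverse transposition of trnE and two random TDRL moves,
and accept the first order whose SCI percentage with MIQGO rounds to the
reported 37% and which is not reachable from MIQGO by any single event.
It reproduces the *statistical* character of the real arrangement (its
event pathway and conservation score), not its literal gene sequence; any
conclusion that depends on the literal BemGO arrangement must not be drawn
from it.  Its provenance line marks it `figure-derived/synthetic`.

## Rearrangement events

Four event kinds operate on linearized orders: transposition (block
moves), inversion (block reversed in place, strands flipped), inverse
transposition (block moves and flips), and tandem duplication random loss.
Every event and pathway returned by the package is verified by replay
(`apply(events, source) == target`); this invariant is asserted in all
tests.

**TDRL semantics.**  Because the random-loss step keeps each survivor at
its position inside the first or the second tandem copy, a one-TDRL
product is always *(genes kept in copy 1, in source order) ++ (genes kept
in copy 2, in source order)*.  Hence, writing the target as ranks in the
source: one TDRL suffices iff the rank sequence is a concatenation of at
most two strictly ascending runs, and the minimum number of TDRL moves is
⌈log₂ r⌉ where r is the number of maximal ascending runs.  Note this is
*not* the same as partitioning the ranks into two increasing
subsequences: ranks (3,1,4,2) split into increasing subsequences
{3,4},{1,2} yet are not a one-TDRL product of (1,2,3,4), because the
copies cannot interleave.  The property suite pins the implementation to
exhaustive enumeration of one-TDRL products (n ≤ 7) and to breadth-first
search over the TDRL move graph (n ≤ 6).  TDRL never changes strands; a
strand mismatch between source and target raises an error naming the
offending genes.

**Single-event detection** enumerates all transpositions, inversions and
inverse transpositions in increasing block size and verifies by replay;
ties are broken by smallest moved block, then leftmost source position,
then kind order T < I < IT.  At n = 38 this is ~10⁵ candidate replays and
runs in seconds.

**Pathway search** (`infer_pathways`) is breadth-first over allowed event
kinds with `max_events` capped at 3.  TDRL successors are enumerated
exhaustively only over windows up to 6 genes (2^w partitions per window);
in addition an unrestricted whole-order TDRL is always tried as the
*closing* move via the rank test, so one-TDRL transformations of any width
are found.  Pathways with a wide intermediate TDRL followed by further
events are therefore outside the search space — a deliberate trade
against the 2^38 partition explosion.  Equal-length pathways are ordered
by (fewest genes moved, leftmost block, kind order); spacer positions
adjacent to each moved block are reported as the pathway's predicted
rearrangement-associated ISPs, as corroborating evidence rather than a
pruning criterion.

For duplication-bearing arrangements, `explain_duplication_pathway`
recognizes two mechanisms from copy strands, adjacency and spacer repeat
structure: two opposite-strand distant copies → duplication followed by
inverse transposition of the non-overlapping copy (the copy overlapping a
neighbour gene is deemed in situ, since relocating it would have disrupted
that neighbour); three or more tandem copies with identical upstream
spacers → one segmental tandem duplication, a partial random loss shaping
the repeat unit, then iterated tandem duplication of the (spacer + gene)
unit.

## Records, spacers, composition

Coordinates are 1-based inclusive (GenBank dialect); a feature wrapping
the circular origin keeps `start > end` with `wrap=True` and is written
as a `join(start..L,1..end)` on output.  The plus strand is defined as
the strand encoding the majority of genes; the GenBank reader asserts
this and flips the record (reverse complement, coordinates remapped,
flag recorded) when violated.

Intergenic spacers are extracted per adjacent annotation pair on the
circle, including the wrap-around junction; a negative length encodes an
overlap (empty sequence).  The accounting identity
Σ gene spans + Σ gaps (overlaps negative) = genome length holds exactly
and is asserted on every simulated record.

AT-skew = (A−T)/(A+T) and GC-skew = (G−C)/(G+C) are computed on the plus
strand of the full sequence; ambiguity codes are excluded from all
denominators, and a zero denominator yields an undefined (None)
component rather than a value.  Skews computed on the reverse complement
flip sign — the property that makes an inverted control region detectable.
Dataset summaries report per-record length, AT%, GC% and both skews with
mean, sample standard deviation (n−1), min and max rows.

## Spacer-remnant homology

`segment_identity_scan` asks whether a spacer is the decayed remnant of a
candidate gene.  The query is slid along the candidate at step 1; an
ungapped identity profile locates local maxima at least half a query
length apart; each peak is refined by global alignment (match +1,
mismatch −1, gap open −2, gap extend −1) of the query against the window
padded by ±20% of the query length, with the window's unused overhang
unpenalized.  Identity = matched columns / alignment columns (gap columns
in the denominator; an ungapped-denominator variant is selectable).
Scoring is a package choice, recorded in report metadata — the original
analyses this mirrors used alignment-program defaults, which it does not
attempt to reproduce; consequently the printed 62–78% identity band of
published spacer-vs-nad2 comparisons is a qualitative, not numeric,
reference point.  Identity is 100 exactly when the query occurs verbatim
in the candidate.

Two ambiguity guards operationalize the caution that AT-rich composition
manufactures similarity: hits within 2 percentage points of the best are
flagged *near ties* (a true remnant has one orthologous segment, not
several equally good ones), and an optional composition-matched null band
reports the 95th percentile of best-hit identity over (by default 100)
shuffles of the query.  `hypothesis_report` compares candidate origins
and names a verdict only when one candidate has a unique top hit leading
the runner-up by at least the near-tie margin.

`majority_conservation` profiles a gapped alignment: a column is conserved
iff its modal non-gap residue occurs in more than half of the non-gap
rows *and* at least half of the rows are non-gap (a gap-dominated column
is never conserved; the source analyses did not state their gap rule, so
this one is the package's).  `longest_common_substring` uses a suffix
automaton (linear time), reports all occurrence positions in both inputs,
and breaks ties by leftmost occurrence in the first input; the quadratic
dynamic program serves as its test oracle, not its implementation.
`decompose_spacer` tiles a mosaic spacer by voting 24-nt windows (step 8)
for the best-matching candidate above a 70% identity floor, merging runs,
enforcing a non-overlapping tiling, and refining each segment by gapped
alignment.

## tRNA structures and character mapping

Cloverleaf templates fix the region layout: acceptor stem 7 bp, DHU stem
4 bp (0 for the serine-AGN template — metazoan mitochondrial trnS1
commonly lacks the DHU arm), anticodon stem 5 bp with the anticodon at
the centre of a 7-nt loop, TΨC stem 5 bp, short spacers, variable region
and unpaired 3' tail; standard template length 71 nt, trnS1 62 nt.  Stems
are indexed from the base outward, so `an5` is the anticodon-stem pair
adjacent to the loop and `tp1` the TΨC pair at the stem base.  A sequence
folds iff at least 80% of template pairs are Watson–Crick or G·U — the
package's operationalization of "capable of folding", configurable;
random 70-mers fail at >99%.  Acceptance is invariant to trailing
unpaired nucleotides.  Stem-pair differences between same-template
structures classify as identical; fully compensatory (both sides changed,
both couples Watson–Crick, e.g. an5 A–T ↔ G–C or tp1 A–T ↔ T–A); hemi
(one side changed, pairing — G·U allowed — preserved); destabilizing
otherwise.

Character states are mapped onto a user-supplied rooted tree: Fitch
parsimony (unordered, multistate; exact for binary trees, checked against
exhaustive labelling enumeration) for qualitative characters such as
anticodon type, and Wagner (ordered, Sankoff dynamic programming with
linear cost) for copy number, so each duplication or loss step costs one.
Because tRNA paralogy can defeat orthology assumptions, the package never
infers trees from tRNA sequences.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions: ~15.3-kb circular
genomes at 80% A+T (i.i.d. background), per-gene lengths in the typical
lepidopteran range (e.g. cox1 1531, nad5 1734, rrnL 1350, control region
350 nt; tRNAs at template length), spacers of 2–8 nt, remnant retention
0.5 and per-site substitution rate 0.10 on remnants.  tRNA genes are
generated from their templates (all stem pairs Watson–Crick, AT-weighted)
so they genuinely fold; minus-strand genes are stored reverse-complemented.
Duplicated copies start identical, and arrangements with ≥3 tandem copies
(4QGO) receive identical inter-copy spacers built as a mosaic of the
downstream spacer, the control-region 3' end, the trnM 3' end and trnI —
the repeat-unit structure iterated tandem duplication produces, and the
ground truth for the mosaic-decomposition stage.

`apply_scripted_event` rebuilds the genome after an event and plants
remnants where the mechanism predicts them: a TDRL lays out both tandem
copies with the non-retained genes of each copy decayed in place (3'
fraction `remnant_retention`, mutated at `subst_rate`); transpositions
and inverse transpositions leave remnants of the moved block at the
source junction; inversions plant none.  Replaying
PanGO → MIQGO through the minimal-window TDRL therefore yields a spacer
between trnQ and nad2 containing a decayed trnM — the fixture for the
origin-hypothesis stage.  Restricting to the minimal window matters: a
whole-genome duplication witness would decay different copies and put the
remnants elsewhere.

Not emulated: codon structure in protein-coding genes, strand-asymmetric
mutation (so synthetic skews are ≈0, unlike the negative skews of real
mitogenomes), rate heterogeneity, and within-family tRNA indels.  Passing
the recovery tests therefore shows the pipeline recovers what the model
plants under realistic composition and decay — not that real spacers will
be equally clean, where the multiple-near-tie ambiguity the reports flag
is common.

## Problem sizes and determinism

Every stochastic component runs from an explicit seed
(`numpy.random.default_rng`); identical configuration and seed give
byte-identical outputs, and pipeline reports embed configuration, seed,
conventions and package version.  Validation sizes were chosen where
brute force is exact and fast: exhaustive common-interval oracles at
n ≤ 8 (200 pairs), one-TDRL enumeration at n ≤ 7, TDRL breadth-first
search at n ≤ 6, single-event brute force at n ≤ 8, quadratic LCS on 100
pairs up to 200 nt, exhaustive parsimony on 100 random 8-tip trees, and
the planted-remnant study on 200 seeded 15-kb genomes.  The whole suite
runs in well under a minute on one CPU.

## Known limitations

* BemGO is a synthetic reconstruction (above); checks against it validate
  the pipeline, not the literature arrangement.
* Pathway search does not explore wide intermediate TDRLs at depth ≥ 2.
* The identity scan's scoring scheme is a package choice; absolute
  identity values are not comparable to numbers produced by other
  alignment programs, only the ranking/near-tie structure is.
* Folding uses a fixed template anchor rather than free secondary-
  structure prediction; tRNAs with unusual arm lengths may fail to fold
  under the shipped templates.
* Event detection compares orders on their given linearization.  If the
  anchor gene itself moved, callers should re-anchor both orders at an
  unmoved gene (``linearize`` is cheap) before comparing; an automatic
  retry under a second rotation was rejected because an event found there
  would carry positions that do not replay on the original linearization,
  breaking the replay-verification invariant.
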