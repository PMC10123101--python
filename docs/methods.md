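# Methods

## Problem and scope

`ampdesign` designs multiplex PCR amplicon panels for two screening
regimes: (a) CRISPR knockout screens, where each amplicon must cover the
expected cut sites of externally designed gRNAs so that induced mutations
can be read out by amplicon sequencing, and (b) natural-variation
(eco-tilling) screens, where amplicons should jointly cover as much of
each candidate gene as possible.  Guide discovery and scoring are out of
scope: gRNAs arrive as tables from dedicated tools (FlashFry/CRISPOR
style) and their specificity (e.g. MIT) and efficiency (e.g. Doench,
out-of-frame) scores are consumed, never computed.  Read mapping and
haplotype calling are likewise downstream; this package only writes the
files those tools take as input.

## Coordinate conventions

Internal coordinates are 0-based half-open throughout.  GFF3 output is
1-based inclusive, BED output 0-based half-open.  Every gene is oriented
so its CDS lies on the + strand of the per-gene record; minus-strand genes
are reverse-complemented at extraction time and features mirrored
(`rel_start' = L − rel_end`).  Guide cut sites are between-base
coordinates 3 bp 5' of the PAM (the SpCas9 blunt cut).  Flanks requested
past a chromosome end are clipped and the achieved flank recorded rather
than failing, so edge genes never abort a run.

## gRNA filters

Applied in the order poly-T → restriction sites → position → specificity
score; the kept set is order-independent (each filter is a pure
partition), only the per-guide removal reason depends on the order, which
records the first failing filter.

* **Poly-T**: a run of ≥ 4 T in the spacer terminates Pol III
  transcription; the scan covers the spacer only, not PAM or vector
  context.
* **Restriction sites**: the simulated construct promoter + spacer +
  scaffold is scanned on both strands for each recognition sequence
  (type IIS sites are directional but clonable from either strand).
  IUPAC-ambiguous recognition sequences are rejected rather than expanded
  (documented limitation).
* **Position**: the anchor is the cut site mapped onto the concatenated
  (spliced) CDS.  Fractions of spliced CDS length are excluded at the 5'
  and 3' ends; a required feature type (e.g. an annotated domain) can be
  demanded instead of or in addition.  Guides whose cut site misses the
  CDS entirely are removed whenever fraction filtering is active.
* **Score**: inclusive threshold (score ≥ min passes); unscored guides
  are removed only when a threshold is set.

## Primer engine

The thermodynamic engine is an interface.  The built-in engine scores a
primer with Biopython's nearest-neighbour melting temperature (unified NN
parameters, 50 mM monovalent salt, 50 nM oligo) and penalty
`|Tm − Tm_opt| + w_gc · (GC-bound violation) + w_len · |len − len_opt|`
(`w_gc = 100` per unit fraction, effectively a hard bound; `w_len = 0.5`
per nt).  Defaults: length 18–27 nt (optimum 20), Tm window 57–63 °C
(optimum 60), GC 20–80%.  An external engine implementing
`score(primer) -> (tm, gc, penalty)` can be substituted without touching
the enumeration contract.

Candidate enumeration walks forward-primer start positions left to right;
accepted candidates' forward starts differ by ≥ 5 bp so amplicons spread
across the sequence.  At each start the best-scoring forward primer and
the best reverse primer over all product sizes in range are paired; ties
break toward shorter length and leftmost position, making the output
deterministic.  Primers never cover an N; candidate lists are sorted by
pair penalty and truncated to 150 per gene.  Products containing a
homopolymer (≥ 10 identical bases by default; N is a mask character and
never counts) are discarded because such amplicons sequence poorly.  With
exon-restricted design (`rpd`) each exon is extended by the maximum
product size on both sides, windows merged, and products confined to
windows — this mirrors how intron-rich genes otherwise waste most of the
candidate budget.

## Specificity screen

Every primer of every candidate is scanned against the *entire* reference
set (both strands).  A binding site qualifies with ≤ 2 total mismatches
and 0 mismatches in the 3'-terminal 4 bases (a polymerase-extension
anchor); both thresholds are configurable and the screen can be disabled.
A candidate fails when either primer has more than one qualifying site, or
when any convergent pair of the candidate's sites would yield an
unintended product ≤ 1000 bp.  Cross-amplification between primers of
*different* selected amplicons is checked once the multiplex mixture is
known (`cross_mixture_check`) and reported as warnings, not removals.
Products formed on a gene by two of that gene's own selected amplicons are
the expected combined span of deliberately stacked assays and are not
reported.  The mismatch scan is exact and exhaustive (vectorised
Hamming-distance over sliding windows), so oracle tests can compare it
against a naive sliding-window implementation position by position.

## Grouping, ranking, selection

A guide is grouped to an amplicon iff its protospacer lies within the
insert with ≥ 15 bp (inclusive) between each primer end and the
protospacer boundary — PAM excluded, per-preset distance (150 bp for
Sanger designs so traces resolve before the cut).  When an amplicon
covers more guides than the per-amplicon maximum, the retained subset
minimises overlapping guide pairs, then maximises mean specificity, then
mean efficiency; small instances (≤ 20 000 combinations) are solved
exactly, larger ones by a deterministic greedy on the same key.

Amplicons are ranked by guide count (desc), overlapping guide pairs (asc,
ties by total overlapped bases), mean specificity (desc), mean efficiency
(desc); missing scores rank below any present score.  The final tie-break
is leftmost forward start then amplicon id, making the order strict and
reproducible.  Selection greedily takes top-ranking amplicons whose
products (primers included) are disjoint, up to the per-gene maximum.
Zero-guide amplicons are never selected in CRISPR mode: a gene whose
specific amplicons all lack groupable guides is a dropout with reason
"no gRNA–amplicon overlap", which keeps the dropout taxonomy faithful.

NatVar (coverage) mode solves weighted interval scheduling exactly by
dynamic programming with weight = product size; ties prefer fewer
amplicons, then the leftmost start sequence.  Iterative tiling masks the
selected primer binding sites with N and reruns the same settings;
round-2 amplicons may span round-1 primer sites (tiling is the point) but
never place a primer on them.

Dropout reasons follow a fixed precedence: no gRNAs supplied → none
passed the filters → no specific amplicons → no gRNA–amplicon overlap
(CRISPR); sequence too short → no specific amplicons (NatVar).

Retention is reported per gene family as the percentage of genes with at
least `min_amplicons` selected amplicons each covering at least
`min_guides` guides (defaults 1 and 2; `min_guides=1` is the genome-wide
variant).

## Presets

| preset | product size | guide–primer distance | notes |
|--------|--------------|----------------------|-------|
| hiplex | 120–150 bp | 15 bp | short-read multiplex sequencing |
| pe     | 220–250 bp | 15 bp | paired-end 150 bp reads |
| sanger | 400–800 bp | 150 bp | trace-deconvolution genotyping |
| natvar | 120–150 bp | —     | coverage mode, unlimited amplicons |

Other defaults: 150 candidates/gene, 5 bp primer spacing, homopolymer
threshold 10 nt, poly-T run 4, ≤ 2 amplicons/gene, ≤ 2 guides/amplicon,
border length 10 bp (a compatibility knob for the downstream haplotyping
tools).

## Synthetic data

The generator plants gene families with *exact* pairwise identity: gene 1
is random at a target GC, each further paralog differs from it by exactly
`round((1 − identity) · length)` substitutions at seeded positions.
Substitution-only divergence keeps coordinates aligned across paralogs,
which makes cross-amplification ground truth exact; indel divergence is a
documented extension.  Genomes interleave genes with random spacers and
place alternating genes on the minus strand to exercise orientation.
Guide tables sample NGG-adjacent 20-mers on both strands with seeded
positions and scores.  All randomness flows from the single spec seed
through one named generator.

What the generator does *not* emulate: repeat structure, codon bias,
indel polymorphism, chimeric PCR artifacts, sequencing error.  Passing
tests on fixtures therefore demonstrate algorithmic correctness
(planted-truth recovery, oracle agreement, optimality) and the
qualitative homology effect — high-identity families lose retention under
short-amplicon settings — not genome-scale retention figures, which
depend on real genome composition and the exact thermodynamic engine.

## Problem sizes and determinism

The test suite and the acceptance script run on families of 3–4 genes of
800 bp (plus many micro-instances for the exhaustive oracles: coverage DP
vs enumeration at ≤ 15 candidates, greedy selection vs an independent
re-implementation at ≤ 12, subset choice at ≤ 6 guides).  These sizes keep
every oracle exact while exercising all code paths; the pipeline itself
has no scale assumptions beyond memory.  Fixed inputs and seeds give
byte-identical outputs on repeated runs.

## Known limitations

* No primer-dimer or hairpin thermodynamics beyond the penalty model; an
  external engine should be plugged in when those matter.
* IUPAC-ambiguous restriction sites and degenerate primers unsupported.
* Trans-spliced or multi-contig genes are not handled.
* 3D pooling is not implemented (the layout API reserves the dimension
  field); the ~5% per-pool detection floor quoted for pooled sequencing
  is an empirical property of the sequencing assay, not computed here.
* Overlapping genes are extracted independently; shared sequence will
  make each the other's specificity liability.
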