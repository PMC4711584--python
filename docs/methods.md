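# Methods

## The promoter class and its representation

The σ^I promoters of cellulosome-producing clostridia are bipartite: an
"extended -35" element whose invariant core is an AAA triad, a 13–14 nt
spacer, a -10 tetrad with consensus CGWA, and a TW dinucleotide four bases
3' of the -10.  Factor specificity is carried mainly by the columns
immediately 5' of the AAA triad (a single conserved C three columns
upstream for σ^I6, with a weaker CGA run before it; a C-rich block for
σ^I3) and by the -10 third position (strict A in the σ^I6 regulon, A/T in
σ^I3's).  `sigiscan` represents this class at three levels: an anchored
alignment of seed promoters, a degenerate IUPAC consensus at a conservation
threshold, and a probabilistic scoring model (PWMs + spacer distribution).

## Anchoring

The published alignments are reproduced by deterministic anchoring on the
two cores rather than by a general-purpose aligner, so results do not
depend on aligner versions.  For each seed the 3'-most -10 tetrad match is
located and an AAA core is sought 13–14 nt upstream.  Two details matter:

* **The -10 anchor pattern is CGNA, not CGWA.**  The seed tables align
  promoters whose tetrad carries C or G at the third position (the sigI4
  promoter pair, cel8A, cel9Q) in the -10 block; anchoring on strict CGWA
  would reject them even though the printed alignments retain them.  The
  derived consensus over the sets is still CGWA.  The anchor pattern is a
  `MotifSpec` field and can be tightened.
* **Ties prefer the largest spacer**, because the published alignments
  left-justify the AAA triad within the poly-A runs that often follow it.
  Gap characters stored with a seed are honoured as spacer-shortening: a
  placement whose printed spacer width (gapless spacer plus gaps inside it)
  would exceed the maximum is not considered, which reproduces, e.g., the
  13 nt spacer of the sigI1 promoter.

Seeds with no valid placement are reported as rejected with a reason; on
the packaged tables the rejected rows are exactly those whose printed -35
triad is incomplete (sigI7 in both organisms, cel9P, rsgI9, sdbA, and the
hypothetical-protein gene Clo1313_1436).

`align_as_printed` bypasses per-row anchoring and trusts the printed gapped
layout instead: the -10 columns are taken from the rows that do anchor
(they must agree), and the -35 core sits `spacer_max` columns 5' of it
because gaps pad shorter spacers.  This retains the non-anchoring rows at
their printed columns and is what the conservation statistics of the
14-sequence operon-promoter alignment are computed on.

## Consensus calling

Per column, the single base with frequency ≥ threshold (default 0.85) is
emitted; failing that, the 2-fold IUPAC code whose two bases jointly reach
the threshold (3- and 4-fold codes collapse to N, since the source
alignments use only 2-fold degeneracy).  When two 2-fold codes cover the
column equally — which actually happens at the -10 third position of the
operon-promoter alignment, where A=10/14, T=2/14, C=2/14 makes both W and M
cover 12/14 — the tie is broken toward the code that is a priori more
frequent in a low-GC genome (precedence W, K, M, R, Y, S).  This yields the
W of CGWA; a purely alphabetical tie-break would call M, which no low-GC
promoter compilation uses.

## Scoring model

PWM column probabilities are `(count_b + 4·α·q_b) / (n + 4·α)` with
pseudocount α = 0.5 and background q from the genome composition (default
GC 0.39, matching the *C. thermocellum* chromosome).  Extension columns not
covered by a short seed are excluded from that column's counts.  The spacer
distribution over [13, 14] uses +1 smoothing.  A placement's score is the
summed log₂-odds over extension+core, -10 and downstream columns plus
`log₂P(spacer) − max log₂P`, so the modal spacer costs nothing and the
score of a site equals the familiar PWM log-odds at that register.
Ambiguous input bases (IUPAC codes) contribute the background-weighted
average of the covered bases to both numerator and denominator.

The hit threshold `min_score` is calibrated per model as the minimum
best-placement score over the model's own training seeds minus a one-point
margin — the analysis offers no absolute cutoff, and this choice guarantees
every validated promoter is itself recovered.  The margin and the
calibration set are recorded in the serialized model.

Variant rescoring holds the wild-type placement fixed so that a score
change is attributable to the mutated column (a re-search mode exists
behind a flag); `hits_consensus_column` reports whether the position falls
in a non-N column of the trained consensus.  Note that with six extension
columns the σ^I6 model flags the conserved C (and the A/C- and G/C-rich
columns that pass the threshold as 2-fold codes) but not the weaker CGA
positions, which are still scored by the PWM — mirroring the observation
that those bases matter despite falling below the bolding threshold.

## Genome scanning

Upstream regions are extracted in coding-strand orientation over a window
(default 1000 nt, exceeding the longest packaged 5'UTR of 846 nt), capped
at neighbouring annotated features by default, truncated at linear-replicon
edges and wrapped on circular ones.  Every (-10 position × spacer)
placement in the region is scored; hits ≥ threshold are ranked best-first
with greedy non-overlap selection, one hit per gene by default.  The
reported `utr_5p` is the distance from the base 3' of the downstream
element to the gene start — a proxy, since true 5'UTRs are measured from a
transcription start that predictions do not have; the genomic span of the
promoter is reported alongside so either convention can be recovered.

Ortholog support scans the ortholog's upstream region with the same model
and compares the bases at the model's consensus (non-N) columns;
`supported` requires identity at ≥ `min_element_identity` of those columns
(default 1.0, i.e. identical elements, the criterion used for the
*C. straminisolvens* comparisons).

## Synthetic genomes

The generator emulates the context the models target: a single linear
low-GC chromosome (i.i.d. background, default 39% GC) where genes of
300–900 nt alternate with 320–500 nt intergenic gaps, roughly half the
genes on each strand.  A chosen fraction of genes (default 0.4) receives
one instance sampled from a motif model (per-column PWM draws, spacer from
the model distribution, background fill elsewhere), written verbatim into
the chromosome so that it ends 20–120 nt before the start codon on the
coding strand.  The intergenic minimum must hold two plants plus offsets
(one gap can serve a minus-strand gene on its left and a plus-strand gene
on its right), which the configuration validates.  An ortholog mode copies
the genome and re-writes only the planted spans at a per-base mutation
rate.  All outputs are byte-reproducible from the integer seed.

What the generator does **not** emulate: codon structure or ORFs inside
genes, operons, transcription itself, genome-scale compositional
heterogeneity (skews, repeats, horizontally acquired islands) and real
intergenic length distributions.  Passing recovery tests therefore shows
that the scanner finds what the model describes in the background the model
assumes; it does not bound false-positive rates on a real chromosome, where
composition bias will shift the score distribution.  The suite estimates
and reports the per-gene false-positive rate on promoter-free synthetic
genomes (50 replicates) without asserting a bound.

## Numerical and design choices

* Coordinates are 1-based inclusive at every interface (GFF3 convention);
  BED export converts to 0-based half-open.
* The downstream element sits at offset 4 after the -10 (the four
  unconstrained columns before TW in the candidate-table layout); offset 3
  is representable via `MotifSpec(downstream_offset=3)` for the alternative
  "three bases downstream" reading.
* The σ^I6 extension is six columns so that both the CNNAAA C (three
  columns 5' of AAA) and the weaker CGA run before it are covered; the two
  published anchorings of the 5' C (five or three columns upstream) are
  both expressible through `minus35_extension_len`.
* Information content is the standard 2 − H bits; the small-sample
  correction 3/(2·ln2·n) is off by default so logos of the tiny seed sets
  match the uncorrected values used everywhere else.
* Annotation ties (equal scores) resolve to the 3'-most -10, then the
  smaller spacer; scan determinism is guaranteed by sorting on
  (score desc, gene id).
* Test and acceptance simulations use 10–20 genes per genome over 20–50
  seeds — large enough for the binomial bounds asserted, small enough to
  keep the suite quick.

## Known limitations

* The σ^I3 consensus derived from the four packaged *C. thermocellum*
  seeds is weaker than the published eight-sequence version (which included
  unprinted *C. straminisolvens* orthologs): the C-rich extension appears
  as MCCYY rather than CCCYY.  The -10 consensus CGWA is unaffected.
* Scanning is restricted to the coding strand of annotated genes' upstream
  windows; antisense and intragenic promoters are out of scope.
* Scores are recognition scores, not predictions of promoter strength;
  reporter activities are not modelled.
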