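# Methods

`senescmir` re-implements, as a tested library, the computational arc of a
plant senescence small-RNA study: small-RNA libraries from two tissues (leaf,
silique) sampled at four stages (young, mature, early senescence, late
senescence) are processed and screened for regulated miRNAs; sequences that
are not known miRNAs but are senescence-induced are clustered into candidate
loci and tested for hairpin character; locus small RNAs are scored against a
transcriptome with the plant target-penalty scheme; and PARE (degradome)
libraries validate predicted cleavage. A seeded synthetic-study generator
supplies inputs with the statistical structure the analysis assumes, so the
whole pipeline runs and is tested with no external data.

## Read processing and normalization

Raw reads are insert + 3′ adapter. The trimmer cuts at the leftmost exact
occurrence of the adapter's first `min_overlap` (default 7) bases and keeps
inserts of 18–30 nt; reads with no adapter hit, out-of-range inserts or
ambiguous bases are rejected, with per-reason accounting so that
raw = kept + rejected always holds. The lower bound of 18 nt is what
perfect-match miRNA quantification needs; the upper bound reflects the
20–30 nt gel selection of small-RNA libraries.

Mapping is exact-match on both strands (a seed-and-verify k-mer index; the
test suite checks it against a naive linear scan). The analysis is built on
perfect sequence identity throughout — distinct sequences are the unit of
account, multi-mapping sequences contribute their full count at each locus
for locus-level analyses but are counted once in library totals.

Sequences with *any* hit overlapping an annotated tRNA/rRNA/snoRNA/snRNA
interval (strand-agnostic, ≥1 nt) are removed as structural contaminants;
genome-matched = structural + retained is asserted at run time. Retained
counts are normalized to transcripts per two million (TP2M):
`count / retained_total × 2·10⁶`. The same function serves per-ten-million
(TP10M) reporting via its `scale` argument.

## Differential miRNA screen

Known miRNAs are quantified by exact identity to catalog mature sequences;
family members sharing a sequence report the same abundance and never
double-count totals. The screen is the replicate-free single-library-per-
stage design: a miRNA passing a 50 TP2M floor in at least one library of the
tissue is flagged up (down) if fold change vs the mature stage is ≥3 (≤1/3)
in early or late senescence. Fold changes use a 1 TP2M pseudocount to guard
zero denominators. Library-vs-library R² is the squared Pearson correlation
of log10(TP2M + 1) over miRNAs passing the floor in either library; the log
scale is the package's choice (abundances span orders of magnitude) with a
linear option retained.

## Locus discovery

Candidate sequences are distinct retained sequences that (i) match no
catalog miRNA, (ii) pass the same 50 TP2M floor, and (iii) are ≥3-fold
induced in early- or late-senescence leaf vs mature leaf. The floor is this
package's addition: at finite depth a floorless fold filter admits every
singleton read that happens to appear only in a senescence library, which is
sampling noise, not signal.

Candidate genome hits extended by ±250 nt are merged (gap ≤ 100 nt) into
windows. Per window, strand bias = majority-strand share of *all* retained
sRNA abundance mass in the window (not only candidates); windows with bias
> 0.9 survive, as expected of hairpin-derived loci and unlike the
double-stranded signature of siRNA regions. The locus core is the hit span
of the abundant members (≥5% of the window's top member mass), so stray
low-count candidates cannot stretch it.

### Hairpin criterion

A miRNA-like precursor is a single stem-loop. The folding score is computed
by an in-package dynamic program over single-hairpin structures: nested pairs
(Watson–Crick + G:U) around one terminal loop of ≥3 nt, counting only pairs
in helices of at least `min_helix = 5` consecutive stacked pairs;
score = 2·credited_pairs / window_length ∈ [0, 1], and the reported value is
the maximum over the window and its reverse complement (G:U pairing is not
strand-symmetric; taking the max makes the score independent of which strand
was read). The helix-length constraint is essential: *unconstrained*
maximum-matching pairs most bases of any random sequence and separates
nothing, whereas with it, i.i.d. random 200-mers score ~0.35–0.52 while
inverted repeats score ≥0.9 (both measured by the shipped Monte-Carlo
tests). The pass threshold is 0.6. Because precursor boundaries are unknown,
folding tries a small grid of asymmetric paddings (0/30/60/90 nt per side,
minimum 50 nt window) of the locus core and keeps the best-scoring window;
this covers precursors up to roughly 300 nt, the usual plant pre-miRNA
range. An external thermodynamic folder can be substituted by scoring the
same windows with any callable, but the pipeline is self-contained by
default.

### Locus report and annotation criteria

A surviving locus is reported with its distinct sRNAs whose abundance summed
across all libraries exceeds a floor (default 200 TP2M summed over the eight
libraries), their sizes, and a per-position abundance track. The
precise-excision (MIRNA annotation, "Meyers") check groups locus sequences
that share both ends within ±1 nt, takes the most abundant group per arm
(arms split at the hairpin's terminal-loop midpoint) and reports their joint
share of locus mass; ≥0.75 passes. The bundled senescence locus sits right
at this boundary (~0.74 at default seeds): its five small RNAs are too many
and too spread for formal miRNA annotation, even though it passes bias and
folding — miRNA-like function without miRNA-grade excision precision.

## Target scoring

The penalty scheme charges, per sRNA position: mismatch 1.0, G:U wobble 0.5,
bulged nucleotide 2.0, all doubled at sRNA positions 2–13 (the 5′ core).
Minimum-penalty antisense alignment is found by DP with a bulge budget
(≤2), with bulges forbidden opposite positions 10–11 so the cleavage
register is unambiguous; the predicted cleavage site is the target position
paired to sRNA base 10 (the 5′ end of the downstream fragment). A vectorized
scan computes per-window-end minima across whole transcripts; full
alignments are reconstructed only where the score is at or below the cutoff.
The cutoff is ≤4.0 *inclusive*: reported plant targets sit exactly at 4.0,
so an exclusive reading would discard the canonical boundary cases. All
constants (penalties, core interval, multiplier, budget) are configurable so
the scorer can be calibrated to any served predictor's settings; the
tubulin-family worked example (4.0/3.5/4.0) is reproducible with
`examples/score_tua_targets.py` given the TAIR10 cDNAs, which are not
bundled.

## PARE processing and validation

PARE tags are 20-nt fragments (MmeI-defined) whose 5′ end marks an uncapped
decay intermediate. Tags are exact-matched in transcript space (they derive
from mRNA); each occurrence increments the 5′-end counter at its position,
multi-transcript tags count at every match, unmatched tags are tallied.
Normalization is per ten million transcript-mapped reads. A predicted site
is *supported* iff the expected position (±`window`, default 0 — the strict
one-bond reading of "between bases 10 and 11"; `window=1` gives the looser
reading) carries signal and ranks ≤5 among the transcript's positions. Rank
and positivity are scale-free, so verdicts are depth-invariant. Site
abundance tracked across stages gets a monotone-trend label from the sign of
the Spearman correlation with stage order.

## Synthetic-study generator

The generator is first-class, tested code and defines the study conditions:

- **Design**: 8 sRNA libraries (leaf/silique × 4 stages) and 6 PARE
  libraries (4 leaf stages + replicated early/late senescence), 100,000
  reads each — a desk-scale stand-in for the real 10⁷-read libraries, chosen
  so the 50 TP2M floor equals ~2.5 read counts and the screen operates in a
  realistic signal/noise regime.
- **Genome**: 2 × 150 kb random chromosomes; 10 structural-RNA intervals per
  chromosome (80–300 nt, labelled rRNA/tRNA/snoRNA/snRNA), placed disjoint
  from planted loci.
- **Senescence locus**: the five published 21/21/21/24/21-nt small RNAs
  embedded in a constructed ~174-nt near-perfect inverted repeat (two arms
  differing at 6 positions so that every mature occurs exactly once, plus
  strand only). Per-mature abundances are proportional to the published
  summed abundances; locus totals ramp
  0.002/0.004/0.02/0.06 (leaf young/mature/early/late; silique slightly
  lower), rising monotonically into late senescence in both tissues.
- **Screen miRNAs**: nine planted catalog miRNAs with mature-stage read
  fractions spanning 0.0005–0.006 (an order-of-magnitude spread, as a real
  miRNA complement has) and effects of 8/6/4-fold up, 6-fold down, and flat,
  plus a two-id family sharing one sequence and one catalog entry absent
  from the data. Regulated effects sit in the several-fold range reported
  for senescence-responsive miRNAs rather than at the 3.0 decision boundary.
- **Reads**: raw sRNA reads are insert + adapter truncated to 36 nt;
  background/structural insert lengths are drawn 18–26 nt with leaf peaked
  at 21 nt and silique at 24 nt. Planted mature sequences are rejected and
  redrawn if they contain the adapter probe. Structural reads are
  `structural_fraction` (0.15) of each library; planted weights are absolute
  per-library read fractions and uniform genomic background absorbs the
  remainder.
- **PARE**: signal tags are exactly the 20-nt transcript substring starting
  at the planted cleavage site (perfect-complement target sites embedded
  mid-transcript); off-target tags start uniformly at transcript positions
  drawn from a per-stage pool whose size shrinks with a complexity factor
  (1.0/1.0/0.12/0.04 across stages), reproducing the collapse in distinct
  PARE sequences that accompanies senescence; replicates of a stage share
  the pool but sample independently.
- **Determinism**: every draw derives from `SimulationConfig.seed` via
  keyed seed sequences; identical configs give byte-identical FASTA/
  GFF3/FASTQ/TSV outputs. A truth ledger (TSV) records each planted
  sequence, position, per-library weight and expected cleavage site;
  downstream tests read expectations from it, not from constants.

**What the generator does not emulate** — and hence what green tests do
*not* establish about real data: sequencing error and quality variation
(mapping here is exact-match, so errors would only discard reads), ligation
and PCR bias, isomiR/excision raggedness (locus sRNAs have perfectly sharp
ends, which flatters the precise-excision check), genomic repeat structure
and multi-mapping ambiguity at scale, poly-A selection chemistry, and
biological replicate variance (the screen is single-library by design, as in
the sequencing design it mirrors).

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally; GFF3 I/O converts to 1-based
  inclusive at the boundary, and reported cleavage sites are 1-based.
- Normalization of an empty retained set is an error, not NaN.
- R² requires ≥3 miRNAs above the floor and non-constant columns.
- Rank ties in PARE validation share the best rank (rank = 1 + number of
  strictly greater positions).
- Exactly-at-threshold behavior: fold ≥ 3 flags, bias must exceed 0.9
  strictly, hairpin ≥ 0.6 passes, target score ≤ 4.0 is kept.
- Spearman trend of a constant profile is labelled `none`.
- The pipeline asserts count conservation per library at run time and embeds
  the config hash and seed in its summary, so reruns are verifiable.

## Problem sizes used in tests and the acceptance script

Tests and `scripts/acceptance.py` run the full 8 + 6 library design at
100,000 reads per library on the 300 kb genome; multi-seed checks (screen
recovery, null-locus robustness, PARE support) use 10–20 seeds with leaf
libraries where the operation under test is leaf-defined. These sizes hold
the screen's floor semantics and window statistics in the regime described
above while keeping a full run in tens of seconds.
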