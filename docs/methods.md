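# Methods

`strainscan` re-implements, at desk scale, the comparative-genomics
computations used to contrast a newly assembled mosquito strain genome
against its reference strain: one-to-one whole-genome alignment,
structural-variant breakpoint classification, a depth-normalized SNP
density landscape, circular-contig (mitogenome) repair and comparison,
and assembly contiguity metrics. All stages run on genomes of a few
megabases in seconds to a couple of minutes on one CPU; nothing in the
package assumes gigabase scale.

## Synthetic data generator (`strainscan.simulate`)

The generator produces the inputs a two-strain resequencing study yields,
with planted truth, so every downstream stage can be validated without
external data.

**Reference genome.** I.i.d. uniform A/C/G/T. This is deliberate: with no
repeat families, unique-k-mer anchoring is well posed on small genomes
and alignment truth is unambiguous. Real genomes of the target organisms
are highly repetitive; conclusions from these tests therefore concern the
correctness of the algorithms, not their robustness to repeats (which the
upstream studies handle by repeat-masking before alignment).

**Derived strain.** Variation is planted in three layers, mutually
exclusive in reference coordinates:

* *SNPs* — per-base substitution probability given by a baseline rate
  (default 2×10⁻³) overridden inside "landscape" intervals (hot/cold
  regions). Multi-strain pool structure is not modeled: a SNP is a site,
  not an allele frequency.
* *Small indels* — rate 2×10⁻⁵ per base, lengths 1–10 bp, spaced ≥50 bp
  apart; emitted as VCF-anchored alleles.
* *Structural variants* — insertions (novel sequence), deletions,
  inversions, intra-/inter-chromosome relocations and tandem
  duplications, applied through a segment edit-script so the truth set
  carries exact coordinates in both the reference and the query frame.
  A 60-bp pad around every SV junction is kept free of point variation so
  planted breakpoints are crisp; consequently large inverted/relocated
  segments carry no internal SNPs. This slightly understates realism but
  makes recovery tests exact.

**Depth track.** One negative-binomial read count per 1-kb bin
(default mean 250 reads ≈ 50× for 200-bp reads; dispersion size 60, i.e.
variance m + m²/60), modulated by a smooth sinusoidal regional trend
(amplitude 0.15, period 3 Mb) emulating mappability/GC coverage waves.
Planted outlier regions draw uniformly from [0, 20) ("low") or
(350, 600] ("high"), strictly outside the retained range.

**Depth-coupled SNP discovery.** Empirically, raw per-window SNP counts
from short-read calling correlate positively with read depth — more reads,
more calls — and that correlation is the reason the landscape statistic
divides by coverage. The generator reproduces the effect by scaling the
SNP planting probability linearly with the local depth trend
(`depth_coupling`, on by default). With a flat trend
(`depth_trend_amplitude = 0`) planted counts in an interval are exact
Binomial(length, rate) draws; the binomial-count test uses that
configuration.

**Mitogenome.** A 16,634-bp "ancestral" circle; the focal strain carries a
184-bp insertion at position 14,831 (final length 16,818 bp), the
comparison strain a 137-bp insertion at 14,523 plus substitutions at rate
5×10⁻³ (the first 30 bp — the linearization anchor gene — are kept
conserved). These values are calibrated so the pair reproduces the
published strain comparison: ≈97.6% identity with two large
control-region indels. The focal circle is emitted "over-assembled":
rotated to a random origin with its first 400 bp spuriously repeated at
the end, the signature that reads spanning a circular origin leave in a
linear contig.

Non-goals of the generator: read-level simulation (FASTQ), sequencing
error models, repeat families, pool allele frequencies.

## Anchor alignment (`strainscan.align`)

Maximal exact matches are seeded by k-mers (default k = 21) that occur
exactly once in each genome, with both strands of the query scanned;
seed runs on a shared diagonal are extended to maximality. Anchors are
chained per (reference chromosome, query chromosome, strand) group by a
sparse best-predecessor dynamic program: a predecessor is compatible when
both inter-anchor gaps are ≤ `max_gap` (default 2,000 bp), overlap is
≤ 50 bp, and the diagonal drift is ≤ `max_diag_drift` (default 500 bp).
The drift bound is what splits blocks at indels ≥ ~0.5 kb; the defaults
therefore resolve SVs of ≥1 kb while chaining through isolated SNPs and
small indels. Chains are peeled off in descending score order.

Block identity is **anchor-covered bases / max(reference span, query
span)** — an approximation of alignment identity that is accurate when
divergence is dominated by well-spaced point variants (at rate r the
expected uncovered fraction is ≈ r·k per SNP flank). It is not a
substitute for full dynamic-programming extension on repeat-rich data.

One-to-one filtering keeps blocks **strictly longer than 10,000 bp** with
**identity ≥ 0.85** (the length bound exclusive, the identity bound
inclusive — both exposed as options), then selects a maximum-total-score
subset with pairwise overlap ≤ 50 bp on both frames. The conflict graph
is split into connected components; components of ≤ 32 blocks are solved
exactly (branch-and-bound maximum-weight independent set), larger ones
greedily by score with ties broken by length then position. On realistic
inputs conflicts are sparse, so selection is effectively exact; the exact
small-component path is also what makes the oracle-equivalence tests
structural rather than fortuitous.

## Breakpoint classification (`strainscan.breakpoints`)

Blocks sorted along the reference yield exactly one breakpoint per
adjacent pair, classified in order: query re-use (duplication in the
reference strain, impossible after strict one-to-one filtering), query
chromosome switch (relocation, different chromosome), strand flip
(inversion, possibly with relocation), query order violation or jump
> `jump_threshold` (default 100 kb; relocation, same chromosome), and
otherwise an alignment gap with signed `delta = qryGap − refGap`:
positive = insertion in the query strain, negative = deletion, zero =
plain gap. The tally's "alignment gap" row counts the whole gap class
(insertions + deletions + zero-delta gaps). Chromosome termini with more
than `min_end_len` (default 10 kb) unaligned reference sequence add one
"other" breakpoint each; with two termini per chromosome this matches the
constant per-chromosome "other" counts seen in published tallies.
Because inversions and relocations produce one breakpoint at each edge,
counts are a census of discontinuities, not of evolutionary events.
Reports are 1-based inclusive; internal coordinates 0-based half-open.

## SNP landscape (`strainscan.landscape`)

1. **Depth mask** — 1-kb bins with read counts < 20 or > 350 (i.e.
   below 4× or above 70× for 200-bp reads) are excluded; the bounds
   themselves are retained.
2. **Indel removal** — only records whose reference and all alternate
   alleles are single bases are counted; multi-allelic SNP records count
   once (a site statistic).
3. **Windows** — width 750 kb, step 250 kb, anchored at 0, truncated at
   chromosome ends; every window is evaluated (interior bases fall in
   three windows).
4. **Statistic** — `normDensity = snpCount / meanDepth`, where
   `meanDepth` is the mean fold-coverage of *retained* bins
   (readCount × readLen / 1000, readLen default 200) and `snpCount`
   counts SNPs lying in the window **and** in a retained bin. "Read depth
   per window" is interpreted as mean per-base fold-coverage, not summed
   bases: only this reading makes the conventional thresholds (500 high,
   < 1 low) attainable at ~50–60× coverage. Windows whose bins are all
   masked are `no_data` and excluded from calls and correlations.
5. **Calls** — `high` iff density > 500, `low` iff density < 1, both
   strict; a window at exactly the threshold is `mid`.

A SNP in a masked bin could arguably still be counted if the caller
emitted it; we exclude it, since the masked depth makes the call itself
untrustworthy. For log-scale plotting, zero-density windows are drawn at
a fixed floor of 10⁻²; the floor never affects calls. The Pearson
correlation helper demands ≥ 3 finite points and is used both for the
count-vs-depth diagnostic and the optional gene-count correlation.

## Circular contigs (`strainscan.circular`)

* **Terminal overlap** — the longest suffix matching a prefix of the same
  contig with mismatch rate ≤ 5% and length ≥ `min_overlap` (default
  50 bp; values < 20 are refused as spurious-match bait). Because a
  candidate longer than the true duplication compares shifted, unrelated
  sequence (~75% mismatch on random DNA), the detected overlap equals the
  planted duplication exactly, and trimming is idempotent.
* **Rotation** — circles are linearized at the unique occurrence of an
  anchor sequence (a conserved gene start); the search is circular (the
  anchor may span the current origin) and strand-aware (a minus-strand
  hit reverse-complements first). Zero or multiple occurrences raise an
  error naming the count.
* **Pairwise comparison** — optimal global alignment with affine gaps
  (match +1, mismatch −1, gap open −4, gap extend −1) via a banded,
  row-vectorized integer Gotoh DP (`strainscan._affine`); the band is
  sized from the unit-cost edit distance (edlib). Affine scoring is
  load-bearing: under unit costs, two nearby long indels in opposite
  strains can be "smeared" into cheaper scattered substitutions, losing
  both reported indels. Identity = match columns / alignment columns
  × 100, gap columns included in the denominator by default
  (`count_gap_columns=False` switches convention, since published
  identity figures rarely state theirs). Gap runs ≥ `min_report_len`
  (default 50 bp) are reported 1-based inclusive in the ungapped frame of
  the sequence bearing the insertion, so length = end − start + 1 always
  holds (e.g. a 184-bp insertion at 14,832 is reported as 14,832–15,015).
  Indel start positions are alignment-justified and may shift by a base
  or two when the flank ends in a chance match.

## Assembly metrics (`strainscan.metrics`)

N50 is the largest L such that sequences of length ≥ L sum to at least
half the total, with ceiling semantics on odd totals. `summarize` counts
upper- and lowercase N as gap characters (other IUPAC ambiguity codes are
sequence) and reports totals with and without Ns. Empty inputs and
non-positive lengths are rejected.

## Validation problem sizes

The test-suite and acceptance scenarios use: a 2 × 2.5-Mb strain pair
with 25 planted SVs (10 deletions, 10 insertions of 1–5 kb, 3 inversions
of 20–30 kb, 2 inter-chromosome relocations of 30–40 kb) for breakpoint
recovery; a 2 × 5-Mb genome with 3 hot and 5 cold 750-kb intervals for
the landscape; 100 random circles of 10–20 kb with 100–500-bp terminal
duplications for trimming; and the 16.8-kb mitogenome pair for
comparison. These sizes were chosen so the whole suite exercises every
stage end to end in about a minute while leaving wide statistical margins
(hot windows sit ≈ 12% above the calling threshold against a noise SD of
under 1%).

## Known limitations

* The aligner estimates identity from anchor coverage and is intended for
  unique-sequence genomes; repeat-rich genomes need masking upstream.
* Relocation destinations additionally register as one insertion
  breakpoint on the destination chromosome — a faithful description of
  the alignment geometry, but a consumer counting "insertions" should be
  aware of it.
* Breakpoint counts are not deduplicated into events.
* The generator's truth VCF represents *called* variants; variant calling
  itself (and its false positives/negatives) is out of scope.
* Pairwise circular comparison is limited to sequences ≤ 100 kb and to
  divergences for which the affine band (twice the edit distance) fits in
  memory.
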