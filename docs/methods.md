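# Methods

`ricevar` re-implements, as a reusable and tested pipeline, the downstream
genome-variation analysis applied to a re-sequenced inbred rice line that
was called against a shared reference genome together with several related
comparison lines: parsing the caller's custom SNP/InDel/SV table formats,
coverage-corrected sliding-window variant-density scanning, identification
of focal-line-specific SNPs, codon-level functional-effect classification,
per-gene variant tabulation, and a SNP-distance neighbor-joining phylogeny.
Read alignment and variant calling themselves are out of scope: the
pipeline starts from call tables.

## Coordinate conventions and input formats

All internal coordinates are 1-based inclusive, matching the SOAPsnp-style
consensus convention of the three custom table formats:

* **SNP consensus (18 columns)** — chromosome, position, reference base,
  consensus genotype (an IUPAC ambiguity code for heterozygous calls),
  consensus quality, two best-allele support blocks (base, quality,
  unique-read and all-read counts), total depth, an opaque
  order-and-quality field that is carried verbatim and never interpreted,
  estimated copy number, a dbSNP presence flag, and the distance to the
  nearest neighbouring SNP.
* **InDel (9 columns)** — the combined type-and-length field is parsed as a
  letter `I`/`D` followed by the length (`I2`, `D3`); `+2`/`-3` is accepted
  as a tolerated dialect.  The event sequence must match the stated length.
* **SV (10 columns)** — cluster bounds, estimated breakpoints, length, an
  insertion-only breakpoint column (`.` otherwise), a read-orientation
  string over {F, R} and supporting pair count.

Readers accept any run of tabs/spaces as the delimiter and write a single
tab.  Strict mode rejects a malformed line with its line number; lenient
mode skips it with a logged warning and a skip count.  Every parsed record
is validated against its type invariants — there is no silent coercion.

BED coverage masks are 0-based half-open on disk and converted at the
boundary (`chrom 0 100` covers 1-based 1..100); GFF3 gene models follow the
gene → mRNA → exon/CDS hierarchy.  A model whose spliced CDS length is not
divisible by 3 (or, when a genome is supplied, does not start with ATG or
end in a stop codon) is flagged invalid, kept for region calls, and
excluded from coding-effect classification.  VCF 4.2 export expands the
IUPAC genotype into ALT alleles (GT `1/1` homozygous non-reference, `0/1`
het containing the reference, `1/2` het of two non-reference alleles).

## Sliding-window density scan

Window frequency is the variant count divided by the number of **covered**
bases in the window, excluding uncovered nucleotides; the genome-scan
defaults are a 100-kb window advanced in 50-kb steps from position 1 of
each chromosome, the final window truncated at the chromosome end.  A
variant is counted in every window containing its position.  Windows with
zero covered bases have undefined frequency and never participate in
threshold estimation or region calling.

The source study reports high/low-frequency regions without stating its
threshold rule, and its printed region counts cannot fix that rule, so the
rule here is this package's own choice: by default a window is *high* when
its frequency strictly exceeds the empirical (1 − α) quantile of all usable
window frequencies genome-wide (α = 0.025, two-sided; *low* symmetric), with
a mean ± 2 SD alternative selectable and per-chromosome estimation
available.  Overlapping or abutting same-kind extreme windows are merged,
and regions — not windows — are what get counted, since reported "regions"
are plural-window entities.  With strictly identical frequencies, or α = 0,
no window can strictly exceed the quantile and no regions are called.

## Line-specific SNPs

A focal SNP locus is line-specific when the comparison lines' genotypes at
the locus are mutually identical *as allele sets* and differ from the focal
genotype.  "Identical" is exact allele-set identity, so a het A/G versus a
hom G/G counts as different; this is the strictest reproducible reading,
and it is configurable.  The comparison lines are not required to match the
reference — only each other — with an optional `must_match_reference` flag
to tighten that.  The test is generalized to N ≥ 1 comparison lines (the
study's case is N = 3).

Whether the original analysis imputed the reference genotype at no-call
loci or required coverage in every line is not recoverable, so both
policies are implemented and neither is asserted as "the" original
behaviour: `absent_as_reference` (default) assigns the homozygous
reference genotype to a line without a call; `require_covered` drops loci
uncovered in any comparison line and counts them separately.  A reference
base disagreement between tables at the same locus raises an error.

## Coding-effect classification

For a SNP inside a gene model, the region is assigned by interval
membership (CDS, then exon-minus-CDS = UTR, else intron; outside every
transcript span = intergenic).  For CDS hits the affected codon is
reconstructed in spliced, strand-oriented CDS coordinates
(reverse-complementing on the minus strand), each non-reference allele of
the genotype is substituted, and the effect is classified under the
standard nuclear genetic code:

* **synonymous / nonsynonymous** — the encoded amino acid is preserved /
  changed;
* **premature stop** — a non-terminal codon becomes a stop codon;
* **start loss** — any change to the annotated initiation codon (no other
  single substitution of ATG yields ATG);
* **stop loss** — the annotated terminal stop codon becomes a non-stop
  codon.  A terminal stop changed into a *different* stop codon is
  synonymous.

These three large-effect classes are the only ones defined; splice-site
disruption is deliberately not a class.  When a heterozygous genotype
carries two non-reference alleles, every allele is evaluated and the most
severe effect is reported (large-effect > nonsynonymous > synonymous), ties
broken by alphabetical alternate allele for determinism.  A SNP overlapping
several gene models yields one annotation per model; chromosome-level
summaries count each SNP once by its most severe annotation, because the
summarised quantities are SNP counts, not SNP × gene pairs.  The "mRNA"
summary column counts SNPs anywhere in the transcript span (UTR, intron or
CDS) — whether the original "mRNA" counts included introns is unstated, and
an exonic-only mode is available.  SNPs in flagged-invalid models get a
region call with the coding effect deferred.

## Per-gene tabulation

For a user-supplied list of gene names, `gene_variation` counts SNPs in the
gene's "DNA" span — the transcript's genomic interval, optionally extended
by a flank, since promoter inclusion in the original table is unstated —
and in its "mRNA" — the exon union by default, or the CDS only under the
stricter "coding regions" reading.  Both readings are supported and
labelled rather than guessed.  Unresolved names are reported, not raised.

## Distances and phylogeny

The per-locus distance between two lines is an allele-sharing score over
the union of loci called in either line (reference imputed at no-call
loci): 0 for identical allele sets, 0.5 for overlapping but unequal sets,
1 for disjoint sets; the pair distance is the mean over loci.  This
handles het calls more gracefully than strict genotype mismatch, which is
selectable.  An optional consensus-quality threshold can filter calls
first; no default filtering is applied, since the original tree's SNP
selection is unstated.

The tree method is canonical neighbor joining (the original work cites a
phylogenetics suite without naming the algorithm; NJ is that suite's
default for such data, recorded here as an assumption).  Implementation
choices that make output deterministic: Q-matrix ties are broken by the
lowest (row, column) index pair; negative branch lengths are clamped to
zero and counted; Newick output fixes branch lengths at six decimals.  NJ
recovers any additive distance matrix exactly, which the tests exploit.

## Synthetic data: what it emulates and what it does not

The simulator generates the study design itself: one shared reference
genome, clean gene models, and four inbred lines' call sets — shared
background SNPs present in all lines with identical genotypes,
focal-line-only SNPs, planted large-effect SNPs constructed codon-by-codon
so their class is true by construction, hotspot blocks multiplying the
local background rate, per-line uncovered intervals with no calls emitted
inside them, and positional-only InDel/SV records to exercise I/O and
window scanning.

Default conditions (one value per parameter, chosen once): two 1-Mb
chromosomes; 20 three-exon genes; background SNP density 8 × 10⁻⁴ per bp —
the genome-wide SNP density of the focal call set analysed by the original
study (≈3.1 × 10⁵ SNPs over a ≈3.7 × 10⁸ bp genome); InDel and SV densities
1.5 × 10⁻⁴ and 8 × 10⁻⁶ per bp, preserving that study's ≈5:1 and ≈100:1
SNP:InDel and SNP:SV ratios; 300 focal-specific SNPs; 6/3/4 planted
premature-stop/start-loss/stop-loss SNPs; one 100-kb hotspot block at 10×
background; 17% of each line's genome uncovered, matching the reported
≈83% consensus coverage; and a 5% heterozygous-call rate, reflecting
mostly-homozygous inbred lines (the original encoding of hets is unstated;
IUPAC codes are assumed).

Two construction rules exist purely to keep the planted truth *exactly*
recoverable, and are documented limitations on realism: heterozygosity is
decided per locus (all carrier lines share the genotype), because
independent per-line het calls would create genuine but unplanted
focal-specific allele-set differences; and shared SNPs are never placed
where all comparison lines are uncovered, because reference imputation
would otherwise manufacture an unplanted focal-specific locus.  The
simulator also makes no attempt at read-level realism, quality-score
realism, linkage structure, or sequence-realistic InDels/SVs.  Passing the
recovery tests therefore shows the pipeline's logic is exact under its own
stated model, not that real call sets are this clean — real data add
caller error, reference bias and shared ancestry that the truth-set
guarantees deliberately exclude.

## Numerical and degenerate-input choices

Window frequencies are exact ratios of two integers; thresholds use the
linear-interpolation empirical quantile.  Region calling requires a
configurable minimum number of usable windows (default 8).  Fewer than
two lines, a non-symmetric or negative distance matrix, fewer than three
taxa for NJ, zero usable loci for a pair, and a reference mismatch across
tables all raise errors rather than guessing.  Chromosome extent for
windowing is taken from the coverage mask's largest covered coordinate
unless explicit lengths are passed.  Chromosomes are always ordered by
natural sort (chr2 before chr10).

## Reference-table fixtures

The only genome-scale results of the original study that are reproducible
without its unreleased sequencing data are arithmetic identities over its
printed tables.  Those tables are shipped as transcribed TSV fixtures
(per-chromosome SNP/InDel/SV counts; high/low region counts; specific-SNP
annotation counts; large-effect class counts), and
`verify_fixture_totals` re-adds each column in exact integer arithmetic
and compares it with the printed total.  In the extracted text of the
source, the region-count table's per-chromosome cells appear as run-together
digit strings; they were segmented during transcription under the
constraint that all six columns sum to the printed totals row, which has a
unique solution also consistent with the surrounding prose about which
chromosomes are richest in high regions.

## Problem sizes used in tests and the acceptance script

The shipped acceptance run uses the default synthetic conditions above
(two 1-Mb chromosomes, ≈2.6 k focal calls), an exhaustive
~5.5 k-substitution effect-oracle scan over a five-gene genome, a
400-variant window-recount oracle, and 25 random additive trees of 4–8
taxa; the whole run completes in a few seconds.  These sizes were chosen
as the smallest at which every planted structure (hotspot windows,
specific loci, all three large-effect classes, four distinguishable lines)
is comfortably represented.

## Known limitations

* The high/low-region threshold rule is this package's construction; the
  original counts are not expected to be reproduced, only the counting
  *convention* (merged regions per chromosome and class).
* Genome-scale published values (total variant counts, the specific-SNP
  total, depth/coverage metrics) require the original raw data and are
  checked only as printed-table arithmetic.
* InDel/SV analysis is count/density only; no frameshift annotation.
* One transcript per gene is assumed; the standard nuclear genetic code is
  hard-coded.
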