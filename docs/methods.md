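# Methods

## Coordinates and gene models

All coordinates are 0-based half-open (BED convention). A transcript is an
ordered chain of non-overlapping exons on one strand; a gene is a set of
isoforms with one *representative* — the isoform with the longest genomic
span, ties broken by the lexicographically smallest transcript id. The TSS
of a `+` gene is the representative's lowest coordinate, of a `-` gene its
highest; 5'/3' language throughout the package is transcriptional, not
genomic.

## Exon classification

Each exon of each isoform receives exactly one of seven categories.
Terminal exons are positional: the 5'-most exon of a transcript is
`promoter`, the 3'-most `polyA`; a single-exon transcript is labelled
`promoter` (a terminal label must win, and the 5' one was chosen). Internal
exons start as `canonical` and are updated by pairwise comparison against
every other isoform of the gene:

* no overlapping exon (≥1 bp shared) in the partner → `variant`;
* an overlapping exon whose donor (3' splice boundary) differs →
  `altDonor`; whose acceptor (5' boundary) differs → `altAcceptor`;
  both → `altBoth`.

Updates are sticky in the severity order canonical < altDonor/altAcceptor
< altBoth < variant, and donor/acceptor mismatches accumulated across
different comparisons combine to `altBoth`. Two choices were genuinely
open and are fixed as follows: (1) boundary comparisons ignore the *outer*
boundary of a terminal exon in the partner isoform, because transcription
starts/ends are not splice sites and would otherwise inflate the
alternative categories; (2) when several partner exons overlap one exon,
the partner with the fewest boundary mismatches is the comparator — an
exon should not be called alternative against a paralogous overlap when an
identical exon also exists. The classifier is invariant to transcript
order within a gene (verified by property test).

## Region-location classes

An interval's midpoint is tested in precedence order against: the nearest
TSS (ProximalPromoter within 250 bp, Promoter1K within 1 kb, Promoter3K
within 3 kb), gene spans (Genebody), pericentromeric/subtelomeric windows
(annotated centromeres/telomeres expanded by 100 kb), distance to the
nearest gene (Genedesert beyond 1 Mb), else OtherIntergenic. The class
names fix the 1 kb/3 kb rings; the proximal radius (250 bp), desert
distance (1 Mb) and heterochromatin window (100 kb) are conventional
defaults, all exposed in `RegionClassifierConfig`. Nearest gene and the
strand-signed TSS distance (positive downstream) are always reported.
Enhancers whose midpoints fall within ±5 kb of any TSS are discarded to
avoid mislabelling promoters; survivors are assigned to the nearest TSS.

## Coverage

*Physical* coverage extends each alignment to the expected fragment length
(default 150 bp; per-sample override via configuration column 4) from its
5' end: `+` reads extend downstream from the start, `-` reads upstream
from the end, clipped at position 0. CIGAR gaps are ignored in ChIP mode —
the footprint models the sequenced DNA fragment. RNA-seq mode instead uses
the aligned CIGAR blocks intersected with exons, concatenating per-exon
vectors in transcription order (flanks, if requested, are plain genomic
windows beyond the terminal exons).

Extraction batches regions into chunks (default 100) and issues one merged
index query per chunk and chromosome, distributing reads back to every
overlapping region without deduplication; the result is provably identical
to per-region queries for every chunk size (tested for 1–1000). Queries are
padded by the fragment length so fragments reaching into a window from
outside are counted. Library size counts alignments that are mapped,
primary, non-supplementary, not QC-fail, not duplicate, and at or above a
MAPQ threshold (default 0); the exact filter set is config-exposed since
upstream conventions differ.

The legacy run-length codec (value, run-length pairs with a small binary
file format) is retained for whole-genome vectors; it is exact and
minimal, but scales poorly for dense modern libraries, which is why the
chunked-query strategy is the default path.

## Normalization and profiles

Variable-length bodies are equalised to a fixed column count (default
1001) by an interpolating natural cubic spline through all (index, value)
points evaluated at equally spaced abscissae — constants and endpoints are
preserved exactly — or by splitting into near-equal contiguous bins and
averaging (bins differ by at most one base; the leading bins take the
remainder). The bin method cannot upsample, so bodies shorter than the
target are linearly interpolated. Point windows are computed at single-base
resolution and bin-averaged to at most 2001 columns; interval flanks get a
fixed 5 bp per column so margins are comparable across flank sizes. These
resolutions are package choices (the method itself fixes neither) and are
all keyword-exposed.

RPM scaling multiplies by 10⁶/library-size. BAM pairs are combined per
position as `log2((s+p)/(c+p))` with the pseudocount `p = 0.1` expressed in
RPM units, making the ratio invariant to sequencing depth.

The average profile is the per-column mean ± SEM (`sd/√n`) across regions;
an optional symmetric two-sided trim removes the `floor(n·t)` smallest and
largest values per column first, and the SEM uses the post-trim count.
Profile smoothing is a centred moving average with an odd window,
truncated (not reflected) at the edges, so window 1 is the identity.

## Ranking and corrgram

`total`, `max`, `prod` and `diff` are stable descending sorts on row
statistics (ties keep input order); `prod` multiplies per-sample row sums
as-is, so negative log2-ratio sums can flip sign — documented behaviour.
`pca` concatenates samples column-wise, removes column means (no scaling)
and scores rows by projection on the first right singular vector; the sign
is fixed so the scores sum non-negatively, since a principal component's
orientation is arbitrary. `hc` uses Euclidean distance, complete linkage
and the standard recursive leaf order (no optimal leaf ordering). The
corrgram reduces each region to its per-sample row sum and reports all
pairwise Pearson and Spearman coefficients with p-values; zero-variance
samples yield NA with a warning.

## Synthetic data

`FixtureSpec` defaults: 2 gene-bearing chromosomes of 1 Mb with 30 genes,
plus one gene-free chromosome carrying centromere/telomere annotations —
gene-desert (>1 Mb from any gene) and heterochromatin-window classes are
unreachable on a 1 Mb chromosome that contains genes, and the generator
must elicit all eight classes. Two handcrafted isoform pairs (one per
strand) provably produce every internal exon category; a long three-exon
gene anchors Genebody probes; the remaining genes are random multi-isoform
models covering all five biotypes. CGIs are placed at controlled TSS
offsets (0/600/2000/30000 bp), enhancers at ±4 kb (excluded by the TSS
filter) and ±12 kb (kept).

Reads: 5×10⁴ background fragments with uniform midpoints, plus Gaussian
peaks (sd 200 bp) at every protein-coding TSS sized so peak-centre
coverage ≈ 10× background; fragment midpoints are sampled first and read
starts derived per strand (strand drawn 50/50), so fragment extension
recovers the sampled footprint exactly. Reads are written as a sorted,
indexed BAM; everything is a pure function of the seed.

What the generator does *not* emulate: mappability and GC bias, duplicate
and multi-mapping reads, realistic base qualities or sequence content,
paired-end inserts, chromatin-state-dependent background. Passing tests
therefore demonstrate algorithmic correctness and statistical calibration
under idealised sampling, not robustness to real-library artefacts.

## Numerical and degenerate-input choices

Windows that would cross a chromosome boundary are dropped (not clipped),
with a warning, so matrix columns stay aligned. Unstranded regions and
alignments are treated as `+`. Gene-list matching trims whitespace but is
case-sensitive, and output follows list order so ranking `none` honours a
user-supplied ordering. Columns with fewer than two post-trim survivors
get SEM 0 with a warning. The replot archive stores float64 arrays
verbatim (zip of `.npy` members plus a JSON manifest); round trips are
byte-identical, and a format-version mismatch raises naming both versions.

## Problem sizes

The test suite and the acceptance script run on the default synthetic
study (3 Mb genome, 30 genes, ~5×10⁴ reads, 500-region extraction checks,
200-gene classifier census) — small enough to regenerate in seconds while
leaving every statistical check well-powered.

## Known limitations

Tabix/bigWig coverage backends are deliberately out of scope (the chunked
BAM-index strategy supersedes them), as are paired-end fragment-size
inference, deduplication beyond SAM flags, between-sample normalization
beyond RPM, and remote annotation downloads: annotation stores are local
TSV directories, built here by the generator or by the user's own
tooling.
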