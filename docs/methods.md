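# Methods

This note documents the models and procedures implemented in
`grapesdr`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic data do and do
not establish.

## Collinear block detection (`synteny`)

Anchors are homologous gene pairs (one reference gene, one target
gene) taken from a filtered all-vs-all protein hit table. Chains must
have strictly increasing reference ranks and strictly increasing
(plus) or decreasing (minus) target ranks, with consecutive anchors at
most `max_gap + 1` ranks apart on both genomes. Defaults mirror the
MCScanX parameterization this pipeline emulates: `min_block_size = 5`,
`max_gap = 25`.

Chains are scored by the sum of anchor bitscores, with no gap penalty
— the gap constraint is already a hard limit, and bitscore sums match
the "greatest bit score" selection used downstream. Extraction is
greedy: the best-scoring chain with at least `min_block_size` anchors
is reported and its anchors removed, until none remains; an anchor
therefore belongs to at most one block (the conservative reading of an
overlap-window setting of 1). The best chain is found by dynamic
programming with chain length capped at `min_block_size` in the state,
so a long qualifying chain is found even when a shorter, higher-scoring
chain exists. Ties break on score, then length, then the smallest
anchor key, making output deterministic. The test suite checks this
extraction against exhaustive chain enumeration on 200 random small
instances.

Tandem duplicates are not collapsed before chaining; duplicated target
genes simply contribute extra anchor candidates, of which a chain can
use at most one per reference rank. Both orientations are searched
independently and a block never mixes orientations.

## Conservation windows (`windows`)

The reference is split per contig into consecutive, non-overlapping
windows of 12 genes (the SDR gene count); trailing genes that do not
fill a window are dropped so all windows are comparable. Windows
restart at contig boundaries.

*Orthologous* assignment selects, per haplotype, the single block
anchoring the greatest number of distinct window genes (ties: larger
summed bitscore, then smaller block id). *Homologous* assignment
counts every block anchoring at least `min_window_anchors = 2` window
genes — one anchor is indistinguishable from a stray hit — and scores
each window gene from its greatest-bitscore partner across all counted
regions. The orthologous mode scores genes from the selected block
only, using the best anchor per gene within that block.

The conservation score is `min(1, pair_bitscore / self_bitscore)`;
clamping handles the rare case of a pair alignment outscoring the
reference self-alignment. Scores are rank-normalized to
`(rank − 1)/(n − 1)` (mean ranks for ties; a singleton group maps to
0.5) within two clade groups — eudicots, and all other angiosperms —
so that windows are compared on within-group ranks rather than raw
scores that decay with divergence time. Non-flowering lineages carry
no collinear SDR genes and form their own (empty or near-empty) group.

The SDR-vs-background contrast is a two-group Kruskal–Wallis on the
focus window's values across haplotypes against all other windows;
Dunn's z tests with Benjamini–Hochberg adjustment are exposed for
multi-group comparisons (the adjustment method is a package choice;
"adjusted p" alone does not pin one down).

## LD analysis (`ld`)

**Filtering.** The default profile retains biallelic SNPs with
QUAL > 30; per-sample depth > 5 and ≤ 3× that sample's median depth
(the median is computed per accession before filtering); MAF > 0.05
over non-missing calls; zero missing genotypes; and passing GATK-style
hard filters (QD < 2.0, FS > 60.0, MQ < 40.0, MQRankSum < −12.5,
ReadPosRankSum < −8.0, SOR > 3.0 are removal conditions; absent
annotations pass). The low-coverage profile replaces the depth rule
with exclusive bounds 1 < DP < 15. Rejections are tallied against the
first failing filter in the order qual, depth, maf, missing, hard.

**r².** Squared Pearson correlation of unphased genotype codes
(composite LD, plink's default), computed for all pairs within 300 kbp;
monomorphic sites and pairs with fewer than three shared non-missing
samples are skipped. No per-pair-count window is emulated — that is a
compute shortcut, not statistics.

**Decay.** E[r²] follows the Hill & Weir (1988) sample-size-adjusted
drift expectation with C = ρ·d and n sample chromosomes; ρ is fitted by
bounded least squares from several starts. The half-decay distance is
where the fitted curve reaches half its d→0 value, found by bisection;
the fit is flagged "no decay" when that level lies below the 1/n
asymptote or beyond the observed distance range.

**Landscape.** Each pair contributes its r² to the 1-kbp bin of each
of its two endpoints (a one-dimensional collapse of the 2-D aggregation
used by Tomahawk-style tools); bins with fewer than 5 SNPs are masked.
The SDR boundary estimate is the longest run of unmasked bins with
mean r² ≥ 0.4, tolerating up to 2 intervening low bins.

**Heterozygosity contrast.** Per sample, the ratio of homozygous-alt
to heterozygous calls within a region; zero-het samples are flagged
infinite and excluded from the group test with a warning. A
heterogametic sample carrying one diverged sex haplotype is
heterozygous at every sex-linked site, so its ratio drops inside the
SDR relative to homogametic samples.

## Divergence dating (`dating`)

K2P uses observed transition (P) and transversion (Q) proportions over
unambiguous columns; saturation (1−2P−Q ≤ 0 or 1−2Q ≤ 0) is an error,
not a clamp. dS is Nei–Gojobori (1986): synonymous site fractions per
codon (mutation paths through stop codons excluded), synonymous
differences averaged over all minimal edit paths between codons, and
the Jukes–Cantor correction dS = −¾ ln(1 − 4/3·pS). NG86 stands in
for yn00: at the divergences relevant here (dS ≤ ~0.1) the two agree
closely, while yn00's codon-frequency and ts/tv weighting is a large
estimation machinery of its own; the package's estimator-recovery
tests bound NG86's bias at these scales to a few percent. Codon pairs
containing gaps or ambiguity codes are dropped pairwise.

The clock is applied exactly as printed for this system:
T = K/(2µ) × generation time, µ = 2.5×10⁻⁹ per base per *year*,
g = 3 years, reported in My. Multiplying a per-year rate by a
generation time is dimensionally odd, but it is the arithmetic that
reproduces the published magnitudes, and the package follows it
without asserting a dimensional interpretation. Feature dating
averages the clock-dated K estimates and reports the spread as the
population standard deviation (n in the denominator), the form
consistent with the two-point worked example in the package tests; a
single estimate has no spread.

The dS landscape smooths per-gene dS along position with loess
(tricube weights, locally quadratic, span 0.75 — the span is a package
default, not a published value) and contrasts inside vs outside the
SDR interval with Kruskal–Wallis. Segmented-regression breakpoint
inference is out of scope.

## Promoter scanning (`motifs`)

Promoters are the ≤ 3000 bp immediately upstream of the TSS, taken as
the annotated gene start (plus strand) or end (minus strand) and
reverse-complemented for minus-strand genes, so position always means
"bp upstream of the TSS". Count matrices get a pseudocount of 0.8
times the background (uniform unless provided) before log-odds;
relative score is (score − min)/(max − min) over achievable log-odds
sums, and the reporting threshold defaults to 0.80, the common
TFBSTools-style default. Hits on the reverse strand are mapped back to
promoter coordinates; a hit's offset is the distance from the TSS to
the 5′-most base of the matched window.

A site is group-specific when every promoter of one group has a hit
for the motif within 30 bp of a common offset and no other group's
promoter has any hit in that window — an alignment-free surrogate for
comparing alignment columns, sized to absorb small indel shifts.
Presence/absence calls in the tests scan at relative score 0.9 for an
8-bp consensus: one mismatch scores exactly 7/8 = 0.875, so the 0.80
default would let chance one-mismatch background occurrences block or
fake an all-or-none call.

## Synthetic data (`simulate`)

The generators produce every input with known truth; all are pure
functions of config + seed.

**Genome set** (defaults: 2400 ancestral genes, 20 haplotypes — 8
eudicots at divergence 0.4–1.2, 8 other angiosperms at 0.8–1.6, 4
non-flowering at 1.8–2.2 time units). Each lineage independently
applies gene loss (0.03 per gene per unit time), gene gain (0.02),
tandem duplication (0.01) and segmental inversions (0.002, mean length
8 genes); a WGD flag duplicates the whole gene order. Bit scores decay
as `self · exp(−λ·t·(1−boost))` with λ = 0.4 and lognormal noise (sd
0.1); the planted window (index 40, boost 0.9) is additionally
protected from loss and rearrangement in angiosperms and deleted
outright in non-flowering lineages. This emulates a hyper-conserved
window against a decaying background, not real genome evolution: there
is no rate heterogeneity among background genes beyond the score
noise, no partial-window degradation, and hit tables contain only
true homologs plus self hits.

**Population** (defaults: 10 diploids — 3 heterogametic — on a 2-Mbp
chromosome, SNP density 1/500 bp). Haplotypes are founder-copying
mosaics over 6 founders with switch probability 10⁻⁵ per bp outside
the SDR (925–1075 kbp) and zero inside; heterogametic samples carry
one M-like SDR haplotype bearing M-specific alleles at density 1/100
bp. The copying model produces distance-decaying r² and a sharply
bounded high-LD block, which is what the boundary-detection and
contrast machinery needs; it is not a coalescent and its allele
frequency spectrum, decay shape and absolute r² levels are not meant
to match any real population. QUAL/DP/INFO fields are drawn from
all-passing distributions so the filter path is exercised without
rejections by default.

**Sequences.** Codon pairs use four-fold degenerate families whose
first two positions admit no synonymous change, so each codon carries
exactly one synonymous site and the third-position hit probability
implied by the target dS is exact under the Jukes–Cantor correction;
stop codons cannot arise. LTR pairs diverge under a per-site Poisson
event process with 2:1 transition:transversion odds, exercising both
K2P terms and multiple hits. Promoter sets are uniform-random
sequences with the consensus planted at the configured offset in the
designated groups only.

Passing tests on these generators shows the *machinery* is correct —
chains match enumeration, estimators recover known truth, planted
structure is found at its planted location and significance — not that
the biological conclusions would replicate on real assemblies, whose
noise structure (fragmented annotation, paralog confusion, mapping
artifacts, population structure) the generators deliberately omit.

## Numerical and degenerate-input choices

- Internal coordinates are 0-based half-open; GFF3 (1-based inclusive)
  and VCF (1-based) only at the I/O boundary. Gene-rank ties break by
  end coordinate then gene id.
- The per-query subject cap applies after e-value filtering, ranked by
  bitscore with subject-id tie-breaks, and a duplicate query/subject
  pair keeps its best bitscore.
- Readers never impute: missing genotypes stay missing and are handled
  (excluded) by filters.
- Kruskal–Wallis on all-identical data returns H = 0, p = 1 with a
  warning instead of failing.
- All simulation and test seeds are explicit; stochastic CLI
  subcommands require a seed rather than seeding from the clock.

## Problem sizes

Defaults were chosen so a full desk run stays light: the genome set
(20 haplotypes × ~2400 genes) chains and scores in a few seconds; the
2-Mbp population yields ~5000 SNPs and ~4 million r² pairs in under
half a minute; estimator-recovery runs use 10 000 codons × 10 seeds and
5-kbp LTR pairs × 20 seeds. These sizes give stable statistics (the
acceptance quantities are reproducible across seeds) while remaining
far below the scale of the real 63-haplotype, 56-genome comparisons
the pipeline is modeled on.

## Known limitations

- NG86 rather than yn00/ML; biased upward of a few percent only at
  divergences far above the SDR range.
- The Hill–Weir fit assumes a single genome-wide ρ; a region of
  suppressed recombination violates it, which is precisely what the
  landscape (not the fit) is used to find.
- Group-specific site calling is alignment-free; co-localization within
  30 bp substitutes for alignment-column identity and can in principle
  merge distinct nearby sites.
- The orthologous-mode scoring rule (best anchor within the selected
  block) is a package choice; only the homologous mode's
  "greatest bit score" rule is externally fixed.
- MCScanX's tandem-array collapsing is not emulated; whether it would
  materially change window assignments on real data is untested here.
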