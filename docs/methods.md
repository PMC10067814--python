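# Methods

`chancexpr` models and analyses a random-promoter reporter assay in
yeast: libraries of fully random 120-nt sequences ("random promoters")
placed upstream of random 20-nt barcodes report how much transcription
arises *by chance* from arbitrary DNA, and that chance-activity
distribution is then used as the null against which the expression of
intergenic genomic windows is judged. Expression that chance promoter
activity (plus readthrough from neighboring genes) cannot account for
is the operational signature of putatively functional intergenic
transcription.

## 1. Barcode quantification

**Counts.** Reads carry a 6-nt unique molecular identifier (UMI);
reads sharing a UMI within a (barcode, replicate, molecule) sample are
PCR duplicates and collapse to one molecule. A barcode's *normalized
read count* is NRC = count / (sample total); the *total NRC* merges the
per-replicate NRCs by summation, TNRC_i = Σ_r NRC_{i,r}. Expression is

    E_i = TNRC_i^cDNA / TNRC_i^DNA.

Summing NRCs (rather than raw counts) before the ratio makes E_i
exactly invariant to per-sample sequencing depth. Barcodes need ≥ 100
DNA molecules in *every* replicate to be quantified; a zero DNA TNRC is
flagged unusable, never silently zero.

**Relative expression (REL).** Eight barcodes belong to a positive
control whose gene-level expression relative to the median of all
native genes, `s`, is known from external RNA-seq (supplied as a
configuration scalar, default 0.37). Each barcode then gets eight REL
estimates REL_ij = (E_i / E_j) · s, j = 1..8. Controls with E_j = 0
are excluded with a warning.

**Activity call.** A barcode is *active* when a one-sample t-test of
the eight negative-control E values against E_i rejects
(Benjamini–Hochberg across barcodes, FDR 0.05) and E_i exceeds the
negative-control mean.

**Cutoff grid.** For each cutoff c ∈ {0.1, …, 1.0}, a one-sample
t-test of the eight RELs against c is BH-corrected per cutoff across
the tested population; "significantly higher than c" additionally
requires mean REL > c. A barcode's *bin* is (c, c+0.1] for the highest
exceeded c, with a lowest bin for items exceeding nothing and an open
top bin above 1.0. The BH family is one cutoff across items; the same
engine serves barcodes and windows so the two populations are binned
commensurably. Zero-variance REL vectors (typically all-zero counts)
are resolved by exact comparison to the cutoff and logged.

## 2. Intergenic landscape

**Regions.** Genic footprints are protein-coding genes extended 200 nt
outward from each annotated UTR end (or 200 nt from each CDS end when
UTRs are unannotated) and RNA genes (rRNA, tRNA, snRNA, snoRNA, ncRNA)
extended 50 nt per end. Intergenic regions are the genome minus these
footprints and minus centromeres, telomeres, LTRs and LTR
retrotransposons, as maximal intervals clipped to chromosome bounds.
Coordinates are 1-based inclusive throughout (the GFF3 convention;
BED output converts to 0-based half-open). Each region records its
nearest flanking genes; a missing neighbor (chromosome end) makes the
affected neighbor-expression variant undefined, not zero.

**Windows and expression.** Regions are tiled into non-overlapping
20-nt windows from the lower coordinate; a terminal remainder < 20 nt
is discarded (⌊L/20⌋ windows). Window expression is strand-specific
reads-per-million; gene expression is the mean RPM of the gene's
sense-strand windows; the *reference* for each (environment,
replicate) is the median over all annotated genes, and per-replicate
window REL = RPM / reference. The cutoff grid of §1 then runs per
(window, strand) within each environment.

## 3. Attribution

**Per-bin comparison.** With W_b and B_b the fractions of windows and
barcodes in REL bin b, the attributable fraction within b is
min(W_b, B_b)/W_b (1 when W_b = 0) and the unattributable mass is
max(0, W_b − B_b); the total unattributable fraction sums the
exceedance bins. The lowest bin (nothing significantly above 0.1) is
attributable by definition: expression indistinguishable from the
lowest cutoff requires no promoter activity at all.

**Neighbor filter.** Windows above the REL threshold (the upper edge
of the highest fully-attributable bin) are ranked by the mean
expression of their flanking genes and split into 50 equal groups
(sizes differing by ≤ 1). The top group is removed repeatedly; after
each removal the median neighbor expression of the remainder (ME1) is
compared with medians of 1000 equally sized random samples from *all*
windows (ME2, drawn without replacement, seeded). Removal stops at the
first state where fraction(ME2 ≥ ME1) exceeds 0.05 — the comparison
uses ≥, and the full trace is returned.

**Region-level Monte-Carlo test.** A region of length L contains
N = ⌈L/120⌉ promoter-sized segments. Its observed expression E_obs is
the maximum (or 95th percentile) of its window RELs; each of 100,000
replicates draws N activities with replacement from the measured
promoter REL library and takes their maximum E_sampled; the nominal P
is the fraction with E_sampled > E_obs (strict inequality — ties do
not exceed). P values are BH-corrected across tested units and a unit
is *unexplainable* when the adjusted value is below 0.05. Because
window expression is strand-specific, the test unit is (region,
transcriptional direction); a region counts as unexplainable when
either direction is flagged. A complementary one-sided rank-sum check
asks whether unexplainable regions have higher neighbor expression
than the rest (if they do, readthrough rather than intrinsic activity
is the likely driver).

**Environment sharing.** For items significantly exceeding a cutoff
in one environment, the *shared fraction* is the proportion also
exceeding it in the other, computed in both directions. The trend test
for "sharing falls with the cutoff" is a one-sided binomial sign test
on the pooled slopes of both directions' curves, after masking cutoffs
whose denominator holds fewer than 10 items: a fraction over a handful
of items moves in steps of ≥ 0.1 per item and carries granularity, not
trend information. Zero slopes (a curve resting on its floor) are
ties and drop out, as in any sign test.

## 4. The synthetic study

The generator produces every input the pipeline consumes, plus ground
truth that no pipeline stage reads.

**Chance activity.** Promoter activity on the REL scale is a point
mass of inactive promoters (weight 0.368) plus a lognormal tail
(µ = −3.37, σ = 1 on the log scale). The two anchors are the scale
observed for fully random yeast promoters — roughly 63% of library
barcodes active against the negative control, and of order 0.02%
exceeding the native-gene median — with σ fixed at 1; the model's
shape beyond those anchors is a modelling choice, not a fit.

**Library.** 1,500 random promoters (defaults; nucleotide frequencies
A/T/G/C = 0.243/0.324/0.257/0.176 as synthesised libraries are rarely
equimolar), one barcode each, mixed with eight-barcode negative and
positive controls at 100:5:1. DNA molecule counts per barcode are
negative binomial (mean 300 per library barcode per replicate,
dispersion 20, i.e. ~22% biological CV); cDNA means are DNA mean ×
activity × 10, so the expected cDNA/DNA ratio is linear in activity
and exactly zero for negative controls (a configurable background
leak defaults to 0). Every molecule carries a random 6-nt UMI; 10% of
reads are PCR duplicates; linkage read pairs connect barcodes to
promoters with a 0.2% chimera rate and an optional per-base read error
rate (default 0). Three replicates per environment.

**Landscape.** 500 intergenic regions (default lengths 60–600 nt) laid
out on four chromosomes between planted gene footprints, with
telomeres, a centromere and genes with/without annotated UTRs and RNA
genes so the exclusion and extension logic is exercised; the planted
regions and the regions reconstructed from the emitted GFF3 agree
exactly, by construction and by test. Each 120-nt segment of each
region draws one chance REL per strand, shared between environments;
all six 20-nt windows of a segment inherit its REL, which is what
makes the region test's N = ⌈L/120⌉ null exact on null data. A
functional minority of regions (default 5%) gets one (segment, strand)
raised to 4× the 99th percentile of the chance sample in one
environment only. Readthrough adds RPM decaying exponentially
(length constant 150 nt, edge level 0.2 × the neighbor's RPM) into
regions from flanking genes transcribed toward them. Counts are
negative binomial around REL × reference (reference = median gene at
15 RPM, pinned exactly so truth and measurement share one scale) with
20 M reads per sample; RNA-seq replication is asymmetric by design —
ten samples in rich medium (YPD), three in minimal medium (SCD) —
matching the replication structure of the public expression data the
analysis assumes.

**What the generator does not emulate** — and hence what passing
tests do not show about real data: activities are assigned
independently of promoter sequence (GC/TATA/TFBS detectors are
exercised against their own nulls, or against explicitly planted
associations in tests, not against an emergent sequence–activity
map); no base-call errors, alignment, mappability or coverage bias in
the RNA-seq arm; no index hopping; UMI collisions occur at the natural
4⁻⁶ rate but UMI errors do not; chance activity is drawn per segment,
so sub-segment activity structure is absent.

## 5. Numerical and design choices

* Greedy Hamming clustering processes sequences in decreasing
  abundance with lexicographic tie-break; the centroid is the most
  abundant member. Distinct random barcodes/promoters differ at far
  more sites than the 2/6-mismatch tolerances, so the clustering
  algorithm's identity is immaterial — determinism is what matters.
* TNRC is the sum of per-replicate NRCs (merging normalized, not raw,
  counts), which buys exact depth invariance.
* TATA detection uses the consensus TATAWAWR on both strands — the
  standard yeast definition; a PWM-based detector can substitute.
* Wilcoxon rank-sum tests use exact enumeration for small untied
  samples and the tie-corrected normal approximation otherwise.
* PWM scanning is additive log-odds with a per-TF cutoff; matrices are
  assumed pre-processed (no pseudocounts at scan time); reverse-strand
  hits score the reverse complement and report forward-axis
  coordinates.
* All Monte-Carlo steps (region test, neighbor filter, shuffles) take
  explicit seeds; fixed seeds reproduce every generated byte.
* Desk-scale defaults (1,500 promoters, 500 regions, 10,000–100,000
  Monte-Carlo replicates) are the package's chosen study size; every
  statistical conclusion in the tests carries the sampling error of
  that size in its tolerance.

## 6. Known limitations

* The positive-control scaling `s` is an external input; the package
  does not recompute it from RNA-seq.
* BH families are per cutoff; pooling families across cutoffs would
  change borderline calls.
* The per-bin attribution rule min(W_b, B_b)/W_b is the minimal rule
  consistent with comparing two bin occupancy profiles; cumulative
  variants can be derived from the emitted exceedance curves.
* With readthrough enabled, the region-level test is intentionally
  uncorrected for neighbors (mirroring the analysis it models); the
  neighbor-expression group check is the guard that reports when that
  assumption is violated, and on the synthetic landscape with strong
  readthrough it does fire.
* The trend sign test has little power when a shared-fraction curve
  is mostly at its floor; the masked-denominator rule above is the
  package's guard against over-reading sparse tails.
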