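# Methods

This note documents the models, parameter choices and numerical conventions
behind `microloh`, and what the synthetic-data generators do and do not
emulate.

## The toy locus and hybrid reference

The diploid locus is a 50 kb random genome contig whose central 1.5 kb
"protein-coding exon" is replaced, on the knock-in allele, by the
integrated 5 kb segment of a 6 kb reporter cassette. Sizes are a
compromise: large enough that the exon, its two 5 kb flanks (kept ≥ 1 kb
clear of the junctions so junction-straddling fragments cannot bias flank
coverage) and a surrounding analysis window are all distinct at the default
350 bp fragment length, small enough that a 30× experiment simulates and
maps in about a second. All intervals are 0-based half-open internally;
SAM output converts to 1-based positions.

The mapping reference follows the hybrid-template strategy: the genome
contig keeps the wild-type exon, and only the *integrated* cassette
segment is added as a second contig (plasmid backbone is excluded, so
backbone reads can never be mistaken for knock-in evidence). A coordinate
map relates knock-in-haplotype positions to (contig, position) pairs;
wild-type exon positions have no knock-in image and map to `None`.

Synthetic primer sites replicate the layout of a three-primer knock-in
assay — common forward 200 bp upstream of the exon, wild-type reverse
100 bp inside it, mutant reverse 150 bp into the cassette, long-range
reverse 180 bp downstream — so band logic (wt-only / both / mutant-only,
with allele-distinct long-product sizes) is a deterministic function of
genotype. The printed primer sequences themselves are retained as data and
exercised against a synthetic 300 bp neighbourhood stub in the matcher's
unit tests; the real mouse locus is not shipped.

## Read simulation and the aligner

Fragments are drawn uniformly from the two haplotypes implied by the
genotype (50:50 in expectation), with truncated-normal lengths
(350 ± 50 bp, floor just above the 75 bp read length), FR mates, per-base
substitution errors (default 10⁻³) and duplicate re-emissions at a
configurable rate (default 2 %). The generator consumes a fixed number of
random draws per fragment regardless of haplotype, so two samples
simulated with a common seed share the fragments that land on the common
(wild-type) allele slot. This common-random-numbers property is a
deliberate design choice: paired simulation designs (e.g. comparing
wild-type and heterozygous samples seed-by-seed) then estimate coverage
*ratios* with substantially less variance than independent draws, the
standard variance-reduction argument for matched simulation experiments.

The aligner is intentionally minimal, sized to the toy locus: exact 20-mer
seeds at three offsets per read and strand, ungapped Hamming extension,
mismatch ceiling 10 % of the read length. A unique best placement receives
MAPQ 60, ties MAPQ 0 — a binary MAPQ model is sufficient for a "< 20"
retention threshold. Reads are simulated without indels, so no gapped
extension is needed. Pairs are proper when both mates map to one contig in
FR orientation within 10× the expected fragment length; pairs whose mates
split between the genome flank and the cassette contig are kept separately
as junction evidence. Duplicate marking groups proper pairs by
(contig, outer span, orientation), keeps the highest base-quality-sum
record (ties: lexicographically smallest template id, for determinism) and
only flags; filtering only removes, in the order dedup → MAPQ, recorded in
the provenance log. External SAM can be substituted for the built-in
aligner; emitted SAM is valid for standard readers (checked against pysam
in the tests).

## Physical coverage and zygosity calling

Physical coverage is fragment-span coverage — the number of retained
fragments whose outer span contains a base — accumulated with a difference
array (exactly equal to naive per-base counting; this is pinned by an
oracle test). Region means may be normalized per million retained
fragments; this denominator is a package choice, documented because only
the ratio structure matters downstream.

Dosage uses the flanks as the two-copy anchor:
`wt_dosage = 2·cov(exon2)/cov(flank)`, `ki_dosage = 2·cov(cassette)/cov(flank)`.
The genotype call maximizes a Poisson likelihood over expected copy
numbers {2,1,0}×(per-copy rate from the flanks) for the exon and cassette
coverages, with junction counts (wild-type-spanning fragments must strictly
contain a junction with ≥ 1 bp on each side; knock-in support requires
mates split genome/cassette) folded in as independent Poisson terms. A
Poisson rather than negative-binomial likelihood is used because toy-scale
simulated counts are not overdispersed; a rate floor of 0.05 absorbs
mismapping noise at zero expected copies. With zero flank signal the
caller returns no-call. At 30× fragment depth calls are certain
(LLR ≫ 10); at 3× accuracy is ≈ 94 % with confusions only between
adjacent dosages. The test suite exercises 6 seeds per genotype at 30×
and 17 per genotype at 3×, sizes chosen to keep the default suite fast.

## Morphometry

Per channel: brightness gain → 3×3 median despeckle (removes isolated
single-pixel foreground; this is why rendered processes are ~3 px wide) →
threshold → topology-preserving thinning (scikit-image `skeletonize`).
Skeleton pixels are classified by 8-neighbour count (endpoint = 1,
slab = 2, junction ≥ 3); adjacent junction pixels are merged into one
branching point by 8-connected labelling. Length counts each adjacent
skeleton-pixel pair once: orthogonal step 1 px, diagonal √2 px, scaled by
the pixel size — the geodesic convention of skeleton-analysis plugins.
Thresholding uses the generator's known intensity by default and Otsu as
the fallback for external images (no threshold rule is inherent to the
method). Cell counting opens the mask with a radius-3 disk (erasing
processes, keeping somata) and counts components above a minimum area.

Reporter-negative cell metrics are obtained by subtracting the reporter
channel's summary from the pan-marker channel's summary, floored at zero,
with per-cell values recomputed — subtraction at the summary level is the
primary mode; a pixel-level mode (mask difference before skeletonization)
exists behind `subtract_channel_masks` for sensitivity analysis. Convex
hull area of process endpoints uses Qhull with a degenerate flag for
collinear/short inputs (cross-checked against a brute-force
point-in-triangle hull oracle).

On generator frames with non-touching, unbranched cells the pipeline
recovers endpoint and cell counts exactly and total length within ~2 %
(10 % tolerated for rasterization); branched defaults stay within the same
length tolerance. Real micrographs differ in every optical respect — the
generator has no PSF, noise floor, uneven illumination or touching cells —
so these tests validate the measurement chain, not segmentation robustness.

## Stereology

Counting frames (150×150 µm on a 300×300 µm grid → asf 0.25) tile each
section with one systematic-random offset shared across sections. The
unbiased frame rule counts a cell strictly inside the frame or on the
inclusion edges (top, right), never on the exclusion edges (bottom, left);
unbiasedness of `N̂ = ΣQ/(asf·ssf·tsf)` is verified by simulation over 500
offsets. Defaults: ssf = 1/36 (25 µm sections at a 36-section interval),
tsf = 1 (the full section height is counted; no optical-disector
subheight). Exhaustive mode (all fractions 1) returns exact counts and is
used for the early-timepoint depletion/overshoot recoveries. Precision is
the Schmitz–Hof second estimate — the Gundersen–Jensen systematic-sampling
variance of the section counts, floored at zero, plus a Poisson
counting-noise term ΣQ, all under a square root and divided by ΣQ — pinned
in the tests by a hand computation. The simulated control density
(1.2×10⁻⁶ cells/µm³ over 3×3 mm sections) is desk-scale: it yields
per-frame counts of ~40–90 per section, the working range of a real
fractionator design, at a thousandth of true tissue density.

## Flow cytometry

Events are drawn multinomially from labelled populations; channels are
log-normal on a linear (pre-compensated) scale with hi/lo medians 1000/10
and log-sd 0.25, i.e. ≥ 18 log-sd separation, so midpoint thresholds
(geometric mean, 100) recover labels near-perfectly — gate placement is
not the object of study, fraction estimation is. The wild-type/wild-type
population's receptor channel uses twice the location parameter of the
heterozygous population (two intact alleles). MFI is the arithmetic mean
on the linear scale by default (geometric behind a flag). No spillover,
autofluorescence or acquisition-order drift is modelled, and no automated
outlier exclusion exists: exclusions must be explicit in configuration.

## Expression

Counts are negative-binomial (variance m + d·m²), default dispersion 0.01
and base means log-normal around 300 — the low-dispersion, high-depth
regime of pooled-cell (100-cell) full-length libraries, chosen so that a
5-vs-5 Welch test has essentially full power at 8-fold effects (the
Welch–Satterthwaite df with n = 5 is the binding constraint). Allele-dosage
rules: the receptor gene's mean in the reporter-negative group is exactly
twice the reporter-positive group's; recombinase and reporter counts are
identically zero in the reporter-negative group. These three genes count
toward the requested number of true DEGs; the remainder are planted
symmetrically at ±effect/2 in log2 space.

Analysis conventions: RPKM = counts·10⁹/(length·library size);
log2 fold change on group-mean RPKM with pseudocount 1 (the fold-change
definition is a package choice); genes with all-zero counts in both groups
are dropped before testing so the BH denominator counts only tested genes;
zero-variance identical genes are flagged and excluded (p would be 0/0).
BH is the exact step-up `q(i) = min_{j≥i} p(j)·m/j` capped at 1 (equal to a
brute-force implementation and to statsmodels in the tests). PCA scores
come from the SVD of the row-centred RPKM matrix, optionally prefiltered
to genes with multigroup-F p < 0.05; the sign convention makes the
largest-magnitude loading positive per component. Row z-scores
(mean-centred, sigma-normalized) exclude constant rows.

## Population dynamics

The branching model is the minimal mechanism consistent with the observed
biology; no dynamical equations exist to transcribe, so the model is this
package's construction. Developmental phase: n synchronous divisions from
a founder pool (default 50 heterozygous founders, 15 divisions), each
heterozygous division undergoing reciprocal LOH with probability
mu_loh = 10⁻³, producing one wt/wt and one ki/ki daughter; the expected
label-free fraction at census is ≈ n·mu/2 = 0.75 % (simulation agrees
within 3 SE). ki/ki cells are tracked as a compartment but reported off by
default, since such cells are not observed in vivo. Daily phase: each cell
divides with probability min(1, g·(1 − N/K)) (logistic crowding,
genotype-specific g reflecting receptor-dosage-dependent proliferation), a
one-day Bernoulli kill of efficiency d (default 0.9) applies to
cassette-carrying residents only, and peripheral cells enter as a Poisson
stream after depletion. Counts propagate by binomial sampling per
compartment, so millions of cells simulate in milliseconds. The closed-form
kill step f/(f + (1−f)(1−d)) and the homozygous-founder zero-LOH
prediction are pinned in tests.

## Problem sizes and determinism

Every generator takes an explicit seed and is bit-reproducible; the CLI
derives per-stage sub-seeds by stable hashing of stage names, so re-running
one stage reproduces its slice of a full run. Default problem sizes
(30× fragment depth on 50 kb; 50 k flow events × 6 animals; 20 animals per
stereology arm; 2 000 genes × 10 samples; 200 branching replicates) are
chosen so the full pipeline runs in well under a minute and the complete
test suite in about a minute on one CPU, while keeping every recovery
comparison inside its sampling-noise tolerance.

## Known limitations

- The aligner is ungapped and single-locus; it is not a general-purpose
  mapper, and externally produced SAM is the intended path for real data.
- Coverage ratios over a 1.5 kb exon at 30× have ~8 % sampling CV per
  sample (long-range fragment correlation); paired designs with common
  seeds are provided for this reason, and small-window read-outs (e.g. the
  290 bp exon head) are noisier still.
- The morphometry generator validates measurement, not segmentation:
  touching cells, 3-D stacks and optical artefacts are out of scope
  (frames are 2-D by construction).
- The branching model has ≤ 6 effective parameters and makes no claim of
  mechanistic completeness; it reproduces qualitative regimes (rarity,
  escape, overshoot, influx), not fitted time courses.
- Flow simulation emits compensated intensities; spillover handling would
  have to precede this pipeline.
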