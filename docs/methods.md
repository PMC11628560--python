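# Methods

This note records the models, conventions and defaults the package
implements, the choices made where the design was genuinely open, and what
the simulation-based tests do and do not establish.

## Coordinates and reference genome

All coordinates are 1-based, closed, and circular over L = 16,569 (site L
is adjacent to site 1); an interval with start > end wraps through the
origin. The bundled annotation table uses standard MITOMAP rCRS gene
coordinates: D-loop 16024..576 (7S DNA 16106..191), 12S/16S rRNA
648..1601 and 1671..3229, the 22 tRNA genes, and the 13 protein-coding
genes; ~89 sites are intergenic and belong to no class. Same-class gene
overlaps (e.g. ATP8/ATP6) are handled as site unions.

The bundled sequence (`synthetic_reference.py`) is a **synthetic
stand-in**, not NC_012920.1: bases are placed deterministically (fixed
seed) so that each region class reproduces the published rCRS per-region
G+C content (D-loop 46.79%, mRNA 44.68%, rRNA 44.88%, tRNA 36.63%) and the
genome-wide strand skew (C ≈ 31%, G ≈ 13%), with the N placeholder at
3107 mirrored. Everything that depends only on composition behaves as on
the real reference; the literal base order is random. Analyses of real
data should load a genuine rCRS FASTA; all code paths are identical.

## Fragment model and 5' ends

A fragment is the outer span of a read pair. BAM ingestion keeps properly
paired, non-duplicate, non-secondary templates with both mates MAPQ ≥ 20
(the standard cut for capture data; duplicate marking and alignment are
upstream concerns). Origin-wrapping fragments are representable in the
BED dialect and the simulator only; a linearized-reference BAM cannot
encode them unambiguously.

Every fragment exposes two 5' ends — light strand (leftmost site, read
forward) and heavy strand (rightmost site, complemented into 5'→3') — and
both contribute to all end tallies. End bases and motifs are read from the
reference at the terminal coordinates, so BED inputs without read sequence
are fully supported; sequencing errors at fragment ends average out at
capture depth. Fragments under 4 bp contribute end bases but no motif.

Because both strand ends are counted, the no-preference expectation for an
end base is the *duplex* composition g_b = (f_b + f_complement(b))/2; the
ratio observed/expected is the end-base preference (1.0 = no preference).
Normalizing against the single-strand composition instead would make a
uniformly cleaved genome appear to "prefer" G ends purely because the
light strand is C-rich. The ratio form (rather than a difference) keeps
the null at 1 and is scale-free.

The motif diversity score is the normalized Shannon entropy of the
256-motif spectrum, MDS = Σ −Pᵢ log Pᵢ / log 256; zero-probability motifs
contribute zero, and the log base cancels. All 256 motifs are carried even
when absent.

## FSD profile

Per sample: median fragment size → long/short split (length ≤ median is
short, a deterministic tie rule) → wrap-aware per-site depths → raw score
FSD(i) = (long+1)/(short+1). The pseudocount keeps zero-coverage sites
defined (neutral ratio 1) and is negligible at the >500× depths the method
is designed for. GC correction fits a LOESS (span 0.75, locally linear)
of the raw score on the per-site GC fraction of a ±50-bp circular window
and returns residual + grand mean, preserving scale; a constant GC track
degrades to the identity (logged). The GC covariate takes ≈80 distinct
values, so the fit is evaluated with delta-interpolation and costs far
less than a naive per-site LOESS. z-scaling uses the population
(n-denominator) standard deviation, since the profile is the full site
population; zero variance returns zeros rather than NaN.

The healthy reference profile is the site-wise **median** of a 30-sample
panel's GC-corrected tracks, z-scaled afterwards (median-then-z); the
median makes the reference robust to outlier individuals. Whether scaling
precedes the median is not observable from the outputs either way at panel
sizes of 30; median-then-z was fixed and documented.

## Peaks and windows

Peaks are maximal circular runs of sites strictly above (below) baseline
0; zero-valued sites break runs; runs shorter than 5 bp are discarded. The
apex is the run's max-|z| site, ties to the smallest index. A sample peak
is *new* if its apex lies more than 20 bp (circular apex-to-apex distance)
from every reference apex; no minimum height is imposed beyond the run
definition. The genome is tiled into 255 windows of ⌈L/255⌉ = 65 bp (the
255th window has 59 bp — exact equal division is impossible); window
areas integrate the full z track (Σ max(z,0), Σ max(−z,0)) rather than
only called peaks, which is deterministic and dominated by the ≥5-bp runs
anyway, and window distances are plain Euclidean distances to the
reference profile.

## Variant calling

Candidates are per-site minor alleles from strand-split counts
(MAF = minor/depth). Filters: (1) ≥3 reads on each strand; (2) MAF ≥ 1%;
(3) site outside the repeat tracts 66–71, 303–311, 514–523, 12418–12425,
16184–16193 (inclusive); (4) C>A / G>T below 10% MAF removed as guanine
oxidation artifacts; (5) binomial tests at α = 0.001. Each filter is
evaluated on the raw counts, so the verdict is order-independent, and
failing calls are retained with reasons rather than dropped.

The two binomial tests are operationalized as: *rate* — upper tail
P(X ≥ alt | n = depth, p = p_err) with p_err the mean per-base error
implied by the site's Phred qualities; *quality* — upper tail on the
count of alt bases with Q ≥ 30 against a null fraction of 0.5 (alt calls
as likely low- as high-quality under error). Both are assumptions: the
filter names two binomial tests without defining either, and a
"compare-to-reference-fraction" variant is unusable in the pass-direction
required (with near-perfect reference qualities the test could never reach
significance). The null fraction and Q threshold are parameters of
`CallerParams`. In practice the quality test requires ≥10 high-quality
mutant reads at α = 0.001.

Origin classes: tumor_derived = in tumor, in neither paired control;
germline = in tumor and both controls; anything else somatic_unclassified
(never silently dropped). Copy number is 2 × mean mtDNA depth / mean
nuclear reference-gene depth; the nuclear depth is a user input, as the
reference gene is a protocol choice.

## Detection and tissue-of-origin models

The 1,029-entry feature vector has a fixed name order (profile
correlation, new-peak count, 255+255 window areas, 255 window distances,
median size, 4 end-base preferences, 256 motif proportions, MDS); missing
values are an error, not imputed. The four preferences are included by
default with a switch to exclude them, covering both readings of an
ambiguous assembly convention. mtDNA copy number is kept outside the
vector (appendable).

Forests use 500 trees and 6 features per split, seeded; tenfold CV is
stratified and seeded, shrinking to the minority-class size on small
cohorts (logged). The Youden cutoff is fixed on the out-of-fold training
scores, ties broken toward higher specificity (the conservative screening
choice). Validation scores come from the forest refit on the full training
cohort — CV estimates training performance only. AUC CIs use DeLong's
variance; sensitivity/specificity CIs are Clopper–Pearson. The
tissue-of-origin gate takes the smallest training-control cutoff reaching
the target specificity (99.5% default; unreachable targets fall back to
the max control score, logged), and the TOO forest refuses classes with
fewer than two samples. Leave-one-batch-out trains on all other batches
and evaluates per held-out batch, skipping single-class batches with a
warning; confounded labels show up as pooled-vs-LOBO AUC divergence.

## Simulator: what it emulates, and what it does not

The generator draws a light-strand cut site with probability ∝ (end-base
bias)^γ / protection, a fragment length from the region law of the cut
site, and accepts the implied second cut with probability ∝ its own
cleavage weight. This is the simplest model that produces, jointly:
protection-driven FSD peaks (sites inside protected loci are reachable
mostly by long fragments), region-specific size distributions, end-base
preference, and motif spectra.

Defaults (the fixed study conditions): 150,000 fragments/sample (~1,150×
mean depth, inside the reported capture-depth regime where profiles are
signal-dominated); a baseline landscape of 60 protected loci of 25–60 bp
(weight 8) shared by the whole cohort; healthy length laws of mean 128 bp
(sd 35) with region offsets D-loop 120 / rRNA 127 / mRNA 128 / tRNA 134;
end bias A 1.25, C 0.85, G 1.45, T 0.75 (the G/A-end excess of
ccf-mtDNA). Group effects: MT size shift −10 bp, two extra protected loci
(half-width 60, weight 15, placed in quiet zones of the baseline
landscape), end-bias exponent 0.85 (higher MDS); INF/BT sit between; each
cancer type adds its own loci and size shift so tissue-of-origin has a
recoverable signal. Spike-ins tag a Bernoulli fraction of covering
fragments, optionally re-drawn shorter around the variant site, with
configurable strand balance and base quality. Pileups add per-site
Bernoulli sequencing errors with Phred-consistent qualities.

Not emulated: read-level errors and quality recalibration, PCR/capture
bias beyond the GC covariate, nuclease biochemistry, batch effects on
features, circular (unfragmented) mtDNA molecules, and NUMT
contamination. Passing tests therefore demonstrate that the *pipeline*
recovers programmed structure of these kinds at realistic depth — not
that real cohorts will reach any particular AUC; published cohort-level
performance is outside what simulation can certify.

## Numerical and degenerate-input conventions

Ties at the median are short; constant tracks skip LOESS (identity) and
z-scale to zeros; empty regions, empty panels, zero depth, single-class
cohorts and sub-minimum classes raise errors rather than guessing;
downsampling is without replacement, exact in count, and seeded; all
randomness descends from explicit integer seeds (cohorts spawn per-sample
seeds below 2³¹ from the master seed).

## Problem sizes used in the shipped checks

The test suite runs the full cohort property checks at 100 MT + 100 HC
samples with a 30-sample reference panel at the default depth, 20
replicates for peak-recovery rates, 12 replicates for the mutant-size sign
test, 1,000 random tracks (L = 200) against the peak-calling brute-force
oracle, and 100 random spectra against the entropy oracle; examples use
smaller cohorts (10–30 samples, 30–60k fragments) to stay instant.
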