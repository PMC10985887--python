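# Methods

## The error model and the two-round likelihood test

A pileup column holds reads x₁…x_N with per-read error probabilities
e_i = 10^(−Q_i/10) derived from base qualities (floored at 10⁻⁴ so a
single extravagant quality cannot dominate a column). For a candidate
allele g with fraction θ_g, a read shows g with probability
(1−e_i)θ_g + (e_i/3)(1−θ_g); reads showing any other allele enter the
likelihood through the complementary term. This reduces the test for
each allele to a one-dimensional profile likelihood, maximised by
bounded golden-section/Brent search on [0, 1] (tolerance 10⁻⁸; an
exhaustive grid oracle validates the optimizer in the tests).

Because the null θ_g = 0 lies on the boundary of the parameter space,
t_g = −2(ℓ₀ − ℓ₁) is referred to the 50:50 mixture ½χ²₀ + ½χ²₁:
P_g = ½·(1 − F_χ²₁(t_g)) for t_g > 0 and P_g = 1 at t_g = 0. A flag
(`boundary_mix=False`) falls back to plain χ²₁.

**Calibration and its regime of validity.** Monte-Carlo null columns
(reads drawn purely from the error model) show the mixture p-value is
well calibrated when the expected error count per column
λ = N·ē/3 is large. The packaged calibration check uses N = 20,000
reads (the deep end of mitochondrial WGS coverage) with integer Phred
qualities uniform on 13–23, giving λ ≈ 136; there the empirical
rejection rate matches α = 10⁻² and 10⁻³ within Monte-Carlo error. At
smaller λ (tens and below) the test becomes measurably *conservative* —
the discrete, skewed null puts slightly more than half its mass at
t = 0, so rejection runs a few percent below nominal at the 10⁻² tail —
never anticonservative. Exact analytic computation of the
homogeneous-error case and an independent scipy optimizer cross-check
confirm this is the statistic's finite-sample behaviour, not an
implementation artifact.

Round one is applied per strand; an allele is retained only when
P_g ≤ α on both strands (α = 10⁻³ by default, the level at which P_g is
a good estimate of the allele's error rate). Retained alleles keep
their bases in the consensus step; everything else becomes 'N'.

## Read families, consensus sequences, PCR error

Reads are grouped into families by the exact key (mate-1 position,
mate-2 position, mate-1 CIGAR, mate-2 CIGAR): families are duplicate
templates, and that redundancy is the caller's signal, so
duplicate-flagged reads are grouped like any other. Unpaired reads form
singleton families. Within a family the consensus base is the majority
among members whose allele survived round one (ties: summed quality,
then base order); members carrying *different* retained alleles split
the family into several consensus sequences, one per allele group.

The consensus base error combines:

* P_c(g) = 3^(1−s) · Π e_j over the s supporting members — the chance
  that all copies misread the same base;
* P_pcr(g) ≈ n · e_pcr², with e_pcr = 1 − (1 − per-cycle error)^(2^m−1),
  defaults m = 12 cycles and per-cycle error 10⁻⁶ (PCR fidelity range
  10⁻⁷–10⁻⁵), and n the number of DNA templates behind the consensus —
  by default the family's fragment count. (An alternative reading, n =
  consensus sequences covering the position, is exposed as
  `PcrModel(n_mode="column")`; at 10,000× it drives P_pcr toward 0.1
  and would erase exactly the sub-1% sensitivity the method targets,
  so it is not the default.)

Q(g) = −10·log₁₀(P_c + P_pcr), rounded and clamped to [0, 93]
(Phred+33 encodable). Round two repeats the per-strand likelihood test
with the consensus bases as observations and e = 10^(−Q/10); VAF is the
supporting consensus count over the consensus sequences covering the
position. Indels are not tested against the error model (the simulator
injects no indel errors and real indel errors are rare at template
level); each position's most-supported indel allele is emitted when at
least `min_indel_support` (default 2) consensus sequences carry it,
ties broken on the VCF-style allele strings so runs are reproducible.

For performance the caller consumes a column-oriented read block;
singleton families with all-matching CIGARs take a fully vectorised
path, and only multi-fragment families, mate-overlapping fragments and
indel-bearing reads go through the general consensus machinery. Both
paths implement the same rules and the tests assert they produce
identical callsets.

## Circular coordinates

Segments of the circle are described as (start, end]: size = end −
start when end > start, else (L − start) + end. The two printed sizes
for the worked D-loop insertion are mutually inconsistent (541 counts
start-exclusive, 16,027 counts both-exclusive); the toolkit fixes the
start-exclusive/end-inclusive convention — under which the two arcs of
any chord partition the circle — and reports the naive figure as the
strictly-between count (16,028 − 1). Membership tests, breakpoint
distances and trinucleotide contexts all wrap at the origin.

## NUMT detection

Junction reads are soft-clipped records whose clip (≥ 20 bp) aligns to
the other genome (edlib infix alignment, ≥ 90% identity, and strictly
better than to the read's own genome — this keeps origin-wrapping
mitochondrial reads, whose clips align back to mtDNA, out of the
junction set). Orientation class follows the alignment geometry:
clusters defining the segment start also pin the left nuclear
breakpoint, end-side clusters the right one. Clustering is
single-linkage within 20 bp on the nuclear genome with modal
coordinates as breakpoints (ties toward the smaller coordinate) and a
minimum of 2 junction reads per orientation. Candidates lacking either
orientation, or whose clip alignments disagree in strand, are
discarded — the mechanism that rejects chimeric-insertion false
positives.

Zygosity is the fraction of supportive reads over mean autosomal
coverage (homozygous at ≥ 0.75). Since a junction read needs ≥ 20 bp
anchored on each side of the breakpoint, the pipeline scales the
per-side junction count by read_len/(read_len − 2·min_clip) before
dividing, so a homozygous insertion at 30× yields a fraction near 1.

Assembly is greedy overlap-layout-consensus over the junction reads'
mitochondrial portions, the mitochondrial mates of discordant pairs,
and reads aligned within the candidate segment (clips that align better
to the nuclear genome are trimmed first): overlaps are seeded with
exact 16-mers at several offsets, require ≥ 20 bp and ≥ 95% identity,
longest overlap merges first, and a final per-column majority vote
polishes each contig. Every assembled island is realigned (gapped, both
strands) to the origin-unrolled mitochondrial sequence; islands below
90% identity, on the reverse strand, or outside the junction-derived
segment (± 30 bp) are discarded, and a candidate with no confirming
island is rejected. Aligned mismatches inside the segment, pooled over
islands, become NUMT-FP records. Inserted segments longer than the
fragment span may assemble only partially; the call is then flagged
unassembled and the copy-number filter applies its VAF criterion alone
in that segment.

Tumor/normal pairs are matched by nuclear insertion position within
200 bp: shared → germline, tumor-only → somatic, normal-only → loss.

## Copy number and filters

mtCN = (mt coverage / mean autosomal coverage) × (purity·ploidy +
(1−purity)·2); normal samples use purity 1, ploidy 2 (factor 2).
Coverage means run over all positions including zero-depth ones. The
NUMT-FP filter removes a call inside an inserted segment iff it matches
an identified mismatch and (VAF − threshold)/threshold < 1 — the
difference is signed, so calls far above threshold always survive; the
threshold is 1/(1+mtCN) or 2/(2+mtCN) by zygosity. The 1/mtCN floor
removes VAF < 1/mtCN strictly, retaining the boundary. Both filters are
idempotent and conserve |input| = |kept| + |removed|, with every
removal logged with its reason. For tumor samples the purity/ploidy-
adjusted mtCN is used (a flag allows the raw ratio).

## The synthetic-data generator

The generator reproduces the evaluation design: 20 SNVs + 5 insertions
+ 5 deletions (1–5 bp, uniform — "short") planted uniformly outside the
artifact blacklist (300–317, 16,180–16,193, 3,107) with ≥ 12 bp
spacing; seven VAFs (0.001–0.5) × three depths (5,000–20,000×); paired
150-bp reads with fragment length N(400, 60) truncated below at the
read length; per-base integer Phred qualities N(30, 3) clipped to
[13, 40] and substitution errors injected at the quality-implied rate.
The mutated template is sequenced at vaf×depth and the wild type at the
remainder, so VAF 0.001 at 5,000× gives the mutated molecule 5×.
Alignments are emitted directly from the known read origins (exact
coordinates and CIGARs through the planted indels), so no external
aligner runs; FASTQ and SAM/BAM output are available for routing
through a real aligner externally.

What the generator does *not* emulate: PCR duplication (families larger
than one fragment arise only by coordinate coincidence), indel
sequencing errors, strand-specific error profiles, mapping ambiguity
from reference NUMTs (the pipeline assumes that preprocessing removed
reads mapping to both genomes), and circular fragment sampling — the
template is linear, as in the original simulation protocol, so
reverse-strand coverage thins within ~250 bp of the template ends and a
variant planted there can fail the both-strand admission rule. Passing
tests therefore demonstrate correctness of the statistical machinery
and coordinate handling, not robustness to alignment artifacts in real
data.

The NUMT generator plants a forward-orientation mtDNA segment (circular
(start, end], optionally spanning the origin, optionally carrying
mismatches) into a random nuclear contig at hom/het dosage and emits
the records an aligner would produce against the insertion-free
reference: breakpoint-crossing reads soft-clipped on the side with the
shorter anchor, interior reads mapped to the mitochondrial contig
(split at the origin when they wrap), cross-genome pairs flagged
discordant. Inverted (reverse-strand) insertions are not simulated.

## Benchmarks and problem sizes

The packaged recovery benchmark runs one replicate per cell at 10,000×
for VAF ∈ {0.005, 0.05, 0.5} (about half a million read pairs per
dataset) — deep enough that the admission and calibration behaviour
match the study regime while a full run stays within minutes on one
CPU; the full 21-cell grid is available through
`mitovar bench`/`run_benchmark_grid`. The NUMT benchmark uses 20
seeded fixtures, segment sizes 300–700 bp at 30× locus coverage, five
spanning the origin and five carrying three planted mismatches each.
Pearson correlation between planted and called VAFs is computed over
variants with VAF ≥ 0.05 pooled across cells (within one cell the
planted VAF is constant, so a correlation is undefined).

## Known limitations

* Sensitivity at VAF 0.001 requires the full 20,000× depth and even
  then sits well below 1; this mirrors the method's published regime
  (integration with a conventional caller above 1% VAF via
  `merge_callsets` is the intended deployment).
* The boundary-mixture p-value is conservative at moderate expected
  error counts (see above); detection thresholds are therefore slightly
  strict, never lax.
* The NUMT caller requires both junction orientations; insertions whose
  one flank falls in unalignable nuclear sequence are invisible, as are
  inverted or heavily rearranged insertions.
* Indel calling ranks by support only; no indel error model is fitted.
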