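# Methods

`gcmosaic` maps the compositional organization of a genome from its sequence
alone. The underlying model is the isochore picture: a genome is a mosaic of
long, compositionally fairly homogeneous segments, and the segments cluster
into a small number of *families* characterized by their average GC level.
The package measures that structure in four stages — fixed-window GC
profiling, greedy merging into homogeneous segments, pooling of segments
into a GC-binned weight distribution whose modes define families, and (for
coding sequences) codon-position GC analysis with major-axis regression —
plus a generator of synthetic genomes and ortholog sets with known truth.

## Windowing and segmentation

Chromosomes are cut into non-overlapping windows of fixed size, 25 kb by
default. That size is a compromise: small enough that compact unicellular
chromosomes (often only a few Mb) yield enough windows, large enough that
the per-window binomial sampling noise in GC is small
(√(p(1−p)/25000)·100 ≈ 0.3 %-GC at p = 0.5). The trailing remainder of a
chromosome shorter than one window is discarded rather than padded or
merged, so every window has identical length and a segment's GC is the
plain mean of its member windows. Window GC is computed over unambiguous
bases only — N's and other IUPAC ambiguity codes are excluded from both
numerator and denominator — and a window with fewer than
`min_valid_fraction` (default 0.5) unambiguous bases is flagged invalid.

Segmentation is a greedy left-to-right merge: the first valid window opens a
segment, and each subsequent valid window joins the running segment iff its
GC differs from the running segment mean by at most `merge_threshold`
(default 1.5 %-GC), else it opens a new segment. Invalid windows always
close the running segment, so segments never bridge assembly gaps. The rule
is deliberately simple and online; it is the classical threshold-based
approach for isochore mapping, and like all such rules it tends to
overestimate homogeneity because the dispersion of window GC shrinks as
windows (or segments) grow. Two consequences are worth knowing:

* the segmentation of any prefix of a chromosome is a prefix of the full
  segmentation (no lookahead), and raising the threshold can only reduce
  the number of segments;
* windows whose GC happens to sit more than the threshold from the running
  mean break off as short "breakaway" segments, which accumulate on both
  flanks of every real family in the segment-GC distribution (see family
  detection below).

The exact semantics are pinned by an exhaustive test against two
independently written brute-force implementations over every window
sequence of length ≤ 12 on four GC levels.

Segment names follow the convention *chromosome number* + *genus initial* +
*species-epithet initial* + *running index* ("3Sc2"), with no separators.
Output tables use 1-based inclusive coordinates; everything internal is
0-based half-open.

`heterogeneity` is the sample standard deviation of valid-window GC — a
scale-dependent quantity, only comparable at a fixed window size. The
window-size comparison utility reruns the whole pipeline at several sizes
(typically 25 kb and 100 kb) to show the compositional pattern is not a
windowing artifact; heterogeneity at the smaller size is expected to be
only slightly larger when the genome's compositional domains are truly
large. This comparison is only meaningful when domains are long relative to
the largest window — windows straddling a family boundary take intermediate
GC values and blur the profile — so the robustness fixtures use
megabase-scale domains.

## Binned profiles and family detection

Each segment contributes its full length (its *weight* in bp) to the 0.5
%-GC bin containing its GC; bins are left-closed and anchored at 0.0 so
binning is deterministic with no offset choice. The resulting "distribution
by weight" is the quantity plotted in compositional-pattern figures.

Families were classically read off such histograms by eye. The reproducible
surrogate implemented here: smooth the profile with a centered moving
average (`smooth_bins` = 3), take local maxima of the smoothed profile as
candidate families, and cut at the local minima between adjacent maxima.
Two filters encode what a human reader ignores:

* maxima shorter than `min_peak_fraction` (default 0.08) of the tallest
  peak, or with topographic prominence below 20% of their own height, are
  not candidates — this absorbs the breakaway-segment shoulders the greedy
  rule produces, which otherwise appear as spurious satellite modes holding
  a few percent of the weight ~2 %-GC off every real family;
* detected families holding less than `min_family_fraction` (default 0.02)
  of the total weight are merged into the nearest heavier family (nearest
  by mean GC, ties to the heavier side).

All parameters are exposed; with both filters set to zero the method
degenerates to pure peak/valley partitioning. Family mean GC is the
weight-weighted mean of member-bin midpoints (what a histogram supports); a
switch recomputes it from raw member segments, which also yields the exact
member-GC span. Relative amounts are percentages of the total binned
weight, so they sum to 100.

Families are labelled against the vertebrate isochore scheme with
cutpoints L1/L2 = 37, L2/H1 = 41, H1/H2 = 46, H2/H3 = 53 %-GC, chosen to
bracket the classical vertebrate family averages (36.2 / 39.1 / 43.3 /
48.3 / 54.8). Genomes far outside that range get "extreme-low" (< 30) or
"extreme-high" (≥ 57.5); those bounds were chosen so that the known extreme
genomes (a 19.4 %-GC malaria parasite, a 59.4 %-GC green picoalga, a
28.4 %-GC slime mold) fall outside L1–H3 while a 55.4 %-GC red alga remains
H3. Intervals are left-closed, making classification exhaustive and
exclusive. All cutpoints are configurable.

## Assembly statistics and CDS cleanup

For fragmented assemblies, `scaffold_stats` partitions total length at a
scaffold-size cutoff (default 100 kb, *inclusive*: a record of exactly
100,000 bases counts as large — the two classes must be exhaustive and the
boundary assignment is documented rather than implicit). Window analysis of
fragmented genomes is normally restricted to the large class.

`clean_cds` applies the standard cleanup before codon analysis, in order:
case-insensitive keyword exclusion on the description (partial, putative,
synthetic construct, predicted, not experimental, hypothetical protein,
r-RNA, t-RNA, ribosomal, mitochondrial); length divisible by 3; ATG start;
TAA/TAG/TGA terminal stop; no internal stop; and exact-duplicate removal
keeping the first occurrence. Every record lands in exactly one of
accepted/rejected, with an enumerated rejection reason. The standard
nuclear code is the default; alternative codes (e.g. ciliate stop
reassignment) are a parameter. Exact-duplicate removal is a deliberate,
conservative choice — similarity-threshold redundancy removal differs
between cleanup tools and is not claimed here.

## Codon-position GC and major-axis regression

GC1/GC2/GC3 are per-position GC percentages over the codons of an accepted
CDS; any codon containing an ambiguity code is skipped at all three
positions, so gc = (gc1 + gc2 + gc3)/3 holds exactly. The terminal stop
codon is included by default (the CDS is defined through its stop); a
switch excludes it. GC3 here is all third positions, not synonymous-only
sites.

Relationships between positions, and between orthologs of two species, are
summarized with *major-axis* regression: the first principal axis of the
raw 2×2 covariance matrix, i.e. the line minimizing summed squared
perpendicular distances. This is the textbook symmetric fit when both
variables share units and error structure, as two GC percentages do;
ordinary least squares would build in an arbitrary choice of response
variable and bias the slope toward zero. Reduced major axis
(slope = sign(cov)·sd(y)/sd(x)) is available as an option. The closed form
is used (largest eigenvalue λ of the covariance; slope = (λ − s²ₓ)/sₓᵧ),
which guarantees the slope sign matches the covariance sign and that
swapping the variables maps the slope to its reciprocal. A fit is refused
(and reported as absent in the fit matrix) when either variable is
constant. R is the plain Pearson correlation; histogram overlap between
two species' distributions is the summed per-bin minimum of the normalized
histograms on a shared 0–100 axis (2.5-point bins by default).

Ortholog pairing is an *input* (a two-column table); the package does not
infer orthology.

## Synthetic data: what it emulates and what it does not

`simulate_genome` builds each chromosome as a concatenation of segments:
family drawn by genome proportion, length drawn from a per-family Gaussian
(default mean 75 kb, sd 40 kb — the tens-of-kb-to-~100-kb regime of
compositional domains), truncated at one window and rounded to whole
windows so true boundaries sit exactly on the 25-kb analysis grid and
boundary recovery can be scored exactly. Each window's target GC is the
family mean plus Gaussian jitter (`window_noise_sd`, default 1.0 %-GC — the
order of within-domain variation at the 25-kb scale); bases are i.i.d.
given the target, split evenly between G/C and A/T (a skew switch exists,
default 0). The truth table lists every generated segment with its family
and realized target mean.

The base model is deliberately minimal: no dinucleotide structure, repeats,
coding/noncoding mosaic, or evolutionary process. That is adequate because
every statistic the pipeline computes is a function of mononucleotide GC
alone; passing recovery tests therefore demonstrates correctness of the
method on genomes whose composition varies the way the model assumes, not
robustness to repeat content or assembly artifacts of real genomes.

`simulate_orthologs` draws per-gene latent (GC1, GC2, GC3) targets for
species A from a trivariate Gaussian (configurable means/sds, one common
between-position correlation, clipped to (1, 99)); species B reuses the
same targets with GC3 shifted by a constant. Sequences realize the targets
from *shared* per-base uniform draws, so a zero shift yields byte-identical
sequences and the shift isolates the third-position effect; the first codon
is forced to ATG and the last to a stop. Codons that would realize as
internal stops are rewritten GC-neutrally at the third position (TAA→TAT,
TAG→TAC, TGA→TGT), so every emitted CDS passes cleanup with GC3 exactly
unbiased. Realization noise at the default 400 codons/gene is ≈2.5 %-GC per
position, which slightly attenuates latent correlations (a latent r = 0.5
between GC1 and GC2 is recovered as ≈0.47 in fits at n = 4000).

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale problem sizes chosen to make the
statistical tolerances meaningful: family recovery uses 100 seeded 10-Mb
genomes (8 × 1.25-Mb chromosomes, 1–3 families ≥ 4 %-GC apart, noise sd
1.0); the window-size comparison uses 48-Mb genomes with 1.5-Mb domains;
regression recovery uses 5,000 points; ortholog sets use 2,000–4,000 genes
of 400 codons. Exhaustive segmentation-oracle checks cover all 4-level
window sequences to length 12 (≈22 million sequences). Floating-point ties:
bin edges are left-closed; the merge comparison is ≤ (a window exactly at
threshold distance joins); family-merge ties go to the heavier neighbour;
all reported one-decimal values are rounded only at the reporting layer.

## Known limitations

* The greedy rule is a documented stand-in for classical isochore-mapping
  methodology, whose exact algorithm is not restated in the compositional
  literature it descends from; likelihood or change-point segmentation is
  out of scope.
* Family detection assumes modes separated by ≥ ~4 %-GC at the default
  smoothing; closer families merge.
* Very small families (≲ 2% of the genome, or with peaks ≲ 8% of the main
  peak) are absorbed by the default filters; lower the thresholds to see
  them.
* `scaffold_stats` percentages recomputed from *rounded* megabase totals
  can differ from published one-decimal percentages computed on unrounded
  data by one unit in the last digit.
* Whole-genome analyses of real assemblies require the genome FASTA as
  input; no download functionality is included.
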