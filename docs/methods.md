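# Methods

This note records the models behind each stage of the package, the parameters
that matter, the numerical choices made where the design was open, and the
known limits of what the synthetic-data tests demonstrate.

## K-mer pangenome index

The index maps each canonical k-mer to a presence bit-vector over the panel.
Canonical form is the lexicographic minimum of a k-mer and its reverse
complement; any consistent canonicalization yields identical set relations,
so this choice is free. Windows containing a non-ACGT base are skipped.
The index stores presence only — multiplicities carry no information for the
Jaccard, uniqueness, and collector's-curve analyses built on it.

* `k` (default 31, odd): odd k rules out reverse-complement palindromes, so
  canonical forms are unambiguous. 31 is the standard choice for assembly
  scale indexing — long enough that random collisions are negligible
  (4^31 ≈ 4.6×10^18), short enough to be robust to sequence error in
  assemblies.
* `exclude_seqs` (regex on sequence names): drops sequences (e.g. sex
  chromosomes) before indexing. A panel mixing XX and XY genomes clusters by
  sex chromosome content rather than ancestry; an autosome-only index avoids
  that artifact.
* Unique-k-mer localization rescans the source genome and increments the
  1 Mb bin at each occurrence's leftmost base. Because the k-mers originate
  from that genome, exact lookup is lossless — no realignment step is needed
  — and multi-occurrence k-mers count at every site.
* Hierarchical clustering is average linkage on the distance 1 − J. The
  dendrogram is ultrametric with node height = merge distance / 2, so two
  genomes with similarity J form a cherry with leaf branches (1 − J)/2.
  SciPy's linkage is deterministic on its input, so ties break by input
  order.

The in-memory dict index is intended for panels up to tens of megabases per
genome (the scale of the test suite); it is not a disk-backed gigabase-panel
indexer.

## Aligned runs of homozygosity

Input is a PAF of pairwise alignments between the two haplotypes of one
diploid assembly (secondary alignments, `tp:A:S`, are dropped first). Long
collinear alignments are frequently split by the aligner; records sharing a
query/target pair and strand are therefore chained when both the target gap
and the query gap lie in [0, `max_gap`] and agree within `gap_diff_tol`
(diagonal consistency; on the minus strand the query runs backwards).

* `max_gap` = 100 kb, `gap_diff_tol` = 20 kb: generous enough to heal
  aligner breaks, far below the multi-megabase scale of real homozygous
  runs. Both are flags; merging is applied globally, with `min_merged_span`
  available to restrict chaining to long spans only.
* Merged divergence is the alignment-length-weighted mean of per-record
  divergence, ignoring unaligned gap bases (conservative: gaps are not
  counted as divergent).
* `max_divergence_delta` (off by default) refuses to chain records whose
  divergence estimates differ by more than the given amount. Merging exists
  to heal artificial breaks; it should not fuse a homozygous run with
  flanking diverged sequence into one diluted record. The synthetic truth
  alignment emits exactly adjacent segments (gap 0), where this guard is the
  only thing separating planted runs from their 2%-divergent background;
  real aligner splits leave gaps and are unaffected.
* Classification keeps merged records with target span **strictly greater**
  than `min_length` (50 kb) and divergence **strictly less** than
  `max_divergence` (0.01). Per-record divergence is the `de:f` tag when
  present, else 1 − matches/block. Overlapping survivors are resolved by
  keeping the longer interval and trimming the shorter (dropped when fully
  contained); trims are logged.
* Coverage summaries report Σ length(AROH ≥ t) / assembly length per
  threshold t, non-increasing in t by construction.

AROH coordinates are reported on the target haplotype (haplotype 1 by
convention). The pipeline consumes alignments; it does not run the aligner.
Note that an aligner given a synthetic diploid with uniform 2% background
divergence tends to produce one monolithic alignment rather than splitting
at segment boundaries, so recovery testing uses the simulator's exact truth
alignment.

## Recombination landscape

Markers are F2 genotypes coded AA/AB/BB with the A allele from parent 1.
QC drops, in order: markers with segregation-distortion p below the family
threshold (χ² goodness of fit against 1:2:1, df = 2; defaults 1e-5, with
1e-17 appropriate for families with known strong distortion), markers with
missing fraction strictly above 0.35, and markers whose genotype vector
duplicates an earlier retained marker on the same chromosome (complete
linkage disequilibrium; missing entries match anything, and the duplicate
group's representative is the first member). The QC report accounts for
every input marker.

The Marey map is fitted per chromosome by LOESS of genetic on physical
position with span 0.25 (fraction of points; scale-invariant). Degree 1 with
tricube weights is the default (statsmodels LOWESS); a local-polynomial
degree-2 path is provided. Duplicate physical positions are collapsed to
their mean genetic position first; at least 10 distinct positions are
required.

Before differentiation the fitted sequence is projected onto the nearest
monotone sequence (isotonic regression). A Marey map is physically
non-decreasing; raw LOESS can wiggle, and taking |derivative| of those
wiggles would fold artifactual negative slopes into spurious positive rates.
`monotonic=False` reproduces the raw computation for comparison. A side
benefit is exact conservation: Σ rate_i·Δp_i equals the fitted map length by
construction on a monotone fit.

Rates are attached to inter-marker midpoints (the two-point derivative's
natural location); regions of suppressed recombination are maximal runs of
midpoints with rate < 0.5 cM/Mb spanning ≥ 40 Mb. Linkage-map construction
itself (grouping, ordering, double-crossover pruning) is out of scope; the
module consumes genetic positions from an existing map or from the
simulator's truth. Manual exclusions (e.g. known duplicated/inverted
regions) are supported by filtering the marker table before input rather
than by hard-coded coordinates.

## Bulk segregant analysis

Per SNP, G = 2 Σ o_ij ln(o_ij/e_ij) over the 2×2 table of (bulk × allele)
read counts, with expectations from the margins under independence; zero
cells contribute nothing and a table with a zero margin scores 0 (no
information). G is symmetric under bulk and allele swaps and zero exactly
when the bulks' allele proportions are equal. SNPs with depth < 10 in either
bulk are removed first.

Smoothing is the unweighted mean of SNP G values within ±1 Mb of each center
on a 10 kb grid; empty windows are missing (NaN). Window width follows the
convention of G-statistic BSA tools; both width and step are flags.

Significance thresholds are per-window percentiles (default 99.5) of
simulated null profiles. Two null recipes are provided:

* **Per-SNP redraw** (`n_plants=None`): each SNP's counts are redrawn
  binomially at fixed null frequencies (default 0.5/0.5), preserving
  observed depths. This is the textbook recipe but ignores that both bulks
  are finite pools of plants.
* **Design-matched bootstrap** (`n_plants` given; pipeline default): each
  replicate simulates whole bulks of informative gametes (backcross: one per
  plant; F2: two) with Poisson crossovers at `recomb_rate` cM/Mb, then draws
  reads at the simulated pool frequencies. A 50-gamete pool's allele
  frequency drifts with standard deviation ≈ 0.07 and is correlated over
  megabases, which inflates window-level G far beyond the per-SNP-redraw
  null; thresholds that ignore it are anticonservative. The bootstrap
  reproduces the drift and its along-chromosome correlation and is
  calibrated by construction (measured null window exceedance ≈ 0.005 at the
  99.5th percentile).

Allele frequencies are expressed in the segregating-gamete coding: the
frequency of the selected allele among a bulk's informative (F1-derived)
gametes, so the selected bulk sits at 1.0 at the causal locus and an
unselected bulk at the Mendelian 0.5. Null frequencies are fully overridable
(`null_freqs=`) for read-level codings.

Significant intervals are maximal runs of windows above threshold, bridged
across single-window gaps. Cross-reference consensus projects each
reference's top interval through its PAF chain onto a user-chosen anchor
(linear interpolation within blocks; minus-strand blocks reverse
orientation; the result is the minimal covering interval, with unaligned
overhang reported), then intersects the projections; when the intersection
is empty the deepest point of overlap wins (majority rule), and unmappable
references are recorded. Anchoring on one reference keeps consensus
coordinates well-defined without a graph. Diagnostic SNPs inside the
consensus interval pass on depth ≥ 10 in both bulks and per-bulk observed
frequency within `tol` (default 0.1) of the design expectation, ranked by
depth.

## Synthetic-data generators

All generators are bit-reproducible given (config, seed) and emit a
`TruthSet` (BED + YAML sidecar) with the planted parameters.

* **Diploid pairs**: haplotype 2 is haplotype 1 with i.i.d. substitutions at
  `background_divergence` (default 0.02) outside planted segments, zero
  inside. Indels are off by default so coordinate truth is exact; a simple
  single-base indel rate is available. The exact truth alignment counts real
  mismatches per segment.
* **Panels**: genomes are concatenations of `n_blocks` blocks of
  `block_length` bp, drawn with replacement from a shared pool or generated
  private at `private_rate`; the truth records every block's source.
* **F2 populations**: per gamete, crossover count ~ Poisson(map length/100)
  with positions i.i.d. from the crossover density over relative physical
  position — no interference, the simplest defensible null. Presets:
  uniform, and "periphery" ∝ (2x−1)² for the strongly telomere-biased
  landscapes typical of large plant chromosomes. Distortion is viability
  selection after gamete union (survival 1 − s for one homozygote class, BB
  by default), implemented by rejection sampling on the distortion
  chromosome only — valid because the other chromosomes are independent of
  survival. Monomorphic regions are emitted as a single genotype class;
  missingness is i.i.d.
* **Bulks**: informative gametes carry Poisson crossovers at a uniform
  cM/Mb rate, so the distance-to-recombinant-fraction map is Haldane's
  r(d) = (1 − e^(−2·d_M))/2, which is linear in map distance for small d.
  The selected bulk is conditioned to carry the selected allele at
  `causal_pos` in every informative gamete (full penetrance); the unselected
  bulk is at Mendelian expectation. Depths are Poisson(`mean_depth`), allele
  counts binomial at the pool frequency. Defaults (30 Mb chromosome, 1500
  SNPs, 50 plants/bulk, depth 40, 1 cM/Mb, backcross) describe a realistic
  array-scale BSA experiment.

What the generators do **not** emulate: sequencing reads and their error
models, structural variation beyond planted identity segments, crossover
interference, gene conversion, and realistic marker ascertainment. Passing
tests therefore demonstrate correctness of the algorithms under the stated
models, not robustness to every artifact of real data.

## Problem sizes and calibration checks

The test suite and acceptance script run at desk scale by choice: random
k-mer panels up to 5 genomes × 10 kb (where brute-force set computation is
exact and fast), 10 Mb diploid chromosomes with five planted runs of
0.1–2 Mb, 500 markers × 300 individuals for the landscape recovery, and
300–1500 SNP BSA scans. The BSA null calibration uses 2000 replicate null
experiments: null exceedances arrive in whole-chromosome clusters (the
finite gamete pool's frequency deviation is nearly constant along a 10 Mb
chromosome at 1 cM/Mb), so a few hundred replicates cannot pin the
window-level rate.

## Known limitations

* **BSA localization is bounded by the bulk's crossover spacing.** With N
  informative gametes at rate ρ cM/Mb, the nearest crossover flanking the
  causal locus is exponentially distributed with mean 100/(N·ρ) Mb per side
  (≈ 2 Mb for a 50-gamete backcross bulk at 1 cM/Mb). Inside that plateau
  the selected bulk's allele frequency is exactly 1 and no read depth can
  distinguish positions, so the top smoothed-G window lands within 500 kb of
  the causal position in only ~25–35% of replicates at these settings
  (median error ~0.8 Mb). Consensus intervals of ~2 Mb are the realistic
  resolution; sub-megabase localization requires larger bulks, denser maps,
  or recombinant screening.
* The k-mer index is in-memory; gigabase panels need a disk-backed tool.
* AROH detection resolves at alignment-record granularity; a single
  monolithic alignment hides internal homozygous runs.
* Cross-assembly genotyping of diagnostic SNPs (validating candidates
  against a large assembly collection) is outside the package; the panel
  operation implements the depth/frequency criteria only.
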