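# panhap

Pangenome-haplotype diagnostics for panels of phased plant genome assemblies,
built around the analyses used to characterize diversity, homozygosity,
recombination, and trait loci in *Cannabis sativa*, but applicable to any
diploid plant with phased chromosome-level assemblies. The package is aimed at
researchers who have a panel of assemblies (plus, optionally, F2 linkage
markers and bulk-segregant sequencing data) and want reproducible, testable
versions of four analyses that are usually run as one-off scripts:

1. **K-mer pangenome index** — a presence/absence table of canonical k-mers
   (default k = 31) over a genome panel. A k-mer's canonical form is
   min(kmer, revcomp(kmer)); pairwise similarity is the Jaccard index
   J(a,b) = |K_a ∩ K_b| / |K_a ∪ K_b| over canonical k-mer sets, clustered
   with average linkage on 1 − J. Unique k-mers (present in exactly one
   genome) flag haplotypes unrepresented elsewhere in the panel; their
   occurrence counts in 1 Mb bins localize those haplotypes, and collector's
   curves of cumulative distinct k-mers show how well the germplasm is
   sampled.
2. **Aligned runs of homozygosity (AROH)** — from a pairwise alignment of the
   two haplotypes of one diploid assembly (PAF, minimap2 dialect).
   Artificially split collinear alignments are chained back together, and an
   alignment is classified as an AROH when its span exceeds 50 kb and its
   per-base divergence (the `de:f` tag, or 1 − matches/block) is below 0.01.
   Coverage summaries report the genome fraction in AROH of at least each
   length threshold — an alignment-based view of inbreeding.
3. **Recombination landscape** — F2 markers (AA/AB/BB with A from parent 1)
   are filtered for segregation distortion against 1:2:1 (χ², df = 2),
   missingness > 0.35, and duplicate genotype vectors; the Marey map (cM vs
   bp) is fitted per chromosome by LOESS with span 0.25, monotonized, and the
   recombination rate is |Δ fitted cM| / Δ Mb between successive markers.
   Long runs below 0.5 cM/Mb spanning ≥ 40 Mb are reported as suppressed
   regions.
4. **Bulk segregant analysis (BSA)** — per-SNP G = 2 Σ o·ln(o/e) on the 2×2
   bulk×allele read-count table (SNPs below depth 10 in either bulk are
   dropped), averaged in 2 Mb windows every 10 kb, with per-window
   significance thresholds from simulating the null design (including
   finite-bulk allele-frequency drift). Peak intervals from scans against
   different reference assemblies are projected through pairwise alignment
   chains onto a common anchor and intersected into a consensus interval —
   mitigating single-reference bias — and diagnostic SNPs are selected by
   depth and expected-frequency concordance.

A fifth module, `panhap.simulate`, generates every input the pipeline
consumes — diploid haplotype pairs with planted identical segments, block
panels, F2 genotype matrices under a chosen crossover-density landscape, and
bulk allele counts around a planted causal locus — each with a serialized
`TruthSet`, so all stages are validated against known ground truth.

## Worked example

```python
from panhap import build_index, unique_kmers, jaccard_matrix, collectors_curve
from panhap.simulate import DiploidSim, simulate_diploid, diploid_truth_alignment
from panhap.aroh import merge_collinear, classify_aroh, coverage_by_min_length

idx = build_index({"cultivar_A": "ACGTAC", "cultivar_B": "ACGTTT"}, k=3)
print("distinct canonical 3-mers:", len(idx))
print("unique to A:", sorted(unique_kmers(idx, "cultivar_A")))
print("unique to B:", sorted(unique_kmers(idx, "cultivar_B")))
print("Jaccard:", jaccard_matrix(idx).values[0, 1])
(curve,) = collectors_curve(idx, orderings=[["cultivar_A", "cultivar_B"]])
print("collector's curve:", curve.cumulative)
```

```
distinct canonical 3-mers: 4
unique to A: ['GTA']
unique to B: ['AAA', 'AAC']
Jaccard: 0.25
collector's curve: [2, 4]
```

The two six-base genomes share one canonical 3-mer (`ACG`) out of four, so
J = 1/4; adding the second genome to the index raises the distinct k-mer
count from 2 to 4. The same set algebra drives the 31-mer analyses at genome
scale.

```python
cfg = DiploidSim(
    chrom_lengths={"chr1": 5_000_000},
    background_divergence=0.02,            # 2% substitutions between haplotypes
    roh_segments=[("chr1", 1_000_000, 2_500_000)],  # planted identical segment
    seed=7,
)
hap1, hap2, truth = simulate_diploid(cfg)
records = diploid_truth_alignment(hap1, hap2, truth)
aroh = classify_aroh(merge_collinear(records, max_divergence_delta=0.005))
for iv in aroh:
    print(f"AROH {iv.chrom}:{iv.start}-{iv.end}  divergence={iv.divergence:.4f}")
print(coverage_by_min_length(aroh, 5_000_000, thresholds=[50_000, 1_000_000]).table.to_string(index=False))
```

```
AROH chr1:1000000-2500000  divergence=0.0000
 threshold  covered_bp  proportion
     50000     1500000         0.3
   1000000     1500000         0.3
```

The planted 1.5 Mb identical segment is recovered exactly — it is the only
alignment longer than 50 kb with divergence below 0.01 — and covers 30% of
the 5 Mb chromosome at both length thresholds.

Every stage is also exposed on the command line; see `panhap --help`
(`panhap simulate diploid|panel|f2|bulks`, `panhap kmer index|unique|jaccard|tree|curve|track`,
`panhap aroh`, `panhap recomb`, `panhap bsa run|project`).

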