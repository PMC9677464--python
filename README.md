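# microbin

Iterative embedding-and-clustering binning of metagenomic assemblies
into quality-assessed metagenome-assembled genomes (MAGs).

Genome-resolved metagenomics starts from assembled contigs whose genome
of origin is unknown. `microbin` groups contigs by combining two
signals that are approximately homogeneous within a genome: k-mer
composition (the "genomic signature", informative around k = 4) and
per-sample read depth of coverage (differential coverage across samples
discriminates genomes of similar composition). It is aimed at people
who have an assembly, structural annotations (GFF3), marker-gene hits
against lineage-specific single-copy marker sets, and a per-sample
contig depth table, and who want draft genomes with quantified
completeness and purity.

## Method

Per binning iteration, over the currently un-binned contigs:

1. **Features.** Canonical k-mer counts (default k = 2, 3, 4; windows
   overlapping masked rRNA/CRISPR regions are skipped) and per-sample
   depths, each block centered log-ratio transformed:
   `clr(x)_i = ln(x_i) − mean_j ln(x_j)` per row.
2. **Embedding.** PCA to ≥ 75 % explained variance (≤ 75 dims), then
   t-SNE to 2-D with multi-scale Gaussian affinities at two
   perplexities (starting at 10 and 100, growing by 2 and 5 per
   iteration up to 20 and 130) and Manhattan input distances. For `NUC`
   un-binned contigs the optimizer uses

   - early exaggeration `EX = clamp(NUC × 2.5·10⁻⁴, 4, 100)`,
   - early learning rate `LR_EX = max(2, NUC / EX)`,
   - main learning rate `LR = clamp(NUC × 0.1, 200, 64 000)`,

   and stops each phase when the Kullback–Leibler divergence, measured
   every 250 iterations, improves by less than `KLD × 0.01`.
3. **Clustering.** HDBSCAN (Manhattan metric, min cluster size
   `max(2, round(ln n))`, cluster-selection epsilon cycling
   0.25 → 0.125 → 0.0) swept over min_samples = 1, 5, 10.
4. **Vetting.** Each cluster is scored against a hierarchical
   single-copy marker-set database: completeness is the mean fraction
   of each collocated marker set present; purity is the mean reciprocal
   copy number of the present markers,

   `P_MSS = mean over MS of ( mean over present g in MS of 1 / C_g )`.

   Assessment starts at the domain level and descends one rank at a
   time (default down to class), averaging each sub-domain estimate
   with its domain estimate. Clusters passing the dynamic thresholds
   (completeness starting at 92.5 % and stepping down to 72.5 % single
   sample / 70 % co-assembly; purity ≥ 95 %, escalating to 95–99 % for
   low-completeness clusters and relaxing to 87.5 % in the final stage)
   become MAGs; contaminated clusters are re-clustered with the raw
   depths appended as extra dimensions. Contigs carrying ≥ 40 distinct
   markers at ≥ 90 % purity / ≥ 92.5 % completeness are rescued as
   single-contig MAGs before any embedding.

MAGs are tiered HQ (purity > 90 %, completeness > 70 %), NC
(> 95 %, > 90 %) and MIMAG high-quality draft (NC plus ≥ 18 unique tRNA
isotypes and the 5S/16S/23S rRNAs). A gold-standard evaluation module
computes AMBER-style bp purity/completeness and the adjusted Rand
index, and a seeded synthetic-community generator makes the whole
engine testable without downloads.

## Worked example

```bash
microbin simulate --genomes 4 --samples 2 --contigs-per-genome 15:30 \
    --genome-length 150000:250000 --seed 42 --out community
microbin run --assembly community/assembly.fasta \
    --gff community/annotations.gff \
    --markers community/marker_hits.tsv \
    --depth community/depth.tsv --out bins --seed 0
```

which logs the iteration schedule and result:

```
INFO iteration 1: NUC=82 EX=4.0 LR=200 perp=(10.0, 100.0) eps=0.250 -> 4 clusters, 4 MAGs (thr=92.5)
4 MAGs written to bins (0 contigs un-binned)
```

`bins/summary.tsv` then holds one row per MAG with its marker-based
quality — e.g. `bin_1_1` (24 contigs, 243 689 bp) assessed as class
Clostridia at completeness 1.0 and purity 1.0, tiers `HQ;NC;MIMAG-HQ`.
Scoring against the generator's truth:

```bash
seqkit fx2tab -nl community/assembly.fasta > lengths.tsv
microbin evaluate --bins bins/contig_to_bin.tsv \
    --gold community/gold_standard.tsv --lengths lengths.tsv
```

```
#bin_id reference   bp_purity  bp_completeness  bin_bp
bin_1_1 genome_004  1.0000     1.0000           243689
bin_1_2 genome_003  1.0000     1.0000           237377
bin_1_3 genome_002  1.0000     1.0000           179080
bin_1_4 genome_001  1.0000     1.0000           165586
#overall purity=1.0000 completeness=1.0000 ari=1.0000 bins=4
```

Every bin recovered exactly one planted genome (bp purity and
completeness 1.0), and the partition agrees perfectly with the truth
(adjusted Rand index 1.0).

Real assemblies are consumed the same way: the GFF3 comes from
Prokka-style annotation (rRNA from barrnap, CRISPRs from minced), the
marker-hit table maps contig → ORF → marker accession, and
`--marker-db` accepts a full CheckM-dialect taxon marker-set table
(`microbin.markers.convert_checkm_table` converts one; a miniature
hierarchy is bundled for testing).

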