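# Methods

## Model and assumptions

`microbin` treats binning as iterative density clustering in a learned
2-D view of contig features. The underlying assumptions are the usual
ones for composition/coverage binning: k-mer frequencies (k ≈ 4) are
approximately stationary within a genome and differ between genomes;
average read depth is approximately constant along a genome within a
sample; and with several samples, depth *profiles* separate genomes
whose composition is similar. Both feature families are compositional
(only relative magnitudes are meaningful), hence the centered log-ratio
(CLR) transform — natural log of each component over the row geometric
mean — applied separately to each k-mer block and to the depth block.

Cluster quality is judged by lineage-specific single-copy marker sets.
Completeness of a contig group is the mean, over collocated marker
sets, of the fraction of the set's genes present at least once. Purity
is the mean reciprocal copy number of the present genes, averaged
within and then across marker sets. Two reading choices were genuinely
open and are resolved as follows: genes with zero copies contribute
nothing to purity (they are completeness's business — including them
would penalize incompleteness twice), and marker sets with no present
gene are dropped from the outer mean; a group with no markers at all is
vacuously pure (1.0) but can never pass a completeness threshold.

Taxon assessment starts at the domain maximizing completeness and
descends one rank per step (default floor: class). Sub-domain estimates
are averaged with the domain estimate — the domain set is general but
weak, the lineage set specific but gameable by chance hits — and a
deeper taxon takes over when its averaged completeness is equal or
higher. Ties at a level break to the lexicographically smallest taxon
name, for determinism. A markerless group is reported at domain level
with completeness 0 rather than descending through meaningless 0-vs-0
ties.

## Embedding

PCA first reduces the feature matrix to the smallest number of
components explaining 75 % of the variance, capped at 75; inputs
already at or below the target pass through. The 2-D embedding is
t-SNE with multi-scale affinities: conditional Gaussian affinities are
computed at a small and a large perplexity (schedule (10, 100) on the
first binning iteration, +2/+5 per iteration, capped at (20, 130)) and
averaged before symmetrization. Input-space distances are Manhattan,
which degrades more gracefully than Euclidean in high dimension.

The optimizer is an exact-gradient descent (momentum 0.5 in the
early-exaggeration phase, 0.8 in the main phase, adaptive per-parameter
gains) with the size-adaptive schedule: for `NUC` un-binned contigs,
early exaggeration `EX = clamp(NUC · 2.5e-4, 4, 100)`, early learning
rate `max(2, NUC/EX)`, main learning rate `clamp(0.1 · NUC, 200,
64000)`. Every 250 iterations the KL divergence against the
(un-exaggerated) affinity matrix is measured; a phase stops when the
improvement drops below 1 % of the current KLD, with hard caps of 1000
early / 2000 main iterations as a backstop. Initialization is the
2-D PCA of the input scaled to standard deviation 1e-4 (the usual
deterministic, globally faithful choice); rank-deficient inputs get a
seeded Gaussian second axis. The exact O(n²) gradient is the right
trade-off at the problem sizes this package targets in testing and
desk-scale use (hundreds to a few thousand contigs per embedding);
interpolation-based approximations would only pay off far beyond that.

When n is too small for the large perplexity, both perplexities shrink
proportionally so that the large one becomes (n − 1)/3, with a warning.
This keeps tiny runs well-defined, but note the regime change: when a
genome's contig count is of the order of the (shrunken) large
perplexity, cluster edges blur and fringe contigs become density noise.

## Clustering and thresholds

HDBSCAN (scikit-learn implementation) clusters the embedding with
Manhattan metric, `min_cluster_size = max(2, round(ln n))` (half-up
rounding; the backend needs an integer ≥ 2), a cluster-selection
epsilon cycling 0.25 → 0.125 → 0.0 per binning iteration, and a
min_samples sweep over (1, 5, 10); contigs accepted in an earlier sweep
pass are excluded from later ones within the same embedding.

A cluster is accepted when marker completeness meets the current
threshold and purity meets the requirement for its completeness: base
95 % while the completeness threshold is ≥ 90 %, else 92.5 %,
escalating linearly from the base at cluster completeness 90 % to 95 %
at ≤ 70 % (99 % when the chosen marker set is a whole domain, whose
sets are too generic to vouch for purity alone). The escalation's
functional form between those anchors is a package choice (the anchors
are fixed, the path between them was open; linear is the least
structured option). Rejected clusters are re-clustered in (2-D
coordinates ∥ raw depth columns), each depth column rescaled to the
coordinate spread (divided by its own SD, multiplied by the mean
coordinate SD) so no single high-coverage sample drowns the geometry;
splitting uses epsilon 0 (micro-cluster merging is counterproductive
when the goal is to pull a mixture apart) and recurses until no new
clusters appear or the attempt budget (default 1, final stage 2) is
spent.

Single-sample runs lower the minimum contig size by 500 bp whenever
fewer than half the sweep passes yielded MAGs, floor 500 bp; at the
floor the completeness threshold drops 10 points (92.5 → 82.5 → 72.5)
and the size resets. At the completeness floor a final stage relaxes
purity to 87.5 % for clusters ≥ 90 % complete and doubles split
attempts; the run ends when a final-stage iteration accepts nothing.
Co-assembly runs (> 1 depth column) embed all un-binned contigs
≥ 500 bp, step the threshold down to 70 %, and finish with terminal
rounds at minimum contig sizes 2000/1500/1000/500 bp. With a single
depth column the depth CLR would be identically zero, so that one
column is instead log-transformed and centered by its median across
contigs.

Determinism: one master seed derives the per-iteration embedding seeds
(seed + iteration); HDBSCAN and all feature math are deterministic, so
identical inputs and seed give byte-identical output tables. Bin ids
are `bin_<iteration>_<ordinal>` by descending total bp (iteration 0 is
single-contig rescue).

## Synthetic communities

The generator emulates the input files, not sequencing: each genome is
sampled from its own order-2 Markov chain over {A,C,G,T} whose
transition rows are drawn from a Dirichlet (concentration 1.0 by
default — genomes with clearly distinct tetranucleotide signatures;
order 2 so k = 4 features carry identity). Genomes (default
400–800 kb) are fragmented at uniform random breakpoints into the
requested number of contigs with a 500 bp minimum fragment, matching
the ≥ 500 bp contig tables upstream tools emit. The full marker
complement of the genome's assigned taxon (domain + phylum + class sets
from the bundled 2-domain/4-phylum/6-class hierarchy) is planted once,
placed on contigs with probability proportional to length. Per-sample
depth is a genome abundance (lognormal, median 10×, sigma 1) times
per-contig lognormal noise (sigma 0.1). rRNA and CRISPR features are
planted on a small share of contigs to exercise masking, and 20 tRNA
isotypes plus the three rRNA types per genome to exercise MIMAG
tiering. Optionally several genomes can share one composition chain
(differential-coverage scenarios) and abundances can be pinned.

What this does *not* emulate — and hence what green tests do not prove
about real data: strain-level mixtures, within-genome composition
heterogeneity (mobile elements, skewed regions beyond the planted
masks), chimeric contigs, depth variation along the genome, and marker
mis-annotation. Real assemblies will sit well below the synthetic
ceiling.

The separation diagnostic `composition_separation` compares each
contig's CLR tetranucleotide profile with its own genome's pooled
profile versus the other genomes' profiles; both terms are
contig-level so short-contig sampling noise cancels, putting the
no-signal baseline at ≈ 1 regardless of fragmentation.

## Evaluation

Gold-standard scoring follows the bp conventions: a bin's reference is
the genome with the most base pairs in it (ties to the smaller genome
id); bp purity is the reference's share of the bin, bp completeness
the recovered share of the reference genome; overall metrics sum
majority-genome bp across bins. The adjusted Rand index is computed
over binned contigs only — un-binned contigs are a refusal, not a
cluster, and including them as singletons would reward timid binning.
Tier thresholds are strict inequalities (purity > 90 / > 95,
completeness > 70 / > 90), with MIMAG-HQ additionally requiring ≥ 18
tRNA isotypes and all of 5S/16S/23S.

## Known limitations

- Marker-set purity cannot see contamination between lineages that
  share no markers; a merged Bacteria + Archaea cluster scores purity
  1.0 at both lineages. Only embedding geometry (and bp metrics, when a
  gold standard exists) guards against such merges.
- Contigs left behind once their genome's main cluster was accepted are
  never recruited post hoc; per-genome bp completeness is bounded by
  what clustered on the first pass.
- The exact-gradient t-SNE is quadratic in the number of embedded
  contigs; embeddings beyond ~10⁴ contigs get slow.
- Very small communities (a few hundred contigs) run in the shrunken
  perplexity regime described above; the test fixtures use hundreds to
  ~2000 contigs, where the schedule operates as designed.
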