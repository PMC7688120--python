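# Methods

## The analysis

`allornone` implements the SNP side of a replicated selection experiment:
several independently bred selected lines and unselected control lines
derived from one outbred base population (the motivating design is 4 High
Runner mouse lines and 4 control lines bred for 88 generations at an
effective population size of about 35 per line). Given per-line focal-allele
frequencies of a SNP panel, the pipeline

1. classifies each SNP as **all-or-none**: fixed for the same allele in every
   replicate line of one line type while fixed in no replicate line of the
   other type (or vice versa);
2. groups the all-or-none SNPs into genomic **clusters** by chaining
   same-chromosome neighbours whose gap is at most `max_gap`, keeping groups
   of at least `min_size` members and padding the group span by `pad` on each
   side;
3. **annotates** SNPs against nearby genes, strand-aware, within a window;
4. counts **DE genes** (differentially expressed, q < 0.05) whose spans
   intersect the padded clusters;
5. quantifies surprise under two nulls: an exact/Monte-Carlo **Wright–Fisher
   drift null** for the all-or-none pattern, and position-preserving
   **permutation tests** for spatial clustering and DE co-localization.

## Classification

Fixation is `freq >= 1 - delta` (focal) or `freq <= delta` (other), with
`delta = 0` by default — exact fixation, configurable because empirical
frequencies are sample estimates. "Not fixed" has two readings, both exposed:

- `not_fixed_for_focal` (default): a line of the other type fails the
  criterion as soon as its frequency of the group-fixed allele is below
  `1 - delta`. A control line fixed for the *opposite* allele still counts,
  which is the literal reading of the pattern definition.
- `strict_polymorphic`: the other type's lines must be strictly segregating.

A separate `fail_delta` lets the fixation tolerance be relaxed without
weakening the failure criterion (this makes the classifier monotone in the
fixation tolerance, a property the tests check).

## Clustering

Defaults: `max_gap` 1.5 Mb, `min_size` 3, `pad` 0.1 Mb. The padding and the
minimum group size come from the cluster definition of the motivating
experiment; the gap threshold is not stated there, so the default is the
smallest round value under which the experiment's own chromosome-17 cluster
(largest internal gap ≈ 1.19 Mb between its printed positions) stays intact.
Cluster `length` is `end - start` of the padded interval; for the
chromosome-17 example this is 2,978,108 bp (≈ 3 Mb). Groups smaller than
`min_size` are reported as singletons, never dropped, and the summary is also
meaningful at `min_size = 1`. Padding clamps at position 1, and at the
chromosome length when sizes are supplied.

## Annotation conventions

SNP positions are 1-based; genes are stored 0-based half-open (BED output is
0-based half-open, GFF3 1-based inclusive). The 50 kb window is measured to
the nearest gene-span boundary, not the TSS. Distance counts bases such that
a SNP immediately adjacent to the gene boundary is 1 bp away (a plus-strand
gene at 5,001–8,000 with a SNP at 4,501 is 500 bp upstream). Exons and
introns are numbered 1-based in transcription order, so "intron 1" of a
minus-strand two-exon gene is the genomic gap between its right and left
exons. A SNP may annotate to several genes; no best-gene selection is
performed. These conventions are this package's documented choices — locus
tables in the literature rarely state theirs exactly.

## Wright–Fisher drift null

Per line, the focal-allele gamete count follows the Wright–Fisher chain on
0..2N: Binomial(2N, p′) per generation with p′ = p(1+s)/(1+ps) (genic
selection; s = 0 is drift). Exact evaluation builds the dense transition
matrix and iterates the state vector (feasible for 2N ≤ 200; beyond that a
capability error points to the Monte-Carlo routines). The chain starts at the
count nearest p0·2N; an optional two-point mixture over the adjacent counts
exposes the sensitivity to fractional p0.

With single-line probabilities a = P(fixed focal), b = P(fixed other),
seg = 1 − a − b, the pattern probability for n_s selected and n_c control
lines is, under the default mode,

    a^{n_s}(1−a)^{n_c} + b^{n_s}(1−b)^{n_c}
  + a^{n_c}(1−a)^{n_s} + b^{n_c}(1−b)^{n_s}
  − a^{n_s}b^{n_c} − b^{n_s}a^{n_c},

the last two terms removing the double count of the configuration where one
type is fixed for one allele and the other type for the other (it satisfies
two directions at once). Under `strict_polymorphic` the directions are
disjoint and the plain sum over (linetype, allele) applies with seg as the
failure probability. The exact value agrees with a Monte-Carlo
simulate-and-classify estimate within binomial error (tested).

The expected genome-wide all-or-none count of a neutral panel is the sum of
per-locus probabilities; its 95% interval is the 2.5–97.5 percentile band of
the count resampled per locus as a Bernoulli draw with its exact probability
— distributionally identical to simulating the panel under neutrality, since
loci are independent. Because base-population starting frequencies are
generally unknown, the drift null is reported as a function of p0 rather
than as one headline number.

## Permutation tests

Both tests permute labels while preserving positions, so the null respects
the panel's (or gene set's) own spatial density. Statistics for the
clustering test: fraction of labeled loci in groups of ≥ 3, number of
clusters, and maximum cluster size. The DE test's statistic is the number of
DE genes intersecting any cluster. Tests are one-sided upper with the
add-one estimator p = (1 + #{null ≥ observed}) / (1 + n_perm), never zero,
and bit-reproducible for a fixed seed.

## Synthetic data

The generator emulates the breeding design: every locus starts at a shared
p0 and drifts independently in every line for `generations` generations at
size Ne; selection (coefficient s, favored allele) applies in selected lines
only. Defaults: Ne 35, 88 generations, 4+4 lines, p0 ~ Uniform(0.1, 0.3) — a
standing-variation frequency band plausible for an outbred base population,
which also puts the neutral all-or-none rate (~0.8% per locus) on the order
observed in the motivating experiment. The first generation is drawn from
the real-valued p0, so the neutral endpoint mean is exactly p0 and its
variance is p0(1−p0)(1−(1−1/2N)^t) (both tested against 3-SE bands).

Gene models are laid out non-overlapping in configured windows, strands
alternating, 2–5 exons each, spans equal to exon hulls, with a receptor
family tag per window. DE status is Bernoulli with probability `background`
everywhere, raised to background + enrichment·(1 − background) inside target
windows, so enrichment 0 is uniform and enrichment 1 makes every window gene
DE.

What the generator does **not** emulate: linkage and hitchhiking (loci are
unlinked, so clusters of divergent loci arise only by explicit placement),
mutation, dominance (selection is genic, one parameter), within-family
selection's mechanistic effect on Ne (Ne is a direct input), and realistic
allele-frequency ascertainment. Passing tests therefore show the pipeline's
statistical machinery is correct under the stated model, not that real data
meet the model's assumptions.

Randomness uses independent streams keyed by (seed, purpose, line, locus),
so any locus's outcome is reproducible regardless of how many other loci are
simulated.

## Numerical choices and problem sizes

- Exact-chain probability mass is conserved to < 1e−10 over 88 generations;
  the neutral absorption probability equals p0 to < 1e−6 at 5,000
  generations (2N = 70).
- Monte-Carlo cross-checks use 3 binomial standard errors; the suite's
  largest simulation is 100,000 replicate lines for the exact-vs-MC check.
- Calibration experiments use 20 seeds × 300-locus neutral panels (CI
  coverage) and 200 permutation runs at n_perm = 199 (p-value uniformity);
  the recovery experiment uses 20 seeds × (1,000 neutral + 10 selected,
  s = 0.5) loci. These sizes give the checks adequate power while keeping
  the suite quick.
- Cluster ids are assigned in (chromosome, position) order; all output
  tables are written sorted with fixed column order and shortest round-trip
  float formatting, so reruns are byte-identical.
- Chromosomes sort lexicographically; supply zero-padded names if numeric
  order matters.

## Known limitations

- The drift null assumes independent loci and identical, known p0; linked
  loci under a sweep violate independence, making the null conservative in
  an unquantified direction.
- BED12 cannot carry the receptor family as an attribute; it round-trips
  through the itemRgb color (fixed family→color map). GFF3 is the canonical
  serializer.
- `read_clusters_bed` cannot recover member SNP ids (BED6 has no field for
  them); use the cluster TSV for full fidelity.
- The classifier consumes any panel; it does not re-implement the upstream
  mixed-model significance screen that typically precedes this kind of
  analysis.
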