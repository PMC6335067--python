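# Methods

## Scope and data model

The package analyses per-cytosine bisulfite count reports: one row per
reference cytosine with chromosome, 1-based position, strand, context
(CG / CHG / CHH, H = A, T or C), methylated (unconverted) and
unmethylated (converted) read counts, and optionally the reference
triplet. CG cytosines on opposite strands are independent sites — no
dyad merging — matching the per-strand convention of extractor output.
Internally all intervals are 0-based half-open; cytosine reports and
GFF3 are converted at the I/O boundary, BED passes through unchanged.
Chromosomes are taken as they come (no organellar special-casing);
subgenome summaries group them by their leading letter (A/D).

The "methylation level" of any site set is the weighted level
`sum(m) / sum(m + u)`. Pooling read counts makes dense, shallow and
sparse, deep regions commensurable and is exactly additive across
partitions (a property the test suite checks). The unweighted
mean-of-ratios is available via `method="mean_ratio"` wherever a level
is computed, for sensitivity analysis; it is never the default.

## Methylcytosine calling

A site with coverage `n` and methylated count `m` is *uncallable* when
`n < 3`. Otherwise it is methylated iff the exact binomial upper tail
`P(X >= m | X ~ Bin(n, r)) < 1e-5` **and** `m/n > 0.25`, where `r` is
the bisulfite non-conversion rate (default 0.006; it is an input — the
rate is estimated upstream from an unmethylated spike-in control, which
is out of scope here). The test is one-sided (excess unconverted reads
only), the ratio bound strict, the coverage bound inclusive. No
multiple-testing correction is applied across sites: the fixed
threshold *is* the procedure. The observation model treats
non-conversion as false methylation only — a truly methylated read is
never counted as converted — so the observed proportion at true level
`m` is `m + (1 - m) r`.

Sharing classes across k samples key on exact
(chromosome, position, strand, context): methylated in all k =
constitutive, in exactly one = unique, otherwise varied.

## Differential methylation

**DMRs.** Non-overlapping 100-bp tiles (`[100k, 100(k+1))`). Per
context, a tile is testable when it holds >= 10 *informative*
cytosines — sites with >= 4 reads — in **each** sample (the stricter of
the two readings of "in any two samples"; the permissive either-sample
variant is a flag). Note the deliberate asymmetry inherited from the
procedure: calling uses >= 3 reads ("at least three"), the informative
filter >= 4 (">3"); both knobs sit in `Parameters`. Pooled 2x2 counts
are tested with a two-sided Fisher's exact test — the sum of
hypergeometric point probabilities not exceeding the observed table's
probability, with a 1e-7 relative slack for floating-point ties. The
implementation enumerates the support vectorized in log space (gammaln)
because a genome comparison tests tens of thousands of bins; it is
checked in the suite against both `scipy.stats.fisher_exact` and an
integer-exact enumeration oracle. BH correction runs within one
(context, comparison) family; `q < 0.05` bins are DMRs. Bins are not
merged, and no minimum delta is imposed — delta (sample B minus A,
"hyper" = B higher) is reported for post-filtering.

**DMCs.** Positions covered >= 3x in both samples, binomial call
statuses discordant (methylated in exactly one sample), and
`|level_A - level_B|` >= 0.7 / 0.5 / 0.1 for CG / CHG / CHH. The
discordant-status reading implements the per-sample binomial-test
definition; a per-site Fisher alternative (`method="fisher"`) is
provided since the one-line description admits both readings.

## Profiles

Metagene profiles align features 5'-to-3': each 2-kb flank is cut into
100 fixed-width (20-bp) bins, the body rescaled into 100 fractional
bins; minus-strand features are reversed so bin 0 is always 5'-most.
Flank bins are fixed-width so genomic distances (e.g. the 500-bp CHH
island) stay interpretable; with constant nominal flanks a fractional
flank binning would be arithmetically identical, so no second mode is
offered. Bin statistics pool counts across features
(coverage-weighted); zero-read bins are NaN. RdDM-locus profiles use
the same contract with 5-kb flanks and unstranded loci. Window tracks
pool counts per sliding window (a cytosine contributes to every window
containing it); the trailing partial window is kept and flagged.
Defaults follow the two published track scales (1 Mb sliding 200 kb;
100 kb sliding 1 kb). TE length classes are strict at both ends:
short < 500 bp, long > 4000 bp (a 4000-bp TE is medium), medium
otherwise. When 24-nt alignments rather than loci are supplied,
`merge_alignments` merges overlapping alignments (merge distance 0)
into loci.

## Integration

DMR annotation: promoter (strand-aware `[TSS-2000, TSS)`) > exon >
intron > intergenic on >= 1-bp overlap, each DMR in exactly one
category; TE overlap is an independent flag (longest-overlap TE decides
the length class) because TE percentages are reported separately from
the gene-centric breakdown. Methylation–expression association is
Pearson's r between promoter level and `log2(FPKM + 1)`; alongside
plain r the package reports `sign(r) * r^2` — the signed-R² convention
used in this literature for those headline negative values.
Differential-expression p-values are consumed, never computed: the DEG
filter is `p < 0.05 AND |log2 ratio| >= 2` (inclusive bound, direction
from the sign). Expression clustering z-scores each gene across stages
(constant trajectories map to the zero vector), runs Lloyd k-means
(k = 10, 10 restarts, fixed seed, lowest within-cluster SS kept), then
relabels clusters 1..k by descending first-stage centroid so output is
stable run-to-run; the label order is a reproducibility device, not a
claim about any published cluster numbering. The siRNA-overlap gene
comparison is a two-sided Wilcoxon rank-sum test on per-gene body
levels (exact for small ties-free samples, normal approximation with
tie correction otherwise, as dispatched by scipy). The TE up/down
balance is a 1-df chi-squared goodness-of-fit against 50:50 with no
continuity correction.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume,
not any particular genome:

* **Genome/annotation.** Uniform-random sequence over 2+ chromosomes
  with A/D name prefixes (defaults: A01/D01, 500 kb each). Genes, TE
  genes and TEs are placed non-overlapping with a minimum gap
  (2.6 kb — room for a promoter plus island); TE lengths are drawn per
  class (54% short / 45% medium / 1% long, roughly the published
  distribution shape). Contexts come from the simulated triplets, so
  context proportions are realistic for random sequence but not
  calibrated to any species.
* **True methylomes.** Per-site base levels are Beta-distributed around
  context means (CG 0.75, CHG 0.45, CHH 0.08; concentrations 2/4/8).
  Each gene receives a CHH island: a 500-bp window upstream of the TSS
  whose CHH sites gain a per-gene boost drawn Uniform(0, 0.3) (mean
  0.15). The per-gene draw keeps the stated mean elevation while giving
  promoters genuine between-gene variance — without it, promoter CHH
  would be nearly constant and no methylation–expression coupling could
  be measured at realistic noise. An optional per-subgenome CHH shift
  emulates the A/D asymmetry. The baseline is shared across samples;
  planted DMRs shift the designated sample's level by a fixed delta
  inside chosen 100-bp bins (clamped to [0, 1]; realized deltas are
  recorded in the truth table). Planted bins are drawn only from bins
  with >= 15 sites of the context, so every planted DMR satisfies the
  caller's informative-cytosine precondition by construction.
* **Counts.** Coverage ~ Poisson(30) by default (negative-binomial via
  an overdispersion switch); methylated reads ~
  `Binomial(n, m + (1 - m) * 0.006)`. Zero-coverage sites are kept, as
  in real reports.
* **siRNA loci.** Each 24-nt locus is >= 1 merged alignment
  (24–36 bp); with probability `sirna_coupling` (default 0.7) it is
  placed inside a CHH-hyper region (planted hyper-CHH DMRs, else the
  island windows), otherwise uniformly. A configurable fraction
  (default 0.5) is shared across samples — the constitutive loci.
* **Expression.** `log2(FPKM + 1) = intercept + slope * promoter_CHH +
  N(0, sd)` per sample (slope -4, sd 0.5, intercept 6), with an option
  to couple only a fraction of genes; `log2_ratio` and a Gaussian
  `p_value` contrast last vs first sample. The operation takes promoter
  levels as an explicit genes x samples input so recovery tests can
  control the x-distribution.
* **Determinism.** One RNG stream per artifact (genome, levels, DMR
  plan, per-sample counts, siRNA, expression), all derived from the
  master seed: regenerating one file never perturbs another, and a
  fixed seed reproduces every byte.

What the generator does **not** emulate: read-level artifacts (mapping
bias, M-bias, PCR duplicates), linkage between neighbouring sites
(true methylomes are spatially autocorrelated; here sites are
independent given the regional mean), realistic bimodal CG level
distributions, TE-family-specific methylation, or any H3K9me2 signal
(interval tracks may be supplied externally). Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not performance on real libraries.

## Validation experiments and problem sizes

`bsmeth.benchmarks` packages the validation battery used by the suite
and by `scripts/acceptance.py`; sizes were chosen so everything runs in
a few minutes on one core:

* Binomial caller vs exhaustive tail summation: every (coverage, count)
  with coverage <= 200 at r = 0.006, plus the derived
  minimum-significant-count table (3 reads at n = 3; 4 at n = 10).
* Fisher vs integer-exact enumeration: all 741,321 tables with row
  margins <= 40 (agreement to ~1e-13).
* Null FDR: two samples sharing one featureless 5.5-Mb true methylome,
  independent counts at 30x — 55,000 testable CHH bins; the significant
  fraction is compared to 0.05 + 3 Monte-Carlo SEs. (Under a global
  null BH controls family-wise error, so the observed fraction is
  typically 0.)
* Recovery: 20 CHH bins (delta +0.4) and 20 CG bins (delta -0.8,
  clamped at 0 from the 0.75 baseline) planted on a 1-Mb genome,
  >= 15 sites per bin, 30x; sensitivity and direction are scored
  against the truth table.
* Flatness/conservation: a constant-0.3 methylome (infinite Beta
  concentration); every defined profile/window bin must sit within 6
  binomial standard errors of `0.3 + 0.7 * r`, and the read-weighted
  mean of tiling windows must equal the genome-wide level to 1e-12.
* Coupling: 2,000 genes on a 5.8-Mb genome; measured Pearson r between
  observed promoter CHH and log2(FPKM+1) is compared (+-0.05) with the
  closed-form `s * sd(x) / sqrt(s^2 var(x) + sigma^2)` evaluated on the
  realized promoter levels; with coupling restricted to half the genes,
  the coupled half must out-correlate the uncoupled half. Under these
  conditions sd(x) ~ 0.022 and r ~ -0.21 with a Monte-Carlo SE of
  ~0.02, so the +-0.05 band is a ~2.3-sigma check.
* Determinism: the full pipeline run twice with one seed on a small
  configuration; the SHA-256 manifests must match exactly.

## Numerical choices and degenerate inputs

Undefined levels (zero reads) are NaN and excluded from correlations
with their counts reported. Fisher on an all-zero table returns p = 1.
BH on an empty vector returns an empty vector. `min_methylated_count`
returns None when even full methylation is not significant; a
degenerate alpha > 1 yields 0. Correlations need >= 3 points and
non-degenerate variance, otherwise they are flagged undefined rather
than raised. k-means rejects k > n genes. Promoter windows clipped at
the chromosome start that vanish entirely yield undefined levels.
Floating-point output is formatted at 6 significant digits everywhere
the pipeline writes files, which is what makes byte-level determinism
well-defined.

## Known limitations

Single-cytosine resolution only at >= 3x — shallow libraries lose most
CHH sites. DMRs are single 100-bp bins; contiguous differential blocks
appear as runs of bins, not merged regions (by design, but users
wanting regions must merge downstream). The Fisher test treats reads as
independent Bernoulli trials, ignoring within-read and within-fragment
correlation, so q-values on real data are anti-conservative in
clustered coverage. The DMC definition inherits the asymmetry of its
source procedure (call coverage >= 3 vs informative >= 4). The
synthetic generator's independence assumptions (see above) mean
power/FDR figures transfer to real data only qualitatively.
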