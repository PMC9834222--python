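# Methods

## Scope and data model

`aseflow` operates on per-sample allele count tables in the GATK
ASEReadCounter dialect (`contig, position, variantID, refAllele,
altAllele, refCount, altCount, totalCount`). Counts used everywhere
downstream are `refCount + altCount`, not the file's `totalCount` column:
the folded score and the binomial test are defined on reference vs
alternative reads, and `totalCount` may include other bases. Coordinates
are 1-based throughout, matching VCF; count records are matched to
genotype calls on `(sample_id, contig, position)` rather than variant id,
which tolerates rsID drift between callsets. Multi-allelic and non-SNP
VCF records are skipped (with a logged count) because the folded score is
only defined for biallelic loci.

A minimum read depth of 10 (configurable; 1 disables filtering) is
applied at load time: folded scores and exact binomial tests are
unstable below roughly 10 reads, where a single read shifts the allelic
fraction by 10 percentage points or more. Upstream pipelines often apply
no such filter, so the count of removed records is logged.

## Folded ASE score

`score = |ref/(ref+alt) − 0.5| + 0.5`, evaluated as `max(ref, alt) /
(ref + alt)`. The two forms are algebraically identical; the max form is
exactly swap-symmetric in floating point, whereas the literal form can
differ by one ulp between `(r, a)` and `(a, r)` when the minor fraction
is below 0.25. The score is 0.5 iff the counts are equal and 1.0 iff one
count is zero.

## Homozygosity threshold calibration

Samples with genotypes yield labelled (het/hom) scores. The classifier
under calibration is "score ≥ t ⇒ homozygous". Candidate cuts are the
midpoints between adjacent distinct observed scores plus two sentinels
0.01 below the minimum (call everything homozygous) and 0.01 above the
maximum (call nothing); the sentinel offset is arbitrary since only the
induced classification matters. For each cut, TPR is the fraction of
homozygous loci called and FPR the fraction of heterozygous loci
miscalled; the cut maximizing Youden's J = TPR − FPR is selected, with
ties broken towards the smallest candidate (discarding more potential
artifacts). In the fully degenerate case where every cut has equal J,
the tie rule returns the low sentinel, which can fall below 0.5; real
calibration sets never trigger this.

Heterozygous loci are typically outnumbered ~5:1 by homozygous ones in
genotyped RNA-seq data, and Youden's J on such skewed data would be
dominated by the majority class. Both classes are therefore downsampled
without replacement to the minority class size, the optimal cut recorded
per resample, and the final threshold taken as the mean across resamples
(default 1000, seeded and fully deterministic). The per-resample values
and the full-data ROC are kept in the `ThresholdEstimate` for
diagnostics; their spread shrinks as the calibration set grows.

Boundary rule: a score exactly at the threshold is called homozygous
(`≥`), the conservative choice for retaining a clean heterozygous set.
Genotype calls are authoritative for genotyped samples — a truly
heterozygous locus is retained even with score 1.0, and count records
without a genotype call in a genotyped sample are dropped (logged) rather
than threshold-classified, so each sample has a single, unambiguous
zygosity source. A consequence of the threshold, noted in the output
contract: fully imbalanced loci in *non-genotyped* samples (imprinting,
nonsense-mediated decay of one allele) are indistinguishable from
homozygosity artifacts and are lost by design; only genotype integration
recovers them.

## Significance testing

**Empirical null.** The null major-allele probability `p0` is the median
over samples of each sample's median retained ASE score (midpoint
interpolation for even lengths), computed after depth filtering and
homozygosity filtering. Taking the cohort's own folded background rather
than 0.5 absorbs global reference bias and other technical skew.

**Binomial test.** Each retained record is tested with the exact upper
tail P[X ≥ max(ref, alt)], X ~ Binomial(ref+alt, p0). The one-sided
upper tail is the natural choice for a folded score: only *more*
imbalance than background is of interest, and a folded max-count can
only exceed its expectation in one direction. A two-sided variant
(doubled smaller tail) is available via a flag.

**Multiple testing.** Benjamini–Hochberg (statsmodels' step-up
implementation), by default within each sample — matching per-individual
reporting of significant counts — with a flag for one global batch.
Significance is `q < 0.05`.

**Group comparisons.** Per SNP, the per-sample score vectors are grouped
by the metadata labels. One-vs-rest uses the two-sided Wilcoxon rank-sum
test: exact null distribution when both sides have ≤ 10 observations and
no ties, otherwise the tie-corrected normal approximation *without*
continuity correction (so identical groups give p = 1 exactly). The
omnibus test is Kruskal–Wallis with tie-corrected H referred to
chi-squared with (groups − 1) degrees of freedom; an exact mode that
enumerates the permutation distribution of H exists for small totals and
is used to validate the statistic. A comparison is not testable (NaN,
never 0 or 1 by fiat) below 3 observations per side (one-vs-rest) or per
group (omnibus) — rank tests are degenerate below that. Group tests run
on all retained SNP measurements, not best-SNP-per-gene rows, since
SNP-level hits are what the Manhattan view annotates. BH adjustment runs
across testable SNPs within each comparison.

**Enrichment.** Gene-set enrichment of significant genes (e.g. in
user-supplied eQTL/sQTL gene sets) uses the one-sided hypergeometric
upper tail against the measured-gene background; this is a deliberately
simple, assumption-light test and the package makes no attempt to model
SNP density per gene. QQ inflation uses expected quantiles i/(m+1) and
reports the genomic-inflation-style lambda (median observed chi-squared
quantile over median expected).

## Gene level

ASE mechanisms such as exon-specific splicing and NMD are
position-specific, so per-gene aggregation of scores would dilute or
cancel true signal. Instead the SNP with the lowest p-value represents
the gene for each individual (ties: lower q, then lexicographically
smallest variant id — determinism matters for reproducible tables; the
minimum is taken on p, not q, with q only as tie-break). SNPs mapping to
several genes count towards each. Shared imbalance reports, per gene,
both the number of samples significant at the cutoff and the number
measured at all, making sparse coverage visible; genes with zero
significant samples stay in the table because downstream set operations
need the full background. Plain-text significant/background gene lists
are exported for external GO tools.

## Visualizations

Every figure writes a TSV sidecar with exactly the plotted numbers, and
all numeric assertions in the test suite run against sidecars, never
pixels; sidecars are byte-identical across reruns on identical input.
Density curves use a Gaussian kernel with Silverman bandwidth floored at
1e-3 (the floor keeps single-value classes finite and the output
deterministic). Manhattan plots natural-sort contigs (1..22, X, Y, MT),
plot −log10 of the BH-adjusted omnibus p by default (a flag switches to
raw p), and label the top 5 hits. The interaction network is built from
a user-supplied STRING-format edge list (no live database query, for
reproducibility), keeps edges with confidence ≥ 0.9 by default,
restricts nodes to measured genes, annotates each node with the
per-group median representative-SNP score, and emits connected
components largest first.

## Synthetic cohorts

The generator draws, per (sample, locus): zygosity (homozygous with
probability `fraction_hom`, default 0.8 — matching the roughly 4:1
hom:het ratio of genotyped calibration loci in bulk RNA-seq); read depth
from a negative binomial (mean 50, dispersion 5, floor 1 — RNA-seq depth
is strongly overdispersed, so Poisson would understate low-depth mass);
heterozygous counts Binomial(depth, p) with p = 0.5 unless an imbalance
effect is planted (globally or per group), and the major-allele direction
randomized since the folded score is direction-blind; homozygous counts
Binomial(depth, 1 − 0.01), the 1% minor-allele leak mimicking sequencing
error at truly homozygous loci. A missingness mask (default 0.3) models
sparse per-SNP coverage across samples, and the leading 40% of samples
(default) receive truthful VCF genotypes, mirroring cohorts where only a
subset is exome-sequenced. Four equal patient groups are assigned
round-robin by default. Output is fully deterministic given the seed,
and the truth table records zygosity, true major-allele probability,
planted and measured flags for every pair, including unmeasured ones.

What the generator does *not* model: linkage between loci, per-SNP
allele frequencies (zygosity is i.i.d. across samples rather than
MAF-driven), reference-mapping bias, overdispersed (beta-binomial)
allelic counts, and isoform structure. Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the model's
own assumptions, not robustness to alignment artifacts or overdispersion
in real data.

## Validation experiment sizes

The recovery experiments are sized to run on a laptop in minutes:

- Individual-level recovery: 40 samples × 2,000 loci, 50 loci planted at
  major-allele probability 0.8, 10 seeds. A locus counts as discovered
  when significant (q < 0.05) in ≥ 2 samples; requiring two independent
  samples guards against isolated homozygosity-leak false calls.
  Observed: mean sensitivity ≥ 80%, locus-level false-discovery
  proportion ≤ 10%.
- Group-level recovery: group comparisons need SNPs measured in several
  samples per group, which 40-sample/80%-homozygous cohorts cannot
  supply, so this experiment emulates the setting group comparisons are
  designed for: an 88-sample cohort in four equal groups with common
  well-covered SNPs (50% heterozygous, 30% missing), 20 SNPs planted at
  p = 0.85 in one group. Success: ≥ 90% of planted SNPs in the top 5% of
  testable SNPs by omnibus p, in ≥ 8 of 10 seeds.
- Threshold calibration uses 200 resamples in end-to-end runs and tests;
  the per-resample spread is far below the mean at that count, and the
  1000-resample default remains for production use.

## Known limitations

- The binomial test ignores overdispersion of allelic fractions; with
  strong biological noise it is anti-conservative in real data (a
  beta-binomial extension is a natural follow-up and is deliberately out
  of scope).
- A single cohort-wide `p0` assumes technical skew is shared across
  samples; sample-specific nulls would need many retained loci per
  sample.
- The homozygosity threshold removes genuinely monoallelic heterozygous
  loci in non-genotyped samples (see above); population-level counts
  therefore undercount extreme imbalance unless all samples are
  genotyped.
- Exact rank-test enumeration is only used for validation at small n;
  production paths use scipy's exact/asymptotic switching as described.
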