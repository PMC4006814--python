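# Methods

This note documents the statistical procedures implemented in pathconcord,
the choices made where the design was genuinely open, the synthetic data
model, and the package's known limitations.

## Expression arm

### Ranking metric

Genes are ranked by a simplified moderated t-statistic. For gene g with
group means x̄₁ (case) and x̄₀ (reference), pooled within-group variance
s²_g on d_g = n₀ + n₁ − 2 degrees of freedom:

    s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g)
    t_g   = (x̄₁ − x̄₀) / ( s̃_g · sqrt(1/n₀ + 1/n₁) )

with a fixed prior d₀ (`prior_df`, default 4) and s₀² the median of the
per-gene pooled variances. This is a deliberate simplification of the full
empirical-Bayes treatment, in which the prior degrees of freedom and prior
variance are themselves estimated from the moment structure of the
log-variances; the fixed-prior version preserves the variance-shrinkage
behaviour that stabilises small-sample t-statistics while keeping the
estimator transparent and dependency-free. In typical regimes the two
produce monotonically related ranks, and the enrichment engine accepts any
externally produced RNK list, so users wanting exact limma/eBayes scores can
supply them directly.

Conventions: the reference group defaults to the group of the first sample
column; positive scores mean higher expression in the other (case) group.
Ties in score are broken lexicographically by gene symbol so output is
deterministic. A gene with zero pooled variance scores 0 when its mean
difference is zero (±∞ otherwise, ranking it at the extreme); a matrix in
which every gene has zero variance is an error.

Probe-level matrices are collapsed per gene before ranking. The default
(`maxprobe`) takes, per gene and per sample, the maximum over that gene's
probes; `max_mean_probe` instead keeps the single probe with the highest
mean, for users who prefer one coherent probe profile per gene.

### Enrichment score

For a ranked list of N genes with scores r_i and a set with N_H members
(after restricting the set to the ranked genes), with weight w (default 1)
and N_R = Σ_members |r_i|^w, the running sum gains |r_i|^w / N_R at member
positions and loses 1/(N − N_H) at non-members. ES is the running-sum value
of maximal absolute deviation (first such index on exact ties — a
measure-zero event for continuous scores). The final running-sum value is 0
up to rounding, ES ∈ [−1, 1], and at w = 0 the statistic reduces to the
signed two-sample Kolmogorov–Smirnov distance between member and non-member
rank distributions. Degenerate inputs are hard errors: a set with no ranked
member, a set covering the whole list, or members whose scores are all zero
(N_R = 0).

### Permutation null, NES, and FDR

The null for a set of size s is built by drawing `n_permutations` (default
1000) uniform random s-subsets of the ranked genes — gene-label sampling,
the only permutation scheme available to preranked input. Null pools are
shared across sets of equal size and seeded per size as `(seed, size)`, so
results do not depend on evaluation order and any pool can be regenerated
in isolation.

NES divides ES by the mean of same-sign null ES values (mean of the
magnitudes on the negative side), preserving sign. If no null value shares
the sign of the observed ES, the NES is undefined: the set is reported with
NaN NES/q and excluded from the FDR computation, with a warning, rather
than being assigned an arbitrary value.

The nominal p is the add-one-smoothed same-sign tail fraction
(b + 1)/(m + 1), so p > 0 always and downstream log-based combination is
safe.

The FDR q for a positive NES\* is the tail ratio

    q = [ #{null NES ≥ NES*} / #{null NES ≥ 0} ]
      / [ #{obs  NES ≥ NES*} / #{obs  NES ≥ 0} ]

clipped to [0, 1] and mirrored on the negative side, where the null NES
pool concatenates every set's size-matched pool normalised by that pool's
own same-sign means. A final per-sign pass assigns each set the minimum raw
estimate over itself and all less extreme sets (the q-value convention, as
in BH), making q monotone non-increasing in |NES| without letting the
extreme tail's zero estimates leak to weak sets.

### Set-size filtering

Set membership is first intersected with the ranked genes (the measured
background), then the intersected size is tested against [min_size,
max_size], defaults 15 and 500. Retained sets carry the restricted
membership; the operation is idempotent and a table of dropped sets is
returned.

## GWAS arm

Per cohort, SNP association P-values are consumed as input (association
testing, QC and stratification correction are upstream concerns). A SNP
belongs to a gene iff it lies on the same chromosome within the gene
boundary extended by `flank` (default 100 kb) on each side, clipped at
position 1; one SNP may belong to several genes, and no LD-aware correction
is attempted — gene-dense regions near a strong association (e.g. histone
clusters near the HLA locus) can therefore inflate several genes at once,
a caveat users should keep in mind when interpreting clusters of hits.

The gene-level score is min(1, min_p × n_snps) — the minimal SNP P in the
region Bonferroni-adjusted by the number of SNPs the cohort reports in that
region. Genes at adjusted P ≤ α (default 0.05, inclusive boundary; the
boundary has negligible measure for continuous P) form the significant
class.

The per-cohort pathway test is the upper-tail hypergeometric probability
P[X ≥ k] with N the cohort's universe size, K the pathway's genes in the
universe, n the significant genes, and k the significant pathway genes. The
universe is the set of genes with at least one assigned SNP that belong to
at least one pathway in the collection: this keeps the 2×2 table
well-defined among genes that were actually scored and testable. The tail
is computed as the survival function at k − 1 (log-gamma based); values are
floored at 1e−300 so downstream log-combination never sees 0. No set-size
filter is applied by default — the multiple-testing family is every pathway
with tested genes — but 15/500-style bounds can be switched on, which
changes the BH denominator.

Cross-cohort combination uses Fisher's method, −2Σln p referred to χ² with
2m degrees of freedom; a single cohort returns its own p. The method is
exact for independent cohorts, which the study design (disjoint cohorts)
supports. Stouffer's equal-weight inverse-normal combination is available
as an option. Pathway-level control is Benjamini–Hochberg at FDR 5%
(significant ⇔ bh_q < 0.05, strict).

Calibration note: the min-P Bonferroni score is conservative (the adjusted
P is stochastically larger than uniform under the null) and the
hypergeometric tail is discrete, so null meta-P values are conservative,
never anti-conservative; the observed null rate of BH-significant pathways
is well below the nominal 5%. Tests assert the one-sided (protective)
direction of calibration; exact uniformity of null meta-P is not a property
of this procedure.

## Concordance

Per-dataset significant pathway name lists are intersected by direction
(all 2^m − 1 Venn cells are reported alongside the full intersection). The
cross-modal test compares the common expression list with the
GWAS-significant list by the upper-tail hypergeometric probability with the
full collection size (as read from the GMT) as the universe N; the test is
symmetric in the two lists, and p = 1 whenever the overlap is empty. The
upregulated common list is used by default, with `down` and pooled `both`
options. A flag table (in_expression / in_gwas / in_both per pathway)
supports downstream annotation. The universe can be overridden (e.g. to the
size-filtered collection) when a different multiple-testing family is more
appropriate; this choice materially changes the overlap p and should be
reported with the result.

## Synthetic data model

The generator produces every pipeline input with known ground truth:

- **Collection** — `n_sets` (200) sets over `n_genes` (1200) synthetic
  genes, sizes log-uniform on [15, 120]. `overlap_fraction` routes that
  expected fraction of each set through a shared hub pool (10% of the
  namespace), raising pairwise overlap coefficients above the
  random-chance baseline; the default 0 leaves only chance overlap.
- **Expression** — `n_expression_datasets` (3) independent replicates,
  `samples_per_group` (12; a pair or per-dataset pairs supported for
  unbalanced designs) per group, background N(0, 1), member genes of
  planted up/down sets shifted by ±`effect_size` (0.8 SD) in the case
  group. A gene in both an up and a down planted set keeps the up shift.
- **GWAS** — `n_cohorts` (8) cohorts over a deterministic gene layout:
  20 kb gene bodies spaced 110 kb apart (bodies disjoint, 100 kb-flanked
  regions of neighbours overlapping, so multi-assignment is exercised by
  default; the first gene of each chromosome starts at position 1,
  exercising flank clipping). Each gene carries 5–50 SNPs uniform in its
  body. A fixed `causal_gene_fraction` (0.3) of each planted pathway's
  members — the same genes in every cohort — draw SNP P-values from
  Beta(0.1, 1); all other SNPs from Uniform(0, 1). SNP P-values are
  generated directly rather than via genotypes, since the arm consumes
  association P-values and genotype simulation would add nothing testable.
- **Planting** — 10 up, 5 down, 10 GWAS pathways by default; the GWAS
  pathways coincide with the up-planted ones (`concordant`, the study's
  hypothesis) or are drawn disjointly (`independent`, the calibration
  scenario).

All generators are pure functions of the configuration and seed (component
streams are spawned from one seed sequence), so any part of a study can be
regenerated in isolation and full runs are byte-reproducible.

What the generator does **not** emulate: linkage disequilibrium and
realistic SNP correlation, array-specific noise, batch and site effects
(the reason real multi-site arrays resist pooling), gene–gene expression
correlation beyond the planted shifts, and symbol-mapping noise. Passing
recovery/calibration tests therefore demonstrate correctness of the
statistical machinery under an idealised data model, not end-to-end
performance on real arrays or genotypes.

Problem sizes (1200 genes, 200 sets, 1000 permutations, 3 + 8 datasets)
were chosen as the package's default study scale: large enough that the
competitive enrichment statistic, the meta-analysis and the overlap test
operate in a realistic regime, small enough that the full suite and the
reproduction script run in minutes on a single CPU.

## Numerical and convention choices

- Hypergeometric tails via the survival function at k − 1; p floored at
  1e−300 before any log.
- Overlap coefficient |A∩B| / min(|A|, |B|) (Szymkiewicz–Simpson), the
  standard choice consistent with "overlap generally small" reporting.
- "Shared by more than k sets" uses strict > with k configurable
  (default 3).
- Gene symbols are opaque case-sensitive strings; no alias resolution.
- BED regions are converted to 1-based inclusive coordinates on read; all
  internal coordinates are 1-based inclusive.
- Random subsets are drawn without replacement via per-permutation uniform
  keys; every run derives all streams from the single user seed.
- Output tables carry `# pathconcord <version>` / seed / parameter headers
  and are written deterministically (reruns are byte-identical).

## Known limitations

- Preranked (gene-label) permutation only; phenotype permutation is out of
  scope, so inter-gene correlation inflates significance on real data more
  than on the independent-noise simulations.
- The simplified moderated t is not a drop-in numerical match for full
  empirical-Bayes estimates (ranks, not values, are the contract).
- No LD correction in the GWAS arm (see above).
- The cross-modal universe is a modelling choice; results should always
  state which universe was used.
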