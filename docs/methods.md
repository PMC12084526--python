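# Methods

## The enrichment model

For one disorder, every drug in the database contributes one row to a
logistic regression

  logit P(Y=1) = β₀ + β₁·X₁ + β₂·X₂,

with Y the known-treatment flag, X₁ the drug's total target-gene count and
X₂ the GWAS-implication predictor. The test of β₂ = 0 is *competitive* at
the drug level: it compares GWAS-paired drugs against all other drugs
(~1,200 here) rather than comparing target genes against non-target genes,
and the X₁ covariate removes the advantage a promiscuous drug has in both
being a treatment and overlapping GWAS genes by chance. exp(β₂) is the
odds increase that a GWAS-paired drug is a known treatment.

Assumptions worth stating: drug rows are treated as independent given X₁
(violated when classes share targets — hence the cluster-robust option);
indication tables are taken as binary ground truth; the mapping step is
purely positional, so allele identity and strand never enter.

## SNP→gene mapping

A gene is *implicated* when a GWS SNP (p ≤ `gws_alpha`, default 5×10⁻⁸, the
conventional genome-wide threshold) lies within the gene body ±`flank`
(default 10 kbp, BED half-open arithmetic: `start−flank ≤ pos0 < end+flank`,
lower bound inclusive, upper exclusive). Optional supplements: a GWS SNP
recorded as a cis-eQTL for the gene, or a GWS SNP in one chromatin-loop
anchor with the gene's promoter window (gene start ± 2 kb; gene models carry
no strand) intersecting the other anchor. Contacts require *different*
anchors. Summary-statistic positions are 1-based at the boundary and
converted once on use; all internal interval math is 0-based half-open.

LD pruning is approximated reference-free by greedy distance clumping:
GWS SNPs are visited in ascending p (ties by (chrom, pos)) and absorbed if
within `clump_window` (default 250 kb) of a selected lead. Binary
implication uses **all** GWS SNPs; the per-gene annotation aggregates
(max/mean |β|, |z|, CADD; best regulomeDB category; pLI; any-exonic) are
computed over clumped leads only, so one LD block cannot contribute many
correlated SNPs to a mean. |z| rather than signed z is aggregated so that
max ≥ mean holds and magnitude, not direction, is weighted. regulomeDB
categories are recoded monotonically (1a→7 down to 7→0 in half-steps,
higher = stronger regulatory evidence); any strictly monotone recoding
would serve, and the map is configurable. Genes hit only via eQTL/loops
have no resident SNP; their aggregates are computed over the linking SNPs.

## Predictor codings

`binary` (primary), `count` (number of implicated targets), and annotation
codings that combine a per-gene aggregate across a drug's implicated
targets with `max` (default; motivated by largest-effect weighting being
the one annotation that adds signal) or `mean`. How per-SNP annotations
should collapse to one drug-level scalar is genuinely underdetermined;
both aggregators are implemented and labeled, neither presented as
canonical. Annotation predictors are not standardized by default so
coefficients stay on their native scales; a z-scoring flag exists for
sensitivity analysis. Note that a value-0 annotation (e.g. a non-exonic
hit under `any_exonic`) can yield x2 = 0 for an implicated drug; the
"annotation zero iff binary zero" identity is exact only for positive-
valued annotations such as `max_abs_beta`.

## Fitting, separation, clustering

Newton/IRLS with step-halving, converged at score norm < 1e-8, max 100
iterations; Wald two-sided p from β₂/se₂ against the standard normal;
95% CI multiplier fixed at 1.959964; an LRT p is emitted for diagnostics.
With a handful of overlapping treatments, complete separation is a live
possibility and plain MLE then diverges silently toward infinite odds
ratios. A fit is declared separated when any |β| > 15, se₂ > 50, or Newton
fails to converge, and is then refit with Firth's Jeffreys-prior penalized
score (leverage-corrected score equations; finite under separation), with
covariance from the inverse Fisher information at the penalized optimum.
The fit path (`mle`/`firth`) is always reported, so both branches are
comparable. X₁ enters untransformed (target counts are integers); a
log(X₁) option exists because counts are right-skewed.

The cluster-robust variance (groups = drug-class labels) is the standard
sandwich A⁻¹BA⁻¹ with within-cluster score sums in the meat and **no**
small-sample correction, so singleton clusters reduce exactly to HC0.
Cluster-robust SEs are one defensible reading of "accounting for class";
a mixed-effects model would be another and is out of scope. Bonferroni
correction divides α by the number of disorders tested and reports
min(1, m·p) as the adjusted p.

## Permutation null

The implicated-gene set is replaced by a uniform without-replacement draw
of equal size from the full gene universe; observed hits' SNP support is
transplanted by a random one-to-one assignment so annotation codings stay
testable, while pLI follows the sampled gene. The empirical p uses the
add-one rule (1 + #as-extreme)/(n_perm + 1), two-sided on the Wald z;
degenerate permuted designs (constant x2) count as z = 0, a conservative
convention. Permuted genes are *not* matched on length or SNP density:
the hit set is replaced wholesale, so gene-length confounding does not
enter the permuted statistic; length-matched sampling would be the
refinement if permutation p's were to be compared across gene universes.
Defaults: 10,000 permutations for analyses, 200 in simulation studies.
Permuting indication labels instead of gene lists is a flag-level variant.
Degree-preserving rewiring of the drug–target graph is future work.

## Synthetic data

Two levels, both pure functions of (parameters, seed):

- **Design-level** (`gen_design_direct`): x1 ~ zero-truncated negative
  binomial (mean 8, dispersion 2 — right-skewed like real target counts),
  x2 ~ Bernoulli(0.1), y from the logistic model. Defaults β₀ = −2.0,
  β₁ = 0.04 give a ~15% treatment rate and ~120 x2=1 drugs at n = 1201,
  enough events for Wald inference to be in its asymptotic regime while
  staying sparse like the real design. Because the generative law and the
  fitted model coincide, this level supports exact type-I and recovery
  claims.
- **Full-stack** (`gen_genome` → `gen_sumstats` → `gen_drug_tables`):
  1000 non-overlapping genes on 4 chromosomes; 10,000 SNPs with uniform
  null p-values plus 20 planted GWS loci cycled through a chosen gene pool
  (p ~ U(1e-12, 0.99·5e-8), |β| ~ |N(0.05, 0.01²)|, z and se made mutually
  consistent with p); background planted SNPs placed mid-intergap ≥15 kb
  from genes so they cannot create proximity hits. Drug tables: 1201 drugs,
  ZTNB target counts, 40 treatments per disorder; treatment drugs have one
  target *replaced* by a pool gene with probability `pi_treat` (0.5
  default; 0.05 for non-treatments) — replacement keeps the X₁
  distribution identical across groups, so the planted effect loads on X₂
  only. The induced enrichment is therefore *empirical*, measured by
  brute-force 2×2 enumeration (`empirical_log_or`), never assumed.
  CADD ~ Gamma(2, 3), regulomeDB uniform, exonic ~ Bernoulli(0.05) are
  pragmatic annotation defaults; nothing downstream depends on their shape.

What the generator does **not** emulate: linkage disequilibrium (clumping
is exercised only through distances), allele frequencies, polygenic
effect-size architecture, or curation noise in indication tables. Passing
tests therefore validate the statistical machinery and its calibration,
not robustness to LD structure or database error in real data.

## Benchmark studies (tests + `scripts/acceptance.py`)

Reference sizes, chosen to make each study decisive at desk scale:
1,000 random 2×2 datasets for the contingency oracle (agreement < 1e-6
relative); 1,000 design-level null replicates at n = 1201 for type-I
(expect ≈ 0.05; the Wald test is known to run a shade conservative at ~20
events); 500 replicates with β₂ = log 5 for recovery (mean bias < 0.05,
coverage ≥ 93%); 500 full-stack null replicates × 200 permutations for
calibration (KS against uniform; the add-one p is discrete on a 1/201
grid, which the KS test tolerates at these sizes); 100 random instances
(≤200 genes, ≤500 SNPs) for exact mapping-oracle agreement plus the ±flank
boundary cases; 100 constructed separated datasets for Firth finiteness;
and 100 two-disorder runs (planted pi_treat = 0.9 vs null 0.1 = 0.1) for
discrimination.

## Known limitations

- Distance clumping is not LD clumping; in regions of long-range LD it
  will over-count independent loci.
- Promoters are strand-unaware (gene models carry no strand).
- The eQTL table is taken as pre-filtered; no tissue modeling.
- Wald inference is slightly conservative at very small overlap counts;
  the permutation p is the more trustworthy number there.
- Indication coding is binary; ordinal trial-phase coding is out of scope.
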