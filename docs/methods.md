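# Methods

This note documents the models, the defaults and their rationale, the
numerical choices, and what a green test does and does not establish.

## Screen scoring

Each cross yields counts in four balancer classes; with no lethality they
arrive 1:1:1:1.  Balancers carry a small viability cost, so the **largest**
balancer class is taken as the closest estimate of the expected class size
and the phenotype is

    survival proportion = knockdown count / max(CyO, Sb, double-balanced).

Choices:

* Proportions > 1 are retained with a logged warning, not truncated: the
  denominator is an estimate, and truncation would bias the downstream
  association phenotype.
* Strains with fewer than 200 scored flies are flagged, not dropped
  (threshold configurable).
* The per-strain chi-square is a 2-class test (knockdown vs largest
  balancer, 1:1 expectation, df = 1).  `mendelian_chisq` also accepts any
  class/ratio layout with df = #classes − 1.
* `screen_summary` regresses proportion on the largest-class count; a small
  R² is the sanity check that the phenotype is not driven by the denominator.

## Genotypes, filtering, relatedness

Inbred lines are coded 0/1 (homozygous reference/alternate); heterozygous
VCF calls are treated as missing with a logged count.  Variant filters:
biallelic only, MAF ≥ 0.05 (inclusive), missingness ≤ 0.2 (configurable).
Missing genotypes are mean-imputed per variant both for the relatedness
matrix and for association — the data are silent on the original handling,
and imputation keeps the strain set constant across variants.

The relatedness matrix is the **centered** (not variance-standardized) GRM
K = WWᵀ/p, W the per-variant mean-centered genotype matrix, p the variant
count.  Consequences used as test invariants: K1 = 0, K is PSD up to
roundoff, K is invariant to allele-label flips and to variant duplication,
and trace(K) = (n/p)·Σⱼ var(columnⱼ).

## Linear mixed model

    y = α + xβ + u + ε,   u ~ MVN(0, λτ⁻¹K),   ε ~ MVN(0, τ⁻¹Iₙ)

One eigendecomposition K = U D Uᵀ diagonalises the covariance; the
likelihood profiles over (α, τ) in closed form and λ is found by a 50-point
grid scan of log₁₀λ on [−5, 5] followed by bounded Brent refinement (the
profile likelihood can be multimodal).

**Criterion: REML by default, ML behind a switch.**  With a centered GRM the
ones vector is an exact null eigenvector of K, and the ML profile likelihood
then diverges like ½·log λ as λ → ∞ (the intercept absorbs the zero-eigen
coordinate exactly, so the weighted residual sum decays one power of λ
faster than the determinant grows for n−1 coordinates).  The REML
determinant penalty log|XᵀV⁻¹X| cancels the divergence and leaves an
interior optimum.  ML remains available (`method="ml"`) but will pin λ̂ at
the search bound on a sizable fraction of null datasets.

**Identifiability.**  With an unstructured panel K is close to a scaled
identity and λ is weakly identified: under the null its one-sided estimator
has roughly half its mass at 0 and a long positive tail (SE ≈ 0.3 at
n = 160).  Tests therefore check the median across seeds, not individual
estimates.

**Per-marker tests.**  The marker is rotated into the eigenbasis and (α, β)
estimated by weighted least squares with weights (λ̂dᵢ + 1)⁻¹.  In the
default approximate mode λ̂ comes from the null model and is reused for all
markers (the standard two-step scheme); `mode="exact"` re-optimises λ per
marker.  The approximation is accurate for moderate effects and degrades
when a single marker explains a large variance share — exactly the case the
exact mode exists for.  The residual variance in the Wald statistic uses
RSS/(n−2), not the ML divisor n, for small-sample calibration.

**Reference distribution.**  Wald p-values default to χ²(1), appropriate for
large panels; a t(n−2) reference (`reference="t"`) is provided for small
panels and is what the calibration tests use at n = 160, where it is exactly
calibrated for a Gaussian phenotype while χ²(1) is ~0.003 anticonservative
at the 0.05 level.

Both Bonferroni and Benjamini–Hochberg columns are emitted; neither is
declared canonical.  Monomorphic markers are skipped with a reason code.

## Variant-to-gene assignment

Gene body = transcript span including UTRs; a variant is assigned to every
gene whose body it lies in or is within 1 kb of (window inclusive at exactly
1000 bp).  Upstream/downstream is resolved by strand.  Unique assignment
keeps the highest-priority category (exon > UTR > intron >
upstream/downstream, the last two equal), then smaller distance, then
lexicographic gene id (logged).  The candidate table uses the multi-map
assignments, so a variant near two genes credits both; this is configurable
in spirit by consuming `unique_assign` output instead.

## Gene-set enrichment

Per-gene score: −log₁₀ of the gene's best (minimum) variant p-value, ranked
descending with gene-id tie-breaks.  The enrichment score is the signed
maximum deviation of the weighted running sum: +score^w/Σ_set score^w at
members (w = 1 by default), −1/(N−k) otherwise; the walk ends at 0 by
construction.  The p-value permutes set-membership labels over the ranked
list, p = (1 + #{ES_perm ≥ ES_obs})/(n_perm + 1); phenotype permutation
would require re-running the association scan per permutation and is not
used.  Reporting filter: size ≥ 5 (inclusive), ES > 0.25 (strict),
p < 0.05 (strict).

Note that under the null the *weighted* ES of a random set is positively
biased when scores are dispersed (the reason normalized enrichment scores
exist elsewhere; NES is out of scope here).  The zero-mean symmetry property
holds for the exchangeable equal-score null, and the permutation p-value is
calibrated regardless because the null distribution is simulated under the
same weighting.

## Evolutionary rate covariation

Inputs are per-gene branch-length vectors (substitutions/site) on a fixed
species-tree branch set per clade; genes may be absent from clades.
Relative rates are the residuals of an ordinary least-squares fit of
log branch lengths on log clade-average branch lengths (intercept included),
so a gene-wide rate multiplier is absorbed and only branch-specific
deviations remain.  Zero-length branches are floored at a 10⁻⁶ pseudocount
*before* the log — flooring rather than adding keeps the transform exactly
scale-equivariant above the floor, so multiplying a gene's lengths by any
positive constant leaves its relative rates unchanged.

For each gene pair and clade with ≥ 8 shared branches (configurable),
Pearson correlation of relative rates gives a one-sided p for r > 0 via
t = r√((n−2)/(1−r²)).  The integrated score sums −log₁₀p over the clades
where both genes are present (absent clades contribute nothing); hits exceed
2, i.e. a combined-evidence scale where a single clade at p = 0.01 suffices.
Log base 10 is the default and configurable.

## Overlap enrichment

Upper-tail hypergeometric tests, P(X ≥ k) including the observed value.
The gene universe is a required explicit argument and is never inferred:
overlap p-values are meaningless without an agreed sampling frame.
Benjamini–Hochberg q-values use the standard step-up procedure
(statsmodels backend, checked against a longhand implementation).

## Synthetic data

The generators state one world and the tests measure it; parameters are not
tuned to outcomes.

* **Genotypes**: ancestral allele frequencies uniform on `maf_range`
  (default 0.1–0.5); with subpopulations, per-subpopulation frequencies are
  Balding–Nichols beta draws at drift parameter `fst_like_drift`, and lines
  fix one allele Bernoulli(subpop frequency) — fully inbred 0/1 calls.
* **Phenotypes**: y = clamp₀¹(μ + Σβⱼxⱼ + g + e), μ = 0.5.  `polygenic_var`
  and `noise_var` are fractions of `total_var`, the overall phenotypic
  variance on the proportion scale.  `total_var` defaults to 0.04
  (sd 0.2): a proportion bounded in [0, 1] cannot have unit variance, and
  sd 0.2 around 0.5 reproduces the wide 0–1 phenotype spread such screens
  show while keeping clamping rare (clamping events are logged).  g is
  multivariate normal with covariance proportional to the realized GRM,
  scaled so its marginal variance is `polygenic_var × total_var`.
* **Cross counts**: balancer classes independent Poisson(n_expected) —
  rather than one multinomial — so the "largest class" estimator is
  genuinely exercised; knockdown class Binomial(n_expected, survival).
* **Gene models**: one chromosome (coordinate logic is identical per
  chromosome), non-overlapping genes with 5′UTR/exon/intron/exon/3′UTR
  structure and > 2 kb intergenic gaps so the ±1 kb window is informative.
* **Rate trees**: random rooted binary species tree per clade; gene branch
  length = clade expectation × lognormal gene multiplier ×
  exp(branch deviation).  Covarying genes share one latent deviation vector
  per clade (sd `latent_rate_sd` = 0.5, a visible-but-not-degenerate signal
  chosen once) plus independent noise of sd `rate_sd`; independent genes
  get deviations of the same total sd, so the group differs only in
  correlation structure.  Genes are present per clade with probability 0.9.

**What the generators do not emulate**: linkage disequilibrium between
variants (variants are independent given the subpopulation), multiple
chromosomes, X-linkage, selection, genotyping error, shared phylogenetic
autocorrelation along branches, or realistic gene-set size distributions.
A green recovery test therefore establishes that the statistics behave
correctly under their own assumptions — not that the screen's biological
findings reproduce, which would require the original panel genotypes and
counts.

## Reproducibility

All randomness flows from explicit seeds (config `seed`, per-generator
offsets); reruns are byte-identical, and the pipeline writes a
`provenance.json` with parameters, library versions and SHA-256 hashes of
every output.  Generated VCF/GFF3/GMT/Newick files round-trip exactly:
Newick branch lengths are serialized at 17 significant digits and read back
in string order (postorder over non-root nodes), so vectors survive a
write/read cycle bit for bit.
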