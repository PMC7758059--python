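# modscreen

Quantitative analysis of dominant-modifier screens run on panels of inbred
reference strains (DGRP-style designs), aimed at geneticists mapping
modifiers of a disease-gene knockdown phenotype.

In such a screen, a knockdown allele is crossed onto ~160 fully inbred,
fully sequenced strains; offspring segregate into four balancer-marked
classes expected 1:1:1:1, and the screen phenotype is the survival
proportion of the knockdown class.  `modscreen` implements every
computational stage downstream of the fly bottles:

1. **Screen scoring** — survival proportion = knockdown count / largest
   balancer class (the largest class being the least lethality-distorted
   estimate of the expected class size), with Pearson chi-square tests
   against Mendelian ratios.
2. **Mixed-model GWAS** — variants filtered at MAF ≥ 0.05 (biallelic only),
   a centered genetic relatedness matrix K = WWᵀ/p, and the linear mixed
   model

   y = α + xβ + u + ε,  u ~ MVN(0, λτ⁻¹K),  ε ~ MVN(0, τ⁻¹Iₙ)

   fitted by one eigendecomposition of K plus a 1-D REML search in λ;
   per-variant Wald tests reuse the null λ (approximate mode) or refit it
   (exact mode).
3. **Candidate genes** — variants with p < 10⁻⁵ assigned to genes within
   ±1 kb of the gene body; multi-gene variants resolved by the priority
   exon > UTR > intron > up/downstream; genes ranked by best variant p.
4. **Gene-set enrichment** — per-gene score −log₁₀(best p), weighted
   Kolmogorov–Smirnov running-sum enrichment score, gene-label permutation
   p-values, and the reporting filter (≥5 genes, ES > 0.25, p < 0.05).
5. **Evolutionary rate covariation (ERC)** — per-clade branch-specific
   relative rates (log-scale residuals against the clade-average branch
   lengths), one-sided Pearson correlation p-values against a focal gene,
   integrated across clades as Σ −log₁₀ p, hits at score > 2.
6. **Overlap enrichment** — upper-tail hypergeometric tests of gene-list
   overlaps with Benjamini–Hochberg q-values.
7. **Synthetic data** — seeded generators for all of the above (structured
   inbred genotypes, bounded survival phenotypes with planted causal and
   polygenic components, balancer cross counts, gene models, gene sets, and
   rate trees with a planted covarying group), so the whole pipeline is
   testable end to end with no external downloads.

See `docs/methods.md` for model details, parameter defaults, and what the
synthetic generators do and do not emulate.

## Worked example

Run the whole synthetic pipeline from one config file:

```sh
cat > demo.yaml <<EOF
gsea_n_perm: 500
sim:
  n_strains: 160
  n_variants: 5000
  n_genes: 200
  n_causal: 1
  causal_effects: [0.4]
  polygenic_var: 0.1
  noise_var: 0.2
  seed: 11
EOF
modscreen run-all --config demo.yaml --seed 11 --outdir demo_out
```

prints

```
pipeline complete: 1 significant variants, 1 candidate genes, 33 ERC hits -> demo_out
```

meaning: one variant cleared p < 10⁻⁵ in the mixed-model scan, it maps to
one candidate gene, and 33 genes have an integrated rate-covariation score
above 2 with the focal gene.  The candidate table shows the planted modifier
recovered as the top (only) hit:

```
$ head -2 demo_out/candidate_genes.tsv
rank  gene_id    best_p                 n_variants  categories  variant_ids
1     gene_0099  5.187140406614659e-44  1           intron      2L_993909
```

and `demo_out/erc.tsv` ranks the same gene first by integrated score
(it is planted in the covarying group with the focal gene).  Scoring the
simulated cross counts alone:

```
$ modscreen score-screen --counts demo_out/cross_counts.tsv --out survival.tsv
160 strains; proportions 0.196-1.011 (mean 0.531); R^2 vs largest class 0.014 (p=0.134)
```

The proportions span is the screen phenotype range; the small R² against the
largest balancer-class count checks that the phenotype is not driven by the
denominator.

Each stage is also available separately (`simulate`, `score-screen`, `grm`,
`gwa`, `annotate`, `gsea`, `erc`, `enrich`), and every subcommand is a thin
wrapper over an importable function (`modscreen.lmm.run_gwa`,
`modscreen.gsea.enrichment_score`, ...).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full synthetic pipeline from scratch under the given seed —
generating the panel, scoring the screen, running the mixed-model scan,
candidate-gene mapping, gene-set enrichment, rate covariation, and the
overlap tests — writing per-stage outputs next to the JSON manifest.
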