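# prsblend

Heterogeneity-aware blending of two related GWAS summary-statistic
datasets — and of their LD reference panels — as a pre-processing step
for polygenic risk scores (PRS).

## The problem

A PRS for a target trait and population is limited by the sample size
of the matching ("proximal") GWAS. A related GWAS — the same disease in
another ancestry, or a genetically correlated disease in the same
ancestry (an "adjunct" study) — carries transferable information, but
only where the two studies' true effects agree. Meta-analysing
everything imports bias at the SNPs whose effects genuinely differ;
ignoring the adjunct study wastes power everywhere else. `prsblend`
resolves this per SNP.

## The method

For each SNP shared by the two studies, with effect estimates
&beta;&#770;₁ (SE &sigma;₁) and &beta;&#770;₂ (SE &sigma;₂):

1. **Adjusted Cochran's Q.** Heterogeneity of effect is tested with

   Q = (&beta;&#770;₁ − &beta;&#770;₂)² / (&sigma;₁² + &sigma;₂² − 2&rho;&sigma;₁&sigma;₂),  Q ~ &chi;²₁

   where &rho; is the correlation between the two estimators induced by
   shared subjects (typically a common control pool), computed as a
   closed-form function of the case/control counts and the shared
   counts.

2. **Local FDR as blending weight.** The Q p-values are converted to
   the local false discovery rate &pi; = Pr(H₀ | p) with a two-groups
   empirical-Bayes estimator (Storey-type &pi;₀ smoother plus a
   probit-scale kernel density estimate). High &pi; = no heterogeneity
   evidence; low &pi; = the effects differ.

3. **Blend.** With &beta;&#770;₁₂ the fixed-effect inverse-variance
   meta-analysis estimate,

   &beta;&#770;_blend = (1 − &pi;) &beta;&#770;₁ + &pi; &beta;&#770;₁₂

   together with its standard error (propagated through the meta and
   blend steps, including the &rho; covariance), a two-sided p-value
   and an effective sample size — a complete summary-statistics file
   any downstream PRS tool can consume. SNPs absent from the adjunct
   study pass through with their proximal values.

4. **Blended LD reference.** Because the blended estimator mixes two
   studies with generally different LD (e.g. different ancestries), the
   package also derives the matching per-block SNP×SNP correlation
   matrix of the blended estimates from the two input panels and the
   per-SNP weights.

The package additionally ships a full paired-trait simulator
(LD-blocked genotypes, controllable effect-sharing architecture, shared
controls) and a scoring/evaluation harness, so the whole pipeline can be
validated end-to-end without external data.

## Worked example

```sh
prsblend simulate --seed 3 --out-dir run --m-snps 400 --n-causal 40 \
    --n-total 600 --n-test 200
prsblend blend --proximal run/proximal.sumstats.tsv \
    --adjunct run/adjunct.sumstats.tsv --out run/blended.tsv \
    --skip-qc --audit
prsblend ldblend --panel1-dir run/ld_panel1 --panel2-dir run/ld_panel2 \
    --blended run/blended.tsv --out-dir run/ld_blended
prsblend score --genotypes run/proximal --weights run/blended.tsv \
    --out run/profile.tsv
prsblend evaluate --profile run/profile.tsv \
    --phenotype run/proximal.pheno.tsv
```

The `blend` step logs its progress to stderr:

```
stage=read proximal_rows=400 proximal_dropped=0 adjunct_rows=400 adjunct_dropped=0
stage=harmonize shared=400 proximal_only=0 flipped=0 strand_ambiguous=0 allele_mismatch=0
stage=rho rho=0.000000
stage=blend rows=400 out=run/blended.tsv
```

and the final command prints the squared correlation between the PRS
and the phenotype: `r2	0.465078`. (This scores the proximal *training*
cohort itself — 300 subjects, 40 causal SNPs, h² = 0.5 — so the value
is in-sample and optimistic; the test suite's predictive comparisons
always score an independent cohort.) `run/blended.tsv` is a
canonical sumstats TSV (`SNP CHR BP A1 A2 AF B SE P N`) whose audit
columns (`lFDR`, `Q`, `Qpval`, `SE_1`, `SE_2`, `source`) show, per SNP,
the heterogeneity evidence and the weight the blend used.

The same operations are available as a library
(`prsblend.harmonize`, `prsblend.cochran_q`, `prsblend.estimate_lfdr`,
`prsblend.blend_pair`, `prsblend.blend_ld_genome`, ...).

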