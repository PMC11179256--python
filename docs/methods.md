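# Methods

This note documents the statistical model behind `prsblend`, the
defaults and numerical choices, what the synthetic-data generator does
and does not emulate, and the known limitations.

## Model

Two GWASs of related traits (or one trait in two populations) report
per-SNP marginal effect estimates b1, b2 with standard errors s1, s2.
The studies may share subjects — most commonly a control pool — which
makes the estimation errors correlate with a coefficient rho that
depends only on sample sizes.

**Overlap correlation.** For case-control studies with c_i cases, u_i
controls and m_c / m_u shared cases / controls,

    rho = [ m_c sqrt(u1 u2 / (c1 c2)) + m_u sqrt(c1 c2 / (u1 u2)) ]
          / sqrt((c1+u1)(c2+u2))

clipped to [0, 1]; for quantitative traits rho = n_shared/sqrt(n1 n2).
This is the overlapping-subjects estimator-correlation for log-odds
effect estimates; the implementation is accepted by a Monte-Carlo
oracle (null log-OR pairs with a shared binomial control pool), not by
citation. For the design with 5,400 / 4,647 cases and 10,308 shared
controls the formula gives 0.3268 and the simulation 0.326 ± 0.007.

**Heterogeneity test.** Per SNP,

    Q = (b1 - b2)^2 / (s1^2 + s2^2 - 2 rho s1 s2),   Q ~ chi2(1).

Because shared subjects induce *positive* error correlation, part of
the error cancels in b1 − b2 and the correct denominator is smaller
than s1² + s2²: the adjustment sharpens the test. Consequently,
running the test with rho = 0 on shared-control data is conservative
(it under-rejects); the adjusted test holds its nominal level exactly
in simulation. rho is a single genome-wide scalar (it is a function of
sample sizes only, matching the test's usage); per-SNP overlap
correction is out of scope.

**Blending weight.** The Q p-values enter a standard two-groups model:
p ~ pi0 * Uniform + (1 - pi0) * f1. The blending weight is the local
false discovery rate pi(p) = Pr(H0 | p), estimated as:

- pi0 by the Storey smoother: pi0(l) = #{p > l}/(m(1-l)) on the grid
  l = 0.05, 0.10, ..., 0.95, a least-squares cubic fit (the
  high-smoothing limit of a cubic smoothing spline — deterministic and
  free of knot-placement choices), evaluated at l = 0.95, clipped to
  (0, 1]. A fixed-lambda estimator is available for small panels
  (< 100 SNPs, where the smoother is unreliable).
- the marginal density on the probit scale x = Phi^{-1}(p), where the
  null density is exactly standard normal, by a Gaussian KDE with
  Silverman bandwidth; lfdr = pi0 phi(x)/f(x), clipped to [0, 1].
- a cumulative-maximum pass in increasing p enforces monotonicity:
  larger p (less heterogeneity evidence) can never receive less weight
  on the meta-analysis. p-values of exactly 1 (Q = 0) are retained and
  clamped to 1 - 1e-12 before the probit; p = 0 is clamped to 1e-12.

The estimator is deterministic given its inputs. Degenerate input with
zero spread in the p-values (e.g. blending a dataset with an exact copy
of itself, where every Q = 0) falls back to pi = 1 everywhere — the
full meta-analysis — since there is no heterogeneity gradient to learn.

**Blend and derived statistics.** With w_i = 1/s_i^2,

    b12 = (w1 b1 + w2 b2)/(w1 + w2)
    Var(b12) = (w1^2 s1^2 + w2^2 s2^2 + 2 w1 w2 rho s1 s2)/(w1+w2)^2
    b_blend = (1 - pi) b1 + pi b12
    Var(b_blend) = (1-pi)^2 s1^2 + pi^2 Var(b12)
                   + 2 pi (1-pi) (w1 s1^2 + w2 rho s1 s2)/(w1+w2)

pi is treated as a fixed plug-in weight; the noise of estimating pi is
ignored in the variance (a documented limitation — the SE is therefore
slightly anti-conservative at SNPs where pi is poorly determined). The
whole variance chain is validated against a Monte-Carlo oracle over a
(s1, s2, rho, pi) grid at 1e6 draws per cell, within 2 %.

Derived outputs per SNP: two-sided normal p-value; effective sample
size N = 1/(2 AF (1-AF) SE^2) capped at N1 + N2 − n_shared (so
downstream tools that scale by N see the variance gain; a linear
(1-pi) N1 + pi (N1+N2) convention is selectable); the reported AF is
the proximal study's, since the target population is proximal. SNPs
missing from the adjunct study are passed through unchanged and
flagged `proximal_passthrough`.

**Blended LD.** Writing b_blend_i = a_i b1_i + c_i b2_i with
a_i = (1-pi_i) + pi_i w1_i/(w1_i+w2_i) and c_i = pi_i w2_i/(w1_i+w2_i),
and using the sampling covariances Cov(bk_i, bk_j) = Rk_ij sk_i sk_j,

    Cov_ij = a_i a_j R1_ij s1_i s1_j + c_i c_j R2_ij s2_i s2_j
             + rho (a_i c_j s1_i s2_j + a_j c_i s1_j s2_i) Rbar_ij

normalized to a correlation matrix. The cross-study LD term uses
Rbar = (R1 + R2)/2 because the true cross-panel LD is unobservable from
two marginal panels; the term vanishes at rho = 0, which is exactly
the cross-ancestry regime where the two panels differ most, so the
approximation only matters for shared-subject cross-trait analyses
where the panels nearly coincide anyway. Matrices are repaired to
positive semi-definite by eigenvalue clipping at 0 with tolerance 1e-8
and diagonal re-normalization (chosen over nearest-correlation
iteration for speed; the blend of two PSD correlation matrices is
nearly PSD already, so the repair is a numerical safeguard). Weights
use per-SNP SEs, matching the per-SNP character of the blend. The
formula is accepted by Monte-Carlo oracles (both jointly normal
estimator draws and a genotype-level two-population simulation) within
0.05 on the correlation scale.

## Input handling

Canonical sumstats columns: `SNP CHR BP A1 A2 AF B SE P N` (A1 =
effect allele, positions 1-based; LD-block manifest intervals are
0-based half-open). Indels and multi-allelic rows are rejected at read
time; the method operates on biallelic SNPs. Harmonization matches by
SNP id, aligns the adjunct to the proximal allele pair directly,
reversed (beta sign flip, AF reflection) or via strand complement, and
drops strand-ambiguous (A/T, C/G) pairs by default since their
orientation cannot be resolved from summary data. All exclusions are
counted, never silent.

The summary-statistic QC filter compares sd_ss = 2/sqrt(N SE^2) with
sd_g = sqrt(2 AF (1-AF)) and removes SNPs with sd_ss < 0.5 sd_g,
sd_ss > sd_g + 0.1, sd_ss < 0.1, or sd_g < 0.05 — the standard
summary-data consistency screen used ahead of PRS construction. The
panel-retention filter keeps a SNP if it is in a supplied reference
panel (e.g. HapMap3) *or* its heterogeneity lFDR falls below a
threshold, so off-panel SNPs that differentiate the two traits can be
rescued.

## The simulator

The generator emulates the paired-study design at desk scale:

- **Effects.** n_causal = 1,000 causal SNPs per trait among
  m = 10,000; heritability h² = 0.5 per trait. A fraction P of causal
  SNPs is shared with within-SNP effect correlation `cor` (bivariate
  normal); the rest are trait-specific and independent. The genome-wide
  genetic correlation is rG = P·cor, and the generator enforces this
  composition identity. Each variance component is rescaled exactly, so
  sum(beta²) = h² per trait and the shared/specific/penetrant partition
  is exact per replicate. Optionally k = 5 high-penetrance SNPs carry
  exactly 5 % of each trait's non-shared heritability as fixed
  alternating-sign effects (fixed rather than drawn so the share is
  exact; they model variants like *NOD2* that strongly differentiate
  related diseases).
- **Genotypes.** Blocks of 20 SNPs; one MAF per block drawn uniform on
  (0.05, 0.5); within-block dosage LD follows an AR(1) profile with
  decay 0.8. Dosages are sums of two thresholded-Gaussian haplotypes
  (Hardy-Weinberg); the latent correlation is inverted per lag through
  the tetrachoric-style relation (Owen's-T closed form + Brent root
  finding, cached) so the *realized dosage* LD matches the requested
  profile within ±0.05. Per-block constant MAF keeps this inversion
  cacheable. A second ancestry reuses the same SNPs with jittered MAFs
  and its own LD decay.
- **Cohorts.** n_total = 4,000 training subjects split
  proximal/adjunct (default 50/50; 40/60 and 20/80 are the other study
  splits of interest), plus an independent 1,000-subject test cohort.
  These sizes are the package's desk-scale default for the simulation
  studies; the generator accepts larger designs.
- **Phenotypes.** y = G_std beta + e, with var(e) set from the
  *realized* genetic variance so realized h² is tight around the
  target (the acceptance run measures 0.499 over 20 replicates).
- **GWAS.** Per-SNP simple linear regression on standardized dosages
  (t p-values, n−2 df). A binary mode draws allele counts for
  case/control pools — with a shared control pool entered into both
  studies — and returns 2×2-table log-OR estimates; this is the route
  that exercises rho. A fast analytic path draws the paired marginal
  estimators directly from their joint normal sampling law
  (mean R beta, covariance R/n, cross-study rho R/sqrt(n1 n2)) and is
  moment-checked against the individual-level route.

What the generator does **not** emulate: realistic MAF/LD spectra
(blocks are AR(1) with constant MAF, real LD is irregular and
long-tailed), cross-block LD, population structure or relatedness,
binary phenotypes with covariates, and imputation noise. Passing tests
therefore demonstrate the *method's* internal correctness and its
qualitative behaviour under controlled sharing architectures, not
performance on real biobank data.

## Predictive comparison harness

The comparison scorer applies the same profile-scoring convention
(average of effect-allele dosage × weight over used SNPs, PLINK-style;
missing dosages mean-imputed from in-sample AF) to three weight sets —
proximal-only, fixed-effect meta, blended — on an independent test
cohort, reporting r² (or rank AUC for binary labels). At the desk
scale above, over 20 seeded replicates: with concentrated sharing
(P = 0.5, cor = 1.0, five penetrant SNPs) the blend outperforms both
baselines (mean r² 0.133 vs 0.117 meta / 0.126 proximal); with diffuse
sharing (P = 1, cor = 0.5) the blend is at least as good as the
meta-analysis. A minimal per-block ridge re-weighting
((R + λI)^{-1} b, default λ = 0.2) exercises the blended LD panel
end-to-end: in a two-ancestry simulation where the adjunct study
dominates power, using the blended panel beats using the proximal
panel alone.

## Numerical and design choices

- p-values are computed on the raw adjusted Q ("adjusted" = the rho
  term, not a multiplicity adjustment); no multiple-testing correction
  enters the weight, by construction of the two-groups model.
- rho must lie in [0, 1); a non-positive Q denominator raises a hard
  error naming the SNP index, since it implies an invalid rho/SE
  combination.
- Blended p-values are two-sided normal (GWAS convention, no df
  correction); p is floored at the smallest positive double.
- pi = 0 and pi = 1 are exact fast paths: the blend returns the
  proximal values / the meta values bit-identically, and the LD blend
  returns panel 1 exactly at pi = 0.
- Scoring matches weights to genotypes by SNP id and allele pair
  (direct or swapped); unmatched or irreconcilable rows are dropped
  from the score, and zero overlap is a hard error.
- All randomness flows through `numpy.random.Generator` seeds;
  repeated runs are bit-identical. CLI runs echo their full scenario
  configuration to the output directory.

## Limitations

- The lFDR is a genome-wide empirical-Bayes quantity: with few SNPs
  (< ~1,000) the density estimate is coarse and the weights noisy; the
  small-panel fallback is deliberately conservative.
- The blended SE ignores estimation noise in pi and in rho.
- The LD blend's cross-study term is an approximation (see above);
  exact only when the panels coincide or rho = 0.
- The simulator's Gaussian-threshold LD is block-diagonal by
  construction; leakage of causal signal across block boundaries, which
  real data has, is absent.
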