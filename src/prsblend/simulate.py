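"""Paired-trait GWAS simulator with controllable effect sharing.

The generator emulates the study design the blending method targets:
two GWASs of related traits (or of one trait in two populations) whose
true per-SNP effects are partially shared. A genome of ``m_snps``
common variants is organized into LD blocks; ``n_causal`` SNPs per
trait carry effects, of which a fraction ``shared_fraction`` (P) is
shared between the traits with within-SNP effect correlation
``shared_effect_cor`` (cor), so the genome-wide genetic correlation is
rG = P * cor -- the *composition* of a given rG between concentrated
(small P, high cor) and diffuse (P=1, low cor) sharing is the design
axis of interest. Optionally a handful of high-penetrance SNPs carry a
fixed share of each trait's non-shared heritability, emulating variants
that strongly differentiate otherwise related diseases.

Genotypes are drawn block-wise from a latent Gaussian threshold model:
within a block, haplotype alleles are indicators of a correlated
Gaussian vector crossing the frequency threshold, and dosages are sums
of two independent haplotypes (Hardy-Weinberg). The latent correlation
is numerically corrected per lag so the *realized dosage* LD matches
the requested AR(1) profile; cross-block LD is zero by construction.
The minor-allele frequency is drawn per block (one value shared by the
block's SNPs), which keeps the threshold correction cacheable.

Quantitative phenotypes are y = G_std * beta + e with the noise
calibrated against the realized genetic variance of the cohort, so the
realized narrow-sense heritability is tight around the target h2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats, optimize

from .heterogeneity import StudyOverlap
from .ld_blend import LDBlock, LDBlockSet


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of one paired-study simulation.

    Defaults follow the simulation design the acceptance properties
    are stated for: heritability 0.5 per trait from 1,000 causal SNPs
    among 10,000, desk-scale cohorts of 4,000 subjects split evenly
    between the proximal and adjunct studies, an rG-0.5 composition,
    and AR(1) LD within 20-SNP blocks.
    """

    m_snps: int = 10_000
    n_causal: int = 1_000
    h2: float = 0.5
    shared_fraction: float = 0.5  # P: fraction of causal SNPs shared
    shared_effect_cor: float = 1.0  # cor: effect correlation at shared SNPs
    rg_target: float | None = None  # checked against P*cor when given
    penetrant_snps: int = 0
    penetrant_h2_fraction: float = 0.05  # of the non-shared heritability
    n_total: int = 4_000
    split: float = 0.5  # proximal share of n_total
    n_test: int = 1_000
    n_shared_controls: int = 0
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 20
    ar1_rho: float = 0.8  # within-block dosage LD decay, proximal ancestry
    ar1_rho_adjunct: float | None = None  # set for two-ancestry mode
    maf_jitter_adjunct: float = 0.0  # +- uniform MAF shift, two-ancestry mode
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError("h2 must lie in [0, 1]")
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ValueError("shared_fraction must lie in [0, 1]")
        if not (-1.0 <= self.shared_effect_cor <= 1.0):
            raise ValueError("shared_effect_cor must lie in [-1, 1]")
        if self.n_causal > self.m_snps:
            raise ValueError("n_causal exceeds m_snps")
        if self.rg_target is not None:
            implied = self.shared_fraction * self.shared_effect_cor
            if abs(implied - self.rg_target) > 0.02:
                raise ValueError(
                    f"infeasible composition: P*cor = {implied:.3f} but "
                    f"rg_target = {self.rg_target}"
                )
        if self.penetrant_snps > 0:
            n_specific = self.n_causal - round(self.shared_fraction * self.n_causal)
            if n_specific < self.penetrant_snps:
                raise ValueError(
                    "penetrant SNPs require at least that many trait-specific "
                    "causal SNPs (shared_fraction < 1)"
                )

    @property
    def rg(self) -> float:
        return self.shared_fraction * self.shared_effect_cor

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrueEffects:
    """True per-SNP effects (standardized-genotype scale) for both traits."""

    beta1: np.ndarray
    beta2: np.ndarray
    labels: np.ndarray  # 'null' / 'shared' / 'trait1_only' / 'trait2_only' / 'penetrant1' / 'penetrant2'

    @property
    def causal_mask(self) -> np.ndarray:
        return self.labels != "null"

    def empirical_rg(self) -> float:
        """Pearson correlation of the paired true effects over all causal
        SNPs (union of SNPs causal in either trait)."""
        m = self.causal_mask
        return float(np.corrcoef(self.beta1[m], self.beta2[m])[0, 1])

    def to_frame(self, snp_ids) -> pd.DataFrame:
        return pd.DataFrame(
            {"SNP": snp_ids, "beta1": self.beta1, "beta2": self.beta2, "label": self.labels}
        )


def _scale_to(v: np.ndarray, target_ss: float) -> np.ndarray:
    ss = float(np.sum(v**2))
    if ss == 0.0:
        return v
    return v * np.sqrt(target_ss / ss)


def draw_effects(
    scenario: SimulationScenario, rng: np.random.Generator | None = None
) -> TrueEffects:
    """Draw true effect vectors for both traits under the scenario.

    Shared causal SNPs get bivariate-normal effects with correlation
    ``shared_effect_cor``; trait-specific causal SNPs get independent
    effects; optional penetrant SNPs get fixed alternating-sign effects
    carrying exactly ``penetrant_h2_fraction`` of the non-shared
    heritability. Each variance component is rescaled exactly, so per
    trait sum(beta^2) = h2 and the partition across shared / specific /
    penetrant components is exact by construction.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    m, nc = scenario.m_snps, scenario.n_causal
    P, cor, h2 = scenario.shared_fraction, scenario.shared_effect_cor, scenario.h2

    n_shared = round(P * nc)
    n_spec = nc - n_shared
    need = n_shared + 2 * n_spec
    idx = rng.choice(m, size=need, replace=False)
    shared_idx = idx[:n_shared]
    spec1_idx = idx[n_shared : n_shared + n_spec]
    spec2_idx = idx[n_shared + n_spec :]

    beta1 = np.zeros(m)
    beta2 = np.zeros(m)
    labels = np.full(m, "null", dtype=object)

    h2_shared = P * h2
    h2_spec = (1.0 - P) * h2

    if n_shared > 0:
        cov = np.array([[1.0, cor], [cor, 1.0]])
        draws = rng.multivariate_normal([0.0, 0.0], cov, size=n_shared)
        beta1[shared_idx] = _scale_to(draws[:, 0], h2_shared)
        beta2[shared_idx] = _scale_to(draws[:, 1], h2_shared)
        labels[shared_idx] = "shared"

    k = scenario.penetrant_snps
    for trait, spec_idx, beta in ((1, spec1_idx, beta1), (2, spec2_idx, beta2)):
        if n_spec == 0:
            continue
        if k > 0:
            pen_idx = spec_idx[:k]
            poly_idx = spec_idx[k:]
            h2_pen = scenario.penetrant_h2_fraction * h2_spec
            pen = np.sqrt(h2_pen / k) * np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
            beta[pen_idx] = pen
            labels[pen_idx] = f"penetrant{trait}"
            beta[poly_idx] = _scale_to(rng.standard_normal(len(poly_idx)), h2_spec - h2_pen)
            labels[poly_idx] = f"trait{trait}_only"
        else:
            beta[spec_idx] = _scale_to(rng.standard_normal(n_spec), h2_spec)
            labels[spec_idx] = f"trait{trait}_only"

    return TrueEffects(beta1=beta1, beta2=beta2, labels=labels)


# ---------------------------------------------------------------------------
# genotypes: latent Gaussian threshold blocks


@lru_cache(maxsize=100_000)
def _latent_corr(target: float, maf: float) -> float:
    """Latent Gaussian correlation giving the requested dosage correlation.

    Dosages are sums of two thresholded-Gaussian haplotypes, so the
    dosage correlation equals the correlation of the allele indicators,
    which is attenuated relative to the latent correlation. Inverts the
    tetrachoric-style relation numerically.
    """
    if abs(target) < 0.02:
        return target
    t = stats.norm.ppf(maf)
    pq = maf * (1.0 - maf)

    def dosage_corr(r: float) -> float:
        # P(Z1<t, Z2<t; r) via Owen's T (equal thresholds, t < 0 or t = 0)
        from scipy.special import owens_t

        p11 = stats.norm.cdf(t) - 2.0 * owens_t(t, np.sqrt((1.0 - r) / (1.0 + r)))
        return (p11 - maf * maf) / pq

    f = lambda r: dosage_corr(r) - target
    lo, hi = (0.0, 0.9999999) if target > 0 else (-0.9999999, 0.0)
    return float(optimize.brentq(f, lo, hi, xtol=1e-8))


@dataclass
class GenotypeData:
    """A cohort's dosage matrix with SNP and sample sidecars."""

    dosages: np.ndarray  # (n_samples, m_snps) int8 in {0,1,2}
    snps: pd.DataFrame  # SNP CHR BP A1 A2 MAF
    sample_ids: list[str]
    block_bounds: list[tuple[int, int]]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def m_snps(self) -> int:
        return self.dosages.shape[1]

    def standardized(self, cols: slice | np.ndarray | None = None) -> np.ndarray:
        """Column-standardized dosages (realized mean 0, SD 1) as float64."""
        g = self.dosages if cols is None else self.dosages[:, cols]
        g = g.astype(np.float64)
        mu = g.mean(axis=0)
        sd = g.std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        return (g - mu) / sd


@dataclass
class Population:
    """Shared genome definition from which cohorts are sampled.

    Holds the per-block MAF, the target dosage LD profile and the
    Cholesky factor of the (threshold-corrected) latent correlation, so
    that any number of cohorts with identical SNPs and LD can be drawn.
    """

    scenario: SimulationScenario
    mafs: np.ndarray  # per SNP (constant within block)
    block_bounds: list[tuple[int, int]]
    target_R: list[np.ndarray]  # dosage-scale LD per block
    _chol: list[np.ndarray] = field(repr=False, default_factory=list)
    snps: pd.DataFrame | None = None

    def ld_panel(self) -> LDBlockSet:
        """The population's LD reference (target dosage correlations)."""
        blocks = []
        for bi, (lo, hi) in enumerate(self.block_bounds):
            ids = list(self.snps["SNP"].iloc[lo:hi])
            blocks.append(
                LDBlock(
                    block_id=f"b{bi:04d}",
                    chrom="1",
                    start=lo,
                    end=hi,
                    snp_ids=ids,
                    matrix=self.target_R[bi].copy(),
                )
            )
        return LDBlockSet(blocks=blocks)

    def sample(self, n: int, rng: np.random.Generator, prefix: str = "s") -> GenotypeData:
        """Draw a cohort of n individuals."""
        m = self.scenario.m_snps
        dos = np.empty((n, m), dtype=np.int8)
        for (lo, hi), L in zip(self.block_bounds, self._chol):
            k = hi - lo
            t = stats.norm.ppf(self.mafs[lo])
            z1 = rng.standard_normal((n, k)) @ L.T
            z2 = rng.standard_normal((n, k)) @ L.T
            dos[:, lo:hi] = (z1 < t).astype(np.int8) + (z2 < t).astype(np.int8)
        return GenotypeData(
            dosages=dos,
            snps=self.snps.copy(),
            sample_ids=[f"{prefix}{i}" for i in range(n)],
            block_bounds=list(self.block_bounds),
        )


def build_population(
    scenario: SimulationScenario,
    rng: np.random.Generator | None = None,
    ar1_rho: float | None = None,
    maf_jitter: float = 0.0,
    base: Population | None = None,
) -> Population:
    """Construct a genome (block MAFs, LD, SNP table) for cohort sampling.

    With ``base`` given, a second-ancestry population is derived: same
    SNPs, MAFs jittered by +-``maf_jitter`` and a (possibly different)
    AR(1) LD decay -- used for cross-ancestry simulations.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    m, bs = scenario.m_snps, scenario.ld_block_size
    rho = scenario.ar1_rho if ar1_rho is None else ar1_rho

    bounds = [(lo, min(lo + bs, m)) for lo in range(0, m, bs)]
    mafs = np.empty(m)
    for lo, hi in bounds:
        if base is not None:
            maf = base.mafs[lo]
            if maf_jitter > 0:
                maf = float(np.clip(maf + rng.uniform(-maf_jitter, maf_jitter), 0.02, 0.5))
        else:
            maf = rng.uniform(*scenario.maf_range)
        mafs[lo:hi] = maf

    target_R, chols = [], []
    for lo, hi in bounds:
        k = hi - lo
        lags = np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        R = rho**lags
        maf = round(float(mafs[lo]), 3)
        latent = np.ones((k, k))
        for lag in range(1, k):
            latent[lags == lag] = _latent_corr(round(float(rho**lag), 3), maf)
        try:
            L = np.linalg.cholesky(latent)
        except np.linalg.LinAlgError:
            vals, vecs = np.linalg.eigh(latent)
            vals = np.clip(vals, 1e-8, None)
            fixed = (vecs * vals) @ vecs.T
            d = np.sqrt(np.diag(fixed))
            L = np.linalg.cholesky(fixed / np.outer(d, d))
        target_R.append(R)
        chols.append(L)

    snps = pd.DataFrame(
        {
            "SNP": [f"rs{i + 1}" for i in range(m)],
            "CHR": "1",
            "BP": np.arange(1, m + 1) * 1000,
            "A1": "A",
            "A2": "G",
            "MAF": mafs,
        }
    )
    return Population(
        scenario=scenario,
        mafs=mafs,
        block_bounds=bounds,
        target_R=target_R,
        _chol=chols,
        snps=snps,
    )


def simulate_genotypes(
    scenario: SimulationScenario,
    rng: np.random.Generator | None = None,
    two_ancestry: bool = False,
) -> tuple[GenotypeData, GenotypeData, LDBlockSet, LDBlockSet]:
    """Draw the proximal and adjunct cohorts (and their LD panels).

    Single-ancestry mode samples both cohorts from one population;
    two-ancestry mode derives a second population with jittered MAFs
    and its own LD decay for the adjunct cohort.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    n1 = round(scenario.n_total * scenario.split)
    n2 = scenario.n_total - n1
    pop1 = build_population(scenario, rng)
    if two_ancestry:
        rho2 = (
            scenario.ar1_rho_adjunct
            if scenario.ar1_rho_adjunct is not None
            else scenario.ar1_rho
        )
        jitter = scenario.maf_jitter_adjunct or 0.05
        pop2 = build_population(scenario, rng, ar1_rho=rho2, maf_jitter=jitter, base=pop1)
    else:
        pop2 = pop1
    g1 = pop1.sample(n1, rng, prefix="p")
    g2 = pop2.sample(n2, rng, prefix="a")
    return g1, g2, pop1.ld_panel(), pop2.ld_panel()


def simulate_phenotypes(
    genotypes: GenotypeData,
    beta_true: np.ndarray,
    h2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Quantitative phenotype y = G_std * beta + e at realized h2.

    The noise variance is set from the cohort's realized genetic
    variance, var(e) = var(g) * (1 - h2)/h2, so var(g)/var(y) is h2 up
    to the sampling noise of the drawn residuals.
    """
    if not (0.0 <= h2 <= 1.0):
        raise ValueError("h2 must lie in [0, 1]")
    n = genotypes.n_samples
    if h2 == 0.0:
        return rng.standard_normal(n)
    g = genotypes.standardized() @ beta_true
    var_g = float(np.var(g))
    if var_g == 0.0:
        return rng.standard_normal(n)
    sd_e = np.sqrt(var_g * (1.0 - h2) / h2)
    return g + rng.normal(0.0, sd_e, size=n)


def run_marginal_gwas(
    genotypes: GenotypeData,
    phenotype: np.ndarray,
    block_size: int = 2_000,
) -> pd.DataFrame:
    """Per-SNP simple linear regression on standardized dosages.

    Returns a canonical summary-statistics table (SNP CHR BP A1 A2 AF B
    SE P N) with the effect allele A1 counted by the dosage. p-values
    from the t distribution with n-2 df.
    """
    y = np.asarray(phenotype, float)
    n = genotypes.n_samples
    if len(y) != n:
        raise ValueError("phenotype length does not match cohort size")
    yc = y - y.mean()
    ss_y = float(yc @ yc)

    m = genotypes.m_snps
    beta = np.empty(m)
    se = np.empty(m)
    for lo in range(0, m, block_size):
        hi = min(lo + block_size, m)
        gs = genotypes.standardized(slice(lo, hi))
        b = gs.T @ yc / n
        ssr = np.maximum(ss_y - n * b**2, 0.0)
        sigma2 = ssr / max(n - 2, 1)
        beta[lo:hi] = b
        se[lo:hi] = np.sqrt(sigma2 / n)
    se = np.maximum(se, 1e-300)
    pval = 2.0 * stats.t.sf(np.abs(beta / se), df=max(n - 2, 1))
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)

    af = genotypes.dosages.mean(axis=0) / 2.0
    out = genotypes.snps[["SNP", "CHR", "BP", "A1", "A2"]].copy()
    out["AF"] = af
    out["B"] = beta
    out["SE"] = se
    out["P"] = pval
    out["N"] = n
    return out


def sample_sumstats_analytic(
    effects: TrueEffects,
    ld_panel: LDBlockSet,
    n1: int,
    n2: int,
    rho: float,
    rng: np.random.Generator,
    mafs: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fast path: draw paired marginal estimates from their sampling law.

    Per block, the marginal-effect estimators are jointly normal with
    mean R * beta_true and covariance R/n per study, and cross-study
    covariance rho * R / sqrt(n1*n2); this matches the moments of the
    individual-level route at matched parameters. SEs are the null
    approximation 1/sqrt(n).
    """
    snp_ids = ld_panel.snp_ids
    m = len(snp_ids)
    if m != len(effects.beta1):
        raise ValueError("effects and LD panel SNP counts differ")
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    n1, n2 = float(n1), float(n2)

    cross = np.array(
        [[1.0 / n1, rho / np.sqrt(n1 * n2)], [rho / np.sqrt(n1 * n2), 1.0 / n2]]
    )
    A = np.linalg.cholesky(cross)

    b1hat = np.empty(m)
    b2hat = np.empty(m)
    lo = 0
    for block in ld_panel:
        k = len(block.snp_ids)
        R = block.matrix
        try:
            L = np.linalg.cholesky(R)
        except np.linalg.LinAlgError:
            vals, vecs = np.linalg.eigh(R)
            L = vecs * np.sqrt(np.clip(vals, 0.0, None))
        mean1 = R @ effects.beta1[lo : lo + k]
        mean2 = R @ effects.beta2[lo : lo + k]
        u = rng.standard_normal((2, k)) @ L.T  # rows: independent R-correlated draws
        e1 = A[0, 0] * u[0]
        e2 = A[1, 0] * u[0] + A[1, 1] * u[1]
        b1hat[lo : lo + k] = mean1 + e1
        b2hat[lo : lo + k] = mean2 + e2
        lo += k

    if mafs is None:
        mafs = np.full(m, 0.25)

    def table(bhat, n):
        se = np.full(m, 1.0 / np.sqrt(n))
        p = np.clip(2.0 * stats.norm.sf(np.abs(bhat / se)), np.finfo(float).tiny, 1.0)
        return pd.DataFrame(
            {
                "SNP": snp_ids,
                "CHR": "1",
                "BP": np.arange(1, m + 1) * 1000,
                "A1": "A",
                "A2": "G",
                "AF": mafs,
                "B": bhat,
                "SE": se,
                "P": p,
                "N": n,
            }
        )

    return table(b1hat, n1), table(b2hat, n2)


def save_genotypes(genotypes: GenotypeData, prefix) -> None:
    """Write a cohort as <prefix>.dosages.npy + SNP/sample sidecar text."""
    from pathlib import Path

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.save(f"{prefix}.dosages.npy", genotypes.dosages)
    genotypes.snps.to_csv(f"{prefix}.snps.tsv", sep="\t", index=False)
    Path(f"{prefix}.samples.txt").write_text("\n".join(genotypes.sample_ids) + "\n")
    bounds = "\n".join(f"{lo}\t{hi}" for lo, hi in genotypes.block_bounds)
    Path(f"{prefix}.blocks.tsv").write_text(bounds + "\n")


def load_genotypes(prefix) -> GenotypeData:
    """Read a cohort written by :func:`save_genotypes`."""
    from pathlib import Path

    prefix = Path(prefix)
    dosages = np.load(f"{prefix}.dosages.npy")
    snps = pd.read_csv(f"{prefix}.snps.tsv", sep="\t", dtype={"SNP": str, "CHR": str})
    samples = Path(f"{prefix}.samples.txt").read_text().split()
    bounds = [
        (int(a), int(b))
        for a, b in (
            line.split("\t") for line in Path(f"{prefix}.blocks.tsv").read_text().split("\n") if line
        )
    ]
    return GenotypeData(dosages=dosages, snps=snps, sample_ids=samples, block_bounds=bounds)


def sample_null_gwas_pair_shared_controls(
    overlap: StudyOverlap,
    m_snps: int,
    rng: np.random.Generator,
    maf_range: tuple[float, float] = (0.1, 0.5),
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Null case-control GWAS pairs sharing subjects, one SNP per draw.

    Allele counts in each subject pool are binomial at the common
    frequency; shared case/control pools are drawn once and entered
    into both studies, inducing the overlap correlation. Effects are
    log odds ratios from the 2x2 allele table with the standard
    1/a+1/b+1/c+1/d variance. Returns (b1, se1, b2, se2).
    """
    p = rng.uniform(*maf_range, size=m_snps)

    def pool(count):
        return rng.binomial(int(round(2 * count)), p) if count > 0 else np.zeros(m_snps)

    shared_ca = pool(overlap.n_shared_cases)
    shared_co = pool(overlap.n_shared_controls)
    ca1 = shared_ca + pool(overlap.n1_cases - overlap.n_shared_cases)
    ca2 = shared_ca + pool(overlap.n2_cases - overlap.n_shared_cases)
    co1 = shared_co + pool(overlap.n1_controls - overlap.n_shared_controls)
    co2 = shared_co + pool(overlap.n2_controls - overlap.n_shared_controls)

    def logor(a, n_case, c, n_ctrl):
        a = np.clip(a, 0.5, None)
        c = np.clip(c, 0.5, None)
        b = np.clip(2 * n_case - a, 0.5, None)
        d = np.clip(2 * n_ctrl - c, 0.5, None)
        return np.log(a * d / (b * c)), np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)

    b1, se1 = logor(ca1, overlap.n1_cases, co1, overlap.n1_controls)
    b2, se2 = logor(ca2, overlap.n2_cases, co2, overlap.n2_controls)
    return b1, se1, b2, se2
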