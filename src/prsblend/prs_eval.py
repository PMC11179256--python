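"""Profile scoring and PRS evaluation.

Scoring follows the semantics of the standard genotype-tool profile
scorer: each individual's score is the average over used SNPs of
weight x effect-allele dosage, with allele flips resolved against the
weight table's effect allele and missing dosages mean-imputed from the
in-sample allele frequency. Performance is the squared Pearson
correlation with a quantitative trait, or the rank (Mann-Whitney) AUC
for a binary one. A minimal LD-aware re-weighting, a per-block ridge
solve (R + lambda I)^{-1} beta, is provided so that a blended LD panel
can be exercised end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ld_blend import LDBlockSet
from .simulate import GenotypeData


@dataclass
class ScoreProfile:
    """Per-individual polygenic scores."""

    sample_id: list[str]
    prs: np.ndarray
    n_snps_used: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "prs": self.prs,
                "n_snps_used": self.n_snps_used,
            }
        )


def score(
    genotypes: GenotypeData,
    weights: pd.DataFrame,
    convention: str = "average",
) -> ScoreProfile:
    """Score individuals with a weight table (canonical sumstats columns).

    Weights are matched to genotype SNPs by id; where the weight table's
    effect allele is the genotype's other allele the weight sign is
    flipped and the dosage complemented (2 - dosage), which is the same
    thing. Missing dosages (coded < 0) are mean-imputed from the
    in-sample AF. ``convention`` is ``"average"`` (default; divide by
    the number of SNPs used) or ``"sum"``.
    """
    table = getattr(weights, "table", weights)
    snp_meta = genotypes.snps.reset_index(drop=True)
    pos = {s: i for i, s in enumerate(snp_meta["SNP"])}
    rows = table[table["SNP"].isin(pos)].copy()
    if len(rows) == 0:
        raise ValueError("no overlapping SNPs between weights and genotypes")
    gi = np.array([pos[s] for s in rows["SNP"]])

    ga1 = snp_meta["A1"].to_numpy()[gi]
    ga2 = snp_meta["A2"].to_numpy()[gi]
    same = (rows["A1"].to_numpy() == ga1) & (rows["A2"].to_numpy() == ga2)
    flipped = (rows["A1"].to_numpy() == ga2) & (rows["A2"].to_numpy() == ga1)
    usable = same | flipped
    if not np.all(usable):
        rows = rows[usable]
        gi = gi[usable]
        flipped = flipped[usable]
    w = rows["B"].to_numpy(float)

    dos = genotypes.dosages[:, gi].astype(float)
    missing = dos < 0
    if missing.any():
        col_mean = np.ma.masked_array(dos, missing).mean(axis=0).filled(0.0)
        dos = np.where(missing, col_mean[None, :], dos)
    # count the weight table's effect allele: complement flipped dosages
    dos = np.where(flipped[None, :], 2.0 - dos, dos)

    prs = dos @ w
    if convention == "average":
        prs = prs / len(w)
    elif convention != "sum":
        raise ValueError(f"unknown scoring convention {convention!r}")
    return ScoreProfile(sample_id=list(genotypes.sample_ids), prs=prs, n_snps_used=len(w))


def evaluate_quantitative(profile: ScoreProfile, phenotype: np.ndarray) -> float:
    """Squared Pearson correlation between PRS and a quantitative trait."""
    y = np.asarray(phenotype, float)
    if len(y) != len(profile.prs):
        raise ValueError("phenotype length does not match profile")
    r = np.corrcoef(profile.prs, y)[0, 1]
    return float(r**2)


def evaluate_binary(profile: ScoreProfile, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC of the PRS against binary labels."""
    y = np.asarray(labels)
    s = np.asarray(profile.prs, float)
    cases = s[y == 1]
    controls = s[y == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("need both cases and controls")
    u = stats.mannwhitneyu(cases, controls, alternative="two-sided").statistic
    return float(u / (len(cases) * len(controls)))


def compare_weight_sets(
    scenario,
    seed: int,
    use_ridge: bool = False,
    shrinkage: float = 0.2,
) -> dict[str, float]:
    """One simulated replicate of the proximal / meta / blended comparison.

    Simulates a paired study under ``scenario``, runs both marginal
    GWASs, blends, and scores an independent test cohort of the
    proximal trait with three weight sets -- proximal-only, fixed-effect
    meta-analysis, and the lFDR blend -- using the same scorer. Returns
    the test-set r2 of each.
    """
    from . import blending, simulate, sumstats_io

    rng = np.random.default_rng(seed)
    effects = simulate.draw_effects(scenario, rng)
    pop = simulate.build_population(scenario, rng)
    n1 = round(scenario.n_total * scenario.split)
    n2 = scenario.n_total - n1
    g1 = pop.sample(n1, rng, prefix="p")
    g2 = pop.sample(n2, rng, prefix="a")
    gt = pop.sample(scenario.n_test, rng, prefix="t")

    y1 = simulate.simulate_phenotypes(g1, effects.beta1, scenario.h2, rng)
    y2 = simulate.simulate_phenotypes(g2, effects.beta2, scenario.h2, rng)
    yt = simulate.simulate_phenotypes(gt, effects.beta1, scenario.h2, rng)

    ss1 = simulate.run_marginal_gwas(g1, y1)
    ss2 = simulate.run_marginal_gwas(g2, y2)
    pair = sumstats_io.harmonize(ss1, ss2, drop_ambiguous=False)
    blended = blending.blend_pair(pair, rho=0.0)

    s = pair.shared
    meta = blending.inverse_variance_meta(
        s["B_1"].to_numpy(), s["SE_1"].to_numpy(), s["B_2"].to_numpy(), s["SE_2"].to_numpy()
    )
    meta_table = s[["SNP", "CHR", "BP", "A1", "A2"]].copy()
    meta_table["B"] = meta.b12

    weight_sets = {
        "proximal": ss1[["SNP", "CHR", "BP", "A1", "A2", "B"]],
        "meta": meta_table,
        "blended": blended.table[["SNP", "CHR", "BP", "A1", "A2", "B"]],
    }
    out: dict[str, float] = {}
    ld = pop.ld_panel() if use_ridge else None
    for name, w in weight_sets.items():
        if use_ridge:
            w = block_ridge_prs(w, ld, shrinkage=shrinkage)
        profile = score(gt, w)
        out[name] = evaluate_quantitative(profile, yt)
    return out


def block_ridge_prs(
    weights: pd.DataFrame,
    ld: LDBlockSet,
    shrinkage: float = 0.1,
) -> pd.DataFrame:
    """LD-aware re-weighting: per-block solve of (R + lambda I) w = beta.

    A deliberately minimal stand-alone re-weighting that decorrelates
    marginal effects within each LD block with ridge regularization
    ``lambda = shrinkage``; it exercises an LD reference end-to-end
    without any posterior machinery. SNPs absent from the panel keep
    their marginal weight. Returns a copy of the weight table with B
    replaced by the re-weighted values.
    """
    if shrinkage < 0:
        raise ValueError("shrinkage must be >= 0")
    table = getattr(weights, "table", weights).copy().reset_index(drop=True)
    pos = {s: i for i, s in enumerate(table["SNP"])}
    b = table["B"].to_numpy(float).copy()
    out = b.copy()
    for block in ld:
        idx = np.array([pos[s] for s in block.snp_ids if s in pos])
        if len(idx) == 0:
            continue
        keep = [i for i, s in enumerate(block.snp_ids) if s in pos]
        R = block.matrix[np.ix_(keep, keep)]
        k = len(idx)
        out[idx] = np.linalg.solve(R + shrinkage * np.eye(k), b[idx])
    table["B"] = out
    return table
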