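"""Inverse-variance meta-analysis and the lFDR-weighted blend.

Per SNP, with proximal estimate (b1, se1) and adjunct estimate
(b2, se2) whose errors are correlated rho through shared subjects:

    w1 = 1/se1^2,  w2 = 1/se2^2
    b12  = (w1*b1 + w2*b2) / (w1 + w2)                 (fixed-effect meta)
    Var(b12) = (w1^2 se1^2 + w2^2 se2^2 + 2 w1 w2 rho se1 se2) / (w1+w2)^2

    b_blend = (1 - pi) * b1 + pi * b12,   pi = lFDR of the heterogeneity test

The blend interpolates between the proximal estimate (pi -> 0: strong
evidence the effects differ, use the unbiased study) and the
meta-analysis (pi -> 1: no heterogeneity evidence, use the lower-variance
combination). The blended variance treats pi as a fixed plug-in weight:

    Var(b_blend) = (1-pi)^2 se1^2 + pi^2 Var(b12) + 2 pi (1-pi) Cov(b1, b12)
    Cov(b1, b12) = (w1 se1^2 + w2 rho se1 se2) / (w1 + w2)

From b_blend and its SE a complete summary-statistics set is derived:
two-sided normal p-values and an effective sample size
``n_eff = 1 / (2*AF*(1-AF)*se^2)`` (capped at the de-duplicated total),
so downstream PRS tools that scale by N see the variance gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import CANONICAL_COLUMNS, AlignedPair


@dataclass
class MetaResult:
    """Fixed-effect meta-analysis effects and standard errors per SNP."""

    b12: np.ndarray
    se12: np.ndarray


@dataclass
class BlendedStats:
    """Complete derived summary statistics for the blended estimator.

    ``table`` is a canonical sumstats DataFrame (SNP CHR BP A1 A2 AF B
    SE P N) with audit columns ``lFDR``, ``Q``, ``Qpval`` and
    ``source`` (``blended`` or ``proximal_passthrough``).
    """

    table: pd.DataFrame

    @property
    def b_blend(self) -> np.ndarray:
        return self.table["B"].to_numpy()

    @property
    def se_blend(self) -> np.ndarray:
        return self.table["SE"].to_numpy()


def inverse_variance_meta(
    b1: np.ndarray,
    se1: np.ndarray,
    b2: np.ndarray,
    se2: np.ndarray,
    rho: float = 0.0,
) -> MetaResult:
    """Fixed-effect inverse-variance meta-analysis of two aligned studies.

    The weights are the usual 1/se^2 (unchanged by rho); the variance of
    the combination carries the shared-subject covariance term and
    reduces to 1/(w1+w2) at rho=0.
    """
    b1, b2 = np.asarray(b1, float), np.asarray(b2, float)
    se1, se2 = np.asarray(se1, float), np.asarray(se2, float)
    if np.any(se1 <= 0) or np.any(se2 <= 0):
        raise ValueError("standard errors must be positive")
    w1, w2 = 1.0 / se1**2, 1.0 / se2**2
    wsum = w1 + w2
    b12 = (w1 * b1 + w2 * b2) / wsum
    var12 = (w1**2 * se1**2 + w2**2 * se2**2 + 2.0 * w1 * w2 * rho * se1 * se2) / wsum**2
    return MetaResult(b12=b12, se12=np.sqrt(var12))


def blended_variance(
    se1: np.ndarray,
    se2: np.ndarray,
    pi: np.ndarray,
    rho: float = 0.0,
) -> np.ndarray:
    """Variance of (1-pi)*b1 + pi*b12 with pi treated as fixed."""
    se1, se2 = np.asarray(se1, float), np.asarray(se2, float)
    pi = np.asarray(pi, float)
    w1, w2 = 1.0 / se1**2, 1.0 / se2**2
    wsum = w1 + w2
    var12 = (w1**2 * se1**2 + w2**2 * se2**2 + 2.0 * w1 * w2 * rho * se1 * se2) / wsum**2
    cov_b1_b12 = (w1 * se1**2 + w2 * rho * se1 * se2) / wsum
    return (1.0 - pi) ** 2 * se1**2 + pi**2 * var12 + 2.0 * pi * (1.0 - pi) * cov_b1_b12


def blend_effects(
    shared: pd.DataFrame,
    meta: MetaResult,
    lfdr: np.ndarray,
    rho: float = 0.0,
    q_stat: np.ndarray | None = None,
    q_pval: np.ndarray | None = None,
    n_eff_convention: str = "se_implied",
    n_overlap: float = 0.0,
) -> BlendedStats:
    """Blend the proximal and meta-analysis estimates with lFDR weights.

    Parameters
    ----------
    shared
        Aligned shared table from :func:`prsblend.harmonize` (columns
        suffixed ``_1`` / ``_2``).
    meta
        Output of :func:`inverse_variance_meta` on the same rows.
    lfdr
        Per-SNP blending weight pi in [0, 1].
    rho
        Scalar overlap correlation.
    n_eff_convention
        ``"se_implied"`` (default): N = 1/(2*AF*(1-AF)*SE^2), capped at
        the de-duplicated total N1 + N2 - n_overlap; ``"linear"``:
        (1-pi)*N1 + pi*(N1+N2).
    n_overlap
        Number of subjects counted in both N1 and N2 (shared cases plus
        shared controls); only used for the cap.

    The reported AF is the proximal study's (the target population).
    """
    lfdr = np.asarray(lfdr, dtype=float)
    n = len(shared)
    if not (len(meta.b12) == len(lfdr) == n):
        raise ValueError("shared table, meta result and lfdr lengths differ")
    if np.any((lfdr < 0) | (lfdr > 1)):
        raise ValueError("lfdr weights must lie in [0, 1]")

    b1 = shared["B_1"].to_numpy()
    se1 = shared["SE_1"].to_numpy()
    se2 = shared["SE_2"].to_numpy()
    n1 = shared["N_1"].to_numpy()
    n2 = shared["N_2"].to_numpy()
    af = shared["AF_1"].to_numpy()

    b_blend = (1.0 - lfdr) * b1 + lfdr * meta.b12
    se_blend = np.sqrt(blended_variance(se1, se2, lfdr, rho))
    z = b_blend / se_blend
    pval = 2.0 * stats.norm.sf(np.abs(z))
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)

    n_cap = n1 + n2 - n_overlap
    if n_eff_convention == "se_implied":
        n_eff = 1.0 / (2.0 * af * (1.0 - af) * se_blend**2)
        n_eff = np.minimum(n_eff, n_cap)
    elif n_eff_convention == "linear":
        n_eff = (1.0 - lfdr) * n1 + lfdr * (n1 + n2)
    else:
        raise ValueError(f"unknown n_eff convention {n_eff_convention!r}")

    table = pd.DataFrame(
        {
            "SNP": shared["SNP"].to_numpy(),
            "CHR": shared["CHR"].to_numpy(),
            "BP": shared["BP"].to_numpy(),
            "A1": shared["A1"].to_numpy(),
            "A2": shared["A2"].to_numpy(),
            "AF": af,
            "B": b_blend,
            "SE": se_blend,
            "P": pval,
            "N": n_eff,
            "lFDR": lfdr,
            "Q": np.full(n, np.nan) if q_stat is None else np.asarray(q_stat, float),
            "Qpval": np.full(n, np.nan) if q_pval is None else np.asarray(q_pval, float),
            "SE_1": se1,
            "SE_2": se2,
            "source": "blended",
        }
    )
    return BlendedStats(table=table)


def passthrough_proximal_only(pair: AlignedPair, blended: BlendedStats) -> BlendedStats:
    """Append proximal-only SNPs unchanged to the blended output.

    SNPs absent from the adjunct study cannot be blended; their original
    proximal effect, SE, p and N are carried through so the output
    remains a complete summary-statistics set over the proximal SNPs.
    """
    extra = pair.proximal_only
    if len(extra) == 0:
        return blended
    collisions = set(extra["SNP"]) & set(blended.table["SNP"])
    if collisions:
        raise ValueError(
            f"proximal-only SNPs collide with blended rows: {sorted(collisions)[:5]}"
        )
    rows = extra[CANONICAL_COLUMNS].copy()
    rows["lFDR"] = np.nan
    rows["Q"] = np.nan
    rows["Qpval"] = np.nan
    rows["SE_1"] = rows["SE"]
    rows["SE_2"] = np.nan
    rows["source"] = "proximal_passthrough"
    table = pd.concat([blended.table, rows], ignore_index=True)
    return BlendedStats(table=table)


def blend_pair(
    pair: AlignedPair,
    rho: float = 0.0,
    n_eff_convention: str = "se_implied",
    n_overlap: float = 0.0,
) -> BlendedStats:
    """End-to-end blend of an aligned study pair.

    Runs the adjusted Cochran Q test on the shared SNPs, converts the Q
    p-values to lFDR weights, meta-analyses, blends, and appends the
    proximal-only passthrough rows.
    """
    from .heterogeneity import cochran_q
    from .lfdr import estimate_lfdr, estimate_pi0

    s = pair.shared
    het = cochran_q(
        s["B_1"].to_numpy(),
        s["SE_1"].to_numpy(),
        s["B_2"].to_numpy(),
        s["SE_2"].to_numpy(),
        rho=rho,
    )
    if np.ptp(het.q_pval) == 0.0:
        # degenerate input (e.g. every Q identical): no heterogeneity
        # gradient to learn from, fall back to the full meta-analysis
        lfdr_weights = np.ones(len(s))
    elif len(s) < 100:
        pi0, _ = estimate_pi0(het.q_pval, method="fixed", lambda_fixed=0.5)
        lfdr_weights = estimate_lfdr(het.q_pval, pi0=pi0).lfdr
    else:
        lfdr_weights = estimate_lfdr(het.q_pval).lfdr
    meta = inverse_variance_meta(
        s["B_1"].to_numpy(),
        s["SE_1"].to_numpy(),
        s["B_2"].to_numpy(),
        s["SE_2"].to_numpy(),
        rho=rho,
    )
    blended = blend_effects(
        s,
        meta,
        lfdr_weights,
        rho=rho,
        q_stat=het.q_stat,
        q_pval=het.q_pval,
        n_eff_convention=n_eff_convention,
        n_overlap=n_overlap,
    )
    return passthrough_proximal_only(pair, blended)
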