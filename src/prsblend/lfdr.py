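"""Local false discovery rates for per-SNP heterogeneity p-values.

The blending weight for each SNP is pi = Pr(H0 | p), the posterior
probability that its two effect estimates share a common truth given
the observed heterogeneity p-value. This is the two-groups local false
discovery rate (lFDR) of Efron / Storey:

    f(p) = pi0 * f0(p) + (1 - pi0) * f1(p),      lfdr(p) = pi0 * f0(p) / f(p)

computed here on the probit scale x = Phi^{-1}(p), where the null
density f0 becomes standard normal and the marginal f is estimated by
Gaussian kernel density estimation. pi0, the null proportion, is
estimated by the Storey smoother: pi0(lambda) = #{p > lambda} /
(m * (1 - lambda)) on a grid, smoothed and read off at the largest
lambda. The result is clipped to [0, 1] and monotonized to be
non-decreasing in p, so that small p (strong heterogeneity) always maps
to low weight on the meta-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.96, 0.05), 2)

_P_EPS = 1e-12


@dataclass
class LfdrResult:
    """Per-SNP lFDR weights with the pi0 estimate and tuning grid used."""

    lfdr: np.ndarray
    pi0: float
    lambda_grid: np.ndarray = field(default_factory=lambda: DEFAULT_LAMBDA_GRID.copy())
    pi0_curve: np.ndarray | None = None


def _check_pvals(pvals: np.ndarray) -> np.ndarray:
    pvals = np.asarray(pvals, dtype=float)
    if np.any(pvals > 1.0) or np.any(pvals < 0.0) or np.any(~np.isfinite(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    # p == 0 and p == 1 are clamped: probit(0/1) is infinite
    return np.clip(pvals, _P_EPS, 1.0 - _P_EPS)


def estimate_pi0(
    pvals: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    method: str = "smoother",
    lambda_fixed: float = 0.5,
) -> tuple[float, np.ndarray]:
    """Estimate the null proportion pi0 from a p-value vector.

    method="smoother": compute pi0(lambda) = #{p > lambda}/(m*(1-lambda))
    on the grid, fit a least-squares cubic (the high-smoothing limit of a
    cubic smoothing spline) and evaluate it at max(lambda).
    method="fixed": return pi0(lambda_fixed) directly.

    Returns ``(pi0, pi0_curve)`` with pi0 clipped to (0, 1].
    """
    pvals = np.asarray(pvals, dtype=float)
    if np.all(pvals == pvals[0]):
        raise ValueError("all p-values identical; pi0 is undefined")
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
    if np.any(np.diff(grid) <= 0) or grid.min() <= 0 or grid.max() >= 1:
        raise ValueError("lambda grid must be strictly increasing within (0, 1)")
    m = len(pvals)

    if method == "fixed":
        pi0 = np.sum(pvals > lambda_fixed) / (m * (1.0 - lambda_fixed))
        return float(np.clip(pi0, 1.0 / m, 1.0)), np.array([pi0])

    if method != "smoother":
        raise ValueError(f"unknown pi0 method {method!r}")
    if m < 100:
        raise ValueError("smoother pi0 estimation needs at least 100 p-values")
    curve = np.array([np.sum(pvals > lam) / (m * (1.0 - lam)) for lam in grid])
    coef = np.polyfit(grid, curve, deg=3)
    pi0 = float(np.polyval(coef, grid.max()))
    return float(np.clip(pi0, 1.0 / m, 1.0)), curve


def estimate_lfdr(
    pvals: np.ndarray,
    pi0: float | None = None,
    lambda_grid: np.ndarray | None = None,
    bw_method: str | float = "silverman",
) -> LfdrResult:
    """Two-groups local false discovery rate per p-value.

    Transforms p to the probit scale, estimates the marginal density by
    a Gaussian KDE (Silverman bandwidth by default), and forms
    ``lfdr = pi0 * phi(x) / f_hat(x)`` clipped to [0, 1], followed by a
    cumulative-maximum pass in increasing p so the result is
    non-decreasing in p. Deterministic given its inputs.
    """
    p = _check_pvals(pvals)
    pi0_curve = None
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
    if pi0 is None:
        pi0, pi0_curve = estimate_pi0(p, lambda_grid=grid)
    if not (0.0 < pi0 <= 1.0):
        raise ValueError(f"pi0 must lie in (0, 1], got {pi0}")

    x = stats.norm.ppf(p)
    kde = stats.gaussian_kde(x, bw_method=bw_method)
    f_hat = kde(x)
    raw = pi0 * stats.norm.pdf(x) / np.maximum(f_hat, 1e-300)
    lfdr = np.clip(raw, 0.0, 1.0)

    order = np.argsort(p, kind="stable")
    lfdr[order] = np.maximum.accumulate(lfdr[order])

    return LfdrResult(lfdr=lfdr, pi0=float(pi0), lambda_grid=grid, pi0_curve=pi0_curve)
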