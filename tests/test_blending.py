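"""Inverse-variance meta-analysis and the lFDR-weighted blend."""

import numpy as np
import pandas as pd
import pytest

from prsblend import blending, sumstats_io
from prsblend.blending import (
    blend_effects,
    blend_pair,
    blended_variance,
    inverse_variance_meta,
    passthrough_proximal_only,
)

from conftest import make_sumstats


def _shared_frame(b1, se1, b2, se2, af=0.3, n1=10_000, n2=20_000):
    m = len(b1)
    return pd.DataFrame(
        {
            "SNP": [f"rs{i + 1}" for i in range(m)],
            "CHR": "1",
            "BP": np.arange(1, m + 1) * 100,
            "A1": "A",
            "A2": "G",
            "AF_1": af,
            "B_1": b1,
            "SE_1": se1,
            "P_1": 0.5,
            "N_1": n1,
            "AF_2": af,
            "B_2": b2,
            "SE_2": se2,
            "P_2": 0.5,
            "N_2": n2,
        }
    )


class TestMeta:
    def test_equal_weight_case(self):
        m = inverse_variance_meta([0.1], [0.05], [0.3], [0.05])
        assert m.b12[0] == pytest.approx(0.2)
        assert m.se12[0] == pytest.approx(0.05 / np.sqrt(2))

    def test_unequal_weights_hand_computed(self):
        m = inverse_variance_meta([0.2], [0.1], [0.4], [0.2])
        assert m.b12[0] == pytest.approx(0.24, abs=1e-12)
        assert m.se12[0] == pytest.approx(np.sqrt(1 / 125), abs=1e-12)

    def test_correlated_errors_variance_monte_carlo(self, rng):
        """With rho=0.3 the meta point estimate is unchanged but its SD
        grows; the closed form must match the empirical SD of jointly
        normal draws within 1%."""
        s1, s2, rho = 0.1, 0.2, 0.3
        m = inverse_variance_meta([0.2], [s1], [0.4], [s2], rho=rho)
        assert m.b12[0] == pytest.approx(0.24, abs=1e-12)
        cov = [[s1**2, rho * s1 * s2], [rho * s1 * s2, s2**2]]
        draws = rng.multivariate_normal([0.2, 0.4], cov, size=1_000_000)
        w1, w2 = 1 / s1**2, 1 / s2**2
        b12 = (w1 * draws[:, 0] + w2 * draws[:, 1]) / (w1 + w2)
        assert m.se12[0] == pytest.approx(b12.std(), rel=0.01)

    def test_meta_between_inputs(self, rng):
        b1, b2 = rng.normal(size=100), rng.normal(size=100)
        se = rng.uniform(0.01, 0.3, size=(2, 100))
        m = inverse_variance_meta(b1, se[0], b2, se[1])
        assert np.all(m.b12 >= np.minimum(b1, b2) - 1e-12)
        assert np.all(m.b12 <= np.maximum(b1, b2) + 1e-12)
        assert np.all(m.se12 <= np.minimum(se[0], se[1]) + 1e-12)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            inverse_variance_meta([0.1], [0.0], [0.2], [0.1])


class TestBlend:
    def test_pi_zero_returns_proximal(self):
        s = _shared_frame([0.2, -0.1], [0.1, 0.05], [0.4, 0.3], [0.2, 0.1])
        meta = inverse_variance_meta(s["B_1"], s["SE_1"], s["B_2"], s["SE_2"])
        out = blend_effects(s, meta, np.zeros(2))
        np.testing.assert_allclose(out.b_blend, s["B_1"])
        np.testing.assert_allclose(out.se_blend, s["SE_1"])

    def test_pi_one_returns_meta(self):
        s = _shared_frame([0.2, -0.1], [0.1, 0.05], [0.4, 0.3], [0.2, 0.1])
        meta = inverse_variance_meta(s["B_1"], s["SE_1"], s["B_2"], s["SE_2"])
        out = blend_effects(s, meta, np.ones(2))
        np.testing.assert_allclose(out.b_blend, meta.b12)
        np.testing.assert_allclose(out.se_blend, meta.se12)

    def test_half_weight_hand_computed_and_monte_carlo(self, rng):
        s = _shared_frame([0.2], [0.1], [0.4], [0.2])
        meta = inverse_variance_meta(s["B_1"], s["SE_1"], s["B_2"], s["SE_2"])
        out = blend_effects(s, meta, np.array([0.5]))
        assert out.b_blend[0] == pytest.approx(0.22, abs=1e-12)
        assert out.se_blend[0] == pytest.approx(np.sqrt(0.0085), abs=1e-12)
        draws = rng.multivariate_normal(
            [0.2, 0.4], [[0.01, 0.0], [0.0, 0.04]], size=1_000_000
        )
        w1, w2 = 100.0, 25.0
        b12 = (w1 * draws[:, 0] + w2 * draws[:, 1]) / (w1 + w2)
        blended = 0.5 * draws[:, 0] + 0.5 * b12
        assert out.se_blend[0] == pytest.approx(blended.std(), rel=0.01)

    def test_blended_se_grid_against_monte_carlo(self, rng):
        """Across a (se1, se2, rho, pi) grid the plug-in SE matches the
        empirical SD of (1-pi)*b1 + pi*b12 within 2%."""
        n = 200_000
        z = rng.standard_normal((n, 2))
        for s1 in (0.05, 0.1, 0.2):
            for s2 in (0.05, 0.1, 0.2):
                for rho in (0.0, 0.3, 0.6):
                    cov = np.array([[s1**2, rho * s1 * s2], [rho * s1 * s2, s2**2]])
                    e = z @ np.linalg.cholesky(cov).T
                    w1, w2 = 1 / s1**2, 1 / s2**2
                    b12 = (w1 * e[:, 0] + w2 * e[:, 1]) / (w1 + w2)
                    for pi in (0.0, 0.25, 0.5, 0.75, 1.0):
                        emp = ((1 - pi) * e[:, 0] + pi * b12).std()
                        form = np.sqrt(blended_variance([s1], [s2], [pi], rho))[0]
                        assert form == pytest.approx(emp, rel=0.02)

    def test_convexity_invariants(self, rng):
        m = 500
        b1 = rng.normal(size=m)
        b2 = rng.normal(size=m)
        se1 = rng.uniform(0.02, 0.3, m)
        se2 = rng.uniform(0.02, 0.3, m)
        pi = rng.uniform(size=m)
        s = _shared_frame(b1, se1, b2, se2)
        meta = inverse_variance_meta(b1, se1, b2, se2, rho=0.2)
        out = blend_effects(s, meta, pi, rho=0.2)
        lo = np.minimum(b1, meta.b12) - 1e-12
        hi = np.maximum(b1, meta.b12) + 1e-12
        assert np.all((out.b_blend >= lo) & (out.b_blend <= hi))
        assert np.all(out.se_blend <= np.maximum(se1, meta.se12) + 1e-12)

    def test_n_eff_conventions(self):
        s = _shared_frame([0.2], [0.1], [0.2], [0.1], af=0.5, n1=100, n2=300)
        meta = inverse_variance_meta(s["B_1"], s["SE_1"], s["B_2"], s["SE_2"])
        lin = blend_effects(s, meta, np.array([0.5]), n_eff_convention="linear")
        assert lin.table["N"][0] == pytest.approx(0.5 * 100 + 0.5 * 400)
        imp = blend_effects(s, meta, np.array([0.0]))
        # pi=0: se = 0.1, n_eff = 1/(2*0.25*0.01) = 200, capped at 400
        assert imp.table["N"][0] == pytest.approx(200.0)

    def test_lfdr_out_of_range_rejected(self):
        s = _shared_frame([0.2], [0.1], [0.4], [0.2])
        meta = inverse_variance_meta(s["B_1"], s["SE_1"], s["B_2"], s["SE_2"])
        with pytest.raises(ValueError):
            blend_effects(s, meta, np.array([1.5]))


class TestPassthrough:
    def _blend(self, pair):
        return blend_pair(pair, rho=0.0)

    def test_missing_adjunct_snps_passed_through_bit_identical(self):
        prox = make_sumstats(10, beta=0.12, se=0.03)
        adj = make_sumstats(7, beta=0.05, se=0.03)
        out = self._blend(sumstats_io.harmonize(prox, adj))
        pt = out.table[out.table["source"] == "proximal_passthrough"]
        assert len(pt) == 3
        orig = prox[prox["SNP"].isin(pt["SNP"])]
        for col in ("B", "SE", "P", "N", "AF"):
            np.testing.assert_array_equal(
                pt.sort_values("SNP")[col].to_numpy(float),
                orig.sort_values("SNP")[col].to_numpy(float),
            )

    def test_full_adjunct_coverage_no_passthrough(self):
        prox = make_sumstats(8, beta=0.1)
        adj = make_sumstats(8, beta=0.15)
        out = self._blend(sumstats_io.harmonize(prox, adj))
        assert (out.table["source"] == "blended").all()

    def test_snp_collision_rejected(self):
        prox = make_sumstats(5)
        adj = make_sumstats(5)
        pair = sumstats_io.harmonize(prox, adj)
        blended = self._blend(pair)
        pair.proximal_only = prox.iloc[:1]  # collides with blended rs1
        with pytest.raises(ValueError, match="collide"):
            passthrough_proximal_only(pair, blended)


class TestEndToEndDegenerate:
    def test_identical_truth_large_n_blends_to_meta(self, rng):
        """Two studies with identical true effects and tiny SEs: median
        lfdr should be high and the blend close to the meta estimate."""
        m = 2_000
        truth = rng.normal(scale=0.05, size=m)
        se = 0.01
        b1 = truth + rng.normal(scale=se, size=m)
        b2 = truth + rng.normal(scale=se, size=m)
        prox = make_sumstats(m, beta=list(b1), se=se, nsamp=50_000)
        adj = make_sumstats(m, beta=list(b2), se=se, nsamp=50_000)
        out = blend_pair(sumstats_io.harmonize(prox, adj))
        t = out.table
        assert np.median(t["lFDR"]) >= 0.9
        w1 = w2 = 1 / se**2
        b12 = (w1 * b1 + w2 * b2) / (w1 + w2)
        assert np.corrcoef(t["B"], b12)[0, 1] > 0.99

    def test_discordant_truth_large_n_keeps_proximal(self, rng):
        """Fully discordant effects at tiny SEs: lfdr ~ 0 at causal SNPs
        and the blend sticks to the proximal estimates there."""
        m = 2_000
        causal = np.arange(200)
        b1 = np.zeros(m)
        b2 = np.zeros(m)
        b1[causal] = rng.uniform(0.1, 0.3, 200) * rng.choice([-1, 1], 200)
        b2[causal] = -b1[causal]
        se = 0.005
        b1n = b1 + rng.normal(scale=se, size=m)
        b2n = b2 + rng.normal(scale=se, size=m)
        prox = make_sumstats(m, beta=list(b1n), se=se, nsamp=100_000)
        adj = make_sumstats(m, beta=list(b2n), se=se, nsamp=100_000)
        out = blend_pair(sumstats_io.harmonize(prox, adj))
        t = out.table.set_index("SNP")
        causal_ids = [f"rs{i + 1}" for i in causal]
        assert t.loc[causal_ids, "lFDR"].max() < 0.01
        np.testing.assert_allclose(
            t.loc[causal_ids, "B"], b1n[causal], atol=0.01
        )

    def test_shrinkage_of_nonsignificant_low_heterogeneity_snps(self, rng):
        """Among low-heterogeneity SNPs the blend shrinks non-significant
        effects toward zero on average and leaves significant ones
        nearly unchanged."""
        m = 5_000
        truth = np.zeros(m)
        truth[:250] = rng.normal(scale=0.15, size=250)  # strong shared signals
        se = 0.02
        b1 = truth + rng.normal(scale=se, size=m)
        b2 = truth + rng.normal(scale=se, size=m)
        prox = make_sumstats(m, beta=list(b1), se=se, nsamp=50_000)
        adj = make_sumstats(m, beta=list(b2), se=se, nsamp=50_000)
        out = blend_pair(sumstats_io.harmonize(prox, adj))
        t = out.table.reset_index(drop=True)
        low_het = t["lFDR"] > 0.5
        sig = t["P"] < 5e-8
        ns = low_het & ~sig
        assert np.abs(t.loc[ns, "B"]).mean() < np.abs(b1[ns.to_numpy()]).mean()
        hits = low_het & sig
        assert hits.sum() > 50
        diff = t.loc[hits, "B"].to_numpy() - b1[hits.to_numpy()]
        assert abs(diff.mean()) < 3 * diff.std(ddof=1) / np.sqrt(hits.sum()) + 1e-3
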