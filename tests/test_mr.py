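"""Wald ratios, correlated IVW, dose scaling, FDR, and sensitivity analyses."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cismr import bh_fdr, exclude_weakest, ivw_correlated, scale_estimate, wald_ratio

from conftest import make_hset


def fixed_effect_ivw_oracle(gamma, gamma_se, Gamma, Gamma_se):
    """Brute-force fixed-effect IVW of per-variant Wald ratios.

    Weights are the inverse first-order variances, gamma_j^2 / Gamma_se_j^2.
    Independent of the GLS implementation under test.
    """
    est, w = [], []
    for G, Gs, g, gs in zip(Gamma, Gamma_se, gamma, gamma_se):
        e, s = wald_ratio(G, Gs, g, gs)
        est.append(e)
        w.append(1.0 / s**2)
    est, w = np.array(est), np.array(w)
    theta = float(np.sum(w * est) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return theta, se


def bh_oracle(pvals):
    """Brute-force step-up definition: adj_i = min over ranks j >= rank(i) of m*p_(j)/j."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, m * p[i] / rank)
        adj[i] = running_min
    return adj


class TestWaldRatio:
    @pytest.mark.parametrize(
        "Gamma, Gamma_se, gamma, gamma_se, est, se",
        [
            (0.05, 0.01, 0.1, 0.02, 0.5, 0.1),
            (0.0, 0.01, 0.161, 0.017, 0.0, 0.0621118),
            (0.05, 0.01, -0.1, 0.02, -0.5, 0.1),
        ],
    )
    def test_ratio_and_se(self, Gamma, Gamma_se, gamma, gamma_se, est, se):
        e, s = wald_ratio(Gamma, Gamma_se, gamma, gamma_se)
        assert e == pytest.approx(est)
        assert s == pytest.approx(se, rel=1e-5)

    def test_zero_exposure_effect_unidentified(self):
        with pytest.raises(ZeroDivisionError, match="unidentified"):
            wald_ratio(0.05, 0.01, 0.0, 0.02)


class TestIvwCorrelated:
    def test_single_variant_reduces_to_wald_ratio(self):
        h = make_hset([0.161], [0.017], [-0.008], [0.003])
        res = ivw_correlated(h)
        e, s = wald_ratio(-0.008, 0.003, 0.161, 0.017)
        assert res.estimate == pytest.approx(e)
        assert res.se == pytest.approx(s)
        assert res.overdispersion is None

    def test_identity_ld_fixed_effects_matches_oracle(self, rng):
        for _ in range(50):
            J = int(rng.integers(2, 7))
            gamma = rng.uniform(0.05, 0.2, J) * rng.choice([-1, 1], J)
            gamma_se = rng.uniform(0.01, 0.05, J)
            Gamma = rng.normal(0, 0.02, J)
            Gamma_se = rng.uniform(0.002, 0.01, J)
            h = make_hset(gamma, gamma_se, Gamma, Gamma_se)
            res = ivw_correlated(h, random_effects=False)
            theta, se = fixed_effect_ivw_oracle(gamma, gamma_se, Gamma, Gamma_se)
            assert res.estimate == pytest.approx(theta, abs=1e-10)
            assert res.se == pytest.approx(se, abs=1e-10)

    def test_duplicated_variant_with_perfect_ld_degenerates_to_single(self):
        r = np.array([[1.0, 1.0], [1.0, 1.0]])
        h = make_hset([0.1, 0.1], [0.02, 0.02], [0.005, 0.005], [0.003, 0.003], r=r)
        single = make_hset([0.1], [0.02], [0.005], [0.003])
        with pytest.warns(RuntimeWarning, match="ill-conditioned"):
            res = ivw_correlated(h)
        assert res.estimate == pytest.approx(ivw_correlated(single).estimate)

    def test_random_effects_never_shrink_se(self, rng):
        for _ in range(20):
            J = int(rng.integers(2, 7))
            gamma = rng.uniform(0.05, 0.2, J)
            h = make_hset(gamma, gamma * 0.1,
                          rng.normal(0, 0.05, J), rng.uniform(0.002, 0.01, J))
            fe = ivw_correlated(h, random_effects=False)
            re = ivw_correlated(h, random_effects=True)
            assert re.se >= fe.se - 1e-15

    def test_correlated_ld_widens_se_for_positively_correlated_instruments(self):
        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        h_corr = make_hset([0.1, 0.12], [0.02, 0.02], [0.005, 0.006], [0.003, 0.003], r=r)
        h_ind = make_hset([0.1, 0.12], [0.02, 0.02], [0.005, 0.006], [0.003, 0.003])
        assert (
            ivw_correlated(h_corr, random_effects=False).se
            > ivw_correlated(h_ind, random_effects=False).se
        )

    @pytest.mark.parametrize("c", [2.0, -0.5])
    def test_equivariance(self, c):
        gamma = np.array([0.1, 0.15, 0.08])
        Gamma = np.array([0.004, 0.007, 0.003])
        base = ivw_correlated(make_hset(gamma, gamma * 0 + 0.02, Gamma, Gamma * 0 + 0.003))
        scaled_g = ivw_correlated(
            make_hset(gamma * c, gamma * 0 + 0.02, Gamma, Gamma * 0 + 0.003)
        )
        scaled_G = ivw_correlated(
            make_hset(gamma, gamma * 0 + 0.02, Gamma * c, Gamma * 0 + 0.003)
        )
        assert scaled_g.estimate == pytest.approx(base.estimate / c)
        assert scaled_G.estimate == pytest.approx(base.estimate * c, rel=1e-6)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            ivw_correlated(make_hset([], [], [], []))


class TestScaleEstimate:
    def test_lowering_scale_flips_sign(self):
        h = make_hset([0.1], [0.02], [-0.00509], [0.003])
        res = ivw_correlated(h)
        scaled = scale_estimate(res, mm_hg_per_dose=5.5, direction="lowering")
        assert scaled.estimate == pytest.approx(-res.estimate * 5.5)
        assert scaled.estimate > 0  # inhibition effect reads positively
        assert scaled.ci_low <= scaled.estimate <= scaled.ci_high

    def test_identity_scale(self):
        res = ivw_correlated(make_hset([0.1], [0.02], [0.005], [0.003]))
        same = scale_estimate(res, mm_hg_per_dose=1.0, direction="raising")
        assert same.estimate == pytest.approx(res.estimate)
        assert same.se == pytest.approx(res.se)

    def test_se_scales_linearly_and_z_preserved(self):
        res = ivw_correlated(make_hset([0.1, 0.2], [0.02, 0.02],
                                       [0.005, 0.011], [0.003, 0.003]))
        scaled = scale_estimate(res, mm_hg_per_dose=5.5)
        assert scaled.se == pytest.approx(res.se * 5.5)
        assert abs(scaled.zscore) == pytest.approx(abs(res.zscore))
        assert scaled.pval == pytest.approx(res.pval)

    def test_double_scaling_refused(self):
        res = ivw_correlated(make_hset([0.1], [0.02], [0.005], [0.003]))
        scaled = scale_estimate(res)
        with pytest.raises(ValueError, match="twice"):
            scale_estimate(scaled)


class TestBhFdr:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.001, 0.02, 0.03, 0.9]), [0.004, 0.04, 0.04, 0.9]
        )

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_ties_symmetric(self):
        np.testing.assert_allclose(bh_fdr([0.05, 0.05]), [0.05, 0.05])

    def test_matches_brute_force_on_exhaustive_orderings(self):
        values = [0.001, 0.01, 0.04, 0.2, 0.6, 1.0]
        for m in range(1, 5):
            for perm in itertools.permutations(values, m):
                np.testing.assert_allclose(bh_fdr(list(perm)), bh_oracle(perm),
                                           atol=1e-12)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_random(self, pvals):
        np.testing.assert_allclose(bh_fdr(pvals), bh_oracle(pvals), atol=1e-12)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.5], []])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            bh_fdr(bad)


class TestExcludeWeakest:
    def test_published_f_pattern_removes_weakest(self):
        # per-variant Fs (51, 20, 8, 86, 15): the F=8 variant goes
        f = np.array([51.0, 20.0, 8.0, 86.0, 15.0])
        h = make_hset([0.131, 0.095, 0.144, 0.161, 0.102],
                      [0.018, 0.021, 0.050, 0.017, 0.027],
                      [0.01] * 5, [0.003] * 5)
        out = exclude_weakest(h, f)
        assert len(out) == 4
        assert "rs3" not in out.rsids  # index 2 held F=8
        assert out.ld.r.shape == (4, 4)

    def test_tie_broken_by_larger_exposure_p(self):
        h = make_hset([0.1, 0.1], [0.02, 0.02], [0.005, 0.004], [0.003, 0.003],
                      pvals=[1e-8, 1e-4])
        out = exclude_weakest(h, np.array([25.0, 25.0]))
        assert out.rsids == ["rs1"]  # rs2 had the larger p

    def test_requires_two_instruments(self):
        h = make_hset([0.1], [0.02], [0.005], [0.003])
        with pytest.raises(ValueError):
            exclude_weakest(h, np.array([25.0]))
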