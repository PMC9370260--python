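import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrax.mr_estimators import (
    CollinearityError,
    InsufficientInstrumentsError,
    cochran_q,
    egger,
    egger_intercept_test,
    ivw,
    max_likelihood,
    penalized_weighted_median,
    wald_ratio,
    weighted_median,
    weighted_median_value,
)
from mrax.summary_io import usable
from mrax.synthetic_data import SimConfig, simulate_two_sample

from conftest import mk_insts


def _sim_insts(cfg):
    """Simulated instruments with no strand flips, straight to harmonized form."""
    from dataclasses import replace

    exp, out, truth = simulate_two_sample(replace(cfg, flip_fraction=0.0))
    from mrax.summary_io import harmonize

    return usable(harmonize(exp, out)), truth


class TestWald:
    @pytest.mark.parametrize(
        "bx,by,sy,beta,se",
        [(1.0, 0.5, 0.1, 0.5, 0.1), (-0.2, 0.1, 0.02, -0.5, 0.1), (0.3, 0.3, 0.1, 1.0, None)],
    )
    def test_ratio_and_first_order_se(self, bx, by, sy, beta, se):
        (h,) = mk_insts([bx], [by], sx=[1e-6], sy=[sy])
        est = wald_ratio(h)
        assert est.beta == pytest.approx(beta)
        if se is not None:
            assert est.se == pytest.approx(se)

    def test_zero_exposure_effect_rejected(self):
        (h,) = mk_insts([0.0], [0.1])
        with pytest.raises(Exception, match="zero"):
            wald_ratio(h)


class TestIVW:
    def test_homogeneous_ratios_give_common_value_and_zero_q(self):
        insts = mk_insts([0.1, 0.2], [0.03, 0.06], sy=[0.01, 0.02])  # equal weights
        est, diag = ivw(insts, model="auto")
        assert est.beta == pytest.approx(0.3)
        assert diag.q == pytest.approx(0.0, abs=1e-20)
        assert diag.i2 == 0.0
        assert est.model == "fixed"

    def test_duplicating_instruments_keeps_beta_and_shrinks_se(self, clean_ten_snp):
        est1, _ = ivw(clean_ten_snp, model="fixed")
        est2, _ = ivw(clean_ten_snp * 2, model="fixed")
        assert est2.beta == pytest.approx(est1.beta)
        assert est2.se == pytest.approx(est1.se / np.sqrt(2))

    def test_random_model_inflates_se_only_under_heterogeneity(self):
        rng = np.random.default_rng(1)
        bx = rng.uniform(0.05, 0.1, 8)
        by = 0.3 * bx + rng.normal(0, 0.08, 8)  # gross over-dispersion vs sy=0.01
        insts = mk_insts(bx, by, sy=np.full(8, 0.01))
        fixed, diag = ivw(insts, model="fixed")
        auto, _ = ivw(insts, model="auto")
        assert diag.q_pvalue < 0.05
        assert auto.model == "random"
        assert auto.se > fixed.se

    def test_ci_brackets_or(self, clean_ten_snp):
        est, _ = ivw(clean_ten_snp)
        assert est.ci_low < est.or_ < est.ci_high

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(mk_insts([0.1], [0.03]))


class TestMaxLikelihood:
    def test_vanishing_exposure_noise_recovers_ivw(self):
        rng = np.random.default_rng(5)
        bx = rng.uniform(0.05, 0.12, 5)
        by = 0.4 * bx + rng.normal(0, 0.02, 5)
        insts = mk_insts(bx, by, sx=np.full(5, 1e-6), sy=np.full(5, 0.02))
        ml = max_likelihood(insts)
        iv, _ = ivw(insts, model="fixed")
        assert ml.beta == pytest.approx(iv.beta, abs=1e-3)

    def test_homogeneous_fixture_returns_common_ratio(self):
        insts = mk_insts([0.1, 0.2, 0.15], [0.05, 0.10, 0.075], sx=np.full(3, 0.01))
        assert max_likelihood(insts).beta == pytest.approx(0.5, abs=1e-6)

    def test_accounts_for_exposure_uncertainty(self, clean_ten_snp):
        # with non-negligible exposure noise the ML SE exceeds the naive IVW SE
        from dataclasses import replace

        noisy = [replace(h, se_exp=0.02) for h in clean_ten_snp]
        iv, _ = ivw(noisy, model="fixed")
        assert max_likelihood(noisy).se > iv.se


class TestEgger:
    def test_noiseless_line_through_origin(self):
        bx = np.array([0.05, 0.08, 0.11, 0.15])
        insts = mk_insts(bx, 0.4 * bx, sy=np.full(4, 0.02))
        est, diag, full = egger(insts)
        assert est.beta == pytest.approx(0.4, abs=1e-8)
        assert full.intercept == pytest.approx(0.0, abs=1e-10)
        assert full.intercept_pvalue > 0.9

    def test_noiseless_affine_recovers_intercept_and_slope(self):
        bx = np.array([0.05, 0.08, 0.11, 0.15])
        insts = mk_insts(bx, 0.05 + 0.4 * bx, sy=np.full(4, 0.02))
        est, diag, full = egger(insts)
        assert est.beta == pytest.approx(0.4, abs=1e-8)
        assert full.intercept == pytest.approx(0.05, abs=1e-8)

    def test_orientation_makes_fit_sign_invariant(self):
        rng = np.random.default_rng(9)
        bx = rng.uniform(0.05, 0.15, 6)
        by = 0.02 + 0.4 * bx + rng.normal(0, 0.01, 6)
        ref, _, reff = egger(mk_insts(bx, by, sy=np.full(6, 0.02)))
        # negating a SNP's exposure and outcome effects is a relabelling only
        bx2, by2 = bx.copy(), by.copy()
        bx2[2] *= -1
        by2[2] *= -1
        got, _, gotf = egger(mk_insts(bx2, by2, sy=np.full(6, 0.02)))
        assert got.beta == pytest.approx(ref.beta)
        assert gotf.intercept == pytest.approx(reff.intercept)

    def test_collinear_exposure_effects_rejected(self):
        insts = mk_insts([0.1, 0.1, 0.1], [0.03, 0.05, 0.04], sy=np.full(3, 0.02))
        with pytest.raises(CollinearityError):
            egger(insts)

    def test_bootstrap_se_reproducible(self, clean_ten_snp):
        _, _, a = egger(clean_ten_snp, bootstrap_reps=300, seed=11)
        _, _, b = egger(clean_ten_snp, bootstrap_reps=300, seed=11)
        assert a.estimate.se == b.estimate.se
        assert a.intercept_se == b.intercept_se

    def test_fewer_than_three_rejected(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(mk_insts([0.1, 0.2], [0.03, 0.06]))

    def test_slope_beats_ivw_under_directional_pleiotropy(self):
        # direct effects alpha_j ~ N(0.03, 0.01²) bias IVW away from theta;
        # the Egger slope should be closer to truth in a large majority of runs
        theta = 0.25
        wins = 0
        n_rep = 500
        # well-powered outcome GWAS (5% cases) so the Egger slope variance
        # does not swamp the comparison
        for k in range(n_rep):
            cfg = SimConfig(
                n_snps=10, theta=theta, pleiotropy_mode="directional",
                pleiotropy_mean=0.03, pleiotropy_sd=0.01,
                n_out=500_000, case_fraction=0.05, seed=60_000 + k,
            )
            insts, _ = _sim_insts(cfg)
            e, _, _ = egger(insts)
            iv, _ = ivw(insts, model="fixed")
            wins += abs(e.beta - theta) < abs(iv.beta - theta)
        assert wins / n_rep >= 0.80


class TestInterceptTest:
    def test_matches_full_egger_analytic_fit(self, clean_ten_snp):
        _, _, full = egger(clean_ten_snp)
        a, se, p = egger_intercept_test(clean_ten_snp)
        assert a == pytest.approx(full.intercept)
        assert se == pytest.approx(full.intercept_se_analytic)

    def test_type_one_error_under_no_pleiotropy(self):
        # nominal 0.05 test; observed rejection over seeded null simulations
        n_rep, rej = 2000, 0
        for k in range(n_rep):
            insts, _ = _sim_insts(SimConfig(n_snps=10, theta=0.25, seed=100_000 + k))
            _, _, p = egger_intercept_test(insts)
            rej += p < 0.05
        assert rej / n_rep <= 0.075


class TestCochranQ:
    def test_identical_ratios(self):
        insts = mk_insts([0.1, 0.2], [0.03, 0.06], sy=[0.01, 0.02])
        q, df, p, i2 = cochran_q(insts, 0.3)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert (df, p, i2) == (1, pytest.approx(1.0), 0.0)

    def test_hand_arithmetic_two_snps(self):
        # unit weights, ratios 0 and 1 about beta=0.5: Q = 0.25 + 0.25
        insts = mk_insts([1.0, 1.0], [0.0, 1.0], sy=[1.0, 1.0])
        q, df, p, i2 = cochran_q(insts, 0.5)
        assert q == pytest.approx(0.5)
        assert df == 1

    def test_i2_never_negative(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            bx = rng.uniform(0.05, 0.2, 6)
            by = rng.normal(0.3 * bx, 0.02)
            insts = mk_insts(bx, by, sy=np.full(6, 0.02))
            est, _ = ivw(insts, model="fixed")
            *_, i2 = cochran_q(insts, est.beta)
            assert 0.0 <= i2 <= 100.0


class TestWeightedMedian:
    def test_equal_weights_odd_count_is_sample_median(self):
        assert weighted_median_value([0.1, 0.3, 0.9], [1, 1, 1]) == pytest.approx(0.3)

    def test_concentrated_weight_drives_estimate(self):
        assert weighted_median_value([0.1, 0.2, 0.9], [0.01, 0.98, 0.01]) == pytest.approx(0.2)

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=9).filter(lambda v: len(set(v)) == len(v)))
    def test_equal_weights_matches_numpy_median_for_odd_counts(self, vals):
        if len(vals) % 2 == 0:
            vals = vals[:-1]
        got = weighted_median_value(vals, np.ones(len(vals)))
        assert got == pytest.approx(float(np.median(vals)))

    def test_estimator_and_bootstrap_reproducible(self, clean_ten_snp):
        a = weighted_median(clean_ten_snp, bootstrap_reps=400, seed=5)
        b = weighted_median(clean_ten_snp, bootstrap_reps=400, seed=5)
        assert (a.beta, a.se) == (b.beta, b.se)
        c = weighted_median(clean_ten_snp, bootstrap_reps=400, seed=6)
        assert c.se != a.se  # different resampling stream

    def test_grid_scan_oracle_equivalence(self):
        # independent root-finding oracle on the cumulative-weight curve
        from scipy.optimize import brentq

        rng = np.random.default_rng(17)
        for _ in range(200):
            theta = np.sort(rng.normal(0.3, 0.5, 5))
            theta += np.arange(5) * 1e-9  # ensure strictly increasing
            w = rng.uniform(0.1, 5.0, 5)
            wn = w / w.sum()
            s = np.cumsum(wn) - wn / 2
            oracle = brentq(
                lambda t: np.interp(t, theta, s) - 0.5, theta[0], theta[-1],
                xtol=1e-13,
            )
            assert abs(weighted_median_value(theta, w) - oracle) < 1e-9


class TestPenalizedWeightedMedian:
    def test_no_outliers_equals_plain_weighted_median(self, clean_ten_snp):
        wm = weighted_median(clean_ten_snp, bootstrap_reps=10, seed=0)
        pwm = penalized_weighted_median(clean_ten_snp, bootstrap_reps=10, seed=0)
        assert pwm.beta == wm.beta

    def test_gross_outlier_downweighted(self):
        rng = np.random.default_rng(23)
        bx = rng.uniform(0.05, 0.12, 10)
        sy = np.full(10, 0.02)
        by = 0.3 * bx + rng.normal(0, sy)
        by[4] = 5.0 * bx[4]  # ratio 5 among ratios ~0.3
        insts = mk_insts(bx, by, sy=sy)
        clean = [h for i, h in enumerate(insts) if i != 4]
        ref = weighted_median(clean, bootstrap_reps=10, seed=0).beta
        pwm = penalized_weighted_median(insts, bootstrap_reps=10, seed=0).beta
        assert abs(pwm - ref) < 0.02

    def test_median_invariant_to_weight_scale(self):
        theta = [0.1, 0.25, 0.4, 0.8]
        w = np.array([1.0, 2.0, 1.5, 0.5])
        assert weighted_median_value(theta, w) == pytest.approx(
            weighted_median_value(theta, 100.0 * w)
        )


def test_all_estimators_rescale_equivariantly(clean_ten_snp):
    from dataclasses import replace
    from mrax.instruments import scale_exposure

    factor = 0.1
    scaled = scale_exposure(clean_ten_snp, factor)
    pairs = [
        (ivw(clean_ten_snp)[0], ivw(scaled)[0]),
        (max_likelihood(clean_ten_snp), max_likelihood(scaled)),
        (egger(clean_ten_snp)[0], egger(scaled)[0]),
        (weighted_median(clean_ten_snp, 200, 3), weighted_median(scaled, 200, 3)),
        (
            penalized_weighted_median(clean_ten_snp, 20, 200, 3),
            penalized_weighted_median(scaled, 20, 200, 3),
        ),
        (wald_ratio(clean_ten_snp[0]), wald_ratio(replace(
            clean_ten_snp[0],
            beta_exp=clean_ten_snp[0].beta_exp / factor,
            se_exp=clean_ten_snp[0].se_exp / factor,
        ))),
    ]
    for full, tenth in pairs:
        assert tenth.beta == pytest.approx(factor * full.beta, rel=1e-6), full.method
        assert tenth.se == pytest.approx(factor * full.se, rel=1e-6), full.method


def test_estimators_agree_without_pleiotropy():
    # strong instruments, no pleiotropy: all six estimates within a few
    # joint standard errors of each other and of the truth
    insts, truth = _sim_insts(SimConfig(n_snps=10, theta=0.25, n_exp=500_000, seed=77))
    ests = [
        ivw(insts)[0],
        max_likelihood(insts),
        egger(insts)[0],
        weighted_median(insts, 500, 1),
        penalized_weighted_median(insts, 20, 500, 1),
        wald_ratio(insts[0]),
    ]
    for e in ests:
        assert abs(e.beta - truth.theta) < 3.0 * max(e.se, 1e-6), e.method
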