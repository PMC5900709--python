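import numpy as np
import pandas as pd
import pytest

from _oracles import dense_wls_solve

from rhythm4c import fourc_prep, synthgen
from rhythm4c.lwmr import (
    LWMRData,
    LWMRFit,
    condition_weights,
    differential_test,
    estimate_sigma_min,
    fit_local_model,
    gaussian_weights,
    log_transform,
    lwmr_profile,
    prepare_lwmr_data,
    regularize_variance,
    rhythm_test,
)


class TestLogTransform:
    def test_zero(self):
        assert log_transform(0.0) == 0.0

    def test_nine_pseudocounts(self):
        assert log_transform(4500.0, 500.0) == pytest.approx(1.0)

    def test_one_pseudocount(self):
        assert log_transform(500.0, 500.0) == pytest.approx(np.log10(2.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform(-1.0)

    def test_monotone(self, rng):
        c = np.sort(rng.uniform(0, 1e4, 100))
        y = log_transform(c)
        assert (np.diff(y) >= 0).all()


class TestGaussianWeights:
    def test_center_is_one(self):
        assert gaussian_weights(np.array([100.0]), 100.0)[0] == 1.0

    def test_one_sigma(self):
        w = gaussian_weights(np.array([2500.0]), 0.0, sigma_g=2500.0)
        assert w[0] == pytest.approx(np.exp(-0.5))

    def test_symmetric(self):
        w = gaussian_weights(np.array([-700.0, 700.0]), 0.0)
        assert w[0] == pytest.approx(w[1])


class TestConditionWeights:
    @pytest.mark.parametrize("n,expected", [(0, 0.5), (1, 1.5), (2, 2.5), (3, 3.5), (4, 4.5)])
    def test_paper_values(self, n, expected):
        assert condition_weights(n) == expected

    def test_generalizes_and_monotone(self):
        w = condition_weights(np.arange(8))
        assert w[2] == 2.5  # 2 of 3 nonzero in a triplicate design
        assert (np.diff(w) > 0).all()


def random_lwmr_data(rng, n_frag=5, n_cond=3, n_rep=4, spread=2000.0):
    positions = np.sort(rng.uniform(-spread, spread, n_frag))
    Y = rng.normal(0.2, 0.1, size=(n_frag, n_cond, n_rep)) ** 2
    w_s = rng.integers(0, n_rep + 1, size=(n_frag, n_cond)) + 0.5
    return LWMRData(
        fragment_ids=np.arange(n_frag),
        positions=positions,
        conditions=[f"c{j}" for j in range(n_cond)],
        times=None,
        Y=Y,
        w_s=w_s.astype(float),
        n_present=np.full((n_frag, n_cond), n_rep),
    )


class TestFitLocalModel:
    def test_matches_dense_wls_oracle(self, rng):
        for _ in range(20):
            data = random_lwmr_data(rng)
            center = float(rng.uniform(-1000, 1000))
            fit = fit_local_model(data, center)
            a_o, b_o = dense_wls_solve(data.positions, data.Y, data.w_s, center, 2500.0)
            np.testing.assert_allclose(fit.a, a_o, rtol=1e-8, atol=1e-10)
            np.testing.assert_allclose(fit.b, b_o, rtol=1e-8, atol=1e-10)

    def test_identical_conditions_zero_delta(self, rng):
        data = random_lwmr_data(rng, n_cond=1)
        Y = np.concatenate([data.Y, data.Y], axis=1)
        data2 = LWMRData(
            fragment_ids=data.fragment_ids,
            positions=data.positions,
            conditions=["c0", "c1"],
            times=None,
            Y=Y,
            w_s=np.concatenate([data.w_s, data.w_s], axis=1),
            n_present=np.concatenate([data.n_present, data.n_present], axis=1),
        )
        fit = fit_local_model(data2, 0.0)
        assert fit.b[0] == pytest.approx(fit.b[1], abs=1e-12)

    def test_constraint_weighted_mean_of_a_is_zero(self, rng):
        data = random_lwmr_data(rng)
        fit = fit_local_model(data, 0.0)
        w_g = gaussian_weights(data.positions, 0.0)
        assert abs(np.sum(w_g * fit.a)) < 1e-10

    def test_b_is_local_mean_for_balanced_flat_weights(self, rng):
        # equal weights everywhere: b_j is the weighted mean of Y in cond j
        data = random_lwmr_data(rng, n_frag=4, n_cond=2, n_rep=3, spread=100.0)
        data.w_s[:] = 3.5
        fit = fit_local_model(data, 0.0)
        w_g = gaussian_weights(data.positions, 0.0)
        for j in range(2):
            expected = np.sum(w_g[:, None] * data.Y[:, j, :]) / (3 * w_g.sum())
            assert fit.b[j] == pytest.approx(expected, rel=1e-9)

    def test_zscore_invariant_to_constant_shift(self, rng):
        data = random_lwmr_data(rng)
        fit1 = fit_local_model(data, 0.0)
        data.Y = data.Y + 0.7
        fit2 = fit_local_model(data, 0.0)
        d1 = differential_test(fit1, ("c0", "c1"))
        d2 = differential_test(fit2, ("c0", "c1"))
        assert d1.z == pytest.approx(d2.z, rel=1e-8)
        np.testing.assert_allclose(fit1.a, fit2.a, atol=1e-9)

    def test_single_fragment_window_returns_none(self):
        data = LWMRData(
            fragment_ids=np.array([0]),
            positions=np.array([0.0]),
            conditions=["c0"],
            times=None,
            Y=np.full((1, 1, 2), 0.3),
            w_s=np.array([[2.5]]),
            n_present=np.array([[2]]),
        )
        assert fit_local_model(data, 0.0) is None

    def test_window_truncation(self, rng):
        data = random_lwmr_data(rng, n_frag=8, spread=30_000.0)
        fit = fit_local_model(data, float(data.positions[0]))
        inside = np.abs(data.positions - data.positions[0]) <= 4 * 2500.0
        assert set(fit.window_fragment_ids) == set(np.flatnonzero(inside))


class TestRegularizeVariance:
    def test_bbar_zero(self):
        assert regularize_variance(0.04, 0.0, 0.1) == pytest.approx(0.04 + 0.01)

    def test_large_bbar_limit(self):
        assert regularize_variance(0.04, 50.0, 0.1) == pytest.approx(0.04)

    def test_bbar_at_scale(self):
        expected = 0.04 + 0.01 / np.e
        assert regularize_variance(0.04, np.log10(2.0), 0.1) == pytest.approx(expected)

    def test_never_below_sigma2_hat(self, rng):
        for _ in range(50):
            s2 = rng.uniform(0, 0.1)
            assert regularize_variance(s2, rng.normal(), rng.uniform(0, 0.3)) >= s2

    def test_inflation_monotone_decreasing_in_bbar(self):
        b = np.linspace(-1, 3, 30)
        vals = [regularize_variance(0.02, bb, 0.1) for bb in b]
        assert (np.diff(vals) < 0).all()


class TestEstimateSigmaMin:
    def test_degenerate_distribution(self):
        s2 = np.full(200, 0.09)
        bb = np.linspace(0, 1, 200)
        assert estimate_sigma_min(s2, bb) == pytest.approx(0.3)

    def test_too_few_fragments(self):
        with pytest.raises(ValueError):
            estimate_sigma_min(np.ones(50), np.ones(50))

    def test_recovers_known_noise_floor(self):
        # high-signal fragments at the floor 0.1^2, low-signal inflated
        rng = np.random.default_rng(0)
        bb = rng.uniform(0, 1, 500)
        s2 = np.where(bb > 0.5, 0.01, 0.05) * rng.uniform(0.9, 1.1, 500)
        est = estimate_sigma_min(s2, bb)
        assert 0.05 < est < 0.2


def make_fit(b, se=0.05, n=100, p=10, times=None):
    b = np.asarray(b, dtype=float)
    J = b.size
    return LWMRFit(
        fragment_id=0,
        position=0.0,
        conditions=[f"c{j}" for j in range(J)],
        window_fragment_ids=np.arange(5),
        a=np.zeros(5),
        b=b,
        cov_b_unit=np.eye(J) * se**2,
        sigma2_hat=1.0,
        n=n,
        p=p,
        sigma_min=0.0,
        times=times,
    )


class TestDifferentialTest:
    def test_equal_effects_zero_z_unit_p(self):
        res = differential_test(make_fit([0.3, 0.3]), ("c0", "c1"))
        assert res.z == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_sign_convention(self):
        res = differential_test(make_fit([0.5, 0.3]), ("c0", "c1"))
        assert res.z > 0
        assert np.sign(res.signed_mlog10p) == 1.0

    def test_known_z_value(self):
        fit = make_fit([0.5, 0.3], se=0.05)
        res = differential_test(fit, ("c0", "c1"), use_covariance=False)
        assert res.z == pytest.approx(0.2 / np.sqrt(2 * 0.05**2))

    def test_underdetermined_flagged(self):
        fit = make_fit([0.5, 0.3], n=5, p=10)
        res = differential_test(fit, ("c0", "c1"))
        assert np.isnan(res.pvalue)


class TestRhythmTest:
    def test_constant_b_no_rhythm(self):
        t = np.arange(0, 24, 4.0)
        res = rhythm_test(make_fit(np.full(6, 0.4), times=t))
        assert res.amplitude == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    @pytest.mark.parametrize("t0", [0.0, 4.0, 8.0, 20.0])
    def test_cosine_identity(self, t0):
        t = np.arange(0, 24, 4.0)
        b = np.cos(2 * np.pi * (t - t0) / 24.0)
        res = rhythm_test(make_fit(b, times=t))
        assert res.amplitude == pytest.approx(1.0, abs=1e-9)
        assert abs(res.phase - t0) % 24 < 1e-9

    def test_chi2_stat_scales_with_se(self):
        t = np.arange(0, 24, 4.0)
        b = 0.1 * np.cos(2 * np.pi * (t - 20) / 24.0) + 0.5
        r1 = rhythm_test(make_fit(b, se=0.01, times=t))
        r2 = rhythm_test(make_fit(b, se=0.1, times=t))
        assert r1.chi2 > r2.chi2

    def test_requires_times(self):
        with pytest.raises(ValueError):
            rhythm_test(make_fit([0.1, 0.2, 0.3, 0.4]))

    def test_log2_fold_change(self):
        t = np.arange(0, 24, 4.0)
        b = 0.5 * np.cos(2 * np.pi * t / 24.0)
        res = rhythm_test(make_fit(b, times=t))
        assert res.log2_fold_change == pytest.approx(1.0 / np.log10(2.0))


@pytest.fixture(scope="module")
def rhythmic_cm():
    cfg = synthgen.FourCSimConfig(
        chrom_length=300_000,
        bait_pos=150_000,
        background_rate=50.0,
        loop_base_amp=150.0,
        loop_center=200_000,
        loop_sigma=5_000.0,
        rhythm_relamp=0.5,
        rhythm_peaktime=20.0,
        n_replicates=3,
        dropout_prob=0.1,
        seed=42,
    )
    cm, truth = synthgen.simulate_4c(cfg)
    return fourc_prep.normalize_library(cm), truth


class TestProfilePipeline:
    def test_masked_fragments_absent(self, rhythmic_cm):
        cm, _ = rhythmic_cm
        prof = lwmr_profile(cm, region=(140_000, 160_000))
        masked = set(cm.fragments.loc[cm.fragments["is_masked"], "fragment_id"])
        assert not masked & set(prof["fragment_id"])

    def test_loop_recovery_position_and_phase(self, rhythmic_cm):
        cm, truth = rhythmic_cm
        prof = lwmr_profile(cm, rhythm=True, region=(160_000, 240_000))
        best = prof.loc[prof["p_rhythm"].idxmin()]
        assert abs(best["position"] - 200_000) <= 2500.0
        assert abs((best["phase"] - 20.0 + 12) % 24 - 12) <= 1.5

    def test_differential_peak_at_loop(self, rhythmic_cm):
        cm, _ = rhythmic_cm
        prof = lwmr_profile(cm, contrast=("ZT20", "ZT8"), region=(160_000, 240_000))
        best = prof.loc[prof["p_diff"].idxmin()]
        assert abs(best["position"] - 200_000) <= 2500.0
        assert best["z"] > 0  # stronger contact at ZT20

    def test_sigma2_reg_at_least_sigma2_hat(self, rhythmic_cm):
        cm, _ = rhythmic_cm
        prof = lwmr_profile(cm, region=(160_000, 240_000))
        ok = prof.dropna(subset=["sigma2_hat"])
        assert (ok["sigma2_reg"] >= ok["sigma2_hat"] - 1e-15).all()

    def test_amplitude_monotone_in_relamp(self):
        # mean rhythm amplitude at the loop grows with the true relative
        # amplitude (Spearman rho over a grid)
        from scipy.stats import spearmanr

        amps = []
        relamps = [0.1, 0.3, 0.5, 0.8]
        for relamp in relamps:
            cfg = synthgen.FourCSimConfig(
                chrom_length=120_000,
                bait_pos=30_000,
                background_rate=50.0,
                loop_base_amp=200.0,
                loop_center=80_000,
                loop_sigma=5_000.0,
                rhythm_relamp=relamp,
                rhythm_peaktime=20.0,
                n_replicates=3,
                seed=7,
            )
            cm, _ = synthgen.simulate_4c(cfg)
            cm = fourc_prep.normalize_library(cm)
            prof = lwmr_profile(cm, rhythm=True, region=(75_000, 85_000))
            amps.append(prof["amplitude"].mean())
        rho = spearmanr(relamps, amps).statistic
        assert rho > 0.9

    def test_prepare_excludes_masked_and_trans(self, rhythmic_cm):
        cm, _ = rhythmic_cm
        data = prepare_lwmr_data(cm)
        masked = set(cm.fragments.loc[cm.fragments["is_masked"], "fragment_id"])
        assert not masked & set(data.fragment_ids)
        assert data.times is not None
        assert len(data.times) == len(data.conditions)
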