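import numpy as np
import pytest

from socnet import (Avalanche, FitRefusedError, GWConfig, analyze_ensemble,
                    exponent_relation_check, fit_powerlaw_tail,
                    fit_size_vs_duration, gw_avalanches, shape_collapse)
from socnet.scaling import default_duration_range, default_size_range


def _zipf_samples(tau, n, x_min, x_max, seed):
    support = np.arange(x_min, x_max + 1, dtype=np.float64)
    p = support ** (-tau)
    p /= p.sum()
    return np.random.default_rng(seed).choice(
        support.astype(np.int64), size=n, p=p)


class TestPowerlawFit:
    def test_mle_recovers_zipf_exponent_precisely(self):
        # reference case for the estimator: tau=1.5, 1e5 samples on [1,1e4]
        samples = _zipf_samples(1.5, 100_000, 1, 10_000, seed=1)
        fit = fit_powerlaw_tail(samples, 1, 10_000)
        assert fit.exponent == pytest.approx(1.5, abs=0.02)

    @pytest.mark.parametrize("tau", [1.2, 1.5, 2.0, 2.5])
    def test_parameter_recovery_suite(self, tau):
        samples = _zipf_samples(tau, 30_000, 1, 10_000, seed=int(tau * 100))
        fit = fit_powerlaw_tail(samples, 1, 10_000)
        # unbiased within ~4 SD of the observed-information stderr
        assert abs(fit.exponent - tau) < 4 * fit.stderr + 0.01
        assert fit.stderr > 0

    def test_cumulative_exponent_bookkeeping(self):
        samples = _zipf_samples(2.0, 5_000, 1, 1_000, seed=3)
        fit = fit_powerlaw_tail(samples, 1, 1_000)
        assert fit.cumulative_exponent == fit.exponent - 1.0

    def test_ccdf_estimator_exact_on_constructed_tail(self):
        # sample multiset built so the empirical CCDF is exactly
        # P(X >= 4^k) = 2^-k: the least-squares slope must be 1/2
        values, counts = [], []
        for k in range(8):
            values.append(4 ** k)
            counts.append(2 ** (9 - k) if k < 7 else 2 ** 3)
        samples = np.repeat(values, counts)
        fit = fit_powerlaw_tail(samples, 1, 4 ** 7)
        assert fit.exponent_ccdf == pytest.approx(0.5, abs=1e-9)

    def test_degenerate_support_refused(self):
        with pytest.raises(FitRefusedError):
            fit_powerlaw_tail(np.full(500, 7), 1, 100)

    def test_too_few_in_range_refused(self):
        with pytest.raises(FitRefusedError):
            fit_powerlaw_tail(np.arange(1, 60), 1, 100)

    def test_nonpositive_samples_refused(self):
        with pytest.raises(FitRefusedError):
            fit_powerlaw_tail([0, 1, 2], 1, 10)


class TestSizeVsDuration:
    def _avs(self, durations, size_fn, per=25):
        out = []
        for t in durations:
            for _ in range(per):
                s = int(size_fn(t))
                out.append(Avalanche(size=s, duration=t,
                                     profile=np.ones(t, dtype=np.int64),
                                     trigger=0, terminated_by="natural"))
        return out

    def test_exact_quadratic_relation(self):
        avs = self._avs(range(1, 15), lambda t: t * t)
        gamma, se = fit_size_vs_duration(avs, 1, 14)
        assert gamma == pytest.approx(2.0, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_relation(self):
        avs = self._avs(range(1, 15), lambda t: 3 * t)
        gamma, _ = fit_size_vs_duration(avs, 1, 14)
        assert gamma == pytest.approx(1.0, abs=1e-12)

    def test_sparse_durations_refused(self):
        avs = self._avs(range(1, 6), lambda t: t)
        with pytest.raises(FitRefusedError):
            fit_size_vs_duration(avs, 1, 5)

    def test_underpopulated_durations_excluded(self):
        avs = self._avs(range(1, 15), lambda t: t * t, per=5)
        with pytest.raises(FitRefusedError):
            fit_size_vs_duration(avs, 1, 14)


class TestExponentRelation:
    def test_mean_field_triple_is_exact(self):
        res, se = exponent_relation_check(1.5, 0.0, 2.0, 0.0, 2.0, 0.0)
        assert res == pytest.approx(0.0)
        assert se == 0.0

    def test_residual_arithmetic(self):
        res, _ = exponent_relation_check(1.5, 0.0, 2.0, 0.0, 1.5, 0.0)
        assert res == pytest.approx(-0.5)

    def test_error_propagation_grows_with_inputs(self):
        _, se0 = exponent_relation_check(1.5, 0.01, 2.0, 0.0, 2.0, 0.0)
        _, se1 = exponent_relation_check(1.5, 0.01, 2.0, 0.05, 2.0, 0.05)
        assert se1 > se0 > 0


class TestShapeCollapse:
    @staticmethod
    def _parabolic(duration, gamma=2.0, n=60):
        x = np.linspace(0.0, 1.0, duration)
        shape = 4.0 * x * (1.0 - x) + 0.05
        prof = np.maximum(1, np.round(
            duration ** (gamma - 1.0) * shape)).astype(np.int64)
        return [Avalanche(size=int(prof.sum()), duration=duration,
                          profile=prof, trigger=0, terminated_by="natural")
                for _ in range(n)]

    def test_recovers_construction_exponent(self):
        avs = sum((self._parabolic(d) for d in (8, 16, 32, 64)), [])
        result = shape_collapse(avs, candidate_gammas=np.arange(1.0, 3.0, 0.02))
        assert result.gamma_shape == pytest.approx(2.0, abs=0.05)
        assert result.collapse_error < 0.1 * result.baseline_error

    def test_unrelated_shapes_do_not_collapse(self):
        # classes whose shapes and amplitudes have no common scaling:
        # the best exponent cannot do meaningfully better than none
        rng = np.random.default_rng(5)
        avs = []
        for d in (8, 16, 32):
            prof = (rng.integers(1, 40, size=d)).astype(np.int64)
            avs += [Avalanche(size=int(prof.sum()), duration=d,
                              profile=prof, trigger=0,
                              terminated_by="natural") for _ in range(60)]
        result = shape_collapse(avs)
        assert result.collapse_error > 0.5 * result.baseline_error

    def test_too_few_classes_refused(self):
        avs = self._parabolic(8) + self._parabolic(16)
        with pytest.raises(FitRefusedError):
            shape_collapse(avs)

    def test_explicit_underpopulated_class_refused(self):
        avs = (self._parabolic(8) + self._parabolic(16)
               + self._parabolic(32, n=10))
        with pytest.raises(FitRefusedError):
            shape_collapse(avs, durations=[8, 16, 32])


class TestGWCalibration:
    def test_subcritical_mean_size_closed_form(self):
        # total progeny of a subcritical branching process with mean m:
        # E[S] = 1/(1-m); m=0.5 gives 2
        avs, _ = gw_avalanches(GWConfig(n_avalanches=20_000, p_two=0.25,
                                        seed=6))
        sizes = np.array([a.size for a in avs])
        se = sizes.std() / np.sqrt(sizes.size)
        assert abs(sizes.mean() - 2.0) < 4 * se

    def test_critical_size_exponent_near_mean_field(self):
        avs, _ = gw_avalanches(GWConfig(n_avalanches=20_000, seed=7))
        fit = fit_powerlaw_tail([a.size for a in avs], 20, 10_000)
        assert fit.exponent == pytest.approx(1.5, abs=0.1)

    def test_collapse_consistent_with_size_duration_fit(self):
        avs, _ = gw_avalanches(GWConfig(n_avalanches=60_000, seed=8))
        gamma, gse = fit_size_vs_duration(avs, 20, 100)
        col = shape_collapse(avs, durations=[8, 16, 32])
        joint = 2 * np.hypot(gse, col.gamma_stderr)
        assert abs(col.gamma_shape - gamma) < max(joint, 0.3)
        assert col.collapse_error < 0.5 * col.baseline_error


class TestAnalyzeEnsemble:
    def test_default_ranges_and_full_fit(self):
        avs, _ = gw_avalanches(GWConfig(n_avalanches=40_000, seed=9))
        n_nodes = 10_000
        assert default_size_range(avs, n_nodes) == (1, 5_000)
        t_rng = default_duration_range(avs, n_nodes)
        assert t_rng[0] == 1
        fit = analyze_ensemble(avs, n_nodes)
        d = fit.to_dict()
        for key in ("tau_s", "alpha_t", "gamma", "relation_residual",
                    "relation_stderr", "relation_consistent"):
            assert key in d
        assert fit.size_fit.cumulative_exponent == fit.tau_s - 1.0
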