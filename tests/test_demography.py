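"""Diffusion engine, composite likelihood, optimisation and uncertainty."""

import numpy as np
import pytest

from reefdiverge.demography import (DEFAULT_BOUNDS, DadiParams,
                                    DemographicModel, ExpectedJAFSEngine,
                                    FitResult, compare_models,
                                    composite_loglik, fim_sd, lrt_adjusted,
                                    numeric_hessian, optimize_fit)
from reefdiverge.jafs import JAFS

CHEAP = dict(pts=(20, 28, 36), timescale_factor=2e-3)


@pytest.fixture(scope="module")
def engine():
    return ExpectedJAFSEngine(8, 8, **CHEAP)


def _toy_spectrum(counts, n):
    return JAFS(np.asarray(counts, dtype=float), n, folded=True)


class TestCompositeLoglik:
    def test_theta_hat_is_ratio_of_sums(self):
        data = _toy_spectrum([[0, 2, 3], [5, 0, 0]], (1, 2))
        model = _toy_spectrum([[0, 0.2, 0.3], [0.5, 0, 0]], (1, 2))
        ll, theta = composite_loglik(model, data)
        assert theta == pytest.approx(10.0)

    def test_proportional_data_recovers_scale(self):
        rng = np.random.default_rng(0)
        m = rng.random((4, 4))
        model = _toy_spectrum(m, (3, 3))
        data = _toy_spectrum(7.5 * m, (3, 3))
        _, theta = composite_loglik(model, data)
        assert theta == pytest.approx(7.5)

    def test_profiled_theta_maximises_loglik(self):
        rng = np.random.default_rng(1)
        m = rng.random((4, 4))
        d = rng.poisson(20 * m).astype(float)
        model = _toy_spectrum(m, (3, 3))
        data = _toy_spectrum(d, (3, 3))
        ll_hat, theta_hat = composite_loglik(model, data)
        from scipy.special import gammaln
        mask = model.mask | data.mask
        mm, dd = m[~mask], d[~mask]
        for theta in np.linspace(0.5 * theta_hat, 1.5 * theta_hat, 21):
            ll = float(np.sum(dd * np.log(theta * mm) - theta * mm
                              - gammaln(dd + 1)))
            assert ll <= ll_hat + 1e-9

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            composite_loglik(_toy_spectrum(np.ones((3, 3)), (2, 2)),
                             _toy_spectrum(np.ones((4, 4)), (3, 3)))


class TestNestingIdentities:
    def test_im_zero_migration_equals_si(self, engine):
        si = engine.expected(DadiParams("SI", nu1=1.5, nu2=0.8, T=0.6))
        im = engine.expected(DadiParams("IM", nu1=1.5, nu2=0.8, T=0.6,
                                        M=0.0))
        assert np.allclose(si.counts, im.counts, rtol=1e-6)

    def test_im2m_collapses_to_im(self, engine):
        im = engine.expected(DadiParams("IM", T=0.6, M=1.5))
        q0 = engine.expected(DadiParams("IM2M", T=0.6, M=1.5, M_e=0.1,
                                        Q=0.0))
        equal_rates = engine.expected(DadiParams("IM2M", T=0.6, M=1.5,
                                                 M_e=1.5, Q=0.4))
        assert np.allclose(im.counts, q0.counts, rtol=1e-6)
        assert np.allclose(im.counts, equal_rates.counts, rtol=1e-6)

    def test_secondary_contact_endpoints(self, engine):
        im = engine.expected(DadiParams("IM", T=0.6, M=2.0))
        si = engine.expected(DadiParams("SI", T=0.6))
        sc_full = engine.expected(DadiParams("SC", T=0.6, M=2.0,
                                             phase_frac=1.0))
        sc_none = engine.expected(DadiParams("SC", T=0.6, M=2.0,
                                             phase_frac=1e-12))
        assert np.allclose(im.counts, sc_full.counts, rtol=1e-6)
        assert np.allclose(si.counts, sc_none.counts, rtol=1e-6)

    def test_ancient_migration_endpoints(self, engine):
        im = engine.expected(DadiParams("IM", T=0.6, M=2.0))
        si = engine.expected(DadiParams("SI", T=0.6))
        am_all = engine.expected(DadiParams("AM", T=0.6, M=2.0,
                                            phase_frac=1e-12))
        am_none = engine.expected(DadiParams("AM", T=0.6, M=2.0,
                                             phase_frac=1.0))
        assert np.allclose(im.counts, am_all.counts, rtol=1e-6)
        assert np.allclose(si.counts, am_none.counts, rtol=1e-6)

    def test_transposition_symmetry(self):
        a = ExpectedJAFSEngine(6, 10, **CHEAP).expected(
            DadiParams("IM", nu1=2.0, nu2=0.7, T=0.5, M=1.0))
        b = ExpectedJAFSEngine(10, 6, **CHEAP).expected(
            DadiParams("IM", nu1=0.7, nu2=2.0, T=0.5, M=1.0))
        keep = ~(a.mask | b.transpose().mask)
        an = a.normalised().counts
        bn = b.transpose().normalised().counts
        assert np.allclose(an[keep], bn[keep], rtol=1e-3, atol=1e-8)


class TestOptimisation:
    def _synthetic_data(self, params, theta=400.0):
        engine = ExpectedJAFSEngine(8, 8, **CHEAP)
        model = engine.expected(params)
        data = model.copy()
        data.counts = model.counts * theta
        return data

    def test_fixed_seed_identical_trace(self):
        data = self._synthetic_data(DadiParams("IM", T=0.8, M=1.0))
        kw = dict(rounds=(1,), runs_per_round=2, maxiter=15, **CHEAP)
        a = optimize_fit(data, "IM", seed=5, **kw)
        b = optimize_fit(data, "IM", seed=5, **kw)
        assert a.trace == b.trace
        assert a.loglik == b.loglik

    def test_recovers_noise_free_im_parameters(self):
        truth = DadiParams("IM", nu1=1.5, nu2=0.8, T=0.8, M=1.2)
        data = self._synthetic_data(truth, theta=2000.0)
        fit = optimize_fit(data, "IM", seed=1, rounds=(1,),
                           runs_per_round=3, maxiter=120, fatol=1e-4,
                           **CHEAP)
        for name in ("nu1", "nu2", "T", "M"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(truth, name), rel=0.15)

    def test_si_data_fit_with_im_drives_migration_to_zero(self):
        data = self._synthetic_data(DadiParams("SI", T=1.0), theta=2000.0)
        fit = optimize_fit(data, "IM", seed=2, rounds=(1,),
                           runs_per_round=3, maxiter=120, fatol=1e-4,
                           **CHEAP)
        assert fit.params.M < 0.05

    def test_unknown_model_rejected(self):
        data = self._synthetic_data(DadiParams("SI", T=1.0))
        with pytest.raises(ValueError):
            optimize_fit(data, "XX")

    def test_estimator_facade_sets_fitted_attributes(self):
        data = self._synthetic_data(DadiParams("SI", T=1.0), theta=500.0)
        est = DemographicModel("SI", rounds=(1,), runs_per_round=1,
                               seed=0, pts=CHEAP["pts"],
                               timescale_factor=CHEAP["timescale_factor"])
        est.set_params(**est.get_params())
        est.fit(data)
        assert est.aic_ == pytest.approx(
            2 * est.result_.n_free_params - 2 * est.loglik_)
        assert est.params_.model_name == "SI"
        pred = est.predict(data)
        assert pred.counts.shape == data.counts.shape


class TestModelComparison:
    def _fit(self, model, ll, k):
        params = DadiParams(model, T=1.0)
        return FitResult(params, ll, 2 * k - 2 * ll, k)

    def test_aic_formula(self):
        table = compare_models([self._fit("SI", -100.0, 3)])
        assert table["aic"].iloc[0] == pytest.approx(206.0)

    def test_identical_fits_declared_tie(self):
        fits = [self._fit("SI", -50.0, 4), self._fit("IM", -50.0, 4)]
        table = compare_models(fits)
        assert table["tie_with_best"].all()

    def test_ordering_by_aic(self):
        fits = [self._fit("SI", -60.0, 4), self._fit("IM", -50.0, 5)]
        table = compare_models(fits)
        assert list(table["model"]) == ["IM", "SI"]


class TestUncertainty:
    def test_quadratic_hessian_matches_closed_form(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(3, 3))
        H_true = -(A @ A.T + 3 * np.eye(3))
        z_star = np.array([0.3, -0.2, 0.5])

        def f(z):
            d = z - z_star
            return 0.5 * d @ H_true @ d

        H_num = numeric_hessian(f, np.zeros(3), rel_step=1e-3)
        assert np.allclose(H_num, H_true, atol=1e-4)

    def test_fim_sd_scales_with_data_mass(self):
        engine = ExpectedJAFSEngine(8, 8, **CHEAP)
        params = DadiParams("SI", nu1=1.2, nu2=0.9, T=0.8)
        model = engine.expected(params)
        data = model.copy()
        data.counts = model.counts * 500.0
        data2 = model.copy()
        data2.counts = model.counts * 1000.0
        fit = FitResult(params, 0.0, 0.0, 4)
        sd1 = fim_sd(fit, data, engine=engine)
        sd2 = fim_sd(fit, data2, engine=engine)
        for name in ("nu1", "nu2", "T"):
            ratio = sd2[name]["sd"] / sd1[name]["sd"]
            assert ratio == pytest.approx(1 / np.sqrt(2), rel=0.08)

    def test_parameter_at_bound_flagged(self):
        engine = ExpectedJAFSEngine(8, 8, **CHEAP)
        lo = DEFAULT_BOUNDS["M"][0]
        params = DadiParams("IM", T=0.8, M=lo)
        model = engine.expected(params)
        data = model.copy()
        data.counts = model.counts * 300.0
        fit = FitResult(params, 0.0, 0.0, 5)
        sd = fim_sd(fit, data, engine=engine)
        assert sd["M"]["at_bound"]


class TestLikelihoodRatio:
    def test_identical_fits_statistic_zero_p_one(self):
        engine = ExpectedJAFSEngine(8, 8, **CHEAP)
        params_im = DadiParams("IM", T=0.8, M=1e-3)
        params_si = DadiParams("SI", T=0.8)
        model = engine.expected(params_im)
        data = model.copy()
        data.counts = model.counts * 200.0
        full = FitResult(params_im, -100.0, 210.0, 5)
        nested = FitResult(params_si, -100.0, 208.0, 4)
        res = lrt_adjusted(full, nested, data, [data], engine=engine)
        assert res["statistic_adjusted"] == 0.0
        assert res["p_value"] == 1.0

    def test_non_nested_pair_rejected(self):
        a = FitResult(DadiParams("SC", T=1.0, M=1.0), -10.0, 30.0, 6)
        b = FitResult(DadiParams("AM", T=1.0, M=1.0), -12.0, 34.0, 6)
        with pytest.raises(ValueError):
            lrt_adjusted(a, b, None, [])

    def test_strong_migration_signal_is_significant(self):
        """IM-truth data strongly rejects SI under the adjusted LRT."""
        from reefdiverge.jafs import bootstrap_jafs, build_jafs
        from reefdiverge.simdata import SimScenario, simulate_pair

        sc = SimScenario("IM", nu1=1.0, nu2=1.0, T_total=1.0, M=2.0,
                         n1=5, n2=5, n_tags=1500, theta_per_tag=0.4,
                         seed=71)
        gm = simulate_pair(sc).genotypes
        data = build_jafs(gm, ("pop1", "pop2"), (8, 8))
        boots = bootstrap_jafs(gm, ("pop1", "pop2"), (8, 8), n_boot=30,
                               seed=72)
        kw = dict(rounds=(1,), runs_per_round=2, maxiter=60, fatol=1e-2,
                  pts=(36,), timescale_factor=2e-3)
        fit_si = optimize_fit(data, "SI", seed=73, **kw)
        fit_im = optimize_fit(data, "IM", seed=74, **kw)
        engine = ExpectedJAFSEngine(8, 8, pts=(36,), timescale_factor=2e-3)
        res = lrt_adjusted(fit_im, fit_si, data, boots, engine=engine)
        assert res["statistic_raw"] > 0
        assert res["p_value"] < 0.05
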