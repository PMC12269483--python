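import numpy as np
import pytest

import discoate as d
from discoate.estimators import _delta_variance

from conftest import identical_sites_dataset


class TestAIPWFold:
    def test_interpolating_outcome_model_ignores_propensity(self, rng):
        X = rng.normal(size=(50, 4))
        beta = np.array([1.0, 0.5, -0.5, 0.2, 0.0])
        Xd = np.hstack([np.ones((50, 1)), X])
        Y = Xd @ beta
        T = rng.integers(0, 2, size=50)
        site = d.SiteData(1, T, Y, X)
        for theta in (np.zeros(5), rng.normal(size=5)):
            est = d.aipw_fold([site], theta, beta, arm=1)
            assert est == pytest.approx(float(Y.mean()))

    def test_all_treated_unit_propensity_collapses_to_sample_mean(self, rng):
        X = rng.normal(size=(40, 3))
        Y = rng.normal(size=40)
        site = d.SiteData(1, np.ones(40), Y, X)
        cfg = d.FitConfig(clip_pi=(1e-6, 1 - 1e-9))
        theta = np.array([40.0, 0.0, 0.0, 0.0])  # pi = 1 numerically
        est = d.aipw_fold([site], theta, np.zeros(4), arm=1, config=cfg)
        assert est == pytest.approx(float(Y.mean()), abs=1e-6)

    def test_true_nuisances_near_truth_at_scale(self):
        spec = d.ScenarioSpec.canonical("I", K=4, n=5000, p=6, seed=42)
        ds = d.generate(spec)
        t1 = d.aipw_fold(ds.sites, spec.theta_true, spec.beta1_true, arm=1)
        assert abs(t1 - 2.0) < 3 * 2.5 / np.sqrt(ds.total_n)

    def test_nonfinite_coefficients_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            d.aipw_fold(small_dataset.sites, np.full(13, np.nan), np.zeros(13))


class TestVariance:
    def test_zero_when_residuals_vanish_and_prediction_constant(self, rng):
        X = rng.normal(size=(30, 3))
        beta = np.array([2.0, 0.0, 0.0, 0.0])
        Xd = np.hstack([np.ones((30, 1)), X])
        site = d.SiteData(1, rng.integers(0, 2, size=30), Xd @ beta, X)
        v = d.estimate_variance([site], np.zeros(4), beta, tau=2.0, arm=1)
        assert v == pytest.approx(0.0, abs=1e-24)

    def test_invariant_to_site_ordering(self, small_dataset, rng):
        theta = 0.2 * rng.normal(size=small_dataset.spec.p + 1)
        beta = 0.2 * rng.normal(size=small_dataset.spec.p + 1)
        v1 = d.estimate_variance(small_dataset.sites, theta, beta, 1.0)
        v2 = d.estimate_variance(small_dataset.sites[::-1], theta, beta, 1.0)
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_delta_variance_nonnegative(self, small_dataset, rng):
        theta = 0.2 * rng.normal(size=small_dataset.spec.p + 1)
        b1 = 0.2 * rng.normal(size=small_dataset.spec.p + 1)
        b0 = 0.2 * rng.normal(size=small_dataset.spec.p + 1)
        assert _delta_variance(small_dataset.sites, theta, b1, b0, 1.0,
                               d.DEFAULT_CONFIG) >= 0.0


class TestEstimatorAgreement:
    def test_pooled_equals_simple_average_on_identical_sites(self):
        ds = identical_sites_dataset(K=6, n=200, p=8)
        cfg = d.FitConfig(lambda_ps=0.05, lambda_om=0.05)
        rp = d.estimate_pooled(ds, config=cfg, seed=0)
        rs = d.estimate_simple_average(ds, config=cfg, seed=0)
        assert rp.tau1 == pytest.approx(rs.tau1, abs=1e-7)
        assert rp.tau0 == pytest.approx(rs.tau0, abs=1e-7)

    def test_disco_orders_coincide_on_identical_sites(self):
        ds = identical_sites_dataset(K=6, n=200, p=8)
        cfg = d.FitConfig(lambda_ps=0.05, lambda_om=0.05,
                          tol_kkt=1e-9, tol_obj=1e-13)
        r1 = d.estimate_disco(ds, order=1, config=cfg, seed=0)
        r2 = d.estimate_disco(ds, order=2, config=cfg, seed=0)
        assert r1.delta == pytest.approx(r2.delta, abs=1e-8)

    def test_single_site_pooled_equals_local_pipeline(self, rng):
        base = d.generate(d.ScenarioSpec.canonical("I", K=3, n=300, p=8, seed=31))
        site = base.sites[0]
        ds = d.MultiSiteDataset(sites=[site], spec=base.spec, true_tau1=2.0,
                                true_tau0=1.0, true_delta=1.0)
        cfg = d.FitConfig(lambda_ps=0.05, lambda_om=0.05)
        rp = d.estimate_pooled(ds, config=cfg, seed=0)
        ps = d.fit_ps_local(site, lam=0.05, config=cfg)
        om1 = d.fit_om_local(site, ps.coef, arm=1, lam=0.05, config=cfg)
        t1 = d.aipw_fold([site], ps.coef, om1.coef, arm=1, config=cfg)
        assert rp.tau1 == pytest.approx(t1, abs=1e-8)


class TestDiscoStructure:
    def test_result_fields_consistent(self, small_dataset):
        res = d.estimate_disco(small_dataset, order=2, seed=3)
        assert res.delta == pytest.approx(res.tau1 - res.tau0, abs=1e-12)
        lo, hi = res.ci_delta
        assert lo <= res.delta <= hi
        assert res.var_delta >= 0
        assert res.estimator == "disco2"
        assert res.comm.total_floats() > 0

    def test_first_order_ships_fewer_floats(self, small_dataset):
        r1 = d.estimate_disco(small_dataset, order=1, seed=3)
        r2 = d.estimate_disco(small_dataset, order=2, seed=3)
        assert r1.comm.total_floats() < r2.comm.total_floats()

    def test_too_few_sites_suggests_remedy(self, small_dataset):
        ds = d.MultiSiteDataset(sites=small_dataset.sites[:2],
                                spec=small_dataset.spec,
                                true_tau1=2, true_tau0=1, true_delta=1)
        with pytest.raises(ValueError, match="K >= 3"):
            d.estimate_disco(ds, order=2)

    def test_dispatch_by_name(self, small_dataset):
        res = d.estimate(small_dataset, "disco1", seed=1)
        assert res.estimator == "disco1"
        with pytest.raises(ValueError):
            d.estimate(small_dataset, "nope")

    def test_fixed_theta_surrogate_outcome_equals_pooled_fold_fit(
        self, shift_dataset
    ):
        """Lossless property end-to-end: with the propensity coefficients
        held fixed, the distributed outcome fit equals the materialized
        fold-pooled weighted lasso."""
        from discoate.estimators import _fit_om_surrogate

        fold = shift_dataset.sites[:3]
        theta = shift_dataset.spec.theta_true
        cfg = d.FitConfig(lambda_om=0.08, tol_kkt=1e-9, tol_obj=1e-13)
        beta, lam, _ = _fit_om_surrogate(fold, theta, 1, 2, cfg, d.CommLog(), 0, 0)
        gold = d.fit_om_pooled(fold, theta, arm=1, lam=0.08, config=cfg)
        np.testing.assert_allclose(beta, gold.coef, atol=1e-6)


class TestResultSerialization:
    def test_json_payload_complete(self, small_dataset):
        res = d.estimate_disco(small_dataset, order=2, seed=3)
        import json

        payload = json.loads(res.to_json(seed=3))
        for key in ("estimator", "delta", "ci_delta", "var_delta",
                    "comm_total_floats", "fold_plan", "lambdas", "seed"):
            assert key in payload
        assert payload["seed"] == 3
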