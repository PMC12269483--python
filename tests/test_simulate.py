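import numpy as np
import pytest

import discoate as d
from discoate.simulate import FormatError, _draw_ar1


class TestAR1Covariance:
    def test_zero_correlation_gives_identity(self):
        np.testing.assert_array_equal(d.make_ar1_covariance(3, 0.0), np.eye(3))

    def test_lag_two_entry_is_rho_squared(self):
        M = d.make_ar1_covariance(6, 0.5)
        assert M[0, 2] == pytest.approx(0.25)
        assert M[3, 1] == pytest.approx(0.25)

    def test_positive_definite_at_high_decay(self):
        M = d.make_ar1_covariance(4, 0.8)
        assert np.linalg.eigvalsh(M).min() > 0

    @pytest.mark.parametrize("rho", [1.0, -1.0, 1.5])
    def test_invalid_decay_rejected(self, rho):
        with pytest.raises(ValueError):
            d.make_ar1_covariance(3, rho)

    def test_markov_draw_matches_target_covariance(self):
        rng = np.random.default_rng(0)
        X = _draw_ar1(rng, 200_000, 4, 0.6)
        emp = np.cov(X.T)
        np.testing.assert_allclose(emp, d.make_ar1_covariance(4, 0.6), atol=0.02)


class TestMisspecificationTransform:
    def test_printed_columns(self):
        X = np.zeros((1, 7))
        X[0, 2] = 2.0  # X3
        out = d.transform_misspecified(X)
        assert out[0, 2] == pytest.approx(8.0)
        X = np.zeros((1, 7))
        out = d.transform_misspecified(X)  # X4 = 0 -> exp(0) = 1
        assert out[0, 3] == pytest.approx(1.0)
        X = np.zeros((1, 7))
        X[0, 4] = 1.0  # X5 = 1, X6 = 0 -> 1 * (1 + 1)^-2 = 1/4
        out = d.transform_misspecified(X)
        assert out[0, 4] == pytest.approx(0.25)

    def test_other_columns_unchanged_and_shape_kept(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 9))
        out = d.transform_misspecified(X)
        assert out.shape == X.shape
        for col in (0, 1, 5, 6, 7, 8):
            np.testing.assert_array_equal(out[:, col], X[:, col])

    def test_too_few_columns_rejected(self):
        with pytest.raises(ValueError):
            d.transform_misspecified(np.zeros((5, 5)))


class TestGenerate:
    def test_shapes_match_spec(self):
        ds = d.generate(d.ScenarioSpec.canonical("I", K=10, n=200, p=100, seed=0))
        assert ds.K == 10
        assert all(s.n == 200 and s.p == 100 for s in ds.sites)
        assert all(np.isin(s.T, (0, 1)).all() for s in ds.sites)
        assert all((s.X_design[:, 0] == 1).all() for s in ds.sites)

    def test_same_seed_is_bit_identical(self):
        a = d.generate(d.ScenarioSpec.canonical("II", K=4, n=50, p=10, seed=9))
        b = d.generate(d.ScenarioSpec.canonical("II", K=4, n=50, p=10, seed=9))
        for sa, sb in zip(a.sites, b.sites):
            np.testing.assert_array_equal(sa.X, sb.X)
            np.testing.assert_array_equal(sa.Y, sb.Y)
            np.testing.assert_array_equal(sa.T, sb.T)
        assert a.true_delta == b.true_delta

    def test_correct_om_truth_is_analytic(self):
        ds = d.generate(d.ScenarioSpec.canonical("I", K=3, n=20, p=8, seed=1))
        assert ds.true_tau1 == 2.0 and ds.true_tau0 == 1.0 and ds.true_delta == 1.0

    def test_misspecified_om_delta_still_one_by_slope_cancellation(self):
        ds = d.generate(d.ScenarioSpec.canonical("VI", K=4, n=20, p=10, seed=2))
        # common slopes on common draws cancel exactly in the difference
        assert ds.true_delta == pytest.approx(1.0, abs=1e-12)
        assert ds.true_tau1 != pytest.approx(2.0, abs=0.01)  # nonlinear shift

    def test_misspecified_om_truth_matches_independent_monte_carlo(self):
        spec = d.ScenarioSpec.canonical("VI", K=4, n=20, p=10, seed=7)
        ds = d.generate(spec)
        rng = np.random.default_rng(424242)
        m = 400_000
        tot = 0.0
        for r in ds.rho:
            X = _draw_ar1(rng, m, 6, float(r))
            Xm = d.transform_misspecified(X)
            tot += np.mean(2.0 + Xm[:, :5] @ np.array([0.3, 0.2, -0.2, 0.2, -0.2]))
        assert ds.true_tau1 == pytest.approx(tot / len(ds.rho), abs=0.01)

    def test_treated_fraction_matches_sampling_oracle(self):
        # >= 1e5 units against an independent draw of E[expit(x'theta)]
        ds = d.generate(d.ScenarioSpec.canonical("I", K=5, n=20000, p=6, seed=3))
        frac = np.mean([s.T.mean() for s in ds.sites])
        rng = np.random.default_rng(777)
        X = _draw_ar1(rng, 200_000, 5, 0.5)
        pi = 1.0 / (1.0 + np.exp(-(-0.5 + X @ np.array([0.5, 0.3, -0.3, 0.3, -0.3]))))
        se = np.sqrt(pi.var() / 100_000 + frac * (1 - frac) / 100_000)
        assert abs(frac - pi.mean()) < 3 * se + 3 * pi.std() / np.sqrt(200_000)

    def test_covariate_shift_spreads_lag_one_autocorrelation(self):
        ds = d.generate(d.ScenarioSpec.canonical("II", K=10, n=400, p=20, seed=4))
        acs = []
        for s in ds.sites:
            x = s.X
            acs.append(np.mean([np.corrcoef(x[:, j], x[:, j + 1])[0, 1]
                                for j in range(x.shape[1] - 1)]))
        assert max(acs) - min(acs) > 0.1
        homog = d.generate(d.ScenarioSpec.canonical("I", K=10, n=400, p=20, seed=4))
        pooled = np.vstack([s.X for s in homog.sites])
        emp = np.cov(pooled.T)
        assert abs(emp[0, 1] - 0.5) < 0.03

    def test_validation_rejects_bad_specs(self):
        with pytest.raises(ValueError):
            d.generate(d.ScenarioSpec.canonical("I", K=2, n=50, p=8, seed=0))
        with pytest.raises(ValueError):
            d.generate(d.ScenarioSpec.canonical("V", K=4, n=50, p=5, seed=0))


class TestOracleAIPWConsistency:
    def test_true_nuisances_recover_effect_at_scale(self):
        """AIPW evaluated at the generating coefficients on ~1e5 rows."""
        spec = d.ScenarioSpec.canonical("I", K=5, n=20000, p=6, seed=11)
        ds = d.generate(spec)
        t1 = d.aipw_fold(ds.sites, spec.theta_true, spec.beta1_true, arm=1)
        t0 = d.aipw_fold(ds.sites, spec.theta_true, spec.beta0_true, arm=0)
        # MC standard error of the influence function at this sample size
        se = 3.0 / np.sqrt(ds.total_n)
        assert abs((t1 - t0) - 1.0) < 3 * se


class TestRoundTripIO:
    def test_write_read_identity(self, tmp_path):
        ds = d.generate(d.ScenarioSpec.canonical("II", K=3, n=40, p=8, seed=5))
        d.write_dataset(ds, tmp_path)
        back = d.read_dataset(tmp_path)
        assert back.spec.K == 3 and back.spec.p == 8
        assert back.true_delta == pytest.approx(ds.true_delta, abs=1e-12)
        for sa, sb in zip(ds.sites, back.sites):
            np.testing.assert_allclose(sa.X, sb.X, atol=1e-12)
            np.testing.assert_allclose(sa.Y, sb.Y, atol=1e-12)
            np.testing.assert_array_equal(sa.T, sb.T)

    def test_small_k_reads_but_fails_at_fold_split(self, tmp_path):
        ds = d.generate(d.ScenarioSpec.canonical("I", K=3, n=30, p=8, seed=6))
        ds.sites = ds.sites[:2]
        ds.spec.K = 2
        d.write_dataset(ds, tmp_path)
        back = d.read_dataset(tmp_path)  # reading succeeds
        with pytest.raises(ValueError, match="K"):
            d.estimate_disco(back, order=2)

    def test_nonbinary_treatment_named_in_error(self, tmp_path):
        ds = d.generate(d.ScenarioSpec.canonical("I", K=3, n=30, p=8, seed=6))
        d.write_dataset(ds, tmp_path)
        f = tmp_path / "site_002.csv"
        lines = f.read_text().splitlines()
        lines[1] = "2" + lines[1][1:]
        f.write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError, match="site 2.*T"):
            d.read_dataset(tmp_path)

    def test_missing_column_named_in_error(self, tmp_path):
        ds = d.generate(d.ScenarioSpec.canonical("I", K=3, n=30, p=8, seed=6))
        d.write_dataset(ds, tmp_path)
        f = tmp_path / "site_001.csv"
        body = f.read_text().splitlines()
        body[0] = body[0].replace("X3", "Z3")
        f.write_text("\n".join(body) + "\n")
        with pytest.raises(FormatError, match="site 1"):
            d.read_dataset(tmp_path)

    def test_yaml_spec_round_trip(self, tmp_path):
        spec = d.ScenarioSpec.canonical("IV", K=5, n=60, p=12, seed=8)
        spec.to_yaml(tmp_path / "spec.yaml")
        back = d.ScenarioSpec.from_yaml(tmp_path / "spec.yaml")
        assert back.scenario_id == "IV" and back.K == 5 and back.p == 12
        np.testing.assert_array_equal(back.theta_true, spec.theta_true)
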