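import numpy as np
import pytest

import discoate as d
from discoate.outcome import make_om_context, om_quadratic
from discoate.protocol import (
    FederationError,
    ProtocolError,
    collect_summaries,
    federation_audit,
    pooled_scope,
    site_scope,
    split_sites,
)
from discoate.solver import PSFamilyLoss

from conftest import identical_sites_dataset


class TestSplitSites:
    def test_round_robin_sizes(self):
        plan = split_sites(10, seed=0)
        assert sorted(len(f) for f in plan.folds) == [3, 3, 4]

    def test_three_sites_one_each(self):
        plan = split_sites(3, seed=1)
        assert sorted(s for f in plan.folds for s in f) == [1, 2, 3]
        assert all(len(f) == 1 for f in plan.folds)

    def test_deterministic_and_disjoint(self):
        a, b = split_sites(17, seed=9), split_sites(17, seed=9)
        assert a.folds == b.folds
        flat = [s for f in a.folds for s in f]
        assert sorted(flat) == list(range(1, 18))

    def test_each_fold_serves_each_role_once(self):
        plan = split_sites(9, seed=2)
        for role in range(3):
            assert sorted(r[role] for r in plan.rotation) == [0, 1, 2]

    def test_too_few_sites(self):
        with pytest.raises(ValueError):
            split_sites(2, seed=0)


class TestSummaries:
    def test_identical_sites_yield_identical_summaries(self):
        ds = identical_sites_dataset(K=4, n=100, p=6)
        theta = np.zeros(7)
        summ = collect_summaries(ds.sites, "ps", theta, order=2)
        for s in summ[1:]:
            np.testing.assert_array_equal(s.gradient, summ[0].gradient)
            np.testing.assert_array_equal(s.hessian, summ[0].hessian)

    def test_row_count_conservation_and_payloads(self, small_dataset):
        p1 = small_dataset.spec.p + 1
        comm = d.CommLog()
        summ = collect_summaries(small_dataset.sites, "ps", np.zeros(p1),
                                 order=2, comm=comm)
        assert sum(s.n_rows_represented for s in summ) == small_dataset.total_n
        assert all(s.payload_floats == p1 + p1 * p1 for s in summ)
        # every non-lead site: one broadcast down, one summary up
        assert len(comm.entries) == 2 * (small_dataset.K - 1)
        summ1 = collect_summaries(small_dataset.sites, "ps", np.zeros(p1), order=1)
        assert all(s.hessian is None and s.payload_floats == p1 for s in summ1)

    def test_covariate_shift_produces_nonzero_hessian_gap(self, shift_dataset):
        p1 = shift_dataset.spec.p + 1
        summ = collect_summaries(shift_dataset.sites, "ps", np.zeros(p1), order=2)
        H_bar = np.mean([s.hessian for s in summ], axis=0)
        gap = np.linalg.norm(H_bar - summ[0].hessian, 2)
        assert gap > 0.01


class TestBuildSurrogate:
    def test_single_site_fold_collapses_to_lead_loss(self, small_dataset, rng):
        lead = small_dataset.sites[0]
        loss = PSFamilyLoss(lead.X_design, lead.T)
        theta = 0.1 * rng.normal(size=lead.p + 1)
        summ = collect_summaries([lead], "ps", theta, order=2)
        surr = d.build_surrogate(loss, summ, theta, order=2)
        for _ in range(4):
            v = 0.3 * rng.normal(size=lead.p + 1)
            assert surr.value_at(v) == pytest.approx(loss.value_at(v), abs=1e-12)

    def test_identical_sites_collapse_both_orders(self, rng):
        ds = identical_sites_dataset(K=5, n=120, p=6)
        lead = ds.sites[0]
        loss = PSFamilyLoss(lead.X_design, lead.T)
        theta = 0.1 * rng.normal(size=7)
        summ = collect_summaries(ds.sites, "ps", theta, order=2)
        s2 = d.build_surrogate(loss, summ, theta, order=2)
        s1 = d.build_surrogate(loss, summ, theta, order=1)
        for _ in range(4):
            v = 0.3 * rng.normal(size=7)
            assert s2.value_at(v) == pytest.approx(loss.value_at(v), abs=1e-10)
            assert s1.value_at(v) == pytest.approx(loss.value_at(v), abs=1e-10)

    def test_gradient_at_expansion_point_is_fold_average(self, shift_dataset, rng):
        fold = shift_dataset.sites[:4]
        lead = fold[0]
        loss = PSFamilyLoss(lead.X_design, lead.T)
        theta = 0.2 * rng.normal(size=lead.p + 1)
        summ = collect_summaries(fold, "ps", theta, order=2)
        surr = d.build_surrogate(loss, summ, theta, order=2)
        g_bar = np.mean([s.gradient for s in summ], axis=0)
        np.testing.assert_allclose(surr.gradient_at(theta), g_bar, atol=1e-14)

    def test_quadratic_surrogate_equals_fold_loss_up_to_constant(
        self, shift_dataset, rng
    ):
        """Second-order expansion of a quadratic is exact: the distributed
        outcome objective matches the materialized fold objective."""
        fold = shift_dataset.sites[:4]
        theta_ref = 0.2 * rng.normal(size=fold[0].p + 1)
        beta_bar = rng.normal(size=fold[0].p + 1)
        lead_loss = om_quadratic(make_om_context(fold[0], 1, theta_ref))
        summ = collect_summaries(fold, "om", beta_bar,
                                 theta_for_weights=theta_ref, arm=1, order=2)
        surr = d.build_surrogate(lead_loss, summ, beta_bar, order=2)
        fold_loss = om_quadratic(
            [make_om_context(s, 1, theta_ref) for s in fold]
        )
        shift = surr.value_at(beta_bar) - fold_loss.value_at(beta_bar)
        for _ in range(5):
            b = rng.normal(size=fold[0].p + 1)
            assert surr.value_at(b) - fold_loss.value_at(b) == pytest.approx(
                shift, abs=1e-9
            )
            np.testing.assert_allclose(
                surr.gradient_at(b), fold_loss.gradient_at(b), atol=1e-10
            )

    def test_mismatched_expansion_points_rejected(self, small_dataset):
        p1 = small_dataset.spec.p + 1
        lead = small_dataset.sites[0]
        loss = PSFamilyLoss(lead.X_design, lead.T)
        summ = collect_summaries(small_dataset.sites[:3], "ps", np.zeros(p1), order=2)
        with pytest.raises(ProtocolError):
            d.build_surrogate(loss, summ, np.ones(p1), order=2)


class TestFederationAudit:
    def test_distributed_estimator_never_crosses_sites(self, small_dataset):
        with federation_audit():
            res = d.estimate_disco(small_dataset, order=2, seed=0)
        assert np.isfinite(res.delta)

    def test_cross_site_row_access_is_detected(self, small_dataset):
        s1, s2 = small_dataset.sites[0], small_dataset.sites[1]
        with federation_audit():
            with site_scope(s1.site_id):
                _ = s1.X  # own rows: fine
                with pytest.raises(FederationError):
                    _ = s2.X
            with pytest.raises(FederationError):
                _ = s1.T  # no scope at all

    def test_pooled_scope_is_an_explicit_exemption(self, small_dataset):
        with federation_audit():
            with pooled_scope():
                _ = np.vstack([s.X for s in small_dataset.sites])


class TestCommLog:
    def test_totals_and_csv_round_trip(self, tmp_path):
        log = d.CommLog()
        log.add(0, 2, 1, "ps", 10)
        log.add(0, 3, 1, "ps", 10)
        log.add(1, 2, 1, "om", 4)
        assert log.total_floats() == 24
        assert log.total_floats("ps") == 20
        log.to_csv(tmp_path / "comm.csv")
        import pandas as pd

        back = pd.read_csv(tmp_path / "comm.csv")
        assert len(back) == 3
        assert back["payload_floats"].sum() == 24
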