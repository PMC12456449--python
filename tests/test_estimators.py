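import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from xrrmeta.data import MetaDataset, StudyCounts
from xrrmeta.estimators import (
    DegenerateVarianceError,
    DesignError,
    InsufficientStudiesError,
    MomentEngine,
    MomentEstimates,
    mom_balanced,
    mom_weighted,
    point_estimates,
    resample_support,
    wald_statistic,
)
from xrrmeta.model import shape_from_moments


def hypergeom_oracle(n_lg, y_lg, n_sm, l):
    """Subset-enumeration weight: C(y_lg, l) C(n_lg - y_lg, n_sm - l) / C(n_lg, n_sm)."""
    return math.comb(y_lg, l) * math.comb(n_lg - y_lg, n_sm - l) / math.comb(n_lg, n_sm)


class TestResampleSupport:
    def test_worked_example_weights(self):
        sup = resample_support(StudyCounts(2, 80, 1, 50, "a"))
        assert list(sup.events) == [0, 1, 2]
        assert sup.size == 50
        oracle = [hypergeom_oracle(80, 2, 50, l) for l in range(3)]
        assert np.allclose(sup.weights, oracle, atol=1e-10)
        assert sup.weights.sum() == pytest.approx(1.0, abs=1e-12)
        # resampled totals are events plus the fixed control events
        assert list(sup.totals) == [1, 2, 3]

    def test_double_zero_correction_gives_singleton(self):
        sup = resample_support(StudyCounts(1, 100, 0, 90, "b"))
        assert list(sup.events) == [1]
        assert list(sup.weights) == [1.0]
        assert list(sup.totals) == [1]

    def test_balanced_study_is_singleton(self):
        sup = resample_support(StudyCounts(3, 50, 1, 50, "c"))
        assert list(sup.events) == [3]
        assert list(sup.weights) == [1.0]
        assert sup.size == 50

    def test_control_arm_larger_keeps_treated_fixed(self):
        # resampling the control arm down: treated events stay fixed
        sup = resample_support(StudyCounts(2, 50, 3, 120, "d"))
        assert set(sup.events) == {2}
        assert sup.size == 50
        oracle = [hypergeom_oracle(120, 3, 50, l) for l in range(4)]
        assert np.allclose(sup.weights, oracle, atol=1e-10)
        assert list(sup.totals) == [2, 3, 4, 5]

    def test_treated_zero_drops_all_zero_control_outcome(self):
        # control larger, treated arm has no events: outcome with zero
        # retained control events would be double-zero and is excluded
        sup = resample_support(StudyCounts(0, 60, 2, 120, "e"))
        assert 0 not in sup.totals
        assert sup.weights.sum() == pytest.approx(1.0, abs=1e-12)

    @given(data=st.data())
    def test_weights_always_sum_to_one(self, data):
        n1 = data.draw(st.integers(1, 150))
        n2 = data.draw(st.integers(1, 150))
        y1 = data.draw(st.integers(0, min(n1, 10)))
        y2 = data.draw(st.integers(0 if y1 else 1, min(n2, 10)))
        sup = resample_support(StudyCounts(y1, n1, y2, n2, "h"))
        assert sup.weights.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(sup.weights >= 0)
        assert np.all(sup.totals >= 1)

    def test_double_zero_rejected(self):
        with pytest.raises(ValueError):
            resample_support(StudyCounts(0, 10, 0, 10, "dz"))


class TestMomBalanced:
    def test_all_zero_treated_arm(self):
        data = MetaDataset.from_studies(
            [StudyCounts(0, 100, 20, 100, f"t{i}") for i in range(6)]
        )
        with pytest.warns(RuntimeWarning):
            est = mom_balanced(data)
        assert est.mu_hat == 0.0
        # corrected second moment is negative here, so truncation binds
        assert est.v_hat == 0.0
        assert est.var_mu_hat > 0.0

    def test_constant_ratio_recovers_the_constant(self):
        data = MetaDataset.from_studies(
            [StudyCounts(1, 50, 3, 50, f"c{i}") for i in range(5)]
        )
        est = mom_balanced(data)
        assert est.mu_hat == pytest.approx(0.25, abs=1e-15)

    def test_unbalanced_input_rejected(self, unbalanced_dataset):
        with pytest.raises(DesignError):
            mom_balanced(unbalanced_dataset)

    def test_too_few_studies(self):
        data = MetaDataset.from_studies([StudyCounts(1, 10, 1, 10, "only")])
        with pytest.raises(InsufficientStudiesError):
            mom_balanced(data)

    def test_moment_identities_on_simulated_data(self):
        """Large-K simulated beta-binomial data recovers (mu, v).

        The uncorrected second-moment identity is checked directly from
        raw counts; the corrected estimator is allowed its small
        continuity-correction shrinkage.
        """
        rng = np.random.default_rng(3)
        K = 5000
        a, b = shape_from_moments(0.5, 0.02)
        pi = rng.beta(a, b, K)
        ytot = rng.poisson(20, K) + 1
        y1 = rng.binomial(ytot, pi)
        data = MetaDataset.from_studies(
            [StudyCounts(int(y1[i]), 1000, int(ytot[i] - y1[i]), 1000, f"s{i}") for i in range(K)]
        )
        est = mom_balanced(data)
        assert est.mu_hat == pytest.approx(0.5, abs=0.01)
        ratio = y1 / ytot
        mu_raw = ratio.mean()
        v_raw = np.sum(ratio**2 - mu_raw / ytot) / np.sum(1 - 1 / ytot) - mu_raw**2
        assert v_raw == pytest.approx(0.02, abs=0.004)
        assert 0.01 < est.v_hat < 0.03


class TestMomWeighted:
    def test_equals_balanced_on_balanced_data(self, balanced_dataset):
        eb = mom_balanced(balanced_dataset)
        ew = mom_weighted(balanced_dataset)
        assert ew.mu_hat == pytest.approx(eb.mu_hat, abs=1e-12)
        assert ew.v_hat == pytest.approx(eb.v_hat, abs=1e-12)
        assert ew.var_mu_hat == pytest.approx(eb.var_mu_hat, abs=1e-12)

    def test_worked_example_hand_expansion(self, worked_example):
        """Two-study example: expand the weighted double sum by hand."""
        est = mom_weighted(worked_example)
        w = [hypergeom_oracle(80, 2, 50, l) for l in range(3)]
        # first study contributes sum_l (l / (l + 1)) w_l; the second,
        # after the double-zero correction, contributes 1/1 exactly
        expected = 0.5 * (sum((l / (l + 1)) * w[l] for l in range(3)) + 1.0)
        assert est.mu_hat == pytest.approx(expected, abs=1e-12)
        assert est.design == "weighted"

    def test_truncation_never_negative(self, unbalanced_dataset):
        est = mom_weighted(unbalanced_dataset)
        assert est.v_hat >= 0.0
        assert est.var_mu_hat > 0.0

    def test_study_order_invariant(self, unbalanced_dataset):
        perm = MetaDataset(tuple(unbalanced_dataset.studies[::-1]), unbalanced_dataset.k_tot)
        a, b = mom_weighted(unbalanced_dataset), mom_weighted(perm)
        assert a.mu_hat == b.mu_hat
        assert a.v_hat == b.v_hat
        assert a.var_mu_hat == b.var_mu_hat

    def test_arm_swap_reflects_point_estimate(self, balanced_dataset):
        est = mom_weighted(balanced_dataset)
        swapped = mom_weighted(balanced_dataset.swap_arms())
        assert swapped.mu_hat == pytest.approx(1.0 - est.mu_hat, abs=1e-12)
        assert swapped.v_hat == pytest.approx(est.v_hat, abs=1e-12)
        assert swapped.var_mu_hat == pytest.approx(est.var_mu_hat, abs=1e-12)


class TestMomentEngine:
    def test_matches_scalar_estimates_row_by_row(self, unbalanced_dataset):
        engine = MomentEngine(unbalanced_dataset)
        mu, v, var = engine.moments(unbalanced_dataset.y1[None, :])
        est = mom_weighted(unbalanced_dataset)
        assert mu[0] == pytest.approx(est.mu_hat, abs=1e-14)
        assert v[0] == pytest.approx(est.v_hat, abs=1e-14)
        assert var[0] == pytest.approx(est.var_mu_hat, abs=1e-14)

    def test_batched_rows_are_independent(self, unbalanced_dataset):
        engine = MomentEngine(unbalanced_dataset)
        rng = np.random.default_rng(0)
        ytot = unbalanced_dataset.y_total
        y1 = np.vstack([rng.integers(0, ytot + 1) for _ in range(6)])
        mu_batch, v_batch, var_batch = engine.moments(y1)
        for r in range(6):
            mu_r, v_r, var_r = engine.moments(y1[r : r + 1])
            assert mu_batch[r] == pytest.approx(mu_r[0], abs=1e-14)
            assert var_batch[r] == pytest.approx(var_r[0], abs=1e-14)


class TestWaldStatistic:
    def test_zero_at_point_estimate_and_symmetric(self, balanced_dataset):
        est = mom_balanced(balanced_dataset)
        assert wald_statistic(est.mu_hat, est) == 0.0
        delta = 0.07
        assert wald_statistic(est.mu_hat + delta, est) == pytest.approx(
            wald_statistic(est.mu_hat - delta, est)
        )

    def test_simple_value(self):
        est = MomentEstimates(mu_hat=0.6, v_hat=0.0, var_mu_hat=0.01, design="balanced", k=5)
        assert wald_statistic(0.5, est) == pytest.approx(1.0)

    def test_invalid_variance(self):
        est = MomentEstimates(mu_hat=0.6, v_hat=0.0, var_mu_hat=0.0, design="balanced", k=5)
        with pytest.raises(DegenerateVarianceError):
            wald_statistic(0.5, est)


def test_point_estimates_dispatch(balanced_dataset, unbalanced_dataset):
    assert point_estimates(balanced_dataset).design == "balanced"
    assert point_estimates(unbalanced_dataset).design == "weighted"
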