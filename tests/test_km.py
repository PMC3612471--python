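import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bjel import (
    DegenerateTailError,
    eval_surv,
    eval_surv_left,
    km_censoring_fit,
    km_fit,
    tail_mean,
    tail_means,
)
from bjel.data import CensoredRegressionData

from .conftest import random_censored_sample
from .oracles import naive_km


class TestProductLimit:
    def test_hand_computed_curve(self):
        c = km_fit([1, 2, 3, 4], [1, 0, 1, 1])
        np.testing.assert_allclose(c.jump_mass, [0.25, 0.0, 0.375, 0.375])
        np.testing.assert_allclose(c.surv, [0.75, 0.75, 0.375, 0.0])
        assert eval_surv(c, 2) == pytest.approx(0.75)
        assert c.is_proper

    def test_uncensored_reduces_to_empirical(self, rng):
        v = rng.normal(size=40)
        v[:10] = v[10:20]  # force ties
        c = km_fit(v, np.ones_like(v))
        support, counts = np.unique(v, return_counts=True)
        np.testing.assert_allclose(c.support, support)
        np.testing.assert_allclose(c.jump_mass, counts / v.size, atol=1e-12)

    def test_all_censored_flat(self):
        c = km_fit([1.0, 2.0, 3.0], [0, 0, 0], largest_as_event=False)
        np.testing.assert_allclose(c.jump_mass, 0.0)
        np.testing.assert_allclose(c.surv, 1.0)
        assert not c.is_proper

    def test_tail_completion_makes_proper(self, rng):
        for seed in range(25):
            v, d = random_censored_sample(np.random.default_rng(seed))
            c = km_fit(v, d, largest_as_event=True)
            assert c.is_proper
            assert abs(c.jump_mass.sum() - 1.0) <= 1e-12

    def test_agrees_with_loop_oracle_with_ties(self, rng):
        for seed in range(30):
            r = np.random.default_rng(seed)
            v, d = random_censored_sample(r, allow_ties=True)
            for complete in (False, True):
                c = km_fit(v, d, largest_as_event=complete)
                support, surv, jumps = naive_km(v, d, largest_as_event=complete)
                np.testing.assert_allclose(c.support, support)
                np.testing.assert_allclose(c.surv, surv, atol=1e-12)
                np.testing.assert_allclose(c.jump_mass, jumps, atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            km_fit([], [])


class TestCensoringFit:
    def test_no_censoring_flat_at_one(self):
        d = CensoredRegressionData(X=[0.0, 1.0, 2.0], Z=[1.0, 2.0, 3.0], delta=[1, 1, 1])
        g = km_censoring_fit(d)
        np.testing.assert_allclose(g.surv, 1.0)

    def test_hand_computed_flipped_curve(self):
        d = CensoredRegressionData(
            X=[0.0, 1.0, 2.0, 3.0], Z=[1.0, 2.0, 3.0, 4.0], delta=[1, 0, 1, 1]
        )
        g = km_censoring_fit(d)
        # the event at 1 leaves 3 at risk when the censoring at 2 occurs
        np.testing.assert_allclose(g.jump_mass, [0.0, 1 / 3, 0.0, 0.0])
        assert eval_surv_left(g, 2.0) == pytest.approx(1.0)
        assert eval_surv(g, 2.0) == pytest.approx(2 / 3)

    def test_tied_death_removed_before_censoring(self):
        # death and censoring both at t=2: the death exits the risk set first
        d = CensoredRegressionData(
            X=[0.0, 1.0, 2.0, 3.0], Z=[1.0, 2.0, 2.0, 4.0], delta=[1, 1, 0, 1]
        )
        g = km_censoring_fit(d)
        k = np.searchsorted(g.support, 2.0)
        # risk set at 2 for censoring: {2, 2, 4} minus the tied death -> 2
        assert g.jump_mass[k] == pytest.approx(0.5)


class TestTailMeans:
    def test_hand_computed_conditional_mean(self):
        c = km_fit([1, 2, 3, 4], [1, 0, 1, 1], largest_as_event=True)
        assert tail_mean(c, 2) == pytest.approx((3 * 0.375 + 4 * 0.375) / 0.75)

    def test_below_support_gives_unconditional_mean(self):
        c = km_fit([1.0, 2.0, 3.0], [1, 1, 1])
        assert tail_mean(c, -10.0) == pytest.approx(2.0)

    def test_degenerate_tail_raises(self):
        c = km_fit([1, 2, 3, 4], [1, 0, 1, 1], largest_as_event=True)
        with pytest.raises(DegenerateTailError):
            tail_mean(c, 4.0)

    def test_single_point_above_gives_point_value(self):
        c = km_fit([1.0, 2.0, 5.0], [1, 1, 1])
        assert tail_mean(c, 3.0) == pytest.approx(5.0)

    def test_vectorized_fallbacks(self):
        c = km_fit([1, 2, 3, 4], [1, 0, 1, 1], largest_as_event=True)
        out = tail_means(c, [2.0, 4.0], fallback="max_support")
        np.testing.assert_allclose(out, [3.5, 4.0])
        out = tail_means(c, [2.0, 7.0], fallback="self")
        np.testing.assert_allclose(out, [3.5, 7.0])


class TestStepFunctionConventions:
    def test_left_and_right_limits(self):
        c = km_fit([2.0, 2.0, 2.0], [1, 0, 0])  # single jump of 1/3 at 2
        assert eval_surv_left(c, 2.0) == pytest.approx(1.0)
        assert eval_surv(c, 2.0) == pytest.approx(2 / 3)
        assert eval_surv_left(c, 1.0) == pytest.approx(1.0)
        assert eval_surv_left(c, 99.0) == pytest.approx(2 / 3)


@settings(max_examples=40, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_surv_monotone_and_in_unit_interval(seed):
    v, d = random_censored_sample(np.random.default_rng(seed), allow_ties=bool(seed % 2))
    c = km_fit(v, d, largest_as_event=bool(seed % 3))
    assert np.all(np.diff(c.surv) <= 1e-15)
    assert np.all((c.surv >= -1e-15) & (c.surv <= 1 + 1e-15))
    assert np.all(c.jump_mass >= 0)
    # jump at t equals S(t-) - S(t)
    left = np.r_[1.0, c.surv[:-1]]
    np.testing.assert_allclose(c.jump_mass, left - c.surv, atol=1e-12)
    # total mass accounting
    np.testing.assert_allclose(c.jump_mass.sum(), 1.0 - c.surv[-1], atol=1e-12)
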