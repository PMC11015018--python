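import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coptdrake.drake import (
    DRAKE_1961_ACC_RANGE,
    DrakeParams,
    Term,
    copt_params,
    drake_1961,
    evaluate_interval,
    evaluate_monte_carlo,
    evaluate_point,
    modified_acc_params,
    scale_acc_range,
)


def _point_params(r_star, f_p, n_e, f_l, f_i, f_c, lifetime):
    return DrakeParams(
        r_star=Term.point(r_star),
        f_p=Term.point(f_p),
        n_e=Term.point(n_e),
        f_l=Term.point(f_l),
        f_i=Term.point(f_i),
        f_c=Term.point(f_c),
        lifetime=Term.point(lifetime),
    )


class TestEvaluatePoint:
    def test_1961_upper_end(self):
        assert evaluate_point(_point_params(1, 0.5, 5, 1, 1, 0.2, 1e8)) == pytest.approx(5e7)

    def test_1961_lower_end(self):
        # product of the published minima is 20, not the famous quoted 200
        assert evaluate_point(_point_params(1, 0.2, 1, 1, 1, 0.1, 1000)) == pytest.approx(20)

    def test_zero_annihilates(self):
        assert evaluate_point(_point_params(1, 0.5, 5, 0, 1, 0.2, 1e8)) == 0.0

    def test_rejects_interval_terms(self):
        with pytest.raises(ValueError):
            evaluate_point(drake_1961())

    @settings(deadline=None, max_examples=30)
    @given(factor=st.floats(min_value=0.1, max_value=10))
    def test_multiplicative_in_each_term(self, factor):
        base = _point_params(1, 0.3, 2, 1, 0.5, 0.15, 1e6)
        scaled = dataclasses.replace(base, n_e=Term.point(2 * factor))
        assert evaluate_point(scaled) == pytest.approx(factor * evaluate_point(base))


class TestEvaluateInterval:
    def test_1961_range(self):
        assert evaluate_interval(drake_1961()) == pytest.approx((20, 5e7))

    def test_copt_range(self):
        params = copt_params((0.00016, 0.011), 0.17)
        lo, hi = evaluate_interval(params)
        assert lo == pytest.approx(2720)
        assert hi == pytest.approx(2.3375e6)

    def test_degenerate_points_collapse(self):
        params = _point_params(1, 0.3, 2, 1, 0.5, 0.15, 1e6)
        lo, hi = evaluate_interval(params)
        assert lo == hi == pytest.approx(evaluate_point(params))

    def test_rejects_inverted_interval(self):
        with pytest.raises(ValueError):
            Term.interval(5.0, 1.0)

    def test_acc_and_copt_agree_when_aligned(self):
        foc, fpt, life = (2e-4, 1e-2), 0.17, 5e8
        acc = DrakeParams(
            r_star=Term.point(1.0),
            f_p=Term.interval(0.2, 0.5),
            n_e=Term.interval(1.0, 5.0),
            f_l=Term.point(1.0),
            f_c=Term.point(1.0),
            f_oc=Term.interval(*foc),
            f_pt=Term.point(fpt),
            lifetime=Term.point(life),
            mode="ACC",
        )
        copt = copt_params(foc, fpt, life)
        assert evaluate_interval(acc) == pytest.approx(evaluate_interval(copt))


class TestScaleAccRange:
    def test_published_reduction(self):
        scaled = scale_acc_range(DRAKE_1961_ACC_RANGE, (3e-5, 2e-3))
        assert scaled == pytest.approx((0.006, 100_000))

    def test_identity_factor(self):
        assert scale_acc_range((200, 5e7), (1, 1)) == pytest.approx((200, 5e7))

    def test_linear_in_base(self):
        assert scale_acc_range((1000, 1e8), (3e-5, 2e-3)) == pytest.approx((0.03, 200_000))

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            scale_acc_range((-1, 10), (0.5, 0.5))


class TestMonteCarlo:
    def test_point_terms_are_degenerate(self):
        params = _point_params(1, 0.3, 2, 1, 0.5, 0.15, 1e6)
        res = evaluate_monte_carlo(params, 1000, seed=1)
        expected = evaluate_point(params)
        assert res.sample_min == pytest.approx(expected)
        assert res.sample_max == pytest.approx(expected)
        assert res.mean == pytest.approx(expected)

    def test_samples_contained_in_interval_bounds(self):
        params = drake_1961()
        lo, hi = evaluate_interval(params)
        res = evaluate_monte_carlo(params, 100_000, seed=7)
        assert res.sample_min >= lo
        assert res.sample_max <= hi

    def test_same_seed_identical_summary(self):
        params = modified_acc_params()
        a = evaluate_monte_carlo(params, 20_000, seed=123)
        b = evaluate_monte_carlo(params, 20_000, seed=123)
        assert a == b

    def test_different_seed_differs(self):
        params = modified_acc_params()
        a = evaluate_monte_carlo(params, 20_000, seed=123)
        b = evaluate_monte_carlo(params, 20_000, seed=124)
        assert a.mean != b.mean

    def test_upper_bound_flag_propagates(self):
        res = evaluate_monte_carlo(modified_acc_params(), 100, seed=0)
        assert res.is_upper_bound
        res_plain = evaluate_monte_carlo(drake_1961(), 100, seed=0)
        assert not res_plain.is_upper_bound

    def test_rejects_bad_sample_count(self):
        with pytest.raises(ValueError):
            evaluate_monte_carlo(drake_1961(), 0, seed=1)


class TestTermDefaults:
    def test_wide_terms_default_loguniform(self):
        assert Term.interval(1e3, 1e8).resolved_distribution() == "loguniform"

    def test_narrow_terms_default_uniform(self):
        assert Term.interval(0.2, 0.5).resolved_distribution() == "uniform"

    def test_explicit_distribution_wins(self):
        assert Term.interval(1e3, 1e8, "uniform").resolved_distribution() == "uniform"

    def test_loguniform_requires_positive_low(self):
        with pytest.raises(ValueError):
            Term.interval(0.0, 1.0, "loguniform")

    def test_loguniform_samples_within_bounds(self):
        rng = np.random.default_rng(5)
        s = Term.interval(1e3, 1e8).sample(10_000, rng)
        assert s.min() >= 1e3 and s.max() <= 1e8


class TestParamsValidation:
    def test_requires_some_civ_factor(self):
        with pytest.raises(ValueError):
            DrakeParams(
                r_star=Term.point(1),
                f_p=Term.point(0.5),
                n_e=Term.point(1),
                f_l=Term.point(1),
                f_c=Term.point(0.1),
                lifetime=Term.point(1e4),
            )

    def test_rejects_both_fi_and_split(self):
        with pytest.raises(ValueError):
            DrakeParams(
                r_star=Term.point(1),
                f_p=Term.point(0.5),
                n_e=Term.point(1),
                f_l=Term.point(1),
                f_c=Term.point(0.1),
                lifetime=Term.point(1e4),
                f_i=Term.point(1),
                f_oc=Term.point(0.01),
                f_pt=Term.point(0.17),
            )

    def test_copt_mode_requires_split(self):
        with pytest.raises(ValueError):
            DrakeParams(
                r_star=Term.point(1),
                f_p=Term.point(0.5),
                n_e=Term.point(1),
                f_l=Term.point(1),
                f_c=Term.point(1),
                lifetime=Term.point(5e8),
                f_i=Term.point(1),
                mode="COPT",
            )
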