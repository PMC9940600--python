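"""Model registry contents, curve evaluation, and algebraic identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from relkin import (
    DomainError,
    MODEL_NAMES,
    evaluate,
    get_model,
    reduce_weibull_to_first_order,
    registry,
)


class TestRegistry:
    def test_contains_exactly_the_eight_models_with_unique_names(self):
        specs = registry()
        assert len(specs) == 8
        assert [s.name for s in specs] == list(MODEL_NAMES)

    def test_weibull_parameters_and_default_lag_fixed_at_zero(self):
        spec = get_model("weibull")
        assert spec.param_names == ("alpha", "beta", "Ti")
        assert spec.fixed_params == {"Ti": 0.0}
        assert spec.free_param_names == ("alpha", "beta")

    def test_peppas_sahlin_parameters(self):
        assert get_model("peppas_sahlin").param_names == ("k1", "k2", "m")

    def test_bounds_are_well_formed(self):
        for spec in registry():
            assert set(spec.default_bounds) == set(spec.param_names)
            for lo, hi in spec.default_bounds.values():
                assert lo < hi


class TestEvaluate:
    @pytest.mark.parametrize(
        "model,params,t,expected",
        [
            ("first_order", {"k1": 0.1}, 0.0, 0.0),
            ("higuchi", {"kH": 10.0}, 4.0, 20.0),
            ("first_order", {"k1": 0.1}, 10.0, 100.0 * (1 - math.exp(-1.0))),
            ("zero_order", {"k0": 2.0}, 3.0, 6.0),
            ("korsmeyer_peppas", {"kKP": 5.0, "n": 0.5}, 4.0, 10.0),
            ("peppas_sahlin", {"k1": 3.0, "k2": 0.5, "m": 0.5}, 4.0, 8.0),
            ("hixson_crowell", {"kHC": 0.01}, 10.0, 100.0 * (1 - 0.9**3)),
        ],
    )
    def test_closed_form_values(self, model, params, t, expected):
        assert evaluate(model, params, [t])[0] == pytest.approx(expected, abs=1e-12)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            evaluate("first_order", {"k1": 0.1}, [-1.0])

    def test_hopfenberg_domain_violation_names_parameter(self):
        with pytest.raises(DomainError, match="kHB"):
            evaluate("hopfenberg", {"kHB": 0.1, "n": 2.0}, [20.0])

    def test_weibull_lag_domain_violation_names_parameter(self):
        with pytest.raises(DomainError, match="Ti"):
            evaluate("weibull", {"alpha": 1.0, "beta": 0.5, "Ti": 2.0}, [1.0])

    @pytest.mark.parametrize("model", ["higuchi", "korsmeyer_peppas"])
    def test_power_law_models_pass_through_origin(self, model):
        params = {"higuchi": {"kH": 7.0}, "korsmeyer_peppas": {"kKP": 7.0, "n": 0.7}}
        assert evaluate(model, params[model], [0.0])[0] == 0.0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        k=st.floats(1e-4, 0.5),
        model=st.sampled_from(["first_order", "hixson_crowell", "weibull"]),
    )
    def test_saturating_models_nondecreasing_and_bounded(self, k, model):
        t = np.linspace(0, min(48.0, 0.99 / k), 50)
        params = {
            "first_order": {"k1": k},
            "hixson_crowell": {"kHC": k},
            "weibull": {"alpha": 1.0 / k, "beta": 0.8, "Ti": 0.0},
        }[model]
        f = evaluate(model, params, t)
        assert np.all(np.diff(f) >= -1e-12)
        assert np.all(f <= 100.0 + 1e-9)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(k=st.floats(1e-4, 0.02))
    def test_hixson_crowell_is_hopfenberg_with_cube_exponent(self, k):
        t = np.linspace(0, 48, 25)
        hc = evaluate("hixson_crowell", {"kHC": k}, t)
        hb = evaluate("hopfenberg", {"kHB": k, "n": 3.0}, t)
        assert np.allclose(hc, hb, atol=1e-10)


class TestWeibullFirstOrderReduction:
    @pytest.mark.parametrize("k1,alpha", [(0.2, 5.0), (1.0, 1.0)])
    def test_reduction_parameters(self, k1, alpha):
        pv = reduce_weibull_to_first_order(k1)
        assert pv["alpha"] == pytest.approx(alpha)
        assert pv["beta"] == 1.0 and pv["Ti"] == 0.0

    def test_pointwise_identity_with_first_order(self):
        t = np.linspace(0, 48, 481)
        pv = reduce_weibull_to_first_order(0.2)
        diff = evaluate("weibull", pv, t) - evaluate("first_order", {"k1": 0.2}, t)
        assert np.max(np.abs(diff)) < 1e-9

    def test_closed_form_spot_check(self):
        pv = reduce_weibull_to_first_order(0.05)
        expected = 100.0 * (1 - math.exp(-1.2))
        assert evaluate("weibull", pv, [24.0])[0] == pytest.approx(expected, abs=1e-9)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            reduce_weibull_to_first_order(0.0)
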