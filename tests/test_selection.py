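"""Model ranking and release-mechanism classification rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from relkin import (
    FitResult,
    NoConvergedFitError,
    ParamVector,
    classify_exponent,
    classify_fit,
    classify_weibull_beta,
    mechanism_report,
    rank,
)


def _fit(model, aic, n_obs=9, n_params=2, converged=True, seg="SGF", **params):
    defaults = {
        "first_order": {"k1": 0.1},
        "higuchi": {"kH": 10.0},
        "korsmeyer_peppas": {"kKP": 5.0, "n": 0.5},
        "weibull": {"alpha": 4.0, "beta": 0.5, "Ti": 0.0},
        "peppas_sahlin": {"k1": 5.0, "k2": 0.1, "m": 0.45},
    }[model]
    defaults.update(params)
    # shared ss_tot across helper fits = "same dataset" for ranking identities
    ss_tot = 500.0
    ss_res = float(np.exp((aic - 2 * n_params) / n_obs))
    return FitResult(
        model_name=model,
        params=ParamVector(model, defaults),
        n_obs=n_obs,
        n_params=n_params,
        ss_res=ss_res,
        ss_tot=ss_tot,
        r_squared=1 - ss_res / ss_tot,
        aic=aic,
        msc=np.log(ss_tot) - aic / n_obs,
        converged=converged,
        segment_label=seg,
    )


class TestRank:
    def test_clear_single_best(self):
        fits = [
            _fit("first_order", 16.3),
            _fit("higuchi", 6.2),
            _fit("korsmeyer_peppas", 3.6),
        ]
        r = rank(fits, co_best_delta_aic=2.0)
        assert r.best == ("korsmeyer_peppas",)
        assert [m for m, *_ in r.order] == ["korsmeyer_peppas", "higuchi", "first_order"]

    def test_two_co_best_within_delta(self):
        # the Table-1-style situation: two models both reported as best fits
        fits = [_fit("peppas_sahlin", -20.534, n_params=3), _fit("korsmeyer_peppas", -18.653)]
        r = rank(fits, co_best_delta_aic=2.0)
        assert set(r.best) == {"peppas_sahlin", "korsmeyer_peppas"}

    def test_single_fit_is_best(self):
        r = rank([_fit("weibull", 3.64)])
        assert r.best == ("weibull",)

    def test_no_converged_fits_raises(self):
        with pytest.raises(NoConvergedFitError):
            rank([_fit("first_order", 5.0, converged=False)])

    def test_aic_order_equals_msc_order(self):
        # on a shared dataset (same ss_tot, n) the two orders must coincide
        fits = [
            _fit("first_order", 12.0, n_params=1),
            _fit("higuchi", 4.4, n_params=1),
            _fit("korsmeyer_peppas", 5.2),
            _fit("weibull", 3.6),
        ]
        by_aic = sorted(fits, key=lambda f: f.aic)
        by_msc = sorted(fits, key=lambda f: -(np.log(f.ss_tot) - f.aic / f.n_obs))
        assert [f.model_name for f in by_aic] == [f.model_name for f in by_msc]


class TestExponentClassification:
    @pytest.mark.parametrize(
        "model,value,label",
        [
            ("korsmeyer_peppas", 0.429, "fickian"),
            ("korsmeyer_peppas", 0.45, "fickian"),
            ("peppas_sahlin", 0.45, "fickian"),
            ("korsmeyer_peppas", 0.471, "non_fickian"),
            ("korsmeyer_peppas", 0.507, "non_fickian"),
            ("korsmeyer_peppas", 0.85, "case_II"),
            ("korsmeyer_peppas", 1.039, "super_case_II"),
            ("korsmeyer_peppas", 1.319, "super_case_II"),
            ("korsmeyer_peppas", 1.362, "super_case_II"),
        ],
    )
    def test_threshold_table(self, model, value, label):
        assert classify_exponent(model, value).label == label

    def test_nonpositive_exponent_rejected(self):
        with pytest.raises(ValueError):
            classify_exponent("korsmeyer_peppas", 0.0)

    def test_only_power_law_models_accepted(self):
        with pytest.raises(ValueError):
            classify_exponent("first_order", 0.5)

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(e=st.floats(1e-3, 3.0))
    def test_labels_partition_the_domain(self, e):
        label = classify_exponent("korsmeyer_peppas", e).label
        if e <= 0.45:
            assert label == "fickian"
        elif abs(e - 0.85) <= 0.005:
            assert label == "case_II"
        elif e < 0.85:
            assert label == "non_fickian"
        else:
            assert label == "super_case_II"

    def test_monotone_in_exponent(self):
        order = ["fickian", "non_fickian", "case_II", "super_case_II"]
        grid = np.linspace(0.01, 3.0, 2000)
        labels = [order.index(classify_exponent("korsmeyer_peppas", e).label) for e in grid]
        assert all(a <= b for a, b in zip(labels, labels[1:]))


class TestWeibullBetaClassification:
    @pytest.mark.parametrize(
        "beta,label",
        [
            (0.396, "fickian"),
            (0.434, "fickian"),
            (0.493, "fickian"),
            (0.401, "fickian"),
            (0.75, "fickian"),
            (0.762, "combined_fickian_controlled"),
            (1.0, "first_order_like"),
            (1.2, "complex"),
        ],
    )
    def test_threshold_table(self, beta, label):
        assert classify_weibull_beta(beta).label == label

    def test_nonpositive_beta_rejected(self):
        with pytest.raises(ValueError):
            classify_weibull_beta(-0.1)

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(b=st.floats(1e-3, 5.0))
    def test_labels_partition_the_domain(self, b):
        label = classify_weibull_beta(b).label
        if abs(b - 1.0) <= 0.005:
            assert label == "first_order_like"
        elif b <= 0.75:
            assert label == "fickian"
        elif b < 1.0:
            assert label == "combined_fickian_controlled"
        else:
            assert label == "complex"


class TestMechanismReport:
    def test_report_from_simulated_super_case_ii_segment(self):
        from relkin import ReleaseSimConfig, SegmentModel, fit_all, simulate_release

        cfg = ReleaseSimConfig(
            segment_models=(
                SegmentModel("higuchi", {"kH": 14.0}),
                SegmentModel("korsmeyer_peppas", {"kKP": 6.0, "n": 1.3}),
                SegmentModel("first_order", {"k1": 0.015}),
            ),
            seed=11,
            noise_sd=0.5,
        )
        grid = fit_all(
            simulate_release(cfg),
            models=["first_order", "higuchi", "korsmeyer_peppas"],
        )
        report = mechanism_report(grid)
        assert list(report["segment"]) == ["SGF", "SIF", "SCoF"]
        sif = report[report.segment == "SIF"].iloc[0]
        assert "super_case_II" in sif["mechanisms"]

    def test_classify_fit_handles_models_without_exponent(self):
        call = classify_fit(_fit("higuchi", 5.0, n_params=1))
        assert call is None
        call = classify_fit(_fit("weibull", 5.0, beta=0.4))
        assert call is not None and call.label == "fickian"
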