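"""Goodness stack, least-squares fitting, and the model x segment grid."""

import math

import numpy as np
import pytest

from relkin import (
    FitOptions,
    ReleaseProfile,
    TooFewPointsError,
    evaluate,
    fit,
    fit_all,
    goodness,
)


class TestGoodness:
    def test_hand_computed_oracle(self):
        # obs [10,20,30], pred [12,18,33]: SS_res = 4+4+9 = 17, SS_tot = 200
        g = goodness([10.0, 20.0, 30.0], [12.0, 18.0, 33.0], n_params=1)
        assert g.ss_res == pytest.approx(17.0)
        assert g.ss_tot == pytest.approx(200.0)
        assert g.r_squared == pytest.approx(1 - 17.0 / 200.0)
        assert g.aic == pytest.approx(3 * math.log(17.0) + 2.0)
        assert g.msc == pytest.approx(math.log(200.0 / 17.0) - 2.0 / 3.0)
        # the AIC<->MSC identity on a shared dataset
        assert g.msc == pytest.approx(math.log(g.ss_tot) - g.aic / 3.0)

    def test_perfect_fit_flagged_with_sentinels(self):
        g = goodness([10.0, 20.0, 30.0], [10.0, 20.0, 30.0], n_params=1)
        assert g.perfect_fit and g.r_squared == 1.0
        assert g.aic == -math.inf and g.msc == math.inf

    def test_mean_predictor_gives_zero_r_squared(self):
        obs = np.array([10.0, 20.0, 30.0])
        g = goodness(obs, np.full(3, obs.mean()), n_params=1)
        assert g.r_squared == pytest.approx(0.0)

    def test_constant_observations_are_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            goodness([5.0, 5.0, 5.0], [4.0, 5.0, 6.0], n_params=1)

    def test_too_many_parameters_rejected(self):
        with pytest.raises(TooFewPointsError):
            goodness([1.0, 2.0, 3.0], [1.0, 2.0, 3.1], n_params=3)


class TestFit:
    def test_noiseless_korsmeyer_peppas_recovery(self):
        t = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        y = evaluate("korsmeyer_peppas", {"kKP": 5.0, "n": 0.5}, t)
        res = fit("korsmeyer_peppas", ReleaseProfile("x", t, y))
        assert res.params["kKP"] == pytest.approx(5.0, abs=1e-6)
        assert res.params["n"] == pytest.approx(0.5, abs=1e-6)
        assert res.r_squared == pytest.approx(1.0, abs=1e-6)

    def test_noiseless_first_order_recovery(self, paper_schedule):
        y = evaluate("first_order", {"k1": 0.3}, paper_schedule)
        res = fit("first_order", ReleaseProfile("x", paper_schedule, y))
        assert res.params["k1"] == pytest.approx(0.3, rel=1e-8)
        assert res.ss_res == pytest.approx(0.0, abs=1e-12)

    def test_noisy_first_order_monte_carlo_median_error_under_5pct(
        self, paper_schedule
    ):
        rng = np.random.default_rng(20260920)
        truth = 0.3
        clean = evaluate("first_order", {"k1": truth}, paper_schedule)
        errors = []
        for _ in range(200):
            y = np.clip(clean + rng.normal(0, 2.0, clean.shape), 0, 110)
            res = fit("first_order", ReleaseProfile("x", paper_schedule, y))
            errors.append(abs(res.params["k1"] - truth) / truth)
        assert np.median(errors) < 0.05

    def test_fit_is_deterministic(self, paper_schedule):
        rng = np.random.default_rng(7)
        y = np.clip(
            evaluate("weibull", {"alpha": 4.0, "beta": 0.6, "Ti": 0.0}, paper_schedule)
            + rng.normal(0, 2, len(paper_schedule)),
            0,
            110,
        )
        prof = ReleaseProfile("x", paper_schedule, y)
        a, b = fit("weibull", prof), fit("weibull", prof)
        assert a.params.values == b.params.values
        assert a.ss_res == b.ss_res and a.aic == b.aic

    def test_too_few_points_is_explicit(self):
        prof = ReleaseProfile("x", [1.0, 2.0], [10.0, 20.0])
        with pytest.raises(TooFewPointsError):
            fit("korsmeyer_peppas", prof)

    def test_fixed_m_peppas_sahlin_variant(self, paper_schedule):
        y = evaluate("peppas_sahlin", {"k1": 6.0, "k2": 0.4, "m": 0.45}, paper_schedule)
        res = fit(
            "peppas_sahlin",
            ReleaseProfile("x", paper_schedule, np.clip(y, 0, 110)),
            FitOptions(fix_params={"m": 0.45}),
        )
        assert res.n_params == 2  # m no longer free
        assert res.params["m"] == 0.45
        assert res.params["k1"] == pytest.approx(6.0, rel=1e-6)

    def test_redundant_parameter_never_increases_ss_res(self, paper_schedule):
        # korsmeyer_peppas nests higuchi (n = 0.5): richer model's SSR <= simpler's
        rng = np.random.default_rng(3)
        y = np.clip(
            evaluate("higuchi", {"kH": 12.0}, paper_schedule)
            + rng.normal(0, 2, len(paper_schedule)),
            0,
            110,
        )
        prof = ReleaseProfile("x", paper_schedule, y)
        simple = fit("higuchi", prof)
        richer = fit("korsmeyer_peppas", prof)
        assert richer.ss_res <= simple.ss_res + 1e-9


class TestFitAll:
    def test_grid_cardinality_six_models_three_segments(self, simple_profile):
        models = [
            "first_order",
            "higuchi",
            "korsmeyer_peppas",
            "peppas_sahlin",
            "hopfenberg",
            "weibull",
        ]
        grid = fit_all(simple_profile, models=models)
        assert len(grid.results) + len(grid.failures) == 18

    def test_segmentwise_generating_models_win_per_segment(self):
        # noiseless segment-wise data: each generating model fits its own
        # segment perfectly; korsmeyer_peppas also nests higuchi, so the SGF
        # tie between two perfect fits must break toward fewer parameters
        from relkin import ReleaseSimConfig, SegmentModel, rank, simulate_release

        cfg = ReleaseSimConfig(
            segment_models=(
                SegmentModel("higuchi", {"kH": 14.0}),
                SegmentModel("korsmeyer_peppas", {"kKP": 6.0, "n": 1.3}),
                SegmentModel("first_order", {"k1": 0.015}),
            ),
            seed=42,
            noise_sd=0.0,
        )
        profile = simulate_release(cfg)
        grid = fit_all(profile, models=["higuchi", "korsmeyer_peppas", "first_order"])
        expected = {"SGF": "higuchi", "SIF": "korsmeyer_peppas", "SCoF": "first_order"}
        for seg_label, want in expected.items():
            ranking = rank(grid.for_segment(seg_label))
            assert ranking.order[0][0] == want, seg_label

    def test_missing_segment_flagged_not_fatal(self):
        profile = ReleaseProfile("x", [0.5, 1.0, 7.0, 10.0, 24.0], [5.0, 8.0, 30.0, 40.0, 60.0])
        with pytest.warns(UserWarning):
            grid = fit_all(profile, models=["first_order", "higuchi"])
        assert {s for s in grid.segments()} == {"SGF", "SCoF"}
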