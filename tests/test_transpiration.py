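import math

import numpy as np
import pandas as pd
import pytest

import lysitran as lt
from lysitran import datasets
from lysitran.exceptions import (
    DomainError,
    MulticollinearityError,
    ParameterError,
)
from lysitran.synthetic import logistic_lai
from lysitran.transpiration import ModelCoefficients, StageCalendar

from conftest import flowering_recovery_frame


class TestEvaluateFlowering:
    def test_unit_argument_collapse(self):
        # all log terms vanish; only the power-law prefactor remains
        assert lt.evaluate_flowering(1, 1, 1, 1) == pytest.approx(0.001)

    def test_stage_mean_drivers(self):
        # independent term-by-term recomputation
        expected = (
            0.001 * 83.67**1.261
            + 0.689 * math.log(0.48)
            + 0.399 * math.log(21.27)
            + 0.527 * math.log(2.5)
        )
        got = lt.evaluate_flowering(83.67, 0.48, 21.27, 2.5)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(1.46, abs=0.005)

    def test_linear_in_prefactor(self):
        base = ModelCoefficients("flowering", dict(a=0.001, b=1.261, c=0, d=0, e=0))
        doubled = ModelCoefficients("flowering", dict(a=0.002, b=1.261, c=0, d=0, e=0))
        assert lt.evaluate_flowering(50, 1, 1, 1, doubled) == pytest.approx(
            2 * lt.evaluate_flowering(50, 1, 1, 1, base)
        )

    @pytest.mark.parametrize("bad", [dict(dar=0), dict(vpd=-0.1), dict(ta=0)])
    def test_domain_errors(self, bad):
        kwargs = dict(dar=50.0, vpd=0.5, ta=20.0, lai=2.0)
        kwargs.update(bad)
        with pytest.raises(DomainError):
            lt.evaluate_flowering(**kwargs)


class TestEvaluatePicking:
    def test_unit_argument_collapse(self):
        # published set yields a negative value even at benign inputs —
        # the documented plausibility caveat on these constants
        assert lt.evaluate_picking(1, 0, 1, 1) == pytest.approx(-5.81)

    def test_wind_term_vanishes(self):
        coefs = ModelCoefficients(
            "picking", dict(a=0.011, b=1.04, c=0.189, d=-0.110, e=0.0, f=0.0)
        )
        a = lt.evaluate_picking(50, 0.5, 20, 0.05, coefs)
        b = lt.evaluate_picking(50, 0.5, 20, 5.0, coefs)
        assert a == pytest.approx(b)

    def test_wind_floor_applied(self):
        # below-floor wind evaluates as at the floor rather than -inf
        assert np.isfinite(lt.evaluate_picking(50, 0.5, 20, 0.0))


class TestEvaluateUnsegmented:
    def test_unit_argument_collapse(self):
        assert lt.evaluate_unsegmented(1, 1, 1, 1, 0) == pytest.approx(0.255)

    def test_stage_mean_drivers(self):
        expected = (
            0.514 * math.log(99.21)
            + 0.08 * math.log(0.84)
            + 0.379 * math.log(26.23)
            + 1.05 * math.log(0.17)
            + 0.006 * math.exp(3.0)
            + 0.249
        )
        got = lt.evaluate_unsegmented(99.21, 0.84, 26.23, 0.17, 3.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(2.10, abs=0.005)

    def test_zero_coefficients(self):
        zero = ModelCoefficients(
            "unsegmented",
            dict(b_dar=0, b_vpd=0, b_ta=0, b_w=0, b_lai=0, intercept=0),
        )
        assert lt.evaluate_unsegmented(50, 0.5, 20, 0.1, 2.0, zero) == 0.0


class TestStageCalendar:
    def test_stage_assignment_closed_left(self):
        cal = StageCalendar(10, 50, 100)
        assert cal.stage_of(5) == "seedling"
        assert cal.stage_of(10) == "flowering_fruit_setting"
        assert cal.stage_of(49) == "flowering_fruit_setting"
        assert cal.stage_of(50) == "picking"  # boundary day is picking
        assert cal.stage_of(100) == "picking"

    def test_beyond_calendar(self):
        with pytest.raises(ParameterError):
            StageCalendar(10, 50, 100).stage_of(101)

    def test_chronology_enforced(self):
        with pytest.raises(ParameterError):
            StageCalendar(50, 10, 100)


class TestPredictSeries:
    def _table(self, days):
        n = len(days)
        return pd.DataFrame(
            {
                "day": days,
                "dar": np.full(n, 83.67),
                "vpd": np.full(n, 0.48),
                "ta": np.full(n, 21.27),
                "w": np.full(n, 0.10),
                "lai": np.full(n, 2.5),
            }
        )

    def test_flowering_only_matches_pointwise(self):
        cal = StageCalendar(0, 90, 100)
        table = self._table(np.arange(0, 10))
        out = lt.predict_series(table, cal)
        direct = lt.evaluate_flowering(83.67, 0.48, 21.27, 2.5)
        assert np.allclose(out["ts"], direct)
        assert (out["stage"] == "flowering_fruit_setting").all()

    def test_negative_predictions_clipped(self):
        # published picking constants go negative at these drivers
        cal = StageCalendar(0, 5, 20)
        out = lt.predict_series(self._table(np.arange(5, 15)), cal)
        assert (out["ts"] == 0.0).all()
        assert (out["flag"] == "negative_clipped").all()

    def test_seedling_days_excluded(self):
        cal = StageCalendar(5, 8, 20)
        out = lt.predict_series(self._table(np.arange(0, 10)), cal)
        assert out["day"].min() == 5
        assert len(out) == 5


class TestFit:
    def test_noiseless_recovery(self):
        frame = flowering_recovery_frame(seed=1, noise_sd=0.0)
        res = lt.TranspirationModel.from_dataframe(frame, "flowering").fit()
        truth = lt.PUBLISHED["flowering"].as_array()
        assert np.abs(res.params.to_numpy() - truth).max() < 1e-6
        assert res.rss < 1e-12
        assert res.converged

    def test_picking_noiseless_recovery(self):
        params = datasets.stage_params(2022, "picking", seed=6, n_days=120)
        climate = lt.generate_microclimate(params)
        frame = climate.copy()
        frame["tm"] = lt.evaluate_picking(
            frame["dar"], frame["vpd"], frame["ta"], frame["w"]
        )
        res = lt.TranspirationModel.from_dataframe(frame, "picking").fit()
        truth = lt.PUBLISHED["picking"].as_array()
        assert np.abs(res.params.to_numpy() - truth).max() < 1e-6

    def test_refit_own_predictions_fixed_point(self, flowering_frame):
        res = lt.TranspirationModel.from_dataframe(flowering_frame, "flowering").fit()
        frame2 = flowering_frame.copy()
        frame2["tm"] = res.predict()
        res2 = lt.TranspirationModel.from_dataframe(frame2, "flowering").fit()
        assert np.abs(res2.params - res.params).max() < 1e-6

    def test_order_invariance(self, flowering_frame):
        res = lt.TranspirationModel.from_dataframe(flowering_frame, "flowering").fit()
        shuffled = flowering_frame.sample(frac=1.0, random_state=0)
        res2 = lt.TranspirationModel.from_dataframe(shuffled, "flowering").fit()
        assert np.abs(res2.params - res.params).max() < 1e-6

    def test_constant_drivers_rank_deficient(self):
        frame = pd.DataFrame(
            {
                "dar": np.full(30, 80.0),
                "vpd": np.full(30, 0.5),
                "ta": np.full(30, 20.0),
                "lai": np.full(30, 2.0),
                "tm": np.linspace(1, 2, 30),
            }
        )
        with pytest.raises(MulticollinearityError):
            lt.TranspirationModel.from_dataframe(frame, "flowering").fit()

    def test_unsegmented_closed_form_vs_iterative(self):
        params = datasets.stage_params(
            2022, "flowering_fruit_setting", seed=8, n_days=120
        )
        climate = lt.generate_microclimate(params)
        frame = climate.copy()
        frame["lai"] = logistic_lai(
            np.linspace(35, 80, len(frame)), lt.LaiTrajectoryParams()
        )
        rng = np.random.default_rng(2)
        frame["tm"] = lt.evaluate_unsegmented(
            frame["dar"], frame["vpd"], frame["ta"], frame["w"], frame["lai"]
        ) + rng.normal(0, 0.05, len(frame))
        model = lt.TranspirationModel.from_dataframe(frame, "unsegmented")
        closed = model.fit()
        iterative = model.fit(method="lm")
        assert np.abs(closed.params - iterative.params).max() < 1e-6

    def test_summary_mentions_form_and_coefs(self, flowering_frame):
        res = lt.TranspirationModel.from_dataframe(flowering_frame, "flowering").fit()
        text = res.summary()
        assert "flowering" in text
        for name in ("a", "b", "c", "d", "e"):
            assert name in text

    def test_too_few_observations(self):
        frame = flowering_recovery_frame(seed=1, n_days=150).head(10)
        with pytest.raises(ParameterError):
            lt.TranspirationModel.from_dataframe(frame, "flowering")


class TestSegmentedModel:
    @staticmethod
    def _two_stage_frame(seed=31, n_flow=60, n_pick=60):
        laip = lt.LaiTrajectoryParams()
        f_params = datasets.stage_params(
            2022, "flowering_fruit_setting", seed=seed, n_days=n_flow
        )
        p_params = datasets.stage_params(2022, "picking", seed=seed + 1, n_days=n_pick)
        flow = lt.generate_microclimate(f_params)
        pick = lt.generate_microclimate(p_params)
        flow["lai"] = logistic_lai(np.linspace(42, 80, n_flow), laip)
        pick["lai"] = laip.lai_max
        rng = np.random.default_rng(seed + 2)
        flow["tm"] = lt.evaluate_flowering(
            flow["dar"], flow["vpd"], flow["ta"], flow["lai"]
        ) + rng.normal(0, 0.05, n_flow)
        # picking truth from a plausible positive-valued coefficient set
        pick_coefs = ModelCoefficients(
            "picking", dict(a=0.011, b=1.04, c=0.189, d=0.2, e=0.05, f=0.3)
        )
        pick["tm"] = lt.evaluate_picking(
            pick["dar"], pick["vpd"], pick["ta"], pick["w"], pick_coefs
        ) + rng.normal(0, 0.05, n_pick)
        pick["day"] = pick["day"] + n_flow
        frame = pd.concat([flow, pick], ignore_index=True)
        return frame, StageCalendar(0, n_flow, n_flow + n_pick)

    def test_segmented_beats_unsegmented_rss(self):
        frame, calendar = self._two_stage_frame()
        seg = lt.SegmentedTranspirationModel(frame, calendar).fit()
        unseg = lt.TranspirationModel.from_dataframe(frame, "unsegmented").fit()
        assert seg.rss < unseg.rss

    def test_predict_covers_both_stages(self):
        frame, calendar = self._two_stage_frame()
        seg = lt.SegmentedTranspirationModel(frame, calendar).fit()
        pred = seg.predict()
        assert set(pred["stage"]) == {"flowering_fruit_setting", "picking"}
        assert len(pred) == len(frame)
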