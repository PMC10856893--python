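import numpy as np
import pandas as pd
import pytest

import lysitran as lt
from lysitran import datasets
from lysitran.exceptions import AlignmentError, ParameterError
from lysitran.synthetic import IrrigationPolicy, logistic_lai


def stage(seed=1, **kw):
    defaults = dict(
        stage_name="flowering_fruit_setting",
        n_days=50,
        mean_dar=83.67,
        mean_vpd=0.48,
        mean_ta=21.27,
        mean_w=0.10,
        seed=seed,
    )
    defaults.update(kw)
    return lt.StageParams(**defaults)


class TestGenerateMicroclimate:
    def test_zero_variance_limit(self):
        out = lt.generate_microclimate(stage(cv=0.0, ar1=0.0))
        assert np.allclose(out["dar"], 83.67)
        assert np.allclose(out["vpd"], 0.48)
        assert np.allclose(out["ta"], 21.27)
        assert np.allclose(out["w"], 0.10)

    def test_seeding_contract(self):
        a = lt.generate_microclimate(stage(seed=1))
        b = lt.generate_microclimate(stage(seed=1))
        c = lt.generate_microclimate(stage(seed=2))
        pd.testing.assert_frame_equal(a, b)
        assert not np.allclose(a["dar"], c["dar"])

    def test_moment_recovery(self):
        params = stage(seed=1, n_days=1000, cv=0.2, ar1=0.5)
        out = lt.generate_microclimate(params)
        # AR(1) series: SE of the mean inflated by sqrt((1+rho)/(1-rho))
        infl = np.sqrt((1 + params.ar1) / (1 - params.ar1))
        for col, mean in [
            ("dar", 83.67),
            ("vpd", 0.48),
            ("ta", 21.27),
            ("w", 0.10),
        ]:
            x = out[col].to_numpy()
            se = x.std(ddof=1) / np.sqrt(len(x)) * infl
            assert abs(x.mean() - mean) < 3 * se, col

    def test_strict_positivity(self):
        out = lt.generate_microclimate(stage(seed=3, n_days=2000, cv=0.5))
        assert (out[["dar", "vpd", "ta", "w"]] > 0).all().all()

    def test_radiation_coupling_positive(self):
        out = lt.generate_microclimate(stage(seed=4, n_days=2000))
        assert np.corrcoef(out["dar"], out["vpd"])[0, 1] > 0.3
        assert np.corrcoef(out["dar"], out["ta"])[0, 1] > 0.3

    @pytest.mark.parametrize(
        "bad",
        [
            dict(mean_dar=0.0),
            dict(mean_vpd=-1.0),
            dict(mean_ta=np.nan),
            dict(ar1=1.0),
            dict(n_days=0),
        ],
    )
    def test_parameter_validation(self, bad):
        with pytest.raises(ParameterError):
            stage(**bad)


class TestGenerateLai:
    def test_logistic_asymptote(self):
        params = lt.LaiTrajectoryParams(lai_max=2.64, midpoint_day=46, rate=0.115)
        assert logistic_lai(46 + 200, params) == pytest.approx(2.64, abs=1e-6)

    def test_monotone_and_bounded(self):
        params = lt.LaiTrajectoryParams(
            lai_max=2.64,
            midpoint_day=45,
            rate=0.115,
            measurement_days=(30, 40, 50, 60, 70, 80),
        )
        out = lt.generate_lai_trajectory(params)
        lai = out["lai"].to_numpy()
        assert (np.diff(lai) >= 0).all()
        assert (lai > 0).all() and (lai <= 2.64).all()

    def test_measurement_days_only(self):
        out = lt.generate_lai_trajectory(lt.LaiTrajectoryParams())
        assert list(out["day"]) == [30, 40, 50, 60, 70, 80]

    def test_noise_seeded(self):
        params = lt.LaiTrajectoryParams(measurement_noise_sd=0.1, seed=7)
        a = lt.generate_lai_trajectory(params)
        b = lt.generate_lai_trajectory(params)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_days_rejected(self):
        with pytest.raises(ParameterError):
            lt.LaiTrajectoryParams(measurement_days=())


class TestGenerateTranspiration:
    def test_noiseless_identity(self):
        climate = lt.generate_microclimate(stage(seed=2))
        lai = np.linspace(1.0, 2.6, len(climate))
        out = lt.generate_transpiration(climate, lai, lt.PUBLISHED["flowering"], 0.0)
        direct = lt.evaluate_flowering(
            climate["dar"], climate["vpd"], climate["ta"], lai
        )
        np.testing.assert_array_equal(out["tm"].to_numpy(), direct)
        assert (out["flag"] == "ok").all()

    def test_noise_sd_recovered(self):
        climate = lt.generate_microclimate(stage(seed=5, n_days=1000))
        lai = np.full(1000, 2.0)
        clean = lt.generate_transpiration(climate, lai, lt.PUBLISHED["flowering"], 0.0)
        noisy = lt.generate_transpiration(
            climate, lai, lt.PUBLISHED["flowering"], 0.05, seed=11
        )
        resid = noisy["tm"].to_numpy() - clean["tm"].to_numpy()
        se = 0.05 / np.sqrt(2 * (len(resid) - 1))  # SE of a Normal sd estimate
        assert abs(resid.std(ddof=1) - 0.05) < 3 * se

    def test_length_mismatch(self):
        climate = lt.generate_microclimate(stage(seed=1, n_days=10))
        with pytest.raises(AlignmentError):
            lt.generate_transpiration(
                climate, np.ones(5), lt.PUBLISHED["flowering"], 0.0
            )


class TestGenerateWeighingRecords:
    def test_static_system(self):
        out = lt.generate_weighing_records(np.zeros(10))
        assert out["w_morning"].nunique() == 1
        assert (out["irrigation"] == 0).all()
        series = lt.transpiration_series(
            out.rename(columns={"day": "date"})[
                ["date", "w_morning", "irrigation", "return_flow"]
            ]
        )
        assert (series["td_mass"] == 0).all()

    def test_roundtrip_bit_exact(self):
        rng = np.random.default_rng(3)
        tm = rng.uniform(0.0, 0.6, 120)
        out = lt.generate_weighing_records(tm, IrrigationPolicy(0.70, 0.10), 4.0)
        recovered = lt.transpiration_series(
            out.rename(columns={"day": "date"})[
                ["date", "w_morning", "irrigation", "return_flow"]
            ]
        )["td_mass"].to_numpy()
        encoded = out["td_encoded"].to_numpy()[:-1]
        assert np.array_equal(recovered, encoded)  # zero tolerance
        # encoding error bounded by the gram quantum
        assert np.abs(encoded - tm).max() <= 2.0**-11

    def test_store_bounds_and_emergency_irrigation(self):
        # heavy demand with a lax trigger: events must still be inserted
        tm = np.full(30, 1.5)
        out = lt.generate_weighing_records(tm, IrrigationPolicy(0.10, 0.0), 4.0)
        store = out["w_morning"].to_numpy() - 30.0
        assert (store >= -1e-12).all() and (store <= 4.0 + 1e-12).all()
        assert out["irrigation"].sum() > 0

    def test_mass_conservation_each_day(self):
        rng = np.random.default_rng(9)
        tm = rng.uniform(0, 0.5, 60)
        out = lt.generate_weighing_records(tm)
        w = out["w_morning"].to_numpy()
        balance = w[:-1] + out["irrigation"].to_numpy()[:-1] - out[
            "return_flow"
        ].to_numpy()[:-1] - out["td_encoded"].to_numpy()[:-1]
        np.testing.assert_array_equal(balance, w[1:])

    def test_capacity_guard(self):
        with pytest.raises(ParameterError):
            lt.generate_weighing_records(np.ones(3), capacity=0.0)
        with pytest.raises(ParameterError):
            lt.generate_weighing_records(np.array([-0.1]))


class TestScenario:
    def test_scenario_tables_coherent(self):
        params = datasets.stage_params(
            2022, "flowering_fruit_setting", seed=21, n_days=40
        )
        scenario = lt.generate_scenario(lt.ScenarioConfig(stage=params))
        assert set(scenario) == {
            "microclimate",
            "growth",
            "lai_daily",
            "transpiration",
            "weighing",
        }
        n = len(scenario["microclimate"])
        assert len(scenario["transpiration"]) == n
        assert len(scenario["weighing"]) == n + 1
        assert (scenario["lai_daily"]["lai"] >= 1.0 - 1e-9).all()
        assert (scenario["transpiration"]["flag"] == "ok").all()
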