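"""Tests of the synthetic study generator: determinism, configured rates,
and the planted outcome structure."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from somexposure.exceptions import InvalidConfigError, SomexposureError
from somexposure.simulate import (
    OutcomeModel,
    Plume,
    PollutantField,
    SimulationConfig,
    assign_outcomes,
    generate_cohort,
    generate_stations,
    simulate_measurements,
    simulate_study,
    separable_config,
    write_study,
)


def small_config(**overrides):
    defaults = dict(n_stations=5, n_patients=60, n_days=20, seed=1)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestStations:
    def test_seed_determinism(self):
        a = generate_stations(small_config())
        b = generate_stations(small_config())
        pd.testing.assert_frame_equal(a.stations, b.stations)

    def test_seeds_differ(self):
        a = generate_stations(SimulationConfig(n_stations=20, seed=1))
        b = generate_stations(SimulationConfig(n_stations=20, seed=2))
        assert not np.allclose(a.stations[["lon", "lat"]], b.stations[["lon", "lat"]])

    def test_single_station_inside_region(self):
        cfg = small_config(n_stations=1)
        st = generate_stations(cfg).stations
        lon0, lon1, lat0, lat1 = cfg.region
        assert lon0 <= st.lon.iloc[0] <= lon1
        assert lat0 <= st.lat.iloc[0] <= lat1

    def test_nonpositive_count_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(n_stations=0)


class TestMeasurements:
    def test_degenerate_noise_returns_exact_baseline(self):
        fields = {"SO2": PollutantField(baseline=7.5, noise_sd=0.0, rho=0.0)}
        cfg = small_config(fields=fields, missing_rate=0.0)
        net = simulate_measurements(generate_stations(cfg), cfg)
        assert (net.measurements["value"] == 7.5).all()

    def test_mcar_rate_recovered(self):
        cfg = SimulationConfig(
            n_stations=25, n_days=140, n_patients=1,
            fields={"SO2": PollutantField(baseline=10.0)},
            missing_rate=0.3, missing_mechanism="MCAR", seed=4,
        )
        net = simulate_measurements(generate_stations(cfg), cfg)
        frac = net.measurements["value"].isna().mean()
        assert net.measurements.shape[0] >= 3000
        assert frac == pytest.approx(0.3, abs=0.02)

    def test_mar_missingness_increases_with_value(self):
        cfg = SimulationConfig(
            n_stations=25, n_days=140, n_patients=1,
            fields={"SO2": PollutantField(baseline=10.0, noise_sd=0.5)},
            missing_rate=0.3, missing_mechanism="MAR", seed=4,
        )
        miss_cfg = cfg
        full_cfg = SimulationConfig(**{**miss_cfg.__dict__, "missing_rate": 0.0})
        full = simulate_measurements(generate_stations(full_cfg), full_cfg)
        got = simulate_measurements(generate_stations(miss_cfg), miss_cfg)
        values = full.measurements["value"]
        missing = got.measurements["value"].isna()
        median = values.median()
        assert missing[values > median].mean() > missing[values <= median].mean()

    def test_values_nonnegative_any_seed(self):
        for seed in (0, 5, 9):
            cfg = small_config(seed=seed)
            net = simulate_measurements(generate_stations(cfg), cfg)
            assert (net.measurements["value"].dropna() >= 0).all()

    def test_invalid_autocorrelation_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(fields={"SO2": PollutantField(baseline=1.0, rho=1.0)})

    def test_each_cell_appears_once(self):
        cfg = small_config()
        net = simulate_measurements(generate_stations(cfg), cfg)
        net.validate()
        assert not net.measurements.duplicated(
            ["station_id", "date", "pollutant"]
        ).any()


class TestCohort:
    def test_ages_clipped_to_study_range(self):
        df = generate_cohort(small_config(n_patients=500)).patients
        assert df.age.between(1 / 3, 86).all()

    def test_age_categories_consistent(self):
        df = generate_cohort(small_config(n_patients=500)).patients
        from somexposure.preprocessing import categorize_age

        assert (df.age_category == categorize_age(df.age.to_numpy())).all()

    def test_male_proportion_recovered(self):
        cfg = small_config(n_patients=5000, p_male=0.53)
        df = generate_cohort(cfg).patients
        assert (df.gender == "male").mean() == pytest.approx(0.53, abs=0.02)

    def test_presentation_dates_leave_room_for_lag(self):
        cfg = small_config(lag=2)
        df = generate_cohort(cfg).patients
        start = pd.to_datetime(cfg.start_date)
        assert ((df.date - start).dt.days >= 2).all()

    def test_population_centers_cluster_patients(self):
        cfg = small_config(
            n_patients=400,
            population_centers=((28.0, -26.0, 0.02, 1.0), (28.3, -25.6, 0.02, 1.0)),
        )
        df = generate_cohort(cfg).patients
        near_a = np.hypot(df.lon - 28.0, df.lat + 26.0) < 0.1
        near_b = np.hypot(df.lon - 28.3, df.lat + 25.6) < 0.1
        assert (near_a | near_b).mean() > 0.95


class TestOutcomes:
    def test_null_model_prevalence_matches_intercept(self):
        cfg = small_config(n_patients=10000)
        cohort = generate_cohort(cfg)
        expo = pd.DataFrame(
            {"SO2": np.ones(10000)}, index=cohort.patients["id"]
        )
        model = OutcomeModel(
            intercept=float(logit(0.19)), pollutants={"SO2": 0.0},
            age=0.0, gender_male=0.0,
        )
        out = assign_outcomes(cohort, expo, model=model, seed=3)
        assert out.patients.outcome.mean() == pytest.approx(0.19, abs=0.02)

    def test_extreme_negative_intercept_gives_no_cases(self):
        cfg = small_config()
        cohort = generate_cohort(cfg)
        expo = pd.DataFrame({"SO2": np.ones(60)}, index=cohort.patients["id"])
        model = OutcomeModel(intercept=-1e9, pollutants={"SO2": 0.0},
                             age=0.0, gender_male=0.0)
        out = assign_outcomes(cohort, expo, model=model, seed=0)
        assert (out.patients.outcome == 0).all()

    def test_positive_so2_effect_raises_case_exposure(self):
        cfg = small_config(n_patients=3000)
        cohort = generate_cohort(cfg)
        rng = np.random.default_rng(8)
        expo = pd.DataFrame(
            {"SO2": rng.normal(15, 5, size=3000)}, index=cohort.patients["id"]
        )
        model = OutcomeModel(intercept=0.0, pollutants={"SO2": 3.0},
                             age=0.0, gender_male=0.0)
        out = assign_outcomes(cohort, expo, model=model, seed=1).patients
        merged = out.merge(expo, left_on="id", right_index=True)
        assert (
            merged.loc[merged.outcome == 1, "SO2"].mean()
            > merged.loc[merged.outcome == 0, "SO2"].mean()
        )

    def test_missing_exposures_are_a_precondition_error(self):
        cfg = small_config()
        cohort = generate_cohort(cfg)
        expo = pd.DataFrame(
            {"SO2": np.ones(59)}, index=cohort.patients["id"][:59]
        )
        with pytest.raises(SomexposureError):
            assign_outcomes(cohort, expo)


class TestEndToEnd:
    def test_csv_outputs_byte_identical_across_runs(self, tmp_path):
        cfg = small_config()
        for d in ("a", "b"):
            net, co = simulate_study(cfg)
            write_study(net, co, tmp_path / d)
        for name in ("stations.csv", "measurements.csv", "cohort.csv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_default_effects_order_so2_strongest(self):
        m = OutcomeModel()
        assert abs(m.pollutants["SO2"]) > abs(m.pollutants["PM10"]) >= abs(
            m.pollutants["NO2"]
        )
        assert m.age > 0

    def test_separable_config_is_strong_signal(self):
        cfg = separable_config(seed=0, n_patients=200)
        assert cfg.outcome.pollutants["SO2"] >= 2 * cfg.outcome.age
        net, co = simulate_study(cfg)
        prev = co.patients.outcome.mean()
        assert 0.3 < prev < 0.7
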