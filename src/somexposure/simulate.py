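"""Seeded synthetic study inputs: a monitoring-station network with sparse
daily pollutant series, and a patient cohort with demographics, coordinates
and a binary respiratory outcome driven by lagged exposures.

The generator emulates the structure of a two-city exposure study: a handful
of fixed air-quality monitoring stations report daily NO2, SO2 and PM10 (CO
and O3 optionally) with substantial missingness; patients live at geocoded
coordinates scattered over the same region, present on some day, and their
outcome probability is a logistic function of the pollutant levels two days
before presentation plus age, gender and race. Everything is deterministic
under the configured seed.

Pollutant surfaces are a baseline plus isotropic Gaussian source plumes —
the simplest spatial field with smooth gradients, so that interpolating
station values to patient addresses is meaningful. Day-to-day variation is a
shared lognormal AR(1) factor per pollutant plus independent lognormal
station noise, both driven by one noise scale so that a zero noise scale
yields exactly the deterministic field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import qmc

from .exceptions import InvalidConfigError, SomexposureError

__all__ = [
    "Plume",
    "PollutantField",
    "OutcomeModel",
    "SimulationConfig",
    "StationNetwork",
    "Cohort",
    "generate_stations",
    "simulate_measurements",
    "generate_cohort",
    "assign_outcomes",
    "simulate_study",
]

REQUIRED_POLLUTANTS = ("NO2", "SO2", "PM10")
OPTIONAL_POLLUTANTS = ("CO", "O3")
GENDER_LEVELS = ("male", "female", "missing")
RACE_LEVELS = (0, 1, 2, 3)


@dataclass(frozen=True)
class Plume:
    """One isotropic Gaussian emission source: peak amplitude (ug/m3) at
    (lon, lat), decaying with e-folding length `scale` in degrees."""

    lon: float
    lat: float
    amplitude: float
    scale: float = 0.15


@dataclass(frozen=True)
class PollutantField:
    """Spatio-temporal model of one pollutant.

    baseline : regional background concentration, ug/m3.
    plumes : additive Gaussian sources on top of the baseline.
    rho : AR(1) autocorrelation of the shared daily log-factor, in [0, 1).
    noise_sd : sd of both the AR(1) innovations and the per-station-day
        lognormal noise (log scale); 0 gives the deterministic field.
    """

    baseline: float
    plumes: tuple[Plume, ...] = ()
    rho: float = 0.6
    noise_sd: float = 0.3

    def spatial(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        value = np.full(np.broadcast(lon, lat).shape, float(self.baseline))
        for p in self.plumes:
            d2 = (np.asarray(lon) - p.lon) ** 2 + (np.asarray(lat) - p.lat) ** 2
            value = value + p.amplitude * np.exp(-d2 / (2.0 * p.scale**2))
        return value


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic outcome coefficients.

    Exposures are standardized and demographic terms mean-centred within the
    cohort before the linear predictor is formed, so `intercept` is
    (approximately) the logit of the outcome prevalence. Defaults encode the
    qualitative structure the analysis is meant to recover: SO2 the strongest
    pollutant effect (|b_SO2| > |b_PM10| >= |b_NO2|) and a positive age
    effect, around a 19% prevalence.
    """

    intercept: float = float(logit(0.19))
    pollutants: dict = field(
        default_factory=lambda: {"SO2": 0.9, "PM10": 0.45, "NO2": 0.3}
    )
    age: float = 0.35
    gender_male: float = 0.15
    race: dict = field(default_factory=lambda: {0: 0.0, 1: 0.0, 2: 0.0, 3: 0.0})


_DEFAULT_FIELDS = {
    # Highveld-like magnitudes (ug/m3) over a two-metropolis region
    "NO2": PollutantField(baseline=25.0, plumes=(Plume(28.05, -26.2, 20.0),)),
    "SO2": PollutantField(baseline=15.0, plumes=(Plume(28.25, -25.75, 18.0),)),
    "PM10": PollutantField(baseline=45.0, plumes=(Plume(27.95, -26.1, 25.0),)),
}


@dataclass(frozen=True)
class SimulationConfig:
    """End-to-end configuration of the synthetic study.

    region : (lon_min, lon_max, lat_min, lat_max) in degrees.
    population_centers : optional ((lon, lat, sd_degrees, weight), ...);
        when given, patient coordinates are drawn from this Gaussian mixture
        (clipped to the region) instead of uniformly — e.g. two metropolitan
        centres of different exposure. Weights are renormalized.
    missing_mechanism : "MCAR" (uniform) or "MAR" (missingness probability
        increasing with the value's rank, i.e. high readings drop out more).
    lag : days between exposure and clinical presentation.
    """

    n_stations: int = 8
    n_patients: int = 483
    n_days: int = 120
    region: tuple[float, float, float, float] = (27.8, 28.4, -26.4, -25.5)
    population_centers: tuple[tuple[float, float, float, float], ...] | None = None
    start_date: str = "2016-03-01"
    fields: dict = field(default_factory=lambda: dict(_DEFAULT_FIELDS))
    missing_mechanism: str = "MCAR"
    missing_rate: float = 0.15
    age_gamma_shape: float = 2.0
    age_gamma_scale: float = 16.0
    age_bounds: tuple[float, float] = (1.0 / 3.0, 86.0)
    p_male: float = 0.53
    p_gender_missing: float = 0.015
    race_probs: tuple[float, ...] = (0.72, 0.14, 0.08, 0.06)
    outcome: OutcomeModel = field(default_factory=OutcomeModel)
    lag: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stations < 1:
            raise InvalidConfigError("n_stations must be >= 1")
        if self.n_patients < 1:
            raise InvalidConfigError("n_patients must be >= 1")
        if self.n_days < 1:
            raise InvalidConfigError("n_days must be >= 1")
        lon0, lon1, lat0, lat1 = self.region
        if not (lon1 > lon0 and lat1 > lat0):
            raise InvalidConfigError("region bounds must be non-degenerate")
        if self.missing_mechanism not in ("MCAR", "MAR"):
            raise InvalidConfigError("missing_mechanism must be MCAR or MAR")
        if not 0.0 <= self.missing_rate < 1.0:
            raise InvalidConfigError("missing_rate must be in [0, 1)")
        for name, f in self.fields.items():
            if not 0.0 <= f.rho < 1.0:
                raise InvalidConfigError(f"{name}: rho must be in [0, 1)")
            if f.noise_sd < 0:
                raise InvalidConfigError(f"{name}: noise_sd must be >= 0")
        if not np.isclose(sum(self.race_probs), 1.0):
            raise InvalidConfigError("race_probs must sum to 1")
        if self.population_centers is not None:
            if not self.population_centers:
                raise InvalidConfigError("population_centers must be non-empty")
            for c in self.population_centers:
                if len(c) != 4 or c[2] <= 0 or c[3] <= 0:
                    raise InvalidConfigError(
                        "each population centre is (lon, lat, sd > 0, weight > 0)"
                    )
        if self.lag < 0:
            raise InvalidConfigError("lag must be >= 0")
        if self.n_days <= self.lag:
            raise InvalidConfigError("n_days must exceed the exposure lag")

    @property
    def pollutants(self) -> tuple[str, ...]:
        return tuple(self.fields.keys())

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# containers

@dataclass
class StationNetwork:
    """Monitoring sites plus their daily pollutant measurements.

    stations : DataFrame (station_id, lon, lat), ids unique.
    measurements : DataFrame (station_id, date, pollutant, value); value is
        NaN when missing; each (station, date, pollutant) appears once.
    """

    stations: pd.DataFrame
    measurements: pd.DataFrame

    def validate(self) -> None:
        if self.stations["station_id"].duplicated().any():
            raise SomexposureError("station ids must be unique")
        known = set(self.stations["station_id"])
        if not set(self.measurements["station_id"]).issubset(known):
            raise SomexposureError("measurement references unknown station")
        vals = self.measurements["value"]
        if (vals.dropna() < 0).any():
            raise SomexposureError("pollutant values must be non-negative")
        if self.measurements.duplicated(["station_id", "date", "pollutant"]).any():
            raise SomexposureError("duplicate (station, date, pollutant) measurement")


@dataclass
class Cohort:
    """Patient records: id, age (years), age_category 1-5, gender, race,
    lon/lat, presentation date, and (once assigned) binary outcome."""

    patients: pd.DataFrame

    def validate(self) -> None:
        df = self.patients
        if df["id"].duplicated().any():
            raise SomexposureError("patient ids must be unique")
        if (df["age"] < 0).any():
            raise SomexposureError("ages must be non-negative")
        if not df["age_category"].isin([1, 2, 3, 4, 5]).all():
            raise SomexposureError("age_category must be in 1..5")
        if "outcome" in df and not df["outcome"].dropna().isin([0, 1]).all():
            raise SomexposureError("outcome must be binary")


# ---------------------------------------------------------------------------
# generation

def _seed_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_stations(config: SimulationConfig) -> StationNetwork:
    """Place monitoring stations quasi-uniformly in the study region.

    A seeded scrambled Halton sequence spreads the sites more evenly than
    i.i.d. uniform draws, mimicking a deliberately sited network.
    """
    rng = _seed_streams(config.seed, 4)[0]
    lon0, lon1, lat0, lat1 = config.region
    sampler = qmc.Halton(d=2, scramble=True, rng=rng)
    unit = sampler.random(config.n_stations)
    lons = lon0 + unit[:, 0] * (lon1 - lon0)
    lats = lat0 + unit[:, 1] * (lat1 - lat0)
    stations = pd.DataFrame(
        {
            "station_id": [f"ST{i + 1:02d}" for i in range(config.n_stations)],
            "lon": lons,
            "lat": lats,
        }
    )
    return StationNetwork(
        stations=stations,
        measurements=pd.DataFrame(columns=["station_id", "date", "pollutant", "value"]),
    )


def simulate_measurements(network: StationNetwork, config: SimulationConfig) -> StationNetwork:
    """Fill the network with daily pollutant series and apply missingness.

    value(station, day) = spatial_field(station) * exp(a_day + e_station,day),
    truncated at 0, where a is a stationary AR(1) log-factor with
    autocorrelation rho and e is i.i.d. noise; both have sd `noise_sd`.
    Missingness is then applied at `missing_rate` — MCAR uniformly, MAR with
    probability proportional to the value's rank (mean rate preserved).
    """
    if network.stations.empty:
        raise InvalidConfigError("network has no stations")
    rng = _seed_streams(config.seed, 4)[1]
    dates = pd.date_range(config.start_date, periods=config.n_days, freq="D")
    lon = network.stations["lon"].to_numpy()
    lat = network.stations["lat"].to_numpy()
    ids = network.stations["station_id"].to_numpy()
    frames = []
    for name, fld in config.fields.items():
        base = fld.spatial(lon, lat)  # (n_stations,)
        a = np.zeros(config.n_days)
        if fld.noise_sd > 0:
            innov = rng.normal(0.0, fld.noise_sd, size=config.n_days)
            a[0] = innov[0] / np.sqrt(1.0 - fld.rho**2)
            for d in range(1, config.n_days):
                a[d] = fld.rho * a[d - 1] + innov[d]
            e = rng.normal(0.0, fld.noise_sd, size=(config.n_days, len(ids)))
        else:
            e = np.zeros((config.n_days, len(ids)))
        values = base[None, :] * np.exp(a[:, None] + e)
        values = np.maximum(values, 0.0)
        flat = values.ravel()  # day-major
        if config.missing_rate > 0:
            if config.missing_mechanism == "MCAR":
                p_miss = np.full(flat.size, config.missing_rate)
            else:  # MAR: higher readings drop out more often
                ranks = pd.Series(flat).rank(method="average").to_numpy()
                p_miss = np.minimum(
                    config.missing_rate * 2.0 * ranks / (flat.size + 1), 1.0
                )
            miss = rng.random(flat.size) < p_miss
            flat = np.where(miss, np.nan, flat)
        frames.append(
            pd.DataFrame(
                {
                    "station_id": np.tile(ids, config.n_days),
                    "date": np.repeat(dates, len(ids)),
                    "pollutant": name,
                    "value": flat,
                }
            )
        )
    measurements = pd.concat(frames, ignore_index=True)
    out = StationNetwork(stations=network.stations, measurements=measurements)
    out.validate()
    return out


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Draw a patient cohort without outcomes.

    Ages come from a right-skewed gamma distribution clipped to the
    configured bounds (default 4 months to 86 years); gender and race follow
    the configured proportions, including a small missing-gender fraction;
    coordinates are uniform in the region; presentation dates are uniform on
    days >= lag so a lagged exposure always exists.
    """
    rng = _seed_streams(config.seed, 4)[2]
    n = config.n_patients
    ages = rng.gamma(config.age_gamma_shape, config.age_gamma_scale, size=n)
    ages = np.clip(ages, *config.age_bounds)
    from .preprocessing import categorize_age

    gender = rng.choice(
        GENDER_LEVELS,
        size=n,
        p=[
            config.p_male,
            1.0 - config.p_male - config.p_gender_missing,
            config.p_gender_missing,
        ],
    )
    race = rng.choice(RACE_LEVELS, size=n, p=config.race_probs)
    lon0, lon1, lat0, lat1 = config.region
    dates = pd.to_datetime(config.start_date) + pd.to_timedelta(
        rng.integers(config.lag, config.n_days, size=n), unit="D"
    )
    if config.population_centers is None:
        lons = rng.uniform(lon0, lon1, size=n)
        lats = rng.uniform(lat0, lat1, size=n)
    else:
        centers = np.asarray(config.population_centers, dtype=float)
        weights = centers[:, 3] / centers[:, 3].sum()
        choice = rng.choice(len(centers), size=n, p=weights)
        lons = rng.normal(centers[choice, 0], centers[choice, 2])
        lats = rng.normal(centers[choice, 1], centers[choice, 2])
        lons = np.clip(lons, lon0, lon1)
        lats = np.clip(lats, lat0, lat1)
    patients = pd.DataFrame(
        {
            "id": [f"P{i + 1:04d}" for i in range(n)],
            "age": ages,
            "age_category": categorize_age(ages),
            "gender": gender,
            "race": race,
            "lon": lons,
            "lat": lats,
            "date": dates,
        }
    )
    cohort = Cohort(patients=patients)
    cohort.validate()
    return cohort


def assign_outcomes(
    cohort: Cohort,
    exposures: pd.DataFrame,
    model: OutcomeModel | None = None,
    seed: int = 0,
) -> Cohort:
    """Draw binary outcomes from a logistic model of lagged exposure and
    demographics.

    `exposures` is indexed by patient id with one complete column per
    pollutant (missing exposures are a precondition error). Pollutants are
    standardized and demographic terms mean-centred within the cohort, then
    P(outcome = 1) = expit(intercept + b . x) and outcomes are Bernoulli
    draws under `seed`.
    """
    model = model or OutcomeModel()
    df = cohort.patients
    missing_ids = set(df["id"]) - set(exposures.index)
    if missing_ids:
        raise SomexposureError(
            f"exposure vector incomplete: {len(missing_ids)} patients lack exposures"
        )
    expo = exposures.loc[df["id"]]
    if expo[list(model.pollutants)].isna().any().any():
        raise SomexposureError("exposure vector contains missing values")
    lin = np.full(len(df), model.intercept)
    for pol, beta in model.pollutants.items():
        col = expo[pol].to_numpy(dtype=float)
        sd = col.std()
        z = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
        lin += beta * z
    age_cat = df["age_category"].to_numpy(dtype=float)
    lin += model.age * (age_cat - age_cat.mean())
    male = (df["gender"] == "male").to_numpy(dtype=float)
    lin += model.gender_male * (male - male.mean())
    for level, beta in model.race.items():
        if beta:
            ind = (df["race"] == level).to_numpy(dtype=float)
            lin += beta * (ind - ind.mean())
    rng = np.random.default_rng(seed)
    outcome = (rng.random(len(df)) < expit(lin)).astype(int)
    patients = df.copy()
    patients["outcome"] = outcome
    out = Cohort(patients=patients)
    out.validate()
    return out


def simulate_study(config: SimulationConfig) -> tuple[StationNetwork, Cohort]:
    """Full synthetic study: stations, measurements, cohort, outcomes.

    Outcomes are driven by the *true* (pre-missingness) pollutant field at
    each patient's location on the lagged day, so the downstream pipeline
    (imputation + interpolation) is recovering a real signal.
    """
    network = generate_stations(config)
    network = simulate_measurements(network, config)
    cohort = generate_cohort(config)
    rng_out = _seed_streams(config.seed, 4)[3]
    # the deterministic spatial field at the patient's address is the true
    # exposure signal; station noise/missingness only obscure its recovery
    df = cohort.patients
    expo = pd.DataFrame(index=df["id"])
    for name, fld in config.fields.items():
        expo[name] = fld.spatial(df["lon"].to_numpy(), df["lat"].to_numpy())
    cohort = assign_outcomes(
        cohort, expo, model=config.outcome, seed=int(rng_out.integers(2**31))
    )
    return network, cohort


# ---------------------------------------------------------------------------
# canonical experiment conditions

def separable_config(seed: int = 0, n_patients: int = 2000) -> SimulationConfig:
    """Strong-signal study for the parameter-recovery experiment.

    Two population centres, one sitting inside the pollutant plumes, with a
    dense station network and near-noiseless measurements; large pollutant
    effects (SO2 strongest) make the outcome an essentially deterministic
    function of exposure with a clear margin between the classes, so a
    correctly working pipeline must recover them.
    """
    fields = {
        "NO2": PollutantField(baseline=25.0, plumes=(Plume(28.25, -25.75, 30.0, 0.12),),
                              noise_sd=0.01, rho=0.0),
        "SO2": PollutantField(baseline=15.0, plumes=(Plume(28.25, -25.75, 40.0, 0.12),),
                              noise_sd=0.01, rho=0.0),
        "PM10": PollutantField(baseline=45.0, plumes=(Plume(28.25, -25.75, 35.0, 0.12),),
                               noise_sd=0.01, rho=0.0),
    }
    outcome = OutcomeModel(
        intercept=0.0,
        pollutants={"SO2": 12.0, "PM10": 6.0, "NO2": 4.0},
        age=0.5,
        gender_male=0.2,
    )
    return SimulationConfig(
        n_stations=36,
        n_patients=n_patients,
        n_days=30,
        population_centers=((28.25, -25.75, 0.05, 0.5), (27.95, -26.25, 0.05, 0.5)),
        fields=fields,
        outcome=outcome,
        missing_rate=0.05,
        seed=seed,
    )


def null_config(seed: int = 0, n_patients: int = 800) -> SimulationConfig:
    """No-signal study: every outcome coefficient zero and balanced classes,
    so held-out accuracy should hover around one half. Sized for repeated
    seeded runs."""
    outcome = OutcomeModel(intercept=0.0, pollutants={"SO2": 0.0, "PM10": 0.0, "NO2": 0.0},
                           age=0.0, gender_male=0.0)
    return SimulationConfig(
        n_stations=6,
        n_patients=n_patients,
        n_days=60,
        outcome=outcome,
        missing_rate=0.1,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# file output

def write_study(network: StationNetwork, cohort: Cohort, out_dir) -> dict:
    """Write stations.csv, measurements.csv and cohort.csv (ISO dates, empty
    field = missing value); returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "stations": out / "stations.csv",
        "measurements": out / "measurements.csv",
        "cohort": out / "cohort.csv",
    }
    network.stations.to_csv(paths["stations"], index=False, float_format="%.10g")
    meas = network.measurements.copy()
    meas["date"] = pd.to_datetime(meas["date"]).dt.strftime("%Y-%m-%d")
    meas.to_csv(paths["measurements"], index=False, float_format="%.10g")
    pat = cohort.patients.copy()
    pat["date"] = pd.to_datetime(pat["date"]).dt.strftime("%Y-%m-%d")
    pat.to_csv(paths["cohort"], index=False, float_format="%.10g")
    return {k: str(v) for k, v in paths.items()}
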