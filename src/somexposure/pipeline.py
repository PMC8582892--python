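"""Stage orchestration: run the whole analysis from a single configuration,
writing every artifact with a manifest so re-runs are verifiably identical.

Stages run in order: simulate (optional) -> impute -> expose -> preprocess ->
train -> cluster -> evaluate. Either the simulate block or three input CSV
paths (stations, measurements, cohort) must be given, never both. All
randomness derives from the global seed; a re-run with the same config
produces byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import InvalidConfigError
from .evaluation import confusion_metrics, node_quality_summary
from .exposure import build_exposure_profiles
from .map_analysis import code_plot_data, u_matrix, ward_cluster_codebooks
from .preprocessing import build_feature_table, impute_measurements
from .simulate import (
    OutcomeModel,
    Plume,
    PollutantField,
    SimulationConfig,
    StationNetwork,
    Cohort,
    simulate_study,
    write_study,
)
from .som import SupervisedKohonenSOM, KohonenSOM, TrainingConfig

REQUIRED_MEASUREMENT_COLUMNS = ("station_id", "date", "pollutant", "value")
REQUIRED_STATION_COLUMNS = ("station_id", "lon", "lat")
REQUIRED_COHORT_COLUMNS = (
    "id", "age", "age_category", "gender", "race", "lon", "lat", "date",
)

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    out_dir: Path
    seed: int = 0
    simulate: SimulationConfig | None = None
    stations_csv: Path | None = None
    measurements_csv: Path | None = None
    cohort_csv: Path | None = None
    pollutants: list[str] | None = None
    lag: int = 2
    power: float = 2.0
    mice_sweeps: int = 10
    grid: tuple[int, int] = (8, 8)
    topology: str = "rectangular"
    supervised: bool = True
    training: TrainingConfig = dc_field(default_factory=TrainingConfig)
    n_clusters: int = 4
    threshold: float = 0.05
    train_fraction: float = 0.7

    def __post_init__(self) -> None:
        paths = [self.stations_csv, self.measurements_csv, self.cohort_csv]
        have_paths = all(p is not None for p in paths)
        some_paths = any(p is not None for p in paths)
        if self.simulate is not None and some_paths:
            raise InvalidConfigError(
                "give either a simulate block or input CSV paths, not both"
            )
        if self.simulate is None and not have_paths:
            raise InvalidConfigError(
                "either a simulate block or all three input CSV paths are required"
            )
        if not 0 < self.train_fraction < 1:
            raise InvalidConfigError("train_fraction must be in (0, 1)")
        if self.lag < 0:
            raise InvalidConfigError("lag must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, doc: dict, base_dir: Path = Path(".")) -> "RunConfig":
        doc = dict(doc)
        seed = int(doc.pop("seed", 0))
        sim = None
        if "simulate" in doc:
            sim_doc = dict(doc.pop("simulate") or {})
            fields = {}
            for name, f in (sim_doc.pop("fields", None) or {}).items():
                plumes = tuple(Plume(**p) for p in f.pop("plumes", []))
                fields[name] = PollutantField(plumes=plumes, **f)
            outcome = sim_doc.pop("outcome", None)
            kwargs = dict(sim_doc)
            if fields:
                kwargs["fields"] = fields
            if outcome:
                race = outcome.pop("race", None)
                om = OutcomeModel(**outcome)
                if race:
                    om = OutcomeModel(
                        intercept=om.intercept, pollutants=om.pollutants,
                        age=om.age, gender_male=om.gender_male,
                        race={int(k): v for k, v in race.items()},
                    )
                kwargs["outcome"] = om
            if "region" in kwargs:
                kwargs["region"] = tuple(kwargs["region"])
            sim = SimulationConfig(seed=seed, **kwargs)
        training = TrainingConfig(seed=seed, **(doc.pop("training", None) or {}))
        grid = doc.pop("grid", (8, 8))
        if isinstance(grid, str):
            rows, cols = grid.lower().split("x")
            grid = (int(rows), int(cols))
        inputs = doc.pop("inputs", None) or {}

        def _path(key):
            p = inputs.get(key)
            return None if p is None else (base_dir / p)

        return cls(
            out_dir=Path(doc.pop("out_dir", "out")),
            seed=seed,
            simulate=sim,
            stations_csv=_path("stations"),
            measurements_csv=_path("measurements"),
            cohort_csv=_path("cohort"),
            grid=tuple(grid),
            training=training,
            **doc,
        )


# ---------------------------------------------------------------------------
# input loading and validation

def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidConfigError(f"{what} is missing column(s): {missing}")


def load_inputs(config: RunConfig) -> tuple[StationNetwork, Cohort]:
    """Read and validate the three input CSVs (fail fast, before computing)."""
    stations = pd.read_csv(config.stations_csv)
    _require_columns(stations, REQUIRED_STATION_COLUMNS, "stations.csv")
    measurements = pd.read_csv(config.measurements_csv)
    _require_columns(measurements, REQUIRED_MEASUREMENT_COLUMNS, "measurements.csv")
    cohort = pd.read_csv(config.cohort_csv)
    _require_columns(cohort, REQUIRED_COHORT_COLUMNS, "cohort.csv")
    measurements["date"] = pd.to_datetime(measurements["date"])
    cohort["date"] = pd.to_datetime(cohort["date"])
    network = StationNetwork(stations=stations, measurements=measurements)
    network.validate()
    co = Cohort(patients=cohort)
    co.validate()
    return network, co


# ---------------------------------------------------------------------------
# manifest

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out_dir: Path, stage: str, inputs: list[Path], seed: int) -> None:
    manifest_path = out_dir / "manifest.json"
    manifest = {}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    manifest[stage] = {
        "inputs": {p.name: _sha256(p) for p in inputs if p.exists()},
        "seed": seed,
        "version": __version__,
    }
    manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=1))


def _write_csv(df: pd.DataFrame, path: Path, index=False) -> None:
    df.to_csv(path, index=index, float_format=_FLOAT_FMT, lineterminator="\n")


# ---------------------------------------------------------------------------
# pipeline

def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the final report dict.

    Artifacts: stations/measurements/cohort CSVs (when simulating),
    measurements_imputed.csv, exposures.csv, exclusions.csv, features.csv,
    scaler.json, model.json, clusters.csv, umatrix.csv, codeplot.csv and
    report.json, plus a manifest.json of input hashes per stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    if config.simulate is not None:
        network, cohort = simulate_study(config.simulate)
        write_study(network, cohort, out)
        _write_manifest(out, "simulate", [], seed)
        pollutants = config.pollutants or list(config.simulate.pollutants)
        lag = config.simulate.lag
    else:
        network, cohort = load_inputs(config)
        pollutants = config.pollutants or sorted(
            network.measurements["pollutant"].unique()
        )
        lag = config.lag

    meas = network.measurements
    if meas["value"].isna().any():
        meas = impute_measurements(meas, n_sweeps=config.mice_sweeps, seed=seed)
    imp = meas.copy()
    imp["date"] = pd.to_datetime(imp["date"]).dt.strftime("%Y-%m-%d")
    _write_csv(imp, out / "measurements_imputed.csv")

    prof = build_exposure_profiles(
        cohort.patients, network.stations, meas,
        pollutants=pollutants, lag=lag, power=config.power,
    )
    _write_csv(prof.profiles.reset_index(), out / "exposures.csv")
    _write_csv(prof.exclusions, out / "exclusions.csv")
    _write_manifest(out, "expose", [out / "measurements_imputed.csv"], seed)

    ft = build_feature_table(prof.profiles, cohort.patients, pollutants=pollutants)
    _write_csv(ft.data.reset_index(), out / "features.csv")
    (out / "scaler.json").write_text(ft.scaler.to_json())
    _write_manifest(out, "preprocess", [out / "exposures.csv"], seed)

    X = ft.data
    supervised = config.supervised and ft.outcome is not None
    training = TrainingConfig(**{**config.training.to_dict(), "seed": seed})
    if supervised:
        y = ft.outcome.to_numpy()
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(X))
        n_train = int(round(config.train_fraction * len(X)))
        train_idx, test_idx = order[:n_train], order[n_train:]
        model = SupervisedKohonenSOM(
            X.iloc[train_idx], y[train_idx],
            grid=config.grid, topology=config.topology,
        )
    else:
        train_idx = np.arange(len(X))
        test_idx = np.array([], dtype=int)
        model = KohonenSOM(X, grid=config.grid, topology=config.topology)
    res = model.fit(training)
    res.save(out / "model.json")
    _write_manifest(out, "train", [out / "features.csv"], seed)

    clustering = ward_cluster_codebooks(res.codebooks, config.n_clusters)
    _write_csv(
        pd.DataFrame({"node": np.arange(res.grid.n_nodes) + 1,
                      "cluster": clustering.labels}),
        out / "clusters.csv",
    )
    umx = u_matrix(res.grid, res.codebooks)
    _write_csv(
        pd.DataFrame({"node": np.arange(res.grid.n_nodes) + 1, "u_value": umx}),
        out / "umatrix.csv",
    )
    _write_csv(code_plot_data(res.codebooks, res.feature_names), out / "codeplot.csv")
    _write_manifest(out, "cluster", [out / "model.json"], seed)

    qe = res.quantization_error()
    nq = node_quality_summary(res, threshold=config.threshold)
    report = {
        "n_patients": int(len(X)),
        "n_excluded": int(len(cohort.patients) - len(X)),
        "n_train": int(len(train_idx)),
        "n_test": int(len(test_idx)),
        "grid": f"{res.grid.n_rows}x{res.grid.n_cols}",
        "supervised": bool(supervised),
        "epochs_run": res.n_epochs_run,
        "quantization_error_mean": qe.mean,
        "quantization_error_sum": qe.total,
        "topographic_error": res.topographic_error(),
        "node_quality_threshold": config.threshold,
        "nodes_within_threshold": nq.n_within,
        "nodes_empty": nq.n_empty,
        "n_nodes": int(res.grid.n_nodes),
    }
    if supervised:
        report["prevalence"] = float(np.mean(ft.outcome))
        report["insample"] = confusion_metrics(y[train_idx], res.predict())
        if len(test_idx):
            report["heldout"] = confusion_metrics(
                y[test_idx], res.predict(X.iloc[test_idx])
            )
    (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    _write_manifest(out, "evaluate", [out / "model.json"], seed)
    return report
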