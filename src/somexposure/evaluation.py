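"""Classification and map-quality metrics, plus the end-to-end
parameter-recovery experiment on synthetic data.

The recovery experiment is the package's acceptance surface: simulate a
study whose outcome truly depends on lagged exposures and demographics, run
the full pipeline (impute, interpolate, encode, train a supervised map), and
check that held-out classification recovers the planted signal — and that a
no-signal configuration does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import SomexposureError
from .preprocessing import build_feature_table, impute_measurements
from .simulate import SimulationConfig, simulate_study
from .exposure import build_exposure_profiles
from .som import SupervisedKohonenSOM, TrainingConfig

__all__ = [
    "confusion_metrics",
    "node_quality_summary",
    "NodeQuality",
    "MapReport",
    "recovery_experiment",
]


def confusion_metrics(y_true, y_pred) -> dict:
    """Accuracy, sensitivity and specificity with the raw confusion counts.

    Class 1 (asthma) is the positive class. A rate whose denominator is zero
    is reported as NaN (undefined), never coerced to 0.
    """
    yt = np.asarray(y_true).astype(int)
    yp = np.asarray(y_pred).astype(int)
    if yt.size == 0:
        raise SomexposureError("confusion metrics undefined on empty input")
    if yt.shape != yp.shape:
        raise SomexposureError("y_true and y_pred must have equal length")
    if not (np.isin(yt, (0, 1)).all() and np.isin(yp, (0, 1)).all()):
        raise SomexposureError("labels must be binary")
    tp = int(np.sum((yt == 1) & (yp == 1)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    total = tp + fn + tn + fp

    def _rate(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "accuracy": _rate(tp + tn, total),
        "sensitivity": _rate(tp, tp + fn),
        "specificity": _rate(tn, tn + fp),
    }


@dataclass
class NodeQuality:
    """Per-node representation quality of a trained map.

    distances : per-node mean Euclidean distance of the patterns mapped to
        that node from its codebook (NaN for empty nodes).
    n_within : occupied nodes whose mean distance <= threshold.
    n_empty : nodes with no patterns mapped to them.
    """

    distances: np.ndarray
    threshold: float
    n_within: int
    n_empty: int

    @property
    def n_nodes(self) -> int:
        return self.distances.size


def node_quality_summary(results, patterns=None, threshold: float = 0.05) -> NodeQuality:
    """Mean object-to-codebook distance per node, and the count of occupied
    nodes at or under the quality threshold.

    Empty nodes are excluded from the within count and reported separately,
    so n_within + (occupied beyond threshold) + n_empty = total nodes.
    """
    X = results._patterns(patterns)
    bmus = results.bmu(X)
    n_nodes = results.grid.n_nodes
    dists = np.linalg.norm(X - results.codebooks[bmus], axis=1)
    per_node = np.full(n_nodes, np.nan)
    for node in range(n_nodes):
        mask = bmus == node
        if mask.any():
            per_node[node] = float(np.mean(dists[mask]))
    occupied = ~np.isnan(per_node)
    n_within = int(np.sum(per_node[occupied] <= threshold))
    return NodeQuality(
        distances=per_node, threshold=threshold,
        n_within=n_within, n_empty=int(n_nodes - occupied.sum()),
    )


@dataclass
class MapReport:
    """Everything the evaluation stage reports about one trained map."""

    qe_mean: float
    qe_sum: float
    topographic_error: float
    node_quality_threshold: float
    nodes_within_threshold: int
    nodes_empty: int
    n_nodes: int
    insample: dict
    heldout: dict
    n_train: int
    n_test: int
    n_excluded: int
    prevalence: float
    so2_contrast: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "quantization_error_mean": self.qe_mean,
            "quantization_error_sum": self.qe_sum,
            "topographic_error": self.topographic_error,
            "node_quality_threshold": self.node_quality_threshold,
            "nodes_within_threshold": self.nodes_within_threshold,
            "nodes_empty": self.nodes_empty,
            "n_nodes": self.n_nodes,
            "insample": self.insample,
            "heldout": self.heldout,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "n_excluded": self.n_excluded,
            "prevalence": self.prevalence,
            "so2_contrast": self.so2_contrast,
            **self.extra,
        }


def recovery_experiment(
    sim_config: SimulationConfig,
    grid=(8, 8),
    training: TrainingConfig | None = None,
    threshold: float = 0.05,
    train_fraction: float = 0.7,
    seed: int | None = None,
) -> MapReport:
    """Simulate -> impute -> interpolate -> encode -> train -> evaluate.

    Trains a supervised map on a seeded 70/30 split, reports in-sample and
    held-out confusion metrics and map quality, and — when the generating
    SO2 effect is positive — the contrast between the mean (scaled) SO2
    codebook component of majority-asthma and majority-non-asthma nodes,
    which should be positive if the map recovered the planted effect.
    """
    seed = sim_config.seed if seed is None else seed
    training = training or TrainingConfig(seed=seed)
    network, cohort = simulate_study(sim_config)

    meas = network.measurements
    if meas["value"].isna().any():
        meas = impute_measurements(meas, seed=seed)
    prof = build_exposure_profiles(
        cohort.patients, network.stations, meas,
        pollutants=list(sim_config.pollutants), lag=sim_config.lag,
    )
    ft = build_feature_table(prof.profiles, cohort.patients,
                             pollutants=list(sim_config.pollutants))
    X = ft.data
    y = ft.outcome.to_numpy()

    rng = np.random.default_rng(seed)
    n = len(X)
    order = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    train_idx, test_idx = order[:n_train], order[n_train:]
    # guard: both classes must be present in the training split
    if np.unique(y[train_idx]).size < 2:
        raise SomexposureError("training split contains a single class")

    model = SupervisedKohonenSOM(X.iloc[train_idx], y[train_idx], grid=grid)
    res = model.fit(training)

    qe = res.quantization_error()
    nq = node_quality_summary(res, threshold=threshold)
    insample = confusion_metrics(y[train_idx], res.predict())
    heldout = confusion_metrics(y[test_idx], res.predict(X.iloc[test_idx]))

    so2_contrast = None
    if "SO2" in ft.data.columns and sim_config.outcome.pollutants.get("SO2", 0) > 0:
        so2_col = list(X.columns).index("SO2")
        node_class = np.argmax(res.y_codebooks, axis=1)
        maj1 = res.codebooks[node_class == 1, so2_col]
        maj0 = res.codebooks[node_class == 0, so2_col]
        if maj1.size and maj0.size:
            so2_contrast = float(maj1.mean() - maj0.mean())

    return MapReport(
        qe_mean=qe.mean,
        qe_sum=qe.total,
        topographic_error=res.topographic_error(),
        node_quality_threshold=threshold,
        nodes_within_threshold=nq.n_within,
        nodes_empty=nq.n_empty,
        n_nodes=res.grid.n_nodes,
        insample=insample,
        heldout=heldout,
        n_train=int(n_train),
        n_test=int(n - n_train),
        n_excluded=int(sim_config.n_patients - n),
        prevalence=float(np.mean(y)),
        so2_contrast=so2_contrast,
    )
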