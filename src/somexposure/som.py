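"""Kohonen self-organizing maps: competitive training, schedules, metrics.

The map is a lattice of nodes, each holding a codebook (prototype) vector
``w_kj`` in the input space. Training presents one scaled input pattern at a
time, finds the best-matching unit (BMU) by Euclidean distance, and moves
every codebook toward the pattern by the neighbourhood-weighted step

    w(t+1) = w(t) + h(t) [z_p - w(t)],

where ``h`` is a Gaussian in grid distance around the BMU, scaled by an
exponentially decaying learning rate eta(t) = eta0 * exp(-t / tau2) and with
an exponentially shrinking radius sigma(t) = sigma0 * exp(-t / tau1).

The supervised variant carries a second codebook layer over the one-hot-coded
binary outcome. During training the BMU minimizes a convex combination
``x_weight * d_X^2 + (1 - x_weight) * d_Y^2`` of distances in the two layers;
at prediction time the BMU is found on the X layer alone (labels are unknown
for new patients) and the class is the argmax of that node's Y codebook.

The public surface follows the statsmodels convention: a model object built
from data (`KohonenSOM`, `SupervisedKohonenSOM`) whose ``fit`` returns a
`SOMResults` carrying the trained codebooks, training history, quality
metrics and a ``summary()`` table. The module-level functions underneath
(`find_bmu`, `learning_rate`, `neighborhood_value`, `update_codebooks`,
`quantization_error`, `topographic_error`) are the individually testable
primitives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateLabelsError,
    InvalidConfigError,
    NoYLayerError,
    SomexposureError,
)
from .grid import SOMGrid

__all__ = [
    "TrainingConfig",
    "KohonenSOM",
    "SupervisedKohonenSOM",
    "SOMResults",
    "QuantizationError",
    "initialize_codebooks",
    "find_bmu",
    "learning_rate",
    "neighborhood_value",
    "update_codebooks",
    "quantization_error",
    "topographic_error",
]


# ---------------------------------------------------------------------------
# configuration

@dataclass
class TrainingConfig:
    """Hyper-parameters of online SOM training.

    eta0 : initial learning rate, in (0, 1].
    tau2 : learning-rate decay constant in iterations (one iteration = one
        pattern presentation); default n_epochs * n_patterns / 4.
    sigma0 : initial neighbourhood radius in grid units; default max(K, J)/2.
    tau1 : radius decay constant; default total_iterations / log(sigma0),
        so the radius reaches ~1 grid unit by the end of training.
    n_epochs : maximum number of passes over the data.
    stop_tol : stop when the relative quantization-error improvement over an
        epoch falls below this.
    x_weight : weight of the X-layer squared distance in the supervised BMU
        search, in (0, 1]; 1 reduces to unsupervised X-layer training.
    seed : seeds initialization and the per-epoch shuffle.
    """

    eta0: float = 0.05
    tau2: float | None = None
    sigma0: float | None = None
    tau1: float | None = None
    n_epochs: int = 100
    stop_tol: float = 1e-5
    x_weight: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.eta0 <= 1.0:
            raise InvalidConfigError(f"eta0 must be in (0, 1], got {self.eta0}")
        if self.tau2 is not None and self.tau2 <= 0:
            raise InvalidConfigError("tau2 must be positive")
        if self.tau1 is not None and self.tau1 <= 0:
            raise InvalidConfigError("tau1 must be positive")
        if self.sigma0 is not None and self.sigma0 < 0:
            raise InvalidConfigError("sigma0 must be >= 0")
        if self.n_epochs < 1:
            raise InvalidConfigError("n_epochs must be >= 1")
        if not 0.0 < self.x_weight <= 1.0:
            raise InvalidConfigError(f"x_weight must be in (0, 1], got {self.x_weight}")

    def resolved(self, grid: SOMGrid, n_patterns: int) -> "TrainingConfig":
        """Fill the data-dependent defaults for a concrete grid and dataset."""
        total = self.n_epochs * n_patterns
        sigma0 = self.sigma0
        if sigma0 is None:
            sigma0 = max(grid.n_rows, grid.n_cols) / 2.0
        tau1 = self.tau1
        if tau1 is None:
            tau1 = total / np.log(sigma0) if sigma0 > 1.0 else float(total)
        tau2 = self.tau2
        if tau2 is None:
            tau2 = total / 4.0
        return TrainingConfig(
            eta0=self.eta0, tau2=tau2, sigma0=sigma0, tau1=tau1,
            n_epochs=self.n_epochs, stop_tol=self.stop_tol,
            x_weight=self.x_weight, seed=self.seed,
        )

    def to_dict(self) -> dict:
        return {
            "eta0": self.eta0, "tau2": self.tau2, "sigma0": self.sigma0,
            "tau1": self.tau1, "n_epochs": self.n_epochs,
            "stop_tol": self.stop_tol, "x_weight": self.x_weight,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# primitives

def initialize_codebooks(
    grid: SOMGrid,
    data_min: np.ndarray,
    data_max: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random codebook initialization within each feature's observed range.

    Each component of each node's codebook is drawn uniformly in the
    corresponding feature's [min, max]; a degenerate range collapses the
    draw to that single value exactly.
    """
    data_min = np.asarray(data_min, dtype=float)
    data_max = np.asarray(data_max, dtype=float)
    if data_min.ndim != 1 or data_min.shape != data_max.shape:
        raise InvalidConfigError("data_min and data_max must be 1-D and congruent")
    if data_min.size == 0:
        raise InvalidConfigError("input dimension must be positive")
    if not (np.all(np.isfinite(data_min)) and np.all(np.isfinite(data_max))):
        raise InvalidConfigError("feature ranges must be finite")
    u = rng.random((grid.n_nodes, data_min.size))
    return data_min + u * (data_max - data_min)


def find_bmu(codebooks: np.ndarray, pattern: np.ndarray) -> int:
    """Linear index of the node whose codebook is Euclidean-nearest to the
    pattern; ties break toward the lowest linear index."""
    diff = codebooks - pattern
    return int(np.argmin(np.einsum("ij,ij->i", diff, diff)))


def learning_rate(t: float, eta0: float, tau2: float) -> float:
    """eta(t) = eta0 * exp(-t / tau2); strictly decreasing in t."""
    return eta0 * float(np.exp(-t / tau2))


def neighborhood_value(
    grid: SOMGrid,
    bmu: int,
    node: int,
    t: float,
    *,
    sigma0: float,
    tau1: float,
    eta0: float,
    tau2: float,
) -> float:
    """Gaussian neighbourhood weight h(t) of `node` around the BMU.

    h = eta(t) * exp(-d_grid(bmu, node)^2 / (2 sigma(t)^2)) with
    sigma(t) = sigma0 * exp(-t / tau1). At the BMU itself h = eta(t). When
    sigma(t) underflows to zero the neighbourhood collapses to a BMU-only
    update (by design, not an error).
    """
    eta = learning_rate(t, eta0, tau2)
    if node == bmu:
        return eta
    sigma = sigma0 * float(np.exp(-t / tau1))
    if sigma <= 0.0:
        return 0.0
    d2 = grid.squared_distances_from(bmu)[node]
    return eta * float(np.exp(-d2 / (2.0 * sigma * sigma)))


def _neighborhood_row(
    grid_sq_dist_row: np.ndarray, eta: float, sigma: float, bmu: int
) -> np.ndarray:
    """Vectorized h over all nodes for one pattern presentation."""
    if sigma <= 0.0:
        h = np.zeros_like(grid_sq_dist_row)
        h[bmu] = eta
        return h
    return eta * np.exp(-grid_sq_dist_row / (2.0 * sigma * sigma))


def update_codebooks(codebooks: np.ndarray, pattern: np.ndarray, h: np.ndarray) -> None:
    """In-place step w <- w + h (z - w); h = 1 lands on the pattern, h = 0
    leaves the codebook untouched."""
    codebooks += h[:, None] * (pattern - codebooks)


@dataclass(frozen=True)
class QuantizationError:
    """Quantization error of a map over a pattern set.

    ``mean`` (headline) is the average squared Euclidean distance of each
    pattern to its BMU codebook; ``total`` is the un-normalized sum over
    patterns, retained because the aggregate and per-object readings of the
    stopping criterion differ only by this normalization.
    """

    mean: float
    total: float
    n_patterns: int


def _bmu_indices(codebooks: np.ndarray, patterns: np.ndarray) -> np.ndarray:
    # pairwise squared distances, patterns x nodes; argmin ties -> lowest index
    d2 = (
        np.einsum("ij,ij->i", patterns, patterns)[:, None]
        - 2.0 * patterns @ codebooks.T
        + np.einsum("ij,ij->i", codebooks, codebooks)[None, :]
    )
    return np.argmin(d2, axis=1)


def quantization_error(codebooks: np.ndarray, patterns: np.ndarray) -> QuantizationError:
    """Mean (and total) squared distance of patterns to their BMU codebooks."""
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    if patterns.shape[0] == 0:
        raise SomexposureError("quantization error is undefined for an empty pattern set")
    bmus = _bmu_indices(codebooks, patterns)
    sq = np.einsum("ij,ij->i", patterns - codebooks[bmus], patterns - codebooks[bmus])
    total = float(np.sum(sq))
    return QuantizationError(mean=total / patterns.shape[0], total=total,
                             n_patterns=patterns.shape[0])


def topographic_error(grid: SOMGrid, codebooks: np.ndarray, patterns: np.ndarray) -> float:
    """Fraction of patterns whose best and second-best matching nodes are not
    direct lattice neighbours."""
    if grid.n_nodes < 2:
        raise SomexposureError("topographic error is undefined on a single-node map")
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    if patterns.shape[0] == 0:
        raise SomexposureError("topographic error is undefined for an empty pattern set")
    d2 = (
        np.einsum("ij,ij->i", patterns, patterns)[:, None]
        - 2.0 * patterns @ codebooks.T
        + np.einsum("ij,ij->i", codebooks, codebooks)[None, :]
    )
    order = np.argsort(d2, axis=1, kind="stable")
    errors = sum(
        0 if grid.are_adjacent(int(first), int(second)) else 1
        for first, second in order[:, :2]
    )
    return errors / patterns.shape[0]


# ---------------------------------------------------------------------------
# models

class KohonenSOM:
    """Unsupervised self-organizing map model.

    Parameters
    ----------
    data : array-like or DataFrame, shape (n_patterns, n_features)
        Scaled input patterns (rows). Feature names are taken from DataFrame
        columns when available.
    grid : tuple (rows, cols) or SOMGrid
    topology : {"rectangular", "hexagonal"}, ignored if `grid` is a SOMGrid.
    """

    def __init__(self, data, grid=(8, 8), topology: str = "rectangular"):
        if isinstance(data, pd.DataFrame):
            self.feature_names = list(data.columns)
            X = data.to_numpy(dtype=float)
        else:
            X = np.asarray(data, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            self.feature_names = [f"x{i}" for i in range(X.shape[1])]
        if X.ndim != 2 or X.shape[0] == 0 or X.shape[1] == 0:
            raise InvalidConfigError("data must be a non-empty 2-D array")
        if not np.all(np.isfinite(X)):
            raise InvalidConfigError("input patterns must be finite (impute first)")
        self.data = X
        self.grid = grid if isinstance(grid, SOMGrid) else SOMGrid(*grid, topology=topology)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, columns: Sequence[str] | None = None,
                       grid=(8, 8), topology: str = "rectangular") -> "KohonenSOM":
        cols = list(columns) if columns is not None else list(df.columns)
        return cls(df[cols], grid=grid, topology=topology)

    # -- training -----------------------------------------------------------

    def fit(self, config: TrainingConfig | None = None, **kwargs) -> "SOMResults":
        """Train by online competitive learning; returns a `SOMResults`.

        Keyword arguments override fields of `config` (or of a default
        `TrainingConfig` when none is given).
        """
        if config is None:
            config = TrainingConfig(**kwargs)
        elif kwargs:
            config = TrainingConfig(**{**config.to_dict(), **kwargs})
        cfg = config.resolved(self.grid, self.data.shape[0])
        return self._train(cfg, y=None)

    def _labels_onehot(self):
        return None

    def _train(self, cfg: TrainingConfig, y: np.ndarray | None) -> "SOMResults":
        X = self.data
        n, dim = X.shape
        grid = self.grid
        ss = np.random.SeedSequence(cfg.seed)
        ss_init_x, ss_init_y, ss_shuffle = ss.spawn(3)
        rng_x = np.random.default_rng(ss_init_x)
        rng_y = np.random.default_rng(ss_init_y)
        rng_shuffle = np.random.default_rng(ss_shuffle)

        W = initialize_codebooks(grid, X.min(axis=0), X.max(axis=0), rng_x)
        supervised = y is not None
        if supervised:
            Y_onehot = np.eye(2)[y]
            u = rng_y.random(grid.n_nodes)
            WY = np.column_stack([u, 1.0 - u])  # rows on the simplex
        else:
            Y_onehot = None
            WY = None

        xw = cfg.x_weight
        history: list[float] = []
        t = 0
        prev_qe = None
        for _epoch in range(cfg.n_epochs):
            order = rng_shuffle.permutation(n)
            for p in order:
                z = X[p]
                eta = cfg.eta0 * np.exp(-t / cfg.tau2)
                sigma = cfg.sigma0 * np.exp(-t / cfg.tau1)
                diff = W - z
                d2x = np.einsum("ij,ij->i", diff, diff)
                if supervised and xw < 1.0:
                    diffy = WY - Y_onehot[p]
                    d2 = xw * d2x + (1.0 - xw) * np.einsum("ij,ij->i", diffy, diffy)
                else:
                    d2 = d2x
                bmu = int(np.argmin(d2))
                h = _neighborhood_row(grid.squared_distances_from(bmu), eta, sigma, bmu)
                W += h[:, None] * (z - W)
                if supervised:
                    WY += h[:, None] * (Y_onehot[p] - WY)
                t += 1
            qe = quantization_error(W, X).mean
            history.append(qe)
            if cfg.stop_tol > 0 and prev_qe is not None and prev_qe > 0:
                if (prev_qe - qe) / prev_qe < cfg.stop_tol:
                    break
            prev_qe = qe

        return SOMResults(
            model=self, grid=grid, codebooks=W, y_codebooks=WY,
            config=cfg, qe_history=history, n_iterations=t,
        )


class SupervisedKohonenSOM(KohonenSOM):
    """Supervised SOM with a second codebook layer over the binary outcome.

    `labels` must contain both classes; they are one-hot coded internally and
    the Y layer is trained by the same neighbourhood update as the X layer.
    """

    def __init__(self, data, labels, grid=(8, 8), topology: str = "rectangular"):
        super().__init__(data, grid=grid, topology=topology)
        y = np.asarray(labels).astype(int)
        if y.shape != (self.data.shape[0],):
            raise InvalidConfigError("labels must be one per pattern")
        if not np.isin(y, (0, 1)).all():
            raise InvalidConfigError("labels must be binary (0/1)")
        if np.unique(y).size < 2:
            raise DegenerateLabelsError(
                "supervised training requires both outcome classes present"
            )
        self.labels = y

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str,
                       columns: Sequence[str] | None = None,
                       grid=(8, 8), topology: str = "rectangular"):
        cols = list(columns) if columns is not None else [
            c for c in df.columns if c != label_column
        ]
        return cls(df[cols], df[label_column].to_numpy(), grid=grid, topology=topology)

    def fit(self, config: TrainingConfig | None = None, **kwargs) -> "SOMResults":
        if config is None:
            config = TrainingConfig(**kwargs)
        elif kwargs:
            config = TrainingConfig(**{**config.to_dict(), **kwargs})
        cfg = config.resolved(self.grid, self.data.shape[0])
        return self._train(cfg, y=self.labels)


# ---------------------------------------------------------------------------
# results

@dataclass
class SOMResults:
    """Trained map: codebooks, training history, and quality metrics.

    Node ordering everywhere is the map's reading order — linear index 0 is
    the bottom-left node, increasing left to right then bottom to top.
    """

    model: KohonenSOM
    grid: SOMGrid
    codebooks: np.ndarray
    y_codebooks: np.ndarray | None
    config: TrainingConfig
    qe_history: list[float] = field(default_factory=list)
    n_iterations: int = 0

    @property
    def n_epochs_run(self) -> int:
        return len(self.qe_history)

    @property
    def feature_names(self) -> list[str]:
        return self.model.feature_names

    def bmu(self, patterns=None) -> np.ndarray:
        """BMU linear index for each pattern (default: the training data)."""
        X = self._patterns(patterns)
        return _bmu_indices(self.codebooks, X)

    def quantization_error(self, patterns=None) -> QuantizationError:
        return quantization_error(self.codebooks, self._patterns(patterns))

    def topographic_error(self, patterns=None) -> float:
        return topographic_error(self.grid, self.codebooks, self._patterns(patterns))

    def predict(self, patterns=None) -> np.ndarray:
        """Class labels from the Y layer at each pattern's X-layer BMU.

        Prediction never looks at a pattern's label: the BMU is found on the
        X codebooks alone. A node with a tied Y codebook predicts class 0.
        """
        if self.y_codebooks is None:
            raise NoYLayerError("model was trained unsupervised; no outcome layer")
        bmus = self.bmu(patterns)
        # argmax ties -> first index -> class 0
        return np.argmax(self.y_codebooks[bmus], axis=1)

    def _patterns(self, patterns) -> np.ndarray:
        if patterns is None:
            return self.model.data
        if isinstance(patterns, pd.DataFrame):
            patterns = patterns[self.feature_names].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(patterns, dtype=float))
        if X.shape[1] != self.codebooks.shape[1]:
            raise InvalidConfigError(
                f"pattern dimension {X.shape[1]} != codebook dimension "
                f"{self.codebooks.shape[1]}"
            )
        return X

    # -- map analysis (delegates) ------------------------------------------

    def ward_clusters(self, n_clusters: int, squared: bool = True) -> np.ndarray:
        from .map_analysis import ward_cluster_codebooks
        return ward_cluster_codebooks(self.codebooks, n_clusters, squared=squared).labels

    def u_matrix(self) -> np.ndarray:
        from .map_analysis import u_matrix
        return u_matrix(self.grid, self.codebooks)

    def code_plot_data(self) -> pd.DataFrame:
        from .map_analysis import code_plot_data
        return code_plot_data(self.codebooks, self.feature_names)

    def node_quality(self, patterns=None, threshold: float = 0.05):
        from .evaluation import node_quality_summary
        return node_quality_summary(self, self._patterns(patterns), threshold=threshold)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        qe = self.quantization_error()
        te = self.topographic_error() if self.grid.n_nodes > 1 else float("nan")
        lines = [
            "Kohonen Self-Organizing Map Results",
            "=" * 55,
            f"{'Map':<28}{self.grid.n_rows} x {self.grid.n_cols} "
            f"({self.grid.topology})",
            f"{'Layers':<28}{'X + outcome (supervised)' if self.y_codebooks is not None else 'X only (unsupervised)'}",
            f"{'Input dimension':<28}{self.codebooks.shape[1]}",
            f"{'Training patterns':<28}{self.model.data.shape[0]}",
            f"{'Epochs run':<28}{self.n_epochs_run} (max {self.config.n_epochs})",
            f"{'Iterations':<28}{self.n_iterations}",
            f"{'Initial learning rate':<28}{self.config.eta0:g}",
            f"{'Initial radius':<28}{self.config.sigma0:g}",
            "-" * 55,
            f"{'Quantization error (mean)':<28}{qe.mean:.6f}",
            f"{'Quantization error (sum)':<28}{qe.total:.6f}",
            f"{'Topographic error':<28}{te:.6f}",
            "=" * 55,
        ]
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        """JSON document: grid geometry, codebooks in reading order (node 1 =
        bottom-left), training config and QE history."""
        doc = {
            "grid": {"n_rows": self.grid.n_rows, "n_cols": self.grid.n_cols,
                     "topology": self.grid.topology},
            "feature_names": self.feature_names,
            "codebooks": self.codebooks.tolist(),
            "y_codebooks": None if self.y_codebooks is None else self.y_codebooks.tolist(),
            "config": self.config.to_dict(),
            "qe_history": self.qe_history,
            "n_iterations": self.n_iterations,
        }
        return json.dumps(doc, sort_keys=True)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "SOMResults":
        doc = json.loads(text)
        grid = SOMGrid(doc["grid"]["n_rows"], doc["grid"]["n_cols"],
                       topology=doc["grid"]["topology"])
        codebooks = np.asarray(doc["codebooks"], dtype=float)
        model = KohonenSOM(codebooks, grid=grid)  # placeholder data = codebooks
        model.feature_names = doc["feature_names"]
        y_cb = doc["y_codebooks"]
        return cls(
            model=model, grid=grid, codebooks=codebooks,
            y_codebooks=None if y_cb is None else np.asarray(y_cb, dtype=float),
            config=TrainingConfig(**doc["config"]),
            qe_history=list(doc["qe_history"]),
            n_iterations=int(doc["n_iterations"]),
        )

    @classmethod
    def load(cls, path) -> "SOMResults":
        with open(path) as fh:
            return cls.from_json(fh.read())
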