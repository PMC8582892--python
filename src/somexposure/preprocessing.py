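"""Feature preparation: chained-equation imputation of missing measurements,
z-score scaling, binary coding of nominal variables, and age categories.

Scaling matters because the map's competitive distance treats every input
component equally: a variable on a larger scale would dominate the BMU
search, producing a scale artifact rather than structure. Nominal inputs
(gender, race) are expanded to full one-hot indicator blocks, including an
explicit missing-gender indicator; age enters as a single ordinal category
so the code plots show one age segment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    ConstantColumnError,
    InvalidConfigError,
    UnimputableColumnError,
    UnknownLevelError,
)

__all__ = [
    "impute_chained",
    "Scaler",
    "scale_features",
    "encode_nominal",
    "decode_nominal",
    "categorize_age",
    "FeatureTable",
    "build_feature_table",
    "GENDER_LEVELS",
    "RACE_LEVELS",
]

GENDER_LEVELS = ("male", "female", "missing")
RACE_LEVELS = (0, 1, 2, 3)


# ---------------------------------------------------------------------------
# imputation

def impute_chained(
    table: pd.DataFrame, n_sweeps: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Complete a numeric table by chained-equation imputation (single
    completed dataset).

    Missing cells start at their column mean; then for `n_sweeps` sweeps,
    each incomplete column is regressed (ordinary least squares, with
    intercept) on all other columns' current values over its observed rows,
    and its missing cells are refilled with the prediction plus a Gaussian
    draw at the residual standard deviation. Observed cells are never
    touched. Deterministic under `seed`.
    """
    if n_sweeps < 0:
        raise InvalidConfigError("n_sweeps must be >= 0")
    df = table.copy()
    numeric = df.to_numpy(dtype=float)
    miss = np.isnan(numeric)
    if not miss.any():
        return df
    for j, col in enumerate(df.columns):
        n_obs = (~miss[:, j]).sum()
        if n_obs == 0:
            raise UnimputableColumnError(f"column {col!r} is entirely missing")
        if n_obs < 2:
            raise UnimputableColumnError(
                f"column {col!r} has fewer than 2 observed values"
            )
    rng = np.random.default_rng(seed)
    filled = numeric.copy()
    col_means = np.nanmean(numeric, axis=0)
    for j in range(filled.shape[1]):
        filled[miss[:, j], j] = col_means[j]
    incomplete = [j for j in range(filled.shape[1]) if miss[:, j].any()]
    for _sweep in range(n_sweeps):
        for j in incomplete:
            obs = ~miss[:, j]
            others = [k for k in range(filled.shape[1]) if k != j]
            X = np.column_stack([np.ones(filled.shape[0]), filled[:, others]])
            beta, *_ = np.linalg.lstsq(X[obs], filled[obs, j], rcond=None)
            pred = X @ beta
            resid = filled[obs, j] - pred[obs]
            dof = max(obs.sum() - len(beta), 1)
            resid_sd = float(np.sqrt(np.sum(resid**2) / dof))
            draws = rng.normal(0.0, resid_sd, size=int(miss[:, j].sum()))
            filled[miss[:, j], j] = pred[miss[:, j]] + draws
    out = df.copy()
    out.iloc[:, :] = filled
    return out


# ---------------------------------------------------------------------------
# scaling

@dataclass
class Scaler:
    """Per-column z-score parameters, reusable on new data."""

    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)

    def fit(self, table: pd.DataFrame, columns=None) -> "Scaler":
        cols = list(columns) if columns is not None else list(table.columns)
        for c in cols:
            sd = float(table[c].std(ddof=0))
            if sd == 0.0:
                raise ConstantColumnError(
                    f"column {c!r} has zero variance and cannot be scaled"
                )
            self.means[c] = float(table[c].mean())
            self.sds[c] = sd
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for c, m in self.means.items():
            out[c] = (out[c] - m) / self.sds[c]
        return out

    def inverse_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for c, m in self.means.items():
            out[c] = out[c] * self.sds[c] + m
        return out

    def to_json(self) -> str:
        return json.dumps({"means": self.means, "sds": self.sds}, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Scaler":
        doc = json.loads(text)
        return cls(means=doc["means"], sds=doc["sds"])


def scale_features(table: pd.DataFrame, columns=None) -> tuple[pd.DataFrame, Scaler]:
    """Z-score the given (default: all) columns; returns the scaled table and
    the fitted scaler for reuse on new data."""
    scaler = Scaler().fit(table, columns=columns)
    return scaler.transform(table), scaler


# ---------------------------------------------------------------------------
# nominal coding

def encode_nominal(table: pd.DataFrame) -> pd.DataFrame:
    """Expand gender and race into full one-hot indicator blocks.

    gender -> gender_male / gender_female / gender_missing; race (coded 0 =
    African or Black, 1 = White, 2 = Indian, 3 = Other) -> race_0 .. race_3.
    Each block's row sum is exactly 1; a level outside the declared sets
    raises UnknownLevelError.
    """
    out = table.copy()
    if "gender" in out.columns:
        bad = set(out["gender"].unique()) - set(GENDER_LEVELS)
        if bad:
            raise UnknownLevelError(f"unknown gender level(s): {sorted(bad)}")
        for level in GENDER_LEVELS:
            out[f"gender_{level}"] = (out["gender"] == level).astype(int)
        out = out.drop(columns=["gender"])
    if "race" in out.columns:
        bad = set(out["race"].unique()) - set(RACE_LEVELS)
        if bad:
            raise UnknownLevelError(f"unknown race level(s): {sorted(bad)}")
        for level in RACE_LEVELS:
            out[f"race_{level}"] = (out["race"] == level).astype(int)
        out = out.drop(columns=["race"])
    return out


def decode_nominal(table: pd.DataFrame) -> pd.DataFrame:
    """Invert `encode_nominal`: indicator blocks back to the original level."""
    out = table.copy()
    g_cols = [f"gender_{lev}" for lev in GENDER_LEVELS]
    if all(c in out.columns for c in g_cols):
        idx = out[g_cols].to_numpy().argmax(axis=1)
        out["gender"] = [GENDER_LEVELS[i] for i in idx]
        out = out.drop(columns=g_cols)
    r_cols = [f"race_{lev}" for lev in RACE_LEVELS]
    if all(c in out.columns for c in r_cols):
        idx = out[r_cols].to_numpy().argmax(axis=1)
        out["race"] = [RACE_LEVELS[i] for i in idx]
        out = out.drop(columns=r_cols)
    return out


# ---------------------------------------------------------------------------
# age categories

def categorize_age(age):
    """Age category 1-5: infants [0, 1]; children (1, 9]; adolescents
    (9, 19]; adults (19, 65]; elderly over 65.

    The published bin labels leave ages strictly between 1 and 2 years
    unlabelled; they are assigned to the children category, the only
    gap-free completion consistent with the labels.
    """
    arr = np.asarray(age, dtype=float)
    if np.any(arr < 0) or np.any(~np.isfinite(arr)):
        raise InvalidConfigError("ages must be finite and non-negative")
    cat = np.digitize(arr, bins=[1.0, 9.0, 19.0, 65.0], right=True) + 1
    if np.isscalar(age) or arr.ndim == 0:
        return int(cat)
    return cat.astype(int)


# ---------------------------------------------------------------------------
# feature table

@dataclass
class FeatureTable:
    """Model-ready per-patient matrix.

    data : DataFrame indexed by patient id — z-scored pollutant exposures,
        a z-scored ordinal age_category column, and one-hot gender/race
        indicators; no missing cells.
    scaler : the fitted z-score parameters (for applying to new data).
    outcome : aligned 0/1 Series when outcomes were present.
    continuous_columns / indicator_columns : column provenance.
    """

    data: pd.DataFrame
    scaler: Scaler
    outcome: pd.Series | None
    continuous_columns: list[str]
    indicator_columns: list[str]

    def validate(self) -> None:
        if self.data.isna().any().any():
            raise InvalidConfigError("feature table contains missing cells")
        for c in self.continuous_columns:
            col = self.data[c]
            if abs(col.mean()) > 1e-8 or abs(col.std(ddof=0) - 1) > 1e-8:
                raise InvalidConfigError(f"column {c!r} is not z-scored")
        for c in self.indicator_columns:
            if not self.data[c].isin([0, 1]).all():
                raise InvalidConfigError(f"indicator column {c!r} not binary")


def build_feature_table(
    exposures: pd.DataFrame,
    cohort_df: pd.DataFrame,
    pollutants=None,
) -> FeatureTable:
    """Join exposures with demographics and produce the scaled, encoded
    feature matrix (patients without an exposure profile are dropped)."""
    if pollutants is None:
        pollutants = list(exposures.columns)
    cohort = cohort_df.set_index("id")
    ids = exposures.index.intersection(cohort.index)
    base = exposures.loc[ids, list(pollutants)].copy()
    base["age_category"] = cohort.loc[ids, "age_category"].astype(float)
    base = pd.concat(
        [base, cohort.loc[ids, ["gender", "race"]]], axis=1
    )
    encoded = encode_nominal(base)
    continuous = [*pollutants, "age_category"]
    scaled, scaler = scale_features(encoded, columns=continuous)
    indicator = [c for c in scaled.columns if c.startswith(("gender_", "race_"))]
    outcome = None
    if "outcome" in cohort.columns:
        outcome = cohort.loc[ids, "outcome"].astype(int)
    ft = FeatureTable(
        data=scaled,
        scaler=scaler,
        outcome=outcome,
        continuous_columns=continuous,
        indicator_columns=indicator,
    )
    ft.validate()
    return ft


def impute_measurements(measurements_df: pd.DataFrame, n_sweeps: int = 10,
                        seed: int = 0) -> pd.DataFrame:
    """Impute the station x day measurement table in wide form.

    Pivots to one row per date with a (station, pollutant) column each,
    runs chained-equation imputation, and melts back to long form. Borrowing
    across stations and pollutants exploits their spatial and chemical
    correlation.
    """
    meas = measurements_df.copy()
    meas["date"] = pd.to_datetime(meas["date"])
    wide = meas.pivot_table(
        index="date", columns=["station_id", "pollutant"], values="value",
        dropna=False,
    )
    wide.columns = [f"{s}|{p}" for s, p in wide.columns]
    completed = impute_chained(wide, n_sweeps=n_sweeps, seed=seed)
    completed = completed.clip(lower=0.0)  # concentrations are non-negative
    long = completed.reset_index().melt(
        id_vars="date", var_name="key", value_name="value"
    )
    long[["station_id", "pollutant"]] = long["key"].str.split("|", expand=True)
    return long[["station_id", "date", "pollutant", "value"]]
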