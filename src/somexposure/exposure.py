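"""Spatial interpolation of station measurements to patient addresses and
assembly of lagged per-patient exposure profiles.

Station values are carried to a patient's coordinates by inverse-distance
weighting (IDW): a convex combination of the stations that reported a value
on the relevant day, with weights proportional to distance^(-power). The
relevant day is the presentation date minus a fixed lag (default two days,
allowing for the airway-inflammation delay that precedes an acute
presentation). Distances use an equirectangular planar approximation, which
is adequate at metropolitan scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidConfigError, NoDataError

__all__ = ["idw_interpolate", "build_exposure_profiles", "ExposureProfiles", "planar_distance_m"]

_EARTH_RADIUS_M = 6_371_000.0
# stations closer than ~1 m are treated as coincident with the target
_COINCIDENT_M = 1.0


def planar_distance_m(lon1, lat1, lon2, lat2, ref_lat: float | None = None) -> np.ndarray:
    """Equirectangular planar distance in metres between degree coordinates."""
    if ref_lat is None:
        ref_lat = (np.mean(lat1) + np.mean(lat2)) / 2.0
    kx = np.cos(np.radians(ref_lat)) * np.pi / 180.0 * _EARTH_RADIUS_M
    ky = np.pi / 180.0 * _EARTH_RADIUS_M
    dx = (np.asarray(lon2, float) - np.asarray(lon1, float)) * kx
    dy = (np.asarray(lat2, float) - np.asarray(lat1, float)) * ky
    return np.sqrt(dx * dx + dy * dy)


def idw_interpolate(stations, target, power: float = 2.0) -> float:
    """Inverse-distance-weighted value at `target` from (lon, lat, value)
    triples.

    Weights are dist^(-power), normalized to sum to one, so the result is a
    convex combination of station values and lies within their range. A
    station within ~1 m of the target returns that station's value exactly.
    """
    if power <= 0:
        raise InvalidConfigError("power must be positive")
    rows = [(lon, lat, v) for lon, lat, v in stations if np.isfinite(v)]
    if not rows:
        raise NoDataError("no stations with observed values for this target")
    lon = np.array([r[0] for r in rows])
    lat = np.array([r[1] for r in rows])
    val = np.array([r[2] for r in rows], dtype=float)
    d = planar_distance_m(target[0], target[1], lon, lat, ref_lat=target[1])
    near = d < _COINCIDENT_M
    if near.any():
        return float(val[int(np.argmax(near))])
    w = d ** (-power)
    return float(np.sum(w * val) / np.sum(w))


@dataclass
class ExposureProfiles:
    """Per-patient lagged exposure values plus the exclusion report.

    profiles : DataFrame indexed by patient id, one column per pollutant.
    exclusions : DataFrame (id, date, pollutant, reason) for patients with no
        reporting station on the lagged day; excluded patients do not appear
        in `profiles`, so len(profiles) + excluded patients = cohort size.
    lag : days between exposure and presentation.
    """

    profiles: pd.DataFrame
    exclusions: pd.DataFrame
    lag: int


def build_exposure_profiles(
    cohort_df: pd.DataFrame,
    stations_df: pd.DataFrame,
    measurements_df: pd.DataFrame,
    pollutants=None,
    lag: int = 2,
    power: float = 2.0,
) -> ExposureProfiles:
    """Assemble each patient's pollutant exposures on presentation_date - lag.

    For every patient and pollutant, IDW-interpolates the stations that have
    an observed (possibly previously imputed) value on the lagged day. A
    patient with zero available stations for any pollutant on that day is
    dropped and listed in the exclusion report — mirroring the exclusion of
    patients for whom no exposure profile can be built.
    """
    if lag < 0:
        raise InvalidConfigError("lag must be >= 0")
    if pollutants is None:
        pollutants = sorted(measurements_df["pollutant"].unique())
    meas = measurements_df.copy()
    meas["date"] = pd.to_datetime(meas["date"])
    cohort = cohort_df.copy()
    cohort["date"] = pd.to_datetime(cohort["date"])
    coords = stations_df.set_index("station_id")[["lon", "lat"]]

    # (date, pollutant) -> station -> value, NaNs dropped
    lut: dict[tuple, pd.Series] = {
        key: grp.dropna(subset=["value"]).set_index("station_id")["value"]
        for key, grp in meas.groupby(["date", "pollutant"], sort=False)
    }

    records = []
    exclusions = []
    for row in cohort.itertuples(index=False):
        day = row.date - pd.Timedelta(days=lag)
        values = {}
        reasons = []
        for pol in pollutants:
            avail = lut.get((day, pol))
            if avail is None or avail.empty:
                reasons.append((pol, "no station with an observed value"))
                continue
            triples = [
                (coords.at[sid, "lon"], coords.at[sid, "lat"], v)
                for sid, v in avail.items()
            ]
            values[pol] = idw_interpolate(triples, (row.lon, row.lat), power=power)
        if reasons:
            for pol, why in reasons:
                exclusions.append(
                    {"id": row.id, "date": day.strftime("%Y-%m-%d"),
                     "pollutant": pol, "reason": why}
                )
        else:
            records.append({"id": row.id, **values})

    profiles = pd.DataFrame.from_records(records, columns=["id", *pollutants])
    profiles = profiles.set_index("id")
    excl = pd.DataFrame.from_records(
        exclusions, columns=["id", "date", "pollutant", "reason"]
    )
    return ExposureProfiles(profiles=profiles, exclusions=excl, lag=lag)
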