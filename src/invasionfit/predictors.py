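"""Predictor construction for site-level invasion models.

Builds the covariate table used to explain local carrying capacity and
growth rate: great-circle distance from the introduction origin, population
age (years since first local detection), effort normalization for
party-hour surveys, and mean/sd standardization in two modes (within each
survey dataset, or jointly across both).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088

#: canonical predictor roster: 2 historical/geographical, 7 land cover, 2 climate
PREDICTOR_COLUMNS = [
    "invasion_distance_km",
    "population_age_yr",
    "developed_open_pct",
    "developed_low_pct",
    "developed_med_pct",
    "developed_high_pct",
    "forest_pct",
    "pasture_pct",
    "crops_pct",
    "precipitation_mm",
    "temperature_c",
]

LAND_COVER_COLUMNS = PREDICTOR_COLUMNS[2:9]
CLIMATE_COLUMNS = PREDICTOR_COLUMNS[9:]


def great_circle_distance(p1, p2):
    """Haversine distance in km between two (lat, lon) points in degrees.

    Symmetric and nonnegative; uses the IUGG mean Earth radius 6371.0088 km.
    """
    lat1, lon1 = p1
    lat2, lon2 = p2
    for v in (lat1, lon1, lat2, lon2):
        if not np.all(np.isfinite(v)):
            raise ValueError("coordinates must be finite")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlmb = np.radians(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def distance_to_origin(lats, lons, origin):
    """Vectorized great-circle distance (km) from each site to ``origin``."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    return great_circle_distance((lats, lons), (float(origin[0]), float(origin[1])))


def pairwise_distances_km(lats, lons):
    """Dense n-by-n great-circle distance matrix in km."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    n = lats.size
    out = np.zeros((n, n))
    for i in range(n):
        out[i, i + 1:] = great_circle_distance(
            (lats[i], lons[i]), (lats[i + 1:], lons[i + 1:])
        )
    return out + out.T


def population_age(first_observation_year, reference_year):
    """Years since first local detection (the site's population age)."""
    if reference_year < first_observation_year:
        raise ValueError(
            f"reference year {reference_year} precedes first observation "
            f"{first_observation_year}"
        )
    return int(reference_year) - int(first_observation_year)


def normalize_effort(count, party_hours):
    """Birds per party-hour: count / effort.

    Nonpositive or missing effort yields NaN so the site-year can be
    flagged and excluded from fitting rather than silently kept.
    """
    count = np.asarray(count, dtype=float)
    hours = np.asarray(party_hours, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(hours > 0, count / hours, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class StandardizationParams:
    """Per-group, per-column mean and sd used for a standardization pass.

    ``groups`` maps a dataset tag (or ``"__all__"`` in joint/untagged mode)
    to ``{column: (mean, sd)}``.  Columns that were constant within their
    group are recorded in ``constant_columns`` and are centered but not
    scaled.
    """

    mode: str
    groups: dict = field(default_factory=dict)
    constant_columns: list = field(default_factory=list)

    def _params_for(self, tag, col):
        if tag in self.groups:
            return self.groups[tag][col]
        if "__all__" in self.groups:
            return self.groups["__all__"][col]
        if len(self.groups) == 1:  # untagged data under single-tag params
            return next(iter(self.groups.values()))[col]
        raise KeyError(f"no standardization group for tag {tag!r}")

    def transform(self, table: pd.DataFrame, tags=None) -> pd.DataFrame:
        out = table.copy()
        tag_arr = _tag_array(table, tags, self.mode)
        for col in table.columns:
            vals = table[col].to_numpy(dtype=float)
            res = np.empty_like(vals)
            for tag in np.unique(tag_arr):
                m = tag_arr == tag
                mu, sd = self._params_for(tag, col)
                res[m] = (vals[m] - mu) / (sd if sd > 0 else 1.0)
            out[col] = res
        return out

    def inverse_transform(self, table: pd.DataFrame, tags=None) -> pd.DataFrame:
        out = table.copy()
        tag_arr = _tag_array(table, tags, self.mode)
        for col in table.columns:
            vals = table[col].to_numpy(dtype=float)
            res = np.empty_like(vals)
            for tag in np.unique(tag_arr):
                m = tag_arr == tag
                mu, sd = self._params_for(tag, col)
                res[m] = vals[m] * (sd if sd > 0 else 1.0) + mu
            out[col] = res
        return out

    def to_dict(self):
        return {
            "mode": self.mode,
            "groups": {
                t: {c: [float(m), float(s)] for c, (m, s) in cols.items()}
                for t, cols in self.groups.items()
            },
            "constant_columns": list(self.constant_columns),
        }


def _tag_array(table, tags, mode):
    if mode != "independent" or tags is None:
        return np.full(len(table), "__all__", dtype=object)
    return np.asarray(tags, dtype=object)


def standardize(table: pd.DataFrame, mode: str = "independent", tags=None):
    """Center to mean 0 and scale to sample sd 1 (ddof=1).

    ``mode="independent"`` standardizes within each dataset tag (BBS-like /
    CBC-like); ``mode="joint"`` pools all rows before computing the moments,
    so tag-level mean differences survive as nonzero within-tag means.
    Constant columns are centered, flagged, and left unscaled.

    Returns ``(standardized table, StandardizationParams)``; the params
    support exact back-transformation of predictions to the original scale.
    """
    if mode not in ("independent", "joint"):
        raise ValueError(f"unknown standardization mode {mode!r}")
    if len(table) < 2:
        raise ValueError("standardization needs at least 2 rows")
    if mode == "joint" and tags is not None and len(pd.unique(pd.Series(tags))) < 2:
        raise ValueError("joint mode requires both dataset tags to be present")

    tag_arr = _tag_array(table, tags, mode)
    params = StandardizationParams(mode=mode)
    out = table.copy()
    for tag in np.unique(tag_arr):
        m = tag_arr == tag
        cols = {}
        for col in table.columns:
            vals = table.loc[m, col].to_numpy(dtype=float)
            mu = float(vals.mean())
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            if sd < 1e-12:
                sd = 0.0
                if col not in params.constant_columns:
                    params.constant_columns.append(col)
                out.loc[m, col] = vals - mu
            else:
                out.loc[m, col] = (vals - mu) / sd
            cols[col] = (mu, sd)
        params.groups[str(tag)] = cols
    return out, params


def build_predictor_table(
    sites: pd.DataFrame,
    covariates: pd.DataFrame,
    series: pd.DataFrame,
    origin,
) -> pd.DataFrame:
    """Assemble the 11-column predictor table, indexed by site_id.

    Invasion distance is recomputed from site coordinates and the
    introduction origin; population age is the span from each site's first
    observed year to its last (the series itself defines detection).  The
    remaining 9 land-cover/climate columns are taken from ``covariates``.
    """
    first = series.groupby("site_id")["year"].min()
    last = series.groupby("site_id")["year"].max()
    sites = sites.set_index("site_id") if "site_id" in sites.columns else sites
    cov = covariates.set_index("site_id") if "site_id" in covariates.columns else covariates

    idx = cov.index.intersection(first.index)
    dist = distance_to_origin(
        sites.loc[idx, "lat"], sites.loc[idx, "lon"], origin
    )
    age = np.array(
        [population_age(first[s], last[s]) for s in idx], dtype=float
    )
    table = pd.DataFrame(index=idx)
    table["invasion_distance_km"] = dist
    table["population_age_yr"] = age
    for col in PREDICTOR_COLUMNS[2:]:
        table[col] = cov.loc[idx, col].to_numpy(dtype=float)
    table.index.name = "site_id"
    return table
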