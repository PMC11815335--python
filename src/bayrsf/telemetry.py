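"""Reading, validating, filtering and temporally annotating GPS surface fixes.

Fastloc-GPS fixes carry two quality metadata fields: a unitless "residual"
value (large values flag potentially large positional error) and the number of
satellites used for the fix (4-12, possibly missing). Fixes are stored in a
:class:`FixSet` -- a thin wrapper around a pandas DataFrame sorted by
(individual, timestamp) -- together with the coordinate-reference descriptor
and a provenance log counting rows removed per filter rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as geojson_shape

from .solar import is_day

__all__ = [
    "FixSet",
    "Individual",
    "read_fixes",
    "filter_fixes",
    "classify_diel",
    "assign_season",
    "read_geojson_geometry",
    "local_metric_projection",
    "WARM_MONTHS",
]

log = logging.getLogger(__name__)

WARM_MONTHS = frozenset({4, 5, 6, 7, 8, 9, 10, 11})

FIX_COLUMNS = [
    "individual_id",
    "timestamp",
    "x",
    "y",
    "lon",
    "lat",
    "residual",
    "n_sats",
]


@dataclass
class Individual:
    """Per-animal covariates: body size and deployment metadata."""

    id: str
    scl_cm: float
    sex: str = "U"
    deploy_start: pd.Timestamp | None = None
    duration_days: float = float("nan")

    def __post_init__(self):
        if not self.scl_cm > 0:
            raise ValueError(f"scl_cm must be positive, got {self.scl_cm}")


@dataclass
class FixSet:
    """Ordered GPS fixes grouped by individual, with filter provenance."""

    fixes: pd.DataFrame
    crs: str = "planar"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.fixes
        missing = [c for c in FIX_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"FixSet missing columns: {missing}")
        self.fixes = df.sort_values(["individual_id", "timestamp"]).reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def individuals(self) -> list:
        return list(self.fixes["individual_id"].unique())

    def per_individual(self):
        return self.fixes.groupby("individual_id", sort=True)


def local_metric_projection(lon, lat, lon0: float, lat0: float):
    """Equirectangular metre projection about (lon0, lat0).

    Adequate over the few-kilometre extent of an embayment; exact planar
    coordinates should be supplied directly when available.
    """
    r_earth = 6371008.8
    x = np.deg2rad(np.asarray(lon, float) - lon0) * r_earth * math.cos(
        math.radians(lat0)
    )
    y = np.deg2rad(np.asarray(lat, float) - lat0) * r_earth
    return x, y


def read_fixes(path: str | Path, crs_spec: str = "planar") -> FixSet:
    """Read a fix table from CSV and project into the working CRS.

    The file must contain columns ``id, timestamp, lon, lat`` and may contain
    ``residual`` and ``n_sats`` (missing values allowed). ``crs_spec`` is
    either ``"planar"`` (lon/lat are already projected metres and are copied
    verbatim to x/y) or ``"local:<lon0>,<lat0>"`` for the built-in local
    metre projection about that origin.

    Rows with unparseable timestamps are rejected and logged; duplicated
    (id, timestamp) rows keep the first occurrence.
    """
    df = pd.read_csv(path)
    n_read = len(df)
    required = {"id", "timestamp", "lon", "lat"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fix table missing mandatory columns: {sorted(missing)}")

    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="ISO8601")
    bad = ts.isna()
    if bad.any():
        for idx in df.index[bad]:
            log.warning("row %d: unparseable timestamp %r — rejected", idx, df.loc[idx, "timestamp"])
    df = df.loc[~bad].copy()
    ts = ts.loc[~bad]

    out = pd.DataFrame(
        {
            "individual_id": df["id"].astype(str).to_numpy(),
            "timestamp": ts.to_numpy(),
            "lon": df["lon"].astype(float).to_numpy(),
            "lat": df["lat"].astype(float).to_numpy(),
            "residual": df["residual"].astype(float).to_numpy()
            if "residual" in df
            else np.nan,
            "n_sats": pd.to_numeric(df["n_sats"], errors="coerce").to_numpy()
            if "n_sats" in df
            else np.nan,
        }
    )

    if crs_spec == "planar":
        out["x"] = out["lon"]
        out["y"] = out["lat"]
    elif crs_spec.startswith("local:"):
        lon0, lat0 = (float(v) for v in crs_spec.split(":", 1)[1].split(","))
        out["x"], out["y"] = local_metric_projection(out["lon"], out["lat"], lon0, lat0)
    else:
        raise ValueError(f"unsupported crs_spec {crs_spec!r}")

    n_before = len(out)
    out = out.drop_duplicates(subset=["individual_id", "timestamp"], keep="first")
    n_dup = n_before - len(out)
    if n_dup:
        log.info("dropped %d duplicated (id, timestamp) rows", n_dup)

    prov = {
        "rows_read": int(n_read),
        "bad_timestamp": int(bad.sum()),
        "duplicates": int(n_dup),
    }
    return FixSet(fixes=out[FIX_COLUMNS], crs=crs_spec, provenance=prov)


def filter_fixes(fs: FixSet, residual_max: float = 35.0, domain=None) -> FixSet:
    """Quality filtering: residual < ``residual_max`` and strictly inside the
    domain polygon.

    The residual threshold is a strict bound on retention -- fixes with
    residual >= 35 (the conventional Fastloc cut) are discarded; fixes with
    missing residual are retained. Points on or outside the domain boundary
    are removed. Idempotent; removal counts per rule are recorded in
    provenance.
    """
    df = fs.fixes
    res = df["residual"].to_numpy(dtype=float)
    keep_res = np.isnan(res) | (res < residual_max)
    n_resid = int((~keep_res).sum())

    df = df.loc[keep_res]
    n_domain = 0
    if domain is not None:
        inside = shapely.contains_xy(domain, df["x"].to_numpy(), df["y"].to_numpy())
        n_domain = int((~inside).sum())
        df = df.loc[inside]

    if len(df) == 0:
        log.warning("filter_fixes: empty result")
    prov = dict(fs.provenance)
    prov["removed_residual"] = prov.get("removed_residual", 0) + n_resid
    prov["removed_outside_domain"] = prov.get("removed_outside_domain", 0) + n_domain
    prov["retained"] = int(len(df))
    return FixSet(fixes=df.reset_index(drop=True), crs=fs.crs, provenance=prov)


def classify_diel(timestamps, lon, lat) -> np.ndarray:
    """Label each instant 'day' or 'night' by solar altitude against the
    refraction-corrected sunrise/sunset threshold (-0.833 deg)."""
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 66.6):
        log.info(
            "classify_diel: |lat| > 66.6 deg present; polar dates classified by "
            "solar altitude sign alone"
        )
    day = is_day(timestamps, lon, lat)
    return np.where(day, "day", "night")


def assign_season(timestamps, tz_offset_hours: float = 0.0) -> np.ndarray:
    """Warm (Apr-Nov) vs cold (Dec-Mar) by calendar month.

    Months are taken in local civil time given as a fixed UTC offset
    (default 0 -- the time basis of the published split is not stated and is
    therefore configurable).
    """
    ts = pd.DatetimeIndex(pd.to_datetime(timestamps, utc=True))
    if tz_offset_hours:
        ts = ts + pd.Timedelta(hours=tz_offset_hours)
    months = ts.month.to_numpy()
    return np.where(np.isin(months, list(WARM_MONTHS)), "warm", "cold")


def annotate_time(fs: FixSet, tz_offset_hours: float = 0.0) -> FixSet:
    """Attach diel ('day'/'night') and season ('warm'/'cold') columns."""
    df = fs.fixes.copy()
    df["diel"] = classify_diel(df["timestamp"], df["lon"], df["lat"])
    df["season"] = assign_season(df["timestamp"], tz_offset_hours)
    return FixSet(fixes=df, crs=fs.crs, provenance=dict(fs.provenance))


def read_geojson_geometry(path: str | Path):
    """Load the (union of) geometry in a GeoJSON file as a shapely geometry."""
    import json

    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [geojson_shape(f["geometry"]) for f in gj["features"]]
        return shapely.union_all(geoms)
    if gj.get("type") == "Feature":
        return geojson_shape(gj["geometry"])
    return geojson_shape(gj)
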