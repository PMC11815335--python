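"""Habitat covariate construction and annotation.

Covariates attached to every use and pseudo-absence row:

* signed distance (m) to the nearest seagrass patch edge -- positive outside
  patches, negative inside, 0 on the boundary; each individual's rows use the
  survey year closest to its deployment year (ties -> later survey);
* bathymetric depth (m below datum, positive down), nearest-cell sampled;
* relative water temperature (deg C delta from the domain mean), from a kriged
  surface built out of repeated station measurements referenced to a buoy.

A collinearity screen computes pairwise simple-regression R^2 between spatial
covariates per season and flags pairs at or above the threshold (default
0.49).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import optimize
from shapely.geometry import MultiPolygon, Polygon

from .raster import Raster

__all__ = [
    "SeagrassLayer",
    "TemperatureSurface",
    "signed_distance_to_edge",
    "select_survey_year",
    "fit_variogram",
    "ordinary_kriging",
    "build_temperature_surface",
    "annotate",
    "collinearity_screen",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# seagrass edge distance
# ---------------------------------------------------------------------------


@dataclass
class SeagrassLayer:
    """Seagrass patch polygons for one survey year; edges are the polygon
    boundaries."""

    survey_year: int
    patches: Polygon | MultiPolygon

    @property
    def edges(self):
        return self.patches.boundary


def signed_distance_to_edge(x, y, layer: SeagrassLayer) -> np.ndarray:
    """Signed Euclidean distance to the nearest patch edge.

    Negative magnitude for points inside a patch (distance is still measured
    to the *edge*, so deep-interior points get large negative values),
    positive outside, 0 on the boundary. Vectorised over points.
    """
    if layer.patches.is_empty:
        raise ValueError("empty seagrass layer")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    pts = shapely.points(x, y)
    d = shapely.distance(pts, layer.edges)
    inside = shapely.contains_xy(layer.patches, x, y)
    out = np.where(inside, -d, d)
    return out if out.size > 1 else out.reshape(())


def select_survey_year(deploy_year: int, available_years) -> int:
    """Survey year closest in time to the deployment year; ties -> later."""
    years = sorted(available_years)
    if not years:
        raise ValueError("no survey years available")
    return min(years, key=lambda yr: (abs(yr - deploy_year), -yr))


# ---------------------------------------------------------------------------
# temperature surface: station regression + ordinary kriging
# ---------------------------------------------------------------------------


@dataclass
class TemperatureSurface:
    grid: Raster                       # delta deg C
    stations: pd.DataFrame             # x, y, delta
    variogram: dict                    # model, nugget, sill, range


def _exponential_semivariance(h, sill, rng):
    return sill * (1.0 - np.exp(-h / rng))


def fit_variogram(coords: np.ndarray, values: np.ndarray, n_bins: int = 12) -> dict:
    """Weighted-least-squares fit of an exponential semivariogram, nugget
    fixed at 0 (so kriging interpolates the stations exactly).

    Empirical semivariances are binned by pair distance up to half the
    maximum pairwise distance, weighted by pair count.
    """
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    g = 0.5 * (values[:, None] - values[None, :]) ** 2
    iu = np.triu_indices(len(values), k=1)
    d, g = d[iu], g[iu]
    dmax = d.max() / 2.0
    edges = np.linspace(0, dmax, n_bins + 1)
    idx = np.digitize(d, edges[1:-1])
    keep = d <= dmax
    centers, gammas, counts = [], [], []
    for b in range(n_bins):
        m = keep & (idx == b)
        if m.sum() > 0:
            centers.append(d[m].mean())
            gammas.append(g[m].mean())
            counts.append(m.sum())
    centers = np.asarray(centers)
    gammas = np.asarray(gammas)
    counts = np.asarray(counts, dtype=float)

    sill0 = values.var() if values.var() > 0 else 1e-12
    rng0 = max(centers.mean(), 1e-6)
    try:
        popt, _ = optimize.curve_fit(
            _exponential_semivariance,
            centers,
            gammas,
            p0=[sill0, rng0],
            sigma=1.0 / np.sqrt(counts),
            bounds=([1e-12, 1e-6], [np.inf, np.inf]),
            maxfev=10000,
        )
        sill, rng = float(popt[0]), float(popt[1])
    except Exception as exc:  # pragma: no cover - defensive
        log.warning("variogram fit failed (%s); using moment defaults", exc)
        sill, rng = float(sill0), float(rng0)
    return {"model": "exponential", "nugget": 0.0, "sill": sill, "range": rng}


def ordinary_kriging(
    coords: np.ndarray, values: np.ndarray, pred_coords: np.ndarray, variogram: dict
) -> np.ndarray:
    """Ordinary-kriging prediction at ``pred_coords``.

    Solves the standard system with a Lagrange multiplier enforcing weights
    that sum to 1; with a zero nugget the predictor interpolates the data
    exactly at station locations.
    """
    n = len(values)
    sill, rng = variogram["sill"], variogram["range"]
    dmat = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    gamma = _exponential_semivariance(dmat, sill, rng)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = gamma
    A[n, :] = 1.0
    A[:, n] = 1.0
    A[n, n] = 0.0

    dp = np.sqrt(
        ((pred_coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    )  # (m, n)
    B = np.empty((n + 1, len(pred_coords)))
    B[:n] = _exponential_semivariance(dp, sill, rng).T
    B[n] = 1.0
    try:
        lam = np.linalg.solve(A, B)
    except np.linalg.LinAlgError:
        lam = np.linalg.lstsq(A, B, rcond=None)[0]
    return lam[:n].T @ values


def build_temperature_surface(
    station_series: pd.DataFrame,
    buoy_series: pd.DataFrame,
    grid: Raster,
) -> TemperatureSurface:
    """Buoy-referenced station means -> delta values -> ordinary kriging.

    ``station_series`` has columns (station, x, y, time, temp) of repeated
    measurements; ``buoy_series`` has (time, temp). For each station an OLS
    regression of station temperature on time-matched buoy temperature gives
    a long-run station mean (the prediction at the buoy's overall mean),
    which removes bias from stations sampled in unrepresentative conditions.
    Station means are converted to deltas about their own mean and kriged
    onto ``grid``. Stations with fewer than 2 buoy-matched observations are
    dropped.
    """
    buoy = buoy_series.set_index("time")["temp"]
    buoy_grand_mean = float(buoy.mean())

    rows = []
    for st, grp in station_series.groupby("station"):
        matched = grp.join(buoy.rename("buoy_temp"), on="time", how="inner").dropna(
            subset=["buoy_temp", "temp"]
        )
        if len(matched) < 2:
            log.info("station %r: <2 buoy-matched observations, dropped", st)
            continue
        bx = matched["buoy_temp"].to_numpy(dtype=float)
        sy = matched["temp"].to_numpy(dtype=float)
        if np.ptp(bx) == 0:
            slope, intercept = 0.0, sy.mean()
        else:
            slope, intercept = np.polyfit(bx, sy, 1)
        mean_at_buoy_mean = intercept + slope * buoy_grand_mean
        rows.append(
            {
                "station": st,
                "x": float(grp["x"].iloc[0]),
                "y": float(grp["y"].iloc[0]),
                "mean_temp": mean_at_buoy_mean,
            }
        )
    stations = pd.DataFrame(rows)
    if len(stations) < 3:
        raise ValueError("need at least 3 usable stations to krige")
    stations["delta"] = stations["mean_temp"] - stations["mean_temp"].mean()

    coords = stations[["x", "y"]].to_numpy()
    deltas = stations["delta"].to_numpy()
    if np.allclose(deltas, 0.0):
        vgm = {"model": "exponential", "nugget": 0.0, "sill": 1e-12, "range": 1.0}
        surf = np.zeros_like(grid.values)
    else:
        vgm = fit_variogram(coords, deltas)
        X, Y = grid.cell_centers()
        pred = ordinary_kriging(
            coords, deltas, np.column_stack([X.ravel(), Y.ravel()]), vgm
        )
        surf = pred.reshape(grid.values.shape)
    out = Raster(values=surf, x0=grid.x0, y0=grid.y0, cell=grid.cell)
    return TemperatureSurface(grid=out, stations=stations, variogram=vgm)


# ---------------------------------------------------------------------------
# annotation & collinearity
# ---------------------------------------------------------------------------


def annotate(
    rows: pd.DataFrame,
    seagrass: dict[int, SeagrassLayer],
    bathy: Raster,
    temp: TemperatureSurface | Raster,
    max_offraster_frac: float = 0.05,
) -> pd.DataFrame:
    """Attach habitat covariates to use/pseudo-absence rows.

    ``rows`` needs columns (x, y, deploy_year); returns a copy with
    ``dist_eelgrass_m``, ``depth_m``, ``temp_delta_c`` columns. Rows whose
    coordinates fall off either raster are excluded (hard error above
    ``max_offraster_frac``).
    """
    temp_grid = temp.grid if isinstance(temp, TemperatureSurface) else temp
    df = rows.copy()
    x = df["x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)

    years = sorted(seagrass)
    dist = np.empty(len(df))
    for dy, grp in df.groupby("deploy_year"):
        layer = seagrass[select_survey_year(int(dy), years)]
        idx = grp.index.to_numpy()
        dist[df.index.get_indexer(idx)] = signed_distance_to_edge(
            df.loc[idx, "x"].to_numpy(), df.loc[idx, "y"].to_numpy(), layer
        )
    df["dist_eelgrass_m"] = dist
    df["depth_m"] = bathy.sample(x, y)
    df["temp_delta_c"] = temp_grid.sample(x, y)

    bad = df[["depth_m", "temp_delta_c"]].isna().any(axis=1)
    frac = bad.mean() if len(df) else 0.0
    if frac > max_offraster_frac:
        raise ValueError(
            f"{frac:.1%} of rows fall off the habitat rasters: layer mismatch"
        )
    if bad.any():
        log.info("excluding %d off-raster rows from modelling", int(bad.sum()))
    return df.loc[~bad].reset_index(drop=True)


def collinearity_screen(
    dt: pd.DataFrame,
    covariates: tuple[str, ...] = ("dist_eelgrass_m", "depth_m", "temp_delta_c"),
    threshold_r2: float = 0.49,
) -> pd.DataFrame:
    """Pairwise simple-linear-regression R^2 between spatial covariates,
    per season; pairs at or above the threshold are flagged (drop one)."""
    out = []
    seasons = dt["season"].unique() if "season" in dt else [None]
    for season in seasons:
        sub = dt if season is None else dt[dt["season"] == season]
        for i, a in enumerate(covariates):
            for b in covariates[i + 1 :]:
                r = np.corrcoef(sub[a], sub[b])[0, 1]
                r2 = float(r**2)
                out.append(
                    {
                        "season": season,
                        "covariate_a": a,
                        "covariate_b": b,
                        "r2": r2,
                        "flagged": r2 >= threshold_r2,
                    }
                )
    report = pd.DataFrame(out)
    for _, row in report[report["flagged"]].iterrows():
        log.warning(
            "collinear pair %s ~ %s (R^2=%.2f, season=%s): drop one",
            row["covariate_a"], row["covariate_b"], row["r2"], row["season"],
        )
    return report
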