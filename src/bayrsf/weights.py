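"""Observation weights for use-availability modelling.

Two down-weighting terms are built and combined:

1. **Telemetry-error weights** from a satellite-count calibration table:
   error records are truncated at their global 95th quantile, per-count mean
   errors inverted and rescaled so the largest weight is exactly 1. Missing
   counts (and computer-generated pseudo-absences) get the minimum weight so
   they never outweigh an observation.

2. **Autocorrelation weights** from a continuous-time movement model fitted
   per individual. IID, OU (exponential position autocorrelation) and OUF
   (position-velocity, two-timescale) models are fitted by maximum likelihood
   on the 2-D positions at the observed irregular times and compared by AICc.
   The fitted normalized position autocorrelation rho(dt) then yields
   per-fix weights w_i = 1 / sum_j rho(|t_i - t_j|), an effective-independence
   scheme: an isolated fix gets weight 1, a burst of tightly clustered fixes
   shares roughly one unit of weight. The effective sample size is
   N_EFF = sum_i w_i, equal to N for an IID individual.

Finally the two terms are combined so that, per individual and season, the
total weight equals N_EFF and is split 50/50 between GPS rows (proportionally
to w_i) and pseudo-absence rows (evenly), multiplied by the error weight, and
rescaled so each seasonal dataset's weights sum to its row count (weights act
as binomial trial counts, so the total must be anchored).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ErrorWeightTable",
    "MovementModel",
    "AutocorrWeights",
    "build_error_weights",
    "fit_movement_model",
    "autocorr_weights",
    "combine_weights",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# satellite-count error weights
# ---------------------------------------------------------------------------


@dataclass
class ErrorWeightTable:
    """Satellite count -> model weight in (0, 1], max weight exactly 1."""

    weights: dict[int, float]
    mean_error_m: dict[int, float]
    na_weight: float = field(init=False)

    def __post_init__(self):
        if not self.weights:
            raise ValueError("empty error-weight table")
        self.na_weight = min(self.weights.values())

    def weight_for(self, n_sats) -> np.ndarray:
        """Vectorised lookup; missing/unknown counts get na_weight."""
        n = pd.to_numeric(pd.Series(np.atleast_1d(n_sats)), errors="coerce")
        out = n.map(self.weights).fillna(self.na_weight).to_numpy(dtype=float)
        return out


def build_error_weights(calibration: pd.DataFrame, quantile_cut: float = 0.95) -> ErrorWeightTable:
    """Build error weights from (n_sats, error_m) calibration records.

    Errors above the global ``quantile_cut`` quantile are discarded, a mean
    error is computed per satellite count, weights are the inverse means
    rescaled so the largest is 1.
    """
    df = pd.DataFrame(calibration)[["n_sats", "error_m"]].dropna()
    if df["n_sats"].nunique() < 2:
        raise ValueError("calibration needs at least 2 distinct satellite counts")
    cut = df["error_m"].quantile(quantile_cut)
    kept = df[df["error_m"] <= cut]
    means = kept.groupby("n_sats")["error_m"].mean()
    dropped = set(df["n_sats"].unique()) - set(means.index)
    for c in dropped:
        log.info("satellite count %s: no surviving calibration records, excluded", c)
    if (means <= 0).any():
        raise ValueError("non-positive mean error in calibration")
    inv = 1.0 / means
    w = inv / inv.max()
    return ErrorWeightTable(
        weights={int(k): float(v) for k, v in w.items()},
        mean_error_m={int(k): float(v) for k, v in means.items()},
    )


# ---------------------------------------------------------------------------
# continuous-time movement models
# ---------------------------------------------------------------------------


@dataclass
class MovementModel:
    """Fitted stationary movement model for one individual's track."""

    family: str                      # "IID" | "OU" | "OUF"
    tau_position: float | None       # s
    tau_velocity: float | None       # s, OUF only
    spatial_variance: float          # m^2, per axis
    mean: tuple[float, float]
    log_likelihood: float
    aicc: float
    n_fixes: int

    def rho(self, dt: np.ndarray) -> np.ndarray:
        """Normalized position autocorrelation at non-negative lags (s)."""
        dt = np.asarray(dt, dtype=float)
        if self.family == "IID":
            return np.where(dt == 0.0, 1.0, 0.0)
        if self.family == "OU":
            return np.exp(-dt / self.tau_position)
        tp, tv = self.tau_position, self.tau_velocity
        return (tp * np.exp(-dt / tp) - tv * np.exp(-dt / tv)) / (tp - tv)


def _aicc(loglik: float, k: int, n: int) -> float:
    if n <= k + 1:
        return np.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _iid_fit(t, xy):
    n = len(t)
    mu = xy.mean(axis=0)
    resid = xy - mu
    sigma2 = float(resid.var(axis=0, ddof=0).mean())
    ll = -n * np.log(2 * np.pi * sigma2) - (resid**2).sum() / (2 * sigma2)
    return mu, sigma2, float(ll)


def _ou_profile_loglik(log_tau: float, t, xy):
    """Exact OU likelihood via the Markov property, with mean and variance
    profiled out analytically (per-axis mean, shared isotropic variance)."""
    tau = np.exp(log_tau)
    n = len(t)
    dt = np.diff(t)
    rho = np.exp(-dt / tau)
    # observation i (i>=1): x_i - rho_i x_{i-1} ~ N(mu (1-rho_i), s2 (1-rho_i^2))
    c = np.concatenate([[1.0], 1.0 - rho])           # mean multiplier
    v = np.concatenate([[1.0], 1.0 - rho**2])        # variance / s2
    v = np.maximum(v, 1e-12)
    mus = []
    rss = 0.0
    for axis in range(2):
        x = xy[:, axis]
        u = np.concatenate([[x[0]], x[1:] - rho * x[:-1]])
        mu = np.sum(c * u / v) / np.sum(c**2 / v)
        mus.append(mu)
        rss += np.sum((u - c * mu) ** 2 / v)
    s2 = rss / (2 * n)
    ll = -n * np.log(2 * np.pi * s2) - np.log(v).sum() - rss / (2 * s2)
    return float(ll), np.array(mus), float(s2)


def _gp_profile_loglik(corr: np.ndarray, xy):
    """Profile likelihood for a stationary Gaussian process with given
    correlation matrix (shared by both axes, isotropic variance)."""
    n = corr.shape[0]
    corr = corr + 1e-10 * np.eye(n)
    try:
        L = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        return -np.inf, np.zeros(2), 1.0
    logdet = 2.0 * np.log(np.diag(L)).sum()
    ones = np.ones(n)
    a = np.linalg.solve(L, np.column_stack([xy, ones]))
    ax, ay, a1 = a[:, 0], a[:, 1], a[:, 2]
    denom = a1 @ a1
    mux = (a1 @ ax) / denom
    muy = (a1 @ ay) / denom
    rss = ((ax - mux * a1) ** 2).sum() + ((ay - muy * a1) ** 2).sum()
    s2 = rss / (2 * n)
    if not np.isfinite(s2) or s2 <= 0:
        return -np.inf, np.zeros(2), 1.0
    ll = -n * np.log(2 * np.pi * s2) - logdet - rss / (2 * s2)
    return float(ll), np.array([mux, muy]), float(s2)


def _ouf_corr(t, tau_p, tau_v):
    dt = np.abs(t[:, None] - t[None, :])
    if abs(tau_p - tau_v) < 1e-9 * tau_p:
        tau_v = 0.999 * tau_p
    return (tau_p * np.exp(-dt / tau_p) - tau_v * np.exp(-dt / tau_v)) / (tau_p - tau_v)


def fit_movement_model(track: pd.DataFrame) -> MovementModel:
    """Fit IID, OU and OUF movement models to one individual's track and
    return the AICc-best.

    ``track`` needs columns timestamp, x, y. Positions are modelled as a
    stationary bivariate Gaussian process with isotropic variance; OU gives
    exponential position autocorrelation, OUF the smoother two-timescale
    form. Fewer than 5 distinct fix times forces IID.
    """
    track = track.sort_values("timestamp")
    ts = pd.to_datetime(track["timestamp"], utc=True)
    t = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
    xy = track[["x", "y"]].to_numpy(dtype=float)
    n = len(t)

    mu, s2, ll = _iid_fit(t, xy)
    candidates = [
        MovementModel("IID", None, None, s2, tuple(mu), ll, _aicc(ll, 3, n), n)
    ]
    if n >= 5 and len(np.unique(t)) >= 5:
        gaps = np.diff(np.unique(t))
        med_gap = float(np.median(gaps))
        span = float(t[-1] - t[0])

        # OU: 1-D search over log tau
        try:
            res = optimize.minimize_scalar(
                lambda lt: -_ou_profile_loglik(lt, t, xy)[0],
                bounds=(np.log(med_gap / 50), np.log(span * 10)),
                method="bounded",
            )
            ll_ou, mu_ou, s2_ou = _ou_profile_loglik(res.x, t, xy)
            tau = float(np.exp(res.x))
            if np.isfinite(ll_ou):
                candidates.append(
                    MovementModel(
                        "OU", tau, None, s2_ou, tuple(mu_ou), ll_ou,
                        _aicc(ll_ou, 4, n), n,
                    )
                )
        except Exception as exc:  # pragma: no cover - defensive
            log.warning("OU fit failed: %s", exc)

        # OUF: 2-D Nelder-Mead over (log tau_p, logit of tau_v/tau_p)
        def nll_ouf(theta):
            tau_p = np.exp(theta[0])
            ratio = 1.0 / (1.0 + np.exp(-theta[1]))
            corr = _ouf_corr(t, tau_p, ratio * tau_p)
            ll_, _, _ = _gp_profile_loglik(corr, xy)
            return -ll_

        try:
            tau0 = candidates[-1].tau_position or med_gap * 5
            res = optimize.minimize(
                nll_ouf,
                x0=[np.log(tau0), 0.0],
                method="Nelder-Mead",
                options={"maxiter": 60, "xatol": 1e-2, "fatol": 1e-4},
            )
            tau_p = float(np.exp(res.x[0]))
            tau_v = float(tau_p / (1.0 + np.exp(-res.x[1])))
            corr = _ouf_corr(t, tau_p, tau_v)
            ll_f, mu_f, s2_f = _gp_profile_loglik(corr, xy)
            if np.isfinite(ll_f):
                candidates.append(
                    MovementModel(
                        "OUF", tau_p, min(tau_v, 0.999 * tau_p), s2_f,
                        tuple(mu_f), ll_f, _aicc(ll_f, 5, n), n,
                    )
                )
        except Exception as exc:  # pragma: no cover - defensive
            log.warning("OUF fit failed: %s", exc)
    elif n < 5:
        log.info("track with %d fixes: IID forced", n)

    best = min(candidates, key=lambda m: m.aicc)
    return best


# ---------------------------------------------------------------------------
# autocorrelation weights / effective sample size
# ---------------------------------------------------------------------------


@dataclass
class AutocorrWeights:
    weights: np.ndarray  # per-fix, in (0, 1]
    n_eff: float

    def __post_init__(self):
        self.n_eff = float(np.sum(self.weights))


def autocorr_weights(track: pd.DataFrame, model: MovementModel) -> AutocorrWeights:
    """Per-fix effective-independence weights w_i = 1 / sum_j rho(|t_i-t_j|).

    IID reduces to all-ones (N_EFF = N); clustered sampling shares weight so
    that a burst of k coincident fixes carries total weight 1.
    """
    ts = pd.to_datetime(track.sort_values("timestamp")["timestamp"], utc=True)
    t = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
    dt = np.abs(t[:, None] - t[None, :])
    rho = model.rho(dt)
    if model.family != "IID":
        np.fill_diagonal(rho, 1.0)
    w = 1.0 / rho.sum(axis=1)
    return AutocorrWeights(weights=w, n_eff=float(w.sum()))


# ---------------------------------------------------------------------------
# combined model weights
# ---------------------------------------------------------------------------


def combine_weights(design: pd.DataFrame, err: ErrorWeightTable) -> pd.DataFrame:
    """Allocate, combine and rescale the final model weights on a design table.

    ``design`` must contain columns ``individual_id, response (1=GPS, 0=pseudo-
    absence), season, n_sats, ac_weight`` (ac_weight present on response-1
    rows). Per individual and season, the GPS rows share 0.5 * N_EFF_season in
    proportion to their autocorrelation weights and the pseudo-absences share
    0.5 * N_EFF_season evenly; each allocation is multiplied by the row's
    error weight (pseudo-absences take the table's NA weight); finally each
    seasonal dataset is rescaled by a single scalar so its weights sum to its
    row count.

    Returns a copy with columns ``error_weight``, ``alloc_weight`` (audit) and
    ``weight`` (final).
    """
    df = design.reset_index(drop=True).copy()
    use = df["response"] == 1
    ew = np.empty(len(df))
    ew[use.to_numpy()] = err.weight_for(df.loc[use, "n_sats"])
    ew[(~use).to_numpy()] = err.na_weight
    df["error_weight"] = ew

    alloc = np.zeros(len(df))
    for (ind, season), grp in df.groupby(["individual_id", "season"], sort=False):
        g_use = grp[grp["response"] == 1]
        g_abs = grp[grp["response"] == 0]
        if len(g_use) and not len(g_abs):
            raise ValueError(
                f"individual {ind!r} season {season!r} has fixes but no "
                "pseudo-absences: use/availability design mismatch"
            )
        if not len(g_use):
            continue
        w = g_use["ac_weight"].to_numpy(dtype=float)
        if np.isnan(w).any():
            raise ValueError(f"missing ac_weight for {ind!r}/{season!r}")
        n_eff = w.sum()
        if w.sum() > 0:
            alloc[g_use.index.to_numpy()] = 0.5 * n_eff * w / w.sum()
        alloc[g_abs.index.to_numpy()] = 0.5 * n_eff / len(g_abs)
    df["alloc_weight"] = alloc

    raw = df["alloc_weight"] * df["error_weight"]
    final = np.zeros(len(df))
    for season, grp in df.groupby("season", sort=False):
        tot = raw.loc[grp.index].sum()
        if tot > 0:
            final[grp.index.to_numpy()] = (
                raw.loc[grp.index] * (len(grp) / tot)
            ).to_numpy()
    df["weight"] = final
    return df
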