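"""Weighted use-availability logistic resource selection models.

The model compares habitat covariates at telemetry fixes (response 1) against
pseudo-absences sampling the available area (response 0) with a logit link,
maximising the weight-multiplied binomial log-likelihood

    l(beta) = sum_i w_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ],

where the observation weights w_i encode telemetry error and autocorrelation
down-weighting and are rescaled to sum to the row count. Spatial covariates
are signed distance to the seagrass edge (optionally quadratic), depth
(optionally quadratic) and relative temperature (linear only, an a priori
restriction against overparameterisation). Non-spatial factors -- diel period
(night indicator) and body size (SCL, cm) -- enter through interactions with
the spatial covariates, respecting marginality.

The public surface follows the statsmodels idiom:

    model = ResourceSelectionModel.from_design(design_df, spec)
    res = model.fit()
    res.summary(); res.params; res.bse; res.aicc; res.pseudo_r2
    res.type2_anova(); res.predict(scenarios)

Model comparison uses AICc with a three-phase ledger (quadratic structure,
then single-factor interactions, then the second factor plus three-way
terms); Akaike weights summarise relative support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import chain, combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg as sla
from scipy import stats
from scipy.special import expit

__all__ = [
    "ModelSpec",
    "ResourceSelectionModel",
    "RSFResults",
    "aicc",
    "akaike_weights",
    "phased_selection",
    "predict_effects",
    "outermost_interval",
    "predict_spatial",
]

log = logging.getLogger(__name__)

COVARIATE_COLUMNS = {
    "dist": "dist_eelgrass_m",
    "depth": "depth_m",
    "temp": "temp_delta_c",
}
SPATIAL_COVARIATES = ("dist", "depth", "temp")
QUADRATIC_ALLOWED = ("dist", "depth")  # temperature quadratic excluded a priori


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Structure of one candidate RSF.

    ``diel_interactions`` / ``scl_interactions`` name the spatial covariates
    whose whole group (linear + any quadratic) interacts with that factor;
    ``threeway`` names covariates with a covariate x diel x scl term and must
    be a subset of both two-way sets (marginality).
    """

    season: str
    quad_dist: bool = False
    quad_depth: bool = False
    diel_interactions: frozenset = field(default_factory=frozenset)
    scl_interactions: frozenset = field(default_factory=frozenset)
    threeway: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "diel_interactions", frozenset(self.diel_interactions))
        object.__setattr__(self, "scl_interactions", frozenset(self.scl_interactions))
        object.__setattr__(self, "threeway", frozenset(self.threeway))
        for s in (self.diel_interactions, self.scl_interactions, self.threeway):
            unknown = s - set(SPATIAL_COVARIATES)
            if unknown:
                raise ValueError(f"unknown covariates {sorted(unknown)}")
        if not (
            self.threeway <= self.diel_interactions
            and self.threeway <= self.scl_interactions
        ):
            raise ValueError(
                "three-way terms require both two-way interactions (marginality)"
            )

    def quad(self, cov: str) -> bool:
        return (cov == "dist" and self.quad_dist) or (
            cov == "depth" and self.quad_depth
        )

    def label(self) -> str:
        bits = ["dist" + ("+dist^2" if self.quad_dist else ""),
                "depth" + ("+depth^2" if self.quad_depth else ""), "temp"]
        if self.diel_interactions:
            bits.append("diel*{" + ",".join(sorted(self.diel_interactions)) + "}")
        if self.scl_interactions:
            bits.append("scl*{" + ",".join(sorted(self.scl_interactions)) + "}")
        if self.threeway:
            bits.append("diel*scl*{" + ",".join(sorted(self.threeway)) + "}")
        return " + ".join(bits)


def _cov_group(spec: ModelSpec, cov: str) -> list[str]:
    g = [cov]
    if spec.quad(cov):
        g.append(cov + "^2")
    return g


def term_names(spec: ModelSpec) -> list[str]:
    """Ordered design-matrix column names (excluding the intercept)."""
    cols: list[str] = []
    for cov in SPATIAL_COVARIATES:
        cols.extend(_cov_group(spec, cov))
    if spec.diel_interactions:
        cols.append("night")
        for cov in SPATIAL_COVARIATES:
            if cov in spec.diel_interactions:
                cols.extend("night:" + b for b in _cov_group(spec, cov))
    if spec.scl_interactions:
        cols.append("scl")
        for cov in SPATIAL_COVARIATES:
            if cov in spec.scl_interactions:
                cols.extend("scl:" + b for b in _cov_group(spec, cov))
    if spec.threeway:
        cols.append("night:scl")
        for cov in SPATIAL_COVARIATES:
            if cov in spec.threeway:
                cols.extend("night:scl:" + b for b in _cov_group(spec, cov))
    return cols


def _base_columns(df: pd.DataFrame) -> dict[str, np.ndarray]:
    base = {
        cov: df[col].to_numpy(dtype=float) for cov, col in COVARIATE_COLUMNS.items()
    }
    base["night"] = (df["diel"].to_numpy() == "night").astype(float)
    base["scl"] = df["scl_cm"].to_numpy(dtype=float)
    return base


def build_design_matrix(df: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Design matrix (with intercept) for ``spec`` evaluated on ``df``."""
    base = _base_columns(df)

    def column(name: str) -> np.ndarray:
        out = np.ones(len(df))
        for part in name.split(":"):
            if part.endswith("^2"):
                out = out * base[part[:-2]] ** 2
            else:
                out = out * base[part]
        return out

    data = {"const": np.ones(len(df))}
    for name in term_names(spec):
        data[name] = column(name)
    return pd.DataFrame(data, index=df.index)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


def aicc(llf: float, k: int, n: int) -> float:
    """Small-sample corrected AIC; +inf when n <= k + 1."""
    if n <= k + 1:
        log.warning("AICc undefined for n=%d <= k+1=%d; +inf", n, k + 1)
        return float("inf")
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


class ResourceSelectionModel:
    """Weighted binomial GLM for one seasonal use-availability dataset."""

    def __init__(self, endog, exog: pd.DataFrame, weights, spec: ModelSpec | None = None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = exog
        self.weights = np.asarray(weights, dtype=float)
        self.spec = spec
        if np.any(self.weights < 0):
            raise ValueError("negative weights")
        self._check_rank()

    @classmethod
    def from_design(cls, design: pd.DataFrame, spec: ModelSpec) -> "ResourceSelectionModel":
        """Build the model from an annotated, weighted design table.

        Rows are restricted to ``spec.season``; requires columns response,
        weight, diel, scl_cm and the three habitat covariates.
        """
        df = design[design["season"] == spec.season].reset_index(drop=True)
        if not len(df):
            raise ValueError(f"no rows for season {spec.season!r}")
        X = build_design_matrix(df, spec)
        return cls(df["response"], X, df["weight"], spec=spec)

    def _check_rank(self):
        X = self.exog.to_numpy(dtype=float)
        scale = np.linalg.norm(X, axis=0)
        scale[scale == 0] = 1.0
        r = np.linalg.matrix_rank(X / scale)
        if r < X.shape[1]:
            # name aliased columns via pivoted QR diagonal
            _, Rm, piv = sla.qr(X / scale, pivoting=True)
            diag = np.abs(np.diag(Rm))
            bad = [self.exog.columns[piv[i]] for i in range(len(diag)) if diag[i] < 1e-8 * diag[0]]
            bad += [self.exog.columns[p] for p in piv[len(diag):]]
            raise ValueError(f"singular design matrix; aliased columns: {bad}")

    def fit(self, tol: float = 1e-10, maxiter: int = 100) -> "RSFResults":
        X = self.exog.to_numpy(dtype=float)
        # column scaling (no centering): conditioning only, back-transformed
        scale = X.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
        Xs = X / scale

        glm = sm.GLM(
            self.endog, Xs, family=sm.families.Binomial(), freq_weights=self.weights
        )
        res = glm.fit(maxiter=maxiter, tol=tol)
        params_s = res.params
        if np.any(np.abs(params_s[1:]) > 20):
            log.warning("possible separation: |standardized beta| > 20")

        params = params_s / scale
        cov = res.cov_params() / np.outer(scale, scale)
        return RSFResults(
            model=self,
            params=pd.Series(params, index=self.exog.columns),
            cov=pd.DataFrame(cov, index=self.exog.columns, columns=self.exog.columns),
            llf=float(res.llf),
            converged=bool(res.converged),
        )


@dataclass
class RSFResults:
    """Fitted weighted RSF: coefficients, covariance, fit statistics."""

    model: ResourceSelectionModel
    params: pd.Series
    cov: pd.DataFrame
    llf: float
    converged: bool

    @property
    def k(self) -> int:
        return len(self.params)

    @property
    def n(self) -> int:
        return len(self.model.endog)

    @property
    def aicc(self) -> float:
        return aicc(self.llf, self.k, self.n)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def cov_params(self) -> pd.DataFrame:
        return self.cov

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    # -- prediction ---------------------------------------------------------

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        X = X[self.params.index]
        return X.to_numpy(dtype=float) @ self.params.to_numpy()

    def predict(self, scenarios: pd.DataFrame, interval: bool = False, alpha: float = 0.05):
        """Predicted probability of use for scenario rows (covariates +
        diel + scl_cm); optional Wald interval on the link scale mapped
        through the inverse logit."""
        X = build_design_matrix(scenarios, self.model.spec)
        eta = self.linear_predictor(X)
        p = expit(eta)
        if not interval:
            return p
        Xv = X[self.params.index].to_numpy(dtype=float)
        se = np.sqrt(np.einsum("ij,jk,ik->i", Xv, self.cov.to_numpy(), Xv))
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"p": p, "lower": expit(eta - z * se), "upper": expit(eta + z * se)}
        )

    # -- fit statistics -----------------------------------------------------

    @property
    def pseudo_r2(self) -> float:
        """Variance-function based coefficient of determination for GLMs.

        R^2_V = 1 - sum w (y - p)^2 / V(p)  /  sum w (y - pbar)^2 / V(pbar)
        with binomial variance V(p) = p(1-p); the null probability pbar comes
        from a weighted intercept-only fit (the weighted mean response).
        """
        y = self.model.endog
        w = self.model.weights
        eps = 1e-12
        p = np.clip(expit(self.linear_predictor(self.model.exog)), eps, 1 - eps)
        pbar = np.clip(np.average(y, weights=w), eps, 1 - eps)
        num = np.sum(w * (y - p) ** 2 / (p * (1 - p)))
        den = np.sum(w * (y - pbar) ** 2 / (pbar * (1 - pbar)))
        return float(1.0 - num / den)

    def type2_anova(self) -> pd.DataFrame:
        """Type II analysis of deviance: per-term likelihood-ratio tests.

        Each term is tested against the model containing all other terms of
        equal or lower order but excluding its higher-order relatives (terms
        whose factor set strictly contains the tested term's factors), via
        explicit refits. df = 1 per column term.
        """
        cols = [c for c in self.params.index if c != "const"]

        def factors(name: str) -> frozenset:
            return frozenset(name.split(":"))

        rows = []
        for term in cols:
            f = factors(term)
            relatives = [c for c in cols if c != term and factors(c) > f]
            keep_full = ["const"] + [c for c in cols if c not in relatives]
            keep_red = [c for c in keep_full if c != term]
            try:
                ll_full = self._refit_llf(keep_full)
                ll_red = self._refit_llf(keep_red)
                lr = max(2.0 * (ll_full - ll_red), 0.0)
                p = float(stats.chi2.sf(lr, df=1))
                rows.append({"term": term, "lr_chi2": lr, "df": 1, "p_value": p})
            except Exception as exc:
                log.warning("term %s untestable: %s", term, exc)
                rows.append(
                    {"term": term, "lr_chi2": np.nan, "df": 1, "p_value": np.nan}
                )
        return pd.DataFrame(rows).set_index("term")

    def _refit_llf(self, columns: list[str]) -> float:
        sub = ResourceSelectionModel(
            self.model.endog, self.model.exog[columns], self.model.weights,
            spec=self.model.spec,
        )
        return sub.fit().llf

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "Weighted use-availability logistic RSF",
            "=" * 62,
            f"season: {spec.season if spec else '-'}   n rows: {self.n}   "
            f"k: {self.k}   converged: {self.converged}",
            f"log-likelihood (weighted): {self.llf:.3f}   AICc: {self.aicc:.3f}",
            f"pseudo-R2 (variance-function): {self.pseudo_r2:.4f}",
            "-" * 62,
            f"{'term':<22}{'coef':>12}{'se':>11}{'z':>8}{'p':>9}",
        ]
        for name in self.params.index:
            b = self.params[name]
            se = self.bse[name]
            z = b / se if se > 0 else np.nan
            p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            lines.append(f"{name:<22}{b:>12.4g}{se:>11.3g}{z:>8.2f}{p:>9.3g}")
        lines.append("=" * 62)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------


def akaike_weights(table: pd.DataFrame, aicc_col: str = "aicc") -> pd.DataFrame:
    """Add delta-AICc and normalized Akaike weights to a comparison table."""
    out = table.copy()
    delta = out[aicc_col] - out[aicc_col].min()
    out["delta_aicc"] = delta
    rel = np.exp(-delta / 2.0)
    out["akaike_weight"] = rel / rel.sum()
    return out


def _subsets(items):
    items = sorted(items)
    return chain.from_iterable(combinations(items, r) for r in range(1, len(items) + 1))


def phased_selection(
    design: pd.DataFrame, season: str
) -> tuple[RSFResults, pd.DataFrame]:
    """Three-phase AICc comparison returning the final fit and the ledger.

    Phase 1 toggles the two candidate quadratic terms (4 models, all three
    spatial covariates always present). Phase 2 adds, to the phase-1 winner,
    every nonempty subset of covariate x factor interactions for one factor
    at a time (diel, then body size). Phase 3 starts from the phase-2 winner,
    adds the second factor's interactions on the winning covariate set and
    explores three-way (covariate x diel x scl) subsets under marginality.
    The final model is the AICc-best over the whole ledger (about 25 models
    per season).
    """
    ledger: list[dict] = []
    fits: dict[ModelSpec, RSFResults] = {}

    def evaluate(spec: ModelSpec, phase: str):
        if spec in fits:
            return fits[spec]
        try:
            res = ResourceSelectionModel.from_design(design, spec).fit()
        except Exception as exc:
            log.warning("model %s dropped: %s", spec.label(), exc)
            return None
        if not res.converged:
            log.warning("model %s dropped: non-convergent", spec.label())
            return None
        fits[spec] = res
        ledger.append(
            {"phase": phase, "spec": spec, "formula": spec.label(),
             "k": res.k, "aicc": res.aicc}
        )
        return res

    # phase 1: quadratic structure
    phase1 = [
        ModelSpec(season=season, quad_dist=qd, quad_depth=qp)
        for qd in (False, True)
        for qp in (False, True)
    ]
    p1 = [(s, evaluate(s, "1")) for s in phase1]
    p1 = [(s, r) for s, r in p1 if r is not None]
    base_spec = min(p1, key=lambda sr: sr[1].aicc)[0]

    # phase 2: single-factor interaction subsets
    for factor in ("diel", "scl"):
        for subset in _subsets(SPATIAL_COVARIATES):
            kw = {f"{factor}_interactions": frozenset(subset)}
            evaluate(replace(base_spec, **kw), "2")
    p2_pool = [e for e in ledger if e["phase"] in ("1", "2")]
    p2_spec = min(p2_pool, key=lambda e: e["aicc"])["spec"]

    # phase 3: second factor + three-way terms
    if p2_spec.diel_interactions or p2_spec.scl_interactions:
        f1_set = p2_spec.diel_interactions or p2_spec.scl_interactions
        other = "scl" if p2_spec.diel_interactions else "diel"
        base3 = replace(p2_spec, **{f"{other}_interactions": f1_set})
        evaluate(base3, "3")
        for tw in _subsets(f1_set):
            evaluate(replace(base3, threeway=frozenset(tw)), "3")
    else:
        # no interaction improved phase 2: still probe joint two-factor models
        for subset in _subsets(SPATIAL_COVARIATES):
            evaluate(
                replace(
                    base_spec,
                    diel_interactions=frozenset(subset),
                    scl_interactions=frozenset(subset),
                ),
                "3",
            )

    table = pd.DataFrame(ledger)
    table = akaike_weights(table).sort_values("aicc").reset_index(drop=True)
    best_spec = table.loc[0, "spec"]
    return fits[best_spec], table


# ---------------------------------------------------------------------------
# effect curves and spatial prediction
# ---------------------------------------------------------------------------


def predict_effects(
    res: RSFResults,
    design: pd.DataFrame,
    varied: str,
    diel: str = "day",
    scl_cm: float | None = None,
    n_grid: int = 100,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Effect curve: vary one covariate over its observed range, hold the
    others at their means, for a given diel period and body size."""
    df = design[design["season"] == res.model.spec.season]
    col = COVARIATE_COLUMNS[varied]
    grid = np.linspace(df[col].min(), df[col].max(), n_grid)
    scen = pd.DataFrame(
        {c: np.full(n_grid, df[c].mean()) for c in COVARIATE_COLUMNS.values()}
    )
    scen[col] = grid
    scen["diel"] = diel
    scen["scl_cm"] = scl_cm if scl_cm is not None else df["scl_cm"].mean()
    out = res.predict(scen, interval=True, alpha=alpha)
    out.insert(0, col, grid)
    out.insert(1, "diel", diel)
    out.insert(2, "scl_cm", scen["scl_cm"].iloc[0])
    return out


def outermost_interval(curves: list[pd.DataFrame]) -> pd.DataFrame:
    """Pointwise outermost 95% interval across a set of scenario curves
    (min of lower bounds, max of upper bounds)."""
    lower = np.min([c["lower"].to_numpy() for c in curves], axis=0)
    upper = np.max([c["upper"].to_numpy() for c in curves], axis=0)
    return pd.DataFrame({"lower": lower, "upper": upper})


def predict_spatial(
    res: RSFResults,
    dist_raster,
    depth_raster,
    temp_raster,
    diel: str,
    scl_cm: float,
    availability=None,
    alpha: float = 0.05,
):
    """Per-cell probability-of-use raster with interval rasters.

    All rasters must be aligned; cells outside the availability polygon (if
    given) are masked to NaN.
    """
    import shapely

    from .raster import Raster

    for r in (depth_raster, temp_raster):
        if not dist_raster.aligned_with(r):
            raise ValueError("habitat rasters are misaligned")
    shape = dist_raster.values.shape
    cells = pd.DataFrame(
        {
            "dist_eelgrass_m": dist_raster.values.ravel(),
            "depth_m": depth_raster.values.ravel(),
            "temp_delta_c": temp_raster.values.ravel(),
            "diel": diel,
            "scl_cm": scl_cm,
        }
    )
    ok = ~cells[["dist_eelgrass_m", "depth_m", "temp_delta_c"]].isna().any(axis=1)
    pred = pd.DataFrame(
        np.nan, index=cells.index, columns=["p", "lower", "upper"]
    )
    pred.loc[ok] = res.predict(cells[ok], interval=True, alpha=alpha).to_numpy()

    if availability is not None:
        X, Y = dist_raster.cell_centers()
        inside = shapely.contains_xy(availability, X.ravel(), Y.ravel())
        pred.loc[~inside] = np.nan

    def as_raster(colname):
        return Raster(
            values=pred[colname].to_numpy().reshape(shape),
            x0=dist_raster.x0, y0=dist_raster.y0, cell=dist_raster.cell,
        )

    return as_raster("p"), as_raster("lower"), as_raster("upper")
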