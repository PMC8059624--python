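"""Mixed-effect decomposition of functional dispersion trends.

Rao's Q is modelled as Q ~ S + J + FRic with survey year as a random
intercept, following the idea that changes in functional dispersion can
be attributed to species richness, evenness and functional richness, or
remain unexplained (pointing to trait turnover instead).  Optionally the
residuals carry an exponential spatial correlation on great-circle
distance, nested by region, as ecosystem-survey stations close together
are not independent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)

PREDICTORS = ("S", "J", "FRic")
RESPONSE = "Q"
EARTH_RADIUS_KM = 6371.0


@dataclass
class ModelFit:
    """Fixed-effect estimates and variance components of one fit."""

    scope: str
    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    year_var: float
    resid_var: float
    r2: float
    n_stations: int
    n_years: int
    spatial: bool = False
    spatial_range_km: float | None = None
    fitted: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)
    residuals: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "scope": self.scope,
                "term": t,
                "estimate": self.params[t],
                "se": self.bse[t],
                "p": self.pvalues[t],
                "r2": self.r2,
                "n_stations": self.n_stations,
                "n_years": self.n_years,
            }
            for t in self.params
        ]
        return pd.DataFrame(rows)


def _design(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    for c in PREDICTORS + (RESPONSE,):
        if table[c].isna().any():
            raise ValueError(f"missing values in {c!r}")
    X = np.column_stack(
        [np.ones(len(table))] + [table[c].to_numpy(dtype=float) for c in PREDICTORS]
    )
    y = table[RESPONSE].to_numpy(dtype=float)
    return X, y, ["intercept", *PREDICTORS]


def _check_collinearity(table: pd.DataFrame) -> None:
    sub = table[list(PREDICTORS)].to_numpy(dtype=float)
    sd = sub.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub, rowvar=False)
    for i in range(len(PREDICTORS)):
        for j in range(i + 1, len(PREDICTORS)):
            c = corr[i, j]
            if sd[i] == 0 or sd[j] == 0 or (np.isfinite(c) and abs(c) > 1 - 1e-10):
                raise ValueError(
                    f"collinear predictors: ({PREDICTORS[i]}, {PREDICTORS[j]})"
                )


def _wald_p(est: np.ndarray, se: np.ndarray) -> np.ndarray:
    z = est / se
    return 2 * stats.norm.sf(np.abs(z))


def haversine_km(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distance (km) between stations."""
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float))
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def _ols_fit(table: pd.DataFrame, scope: str) -> ModelFit:
    X, y, names = _design(table)
    res = sm.OLS(y, X).fit()
    fitted = res.fittedvalues
    r2 = _r2(fitted, y)
    return ModelFit(
        scope=scope,
        params=dict(zip(names, res.params)),
        bse=dict(zip(names, res.bse)),
        pvalues=dict(zip(names, _wald_p(res.params, res.bse))),
        year_var=0.0,
        resid_var=float(res.scale),
        r2=r2,
        n_stations=len(y),
        n_years=int(table["year"].nunique()),
        fitted=fitted,
        residuals=y - fitted,
    )


def _r2(fitted: np.ndarray, observed: np.ndarray) -> float:
    if np.std(fitted) == 0 or np.std(observed) == 0:
        return 0.0
    return float(np.corrcoef(fitted, observed)[0, 1] ** 2)


def _spatial_fit(table: pd.DataFrame, scope: str) -> ModelFit:
    """Profiled-ML linear mixed model with exponential spatial residuals.

    y = X b + u_year + e; cov(e_i, e_j) = s2 * exp(-d_ij / rho) for
    stations in the same year and region (d great-circle km), 0 across
    regions; u_year ~ N(0, g * s2) shared within a year.  b and s2 are
    profiled out; (log g, log rho) maximized numerically.
    """
    X, y, names = _design(table)
    years = table["year"].to_numpy()
    n = len(y)
    blocks = []  # per-year: (row indices, spatial distance matrix masked by region)
    for yr in np.unique(years):
        idx = np.flatnonzero(years == yr)
        sub = table.iloc[idx]
        d = haversine_km(sub["lat"].to_numpy(), sub["lon"].to_numpy())
        reg = sub["region"].to_numpy()
        same = reg[:, None] == reg[None, :]
        blocks.append((idx, d, same))

    def neg_profile_ll(theta):
        g, rho = np.exp(theta)
        quad = 0.0
        logdet = 0.0
        xtvx = np.zeros((X.shape[1], X.shape[1]))
        xtvy = np.zeros(X.shape[1])
        pieces = []
        for idx, d, same in blocks:
            R = np.where(same, np.exp(-d / rho), 0.0)
            np.fill_diagonal(R, 1.0)
            V = R + g  # random year intercept adds g to every entry of the block
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return 1e12
            logdet += 2 * np.log(np.diag(L)).sum()
            Xi, yi = X[idx], y[idx]
            Vx = np.linalg.solve(L, Xi)
            Vy = np.linalg.solve(L, yi)
            xtvx += Vx.T @ Vx
            xtvy += Vx.T @ Vy
            pieces.append((L, Xi, yi))
        beta = np.linalg.solve(xtvx, xtvy)
        for L, Xi, yi in pieces:
            r = np.linalg.solve(L, yi - Xi @ beta)
            quad += r @ r
        s2 = quad / n
        return 0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)

    res = optimize.minimize(
        neg_profile_ll, x0=np.log([0.5, 100.0]), method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
    )
    g, rho = np.exp(res.x)
    # final GLS pass at the optimum
    xtvx = np.zeros((X.shape[1], X.shape[1]))
    xtvy = np.zeros(X.shape[1])
    pieces = []
    for idx, d, same in blocks:
        R = np.where(same, np.exp(-d / rho), 0.0)
        np.fill_diagonal(R, 1.0)
        L = np.linalg.cholesky(R + g)
        Xi, yi = X[idx], y[idx]
        Vx = np.linalg.solve(L, Xi)
        Vy = np.linalg.solve(L, yi)
        xtvx += Vx.T @ Vx
        xtvy += Vx.T @ Vy
        pieces.append((L, Xi, yi, idx))
    beta = np.linalg.solve(xtvx, xtvy)
    quad = sum(
        float(np.linalg.solve(L, yi - Xi @ beta) @ np.linalg.solve(L, yi - Xi @ beta))
        for L, Xi, yi, _ in pieces
    )
    s2 = quad / n
    cov_b = s2 * np.linalg.inv(xtvx)
    se = np.sqrt(np.diag(cov_b))
    fitted = X @ beta
    return ModelFit(
        scope=scope,
        params=dict(zip(names, beta)),
        bse=dict(zip(names, se)),
        pvalues=dict(zip(names, _wald_p(beta, se))),
        year_var=float(g * s2),
        resid_var=float(s2),
        r2=_r2(fitted, y),
        n_stations=n,
        n_years=int(table["year"].nunique()),
        spatial=True,
        spatial_range_km=float(rho),
        fitted=fitted,
        residuals=y - fitted,
    )


def fit_dispersion_model(
    table: pd.DataFrame, scope: str = "all", spatial: bool = False
) -> ModelFit:
    """Fit Q ~ S + J + FRic with a random year intercept (ML).

    ``table`` needs per-station columns Q, S, J, FRic, year, region, lat,
    lon.  ``scope`` is 'all' or a region label to subset.  With fewer
    than 3 year levels the model degrades to a fixed-intercept OLS fit
    (warned).  r2 is the squared correlation between the fixed-effect
    fitted values and the observed response.
    """
    if scope != "all":
        table = table[table["region"] == scope]
    table = table.reset_index(drop=True)
    if len(table) < 10:
        raise ValueError(f"scope {scope!r}: fewer than 10 stations")
    _check_collinearity(table)
    n_years = int(table["year"].nunique())
    if n_years < 3:
        logger.warning(
            "scope %r has %d year level(s); degrading to fixed-intercept OLS",
            scope, n_years,
        )
        return _ols_fit(table, scope)
    if spatial:
        return _spatial_fit(table, scope)
    X, y, names = _design(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary year-variance warnings
        model = sm.MixedLM(y, X, groups=table["year"].to_numpy())
        res = model.fit(reml=False)
    fitted = X @ res.fe_params
    return ModelFit(
        scope=scope,
        params=dict(zip(names, res.fe_params)),
        bse=dict(zip(names, res.bse_fe)),
        pvalues=dict(zip(names, _wald_p(res.fe_params, np.asarray(res.bse_fe)))),
        year_var=float(np.asarray(res.cov_re).ravel()[0]),
        resid_var=float(res.scale),
        r2=_r2(fitted, y),
        n_stations=len(y),
        n_years=n_years,
        fitted=fitted,
        residuals=y - fitted,
    )


def region_specific_fits(
    table: pd.DataFrame, spatial: bool = False
) -> dict[str, ModelFit]:
    """One fit per region label; regions with < 10 stations are skipped."""
    fits: dict[str, ModelFit] = {}
    for region in sorted(table["region"].unique()):
        sub = table[table["region"] == region]
        if len(sub) < 10:
            logger.warning("region %r has %d stations; skipped", region, len(sub))
            continue
        fits[region] = fit_dispersion_model(table, scope=region, spatial=spatial)
    return fits


def model_summary_table(fits: list[ModelFit]) -> pd.DataFrame:
    """Concatenate fits into the model_summary.csv layout."""
    return pd.concat([f.summary_frame() for f in fits], ignore_index=True)
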