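"""Standardization, robust regression and bootstrap confidence intervals.

Recruitment, SI and SST are min–max scaled *within each area* so the three
ecosystems can be pooled into one dataset despite order-of-magnitude
differences in absolute abundance.  The response is ``ln(1 + scaled
recruitment)`` and therefore lives in [0, ln 2].  The pooled model

    y = β₀ + β_SI · SI_scaled + β_SST · SST_scaled + ε

is fit by Huber M-estimation (iteratively reweighted least squares), and the
uncertainty of each coefficient is summarized by three interval families
computed from a random-X (case resampling) bootstrap: the first-order normal
approximation, the bootstrap percentile interval, and the bias-corrected and
accelerated (BCa) percentile interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CollinearityError,
    DegenerateRangeError,
    DegenerateScaleError,
    UnstableBootstrapError,
    ValidationError,
)
from .pbcor import SIEstimate, percentile_from_sorted
from .timeseries import RecruitmentSeries

logger = logging.getLogger(__name__)

COEF_NAMES = ("Intercept", "SI", "SST")

#: MAD-to-sigma consistency factor for Gaussian residuals
_MAD_SCALE = 1.4826


@dataclass(frozen=True)
class ScaledVariable:
    """A vector min–max scaled to [0, 1] within one area, invertibly."""

    source_name: str
    area_id: str
    values: np.ndarray
    original_min: float
    original_max: float

    def invert(self) -> np.ndarray:
        return self.original_min + self.values * (self.original_max - self.original_min)


def min_max_scale(values, name: str, area_id: str) -> ScaledVariable:
    """Scale to [0, 1] by subtracting the minimum and dividing by the range."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValidationError(f"min_max_scale({name}/{area_id}) needs >= 2 values")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise DegenerateRangeError(
            f"{name}/{area_id}: constant vector, min-max scaling undefined"
        )
    return ScaledVariable(name, area_id, (x - lo) / (hi - lo), lo, hi)


def build_regression_table(
    recruits: list[RecruitmentSeries],
    si: list[SIEstimate],
    sst_means: dict[tuple[str, int], float],
) -> pd.DataFrame:
    """Pool per-area standardized rows into one regression table.

    For each area the years with recruitment, SI and SST all present are
    retained (others are dropped and logged); recruitment, SI (the rho
    values) and SST are each min–max scaled within the area, and the response
    is ``ln(1 + scaled recruitment)``.  An area with fewer than two complete
    years makes scaling undefined and is an error.
    """
    si_by_area: dict[str, dict[int, float]] = {}
    for est in si:
        si_by_area.setdefault(est.area_id, {})[est.recruit_year] = est.rho_pb

    rows = []
    for rec in recruits:
        area = rec.area_id
        si_years = si_by_area.get(area, {})
        complete = [
            y for y in rec.years if y in si_years and (area, y) in sst_means
        ]
        dropped = sorted(set(rec.years) - set(complete))
        if dropped:
            logger.warning("%s: dropped years missing SI or SST: %s", area, dropped)
        if len(complete) < 2:
            raise ValidationError(
                f"area {area} has {len(complete)} complete year(s); scaling needs >= 2"
            )
        rec_scaled = min_max_scale(
            [rec.records[y] for y in complete], "recruitment", area
        )
        si_scaled = min_max_scale([si_years[y] for y in complete], "SI", area)
        sst_scaled = min_max_scale(
            [sst_means[(area, y)] for y in complete], "SST", area
        )
        y_resp = np.log1p(rec_scaled.values)
        for i, year in enumerate(complete):
            rows.append(
                {
                    "area_id": area,
                    "recruit_year": year,
                    "y": y_resp[i],
                    "si_scaled": si_scaled.values[i],
                    "sst_scaled": sst_scaled.values[i],
                }
            )
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.sort_values(["area_id", "recruit_year"]).reset_index(drop=True)
    return table


@dataclass
class RobustFit:
    """Result of the Huber IRLS fit."""

    coefficients: np.ndarray  # (intercept, slope_si, slope_sst)
    scale: float
    weights: np.ndarray
    converged: bool
    iterations: int
    residuals: np.ndarray
    fitted: np.ndarray


def _design(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = np.column_stack(
        [
            np.ones(len(table)),
            table["si_scaled"].to_numpy(dtype=float),
            table["sst_scaled"].to_numpy(dtype=float),
        ]
    )
    y = table["y"].to_numpy(dtype=float)
    return X, y


def _irls_huber(
    X: np.ndarray,
    y: np.ndarray,
    tuning_k: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float, np.ndarray, bool, int]:
    """Huber M-estimation by iteratively reweighted least squares.

    The residual scale is the MAD about the residual median, rescaled by
    1.4826, recomputed at every iteration.  An (almost) exact fit — scale
    below machine noise — terminates immediately with unit weights.
    """
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise CollinearityError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    weights = np.ones(n)
    sigma = 0.0
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        resid = y - X @ beta
        sigma = _MAD_SCALE * float(np.median(np.abs(resid - np.median(resid))))
        if sigma < 1e-12:
            weights = np.ones(n)
            converged = True
            break
        u = np.abs(resid) / sigma
        weights = np.where(u <= tuning_k, 1.0, tuning_k / np.maximum(u, 1e-300))
        sw = np.sqrt(weights)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        delta = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        if delta < tol:
            converged = True
            break
    return beta, sigma, weights, converged, iterations


def fit_robust(
    table: pd.DataFrame,
    tuning_k: float = 1.345,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> RobustFit:
    """Fit the pooled robust regression of y on scaled SI and SST.

    Default tuning constant k = 1.345 gives 95% efficiency at the Gaussian
    model.  Non-convergence returns the last iterate with
    ``converged=False`` and a warning rather than raising.
    """
    if len(table) < 4:
        raise ValidationError("robust fit needs at least 4 rows")
    X, y = _design(table)
    beta, sigma, weights, converged, iterations = _irls_huber(
        X, y, tuning_k, tol, max_iter
    )
    if not converged:
        logger.warning("robust fit did not converge in %d iterations", iterations)
    fitted = X @ beta
    return RobustFit(
        coefficients=beta,
        scale=sigma,
        weights=weights,
        converged=converged,
        iterations=iterations,
        residuals=y - fitted,
        fitted=fitted,
    )


@dataclass
class CoefficientCIs:
    """Normal, percentile and BCa intervals per coefficient from a case bootstrap."""

    names: tuple[str, ...]
    estimates: np.ndarray
    normal: np.ndarray  # (p, 2)
    percentile: np.ndarray
    bca: np.ndarray
    n_boot: int
    seed: int
    replicates: np.ndarray = field(repr=False)  # (B_kept, p)

    def significant(self, family: str) -> np.ndarray:
        band = getattr(self, family)
        return (band[:, 0] > 0.0) | (band[:, 1] < 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for family in ("normal", "percentile", "bca"):
            band = getattr(self, family)
            sig = self.significant(family)
            for j, name in enumerate(self.names):
                rows.append(
                    {
                        "coefficient": name,
                        "estimate": self.estimates[j],
                        "family": family,
                        "ci_low": band[j, 0],
                        "ci_high": band[j, 1],
                        "significant": bool(sig[j]),
                    }
                )
        return pd.DataFrame(rows)


def _bca_interval(
    reps: np.ndarray, estimate: float, jack: np.ndarray, alpha: float
) -> tuple[float, float]:
    """BCa interval for one coefficient from sorted replicates.

    z0 comes from the fraction of replicates below the point estimate,
    the acceleration from the jackknife skewness of leave-one-out estimates.
    """
    b = len(reps)
    if np.ptp(reps) <= 0.0:
        return estimate, estimate
    prop = np.count_nonzero(reps < estimate) / b
    prop = min(max(prop, 1.0 / (b + 1)), b / (b + 1.0))
    z0 = stats.norm.ppf(prop)
    d = np.mean(jack) - jack
    denom = np.sum(d * d) ** 1.5
    accel = 0.0 if denom <= 0.0 else float(np.sum(d**3) / (6.0 * denom))
    out = []
    for z_a in (stats.norm.ppf(alpha), stats.norm.ppf(1.0 - alpha)):
        adj = z0 + (z0 + z_a) / (1.0 - accel * (z0 + z_a))
        out.append(percentile_from_sorted(reps, float(stats.norm.cdf(adj))))
    return out[0], out[1]


def bootstrap_cis(
    table: pd.DataFrame,
    tuning_k: float = 1.345,
    tol: float = 1e-8,
    max_iter: int = 50,
    n_boot: int = 2999,
    conf_level: float = 0.95,
    seed: int = 0,
    stratify_by_area: bool = False,
) -> CoefficientCIs:
    """Random-X bootstrap of the robust fit with three interval families.

    Whole observation rows are resampled with replacement (pooled across
    areas by default, within each area when ``stratify_by_area``), the Huber
    fit is recomputed on each resample, and the coefficient replicates yield
    the Normal (Gaussian quantile), percentile (order statistics) and BCa
    intervals.  Resamples whose design is rank deficient are skipped; more
    than 10% of failures aborts.
    """
    if n_boot < 1:
        raise ValidationError(f"n_boot must be >= 1, got {n_boot}")
    X, y = _design(table)
    n, p = X.shape
    point, *_ = _irls_huber(X, y, tuning_k, tol, max_iter)

    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    if stratify_by_area:
        groups = [
            np.flatnonzero((table["area_id"] == a).to_numpy())
            for a in table["area_id"].unique()
        ]
    reps = np.empty((n_boot, p))
    failed = 0
    kept = 0
    for _ in range(n_boot):
        if stratify_by_area:
            idx = np.concatenate([g[rng.integers(0, len(g), len(g))] for g in groups])
        else:
            idx = rng.integers(0, n, n)
        try:
            beta_b, *_ = _irls_huber(X[idx], y[idx], tuning_k, tol, max_iter)
        except CollinearityError:
            failed += 1
            continue
        reps[kept] = beta_b
        kept += 1
    if failed:
        logger.warning("skipped %d rank-deficient bootstrap resamples", failed)
    if failed > 0.10 * n_boot:
        raise UnstableBootstrapError(f"{failed}/{n_boot} bootstrap refits failed")
    reps = reps[:kept]

    jack = np.empty((n, p))
    for i in range(n):
        mask = np.arange(n) != i
        jack[i], *_ = _irls_huber(X[mask], y[mask], tuning_k, tol, max_iter)

    alpha = (1.0 - conf_level) / 2.0
    z = stats.norm.ppf(1.0 - alpha)
    sd = reps.std(axis=0, ddof=1) if kept > 1 else np.zeros(p)
    normal = np.column_stack([point - z * sd, point + z * sd])
    percentile = np.empty((p, 2))
    bca = np.empty((p, 2))
    for j in range(p):
        srt = np.sort(reps[:, j])
        percentile[j] = (
            percentile_from_sorted(srt, alpha),
            percentile_from_sorted(srt, 1.0 - alpha),
        )
        bca[j] = _bca_interval(srt, float(point[j]), jack[:, j], alpha)

    return CoefficientCIs(
        names=COEF_NAMES,
        estimates=point,
        normal=normal,
        percentile=percentile,
        bca=bca,
        n_boot=n_boot,
        seed=int(seed),
        replicates=reps,
    )


def pearson_screen(si_by_year, sst_by_year) -> tuple[float, float]:
    """Classical Pearson correlation between annual SI and SST with its p-value.

    Used as a preliminary collinearity screen before entering both
    predictors in the regression.
    """
    x = np.asarray(si_by_year, dtype=float)
    y = np.asarray(sst_by_year, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("pearson_screen needs equal-length vectors, n >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DegenerateScaleError("pearson_screen: zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class DiagnosticsReport:
    """Residual checks: normality, variance homogeneity, independence."""

    degenerate: bool
    note: str
    normality_p: float | None
    hetero_corr: float | None
    hetero_p: float | None
    lag1_by_area: dict[str, float]
    residual_table: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"check": "normality_shapiro_p", "value": self.normality_p},
            {"check": "abs_resid_vs_fitted_corr", "value": self.hetero_corr},
            {"check": "abs_resid_vs_fitted_p", "value": self.hetero_p},
        ]
        for area, r1 in self.lag1_by_area.items():
            rows.append({"check": f"lag1_autocorr_{area}", "value": r1})
        frame = pd.DataFrame(rows)
        frame["note"] = self.note
        return frame


def residual_diagnostics(fit: RobustFit, table: pd.DataFrame) -> DiagnosticsReport:
    """Check residuals for normality, homoscedasticity and independence.

    Normality: Shapiro-Wilk on the residuals.  Homogeneity: Pearson
    correlation of |residual| with fitted values.  Independence: lag-1
    autocorrelation of residuals within each area, in year order.  An
    exact fit (zero residual variance) is flagged as degenerate instead of
    producing meaningless numbers.
    """
    resid = fit.residuals
    if len(resid) < 5:
        raise ValidationError("diagnostics need at least 5 residuals")
    residual_table = table[["area_id", "recruit_year"]].copy()
    residual_table["fitted"] = fit.fitted
    residual_table["residual"] = resid
    residual_table["weight"] = fit.weights

    if float(np.ptp(resid)) < 1e-12:
        return DiagnosticsReport(
            degenerate=True,
            note="degenerate: zero residual variance",
            normality_p=None,
            hetero_corr=None,
            hetero_p=None,
            lag1_by_area={},
            residual_table=residual_table,
        )

    normality_p = float(stats.shapiro(resid).pvalue)
    if np.ptp(fit.fitted) > 0:
        het = stats.pearsonr(np.abs(resid), fit.fitted)
        hetero_corr, hetero_p = float(het.statistic), float(het.pvalue)
    else:
        hetero_corr, hetero_p = 0.0, 1.0

    lag1: dict[str, float] = {}
    for area, sub in residual_table.groupby("area_id", sort=True):
        r = sub.sort_values("recruit_year")["residual"].to_numpy()
        if len(r) >= 3 and np.ptp(r[:-1]) > 0 and np.ptp(r[1:]) > 0:
            lag1[str(area)] = float(np.corrcoef(r[:-1], r[1:])[0, 1])
    return DiagnosticsReport(
        degenerate=False,
        note="",
        normality_p=normality_p,
        hetero_corr=hetero_corr,
        hetero_p=hetero_p,
        lag1_by_area=lag1,
        residual_table=residual_table,
    )
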