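"""Developmental-trend and time-trend estimation for Wi.

Developmental trends compare Wi across trees of different age/size sampled at
one time point (so all outer rings formed under the same atmosphere); time
trends look backwards along the ring series of individual dominant trees.
The central scientific point is that the two can coincide numerically while
having entirely different causes, so both estimators live here side by side.

Conventions
-----------
* Tabular input is a pandas DataFrame with columns ``wi_ppm`` plus whichever
  predictors are used: ``age_years``, ``height_m``, ``dbh_cm``,
  ``cii_ordinal``, ``calendar_year``, and optionally ``species`` /
  ``tree_id`` grouping columns.
* Slopes are reported in the field's units: ppm per 100 yr for age and
  calendar year, ppm per 10 m for height, ppm per 10 cm for diameter, ppm
  per ordinal step for crown illumination. Raw per-unit slopes are retained
  on the fit objects.
* Smooth curves are penalized cubic B-splines (second-difference penalty)
  with the penalty weight chosen by generalized cross-validation; pointwise
  standard-error bands come from the linear-smoother covariance. A per-group
  constant offset (random-intercept surrogate) is absorbed by backfitting
  before smoothing when group ids are supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline, make_smoothing_spline

__all__ = [
    "TrendFit",
    "SmoothFit",
    "ModelSelectionResult",
    "TimeTrendResult",
    "PREDICTOR_COLUMNS",
    "UNIT_SCALE",
    "UNIT_LABEL",
    "DegenerateDesignError",
    "significance_stars",
    "linear_trend",
    "threshold_subset_trends",
    "exclude_small_trees",
    "smooth_trend",
    "per_predictor_r2",
    "model_selection_aic",
    "mixed_effects_all_species",
    "time_trend",
    "spline_smooth_series",
]

PREDICTOR_COLUMNS = {
    "age": "age_years",
    "height": "height_m",
    "diameter": "dbh_cm",
    "cii": "cii_ordinal",
    "calendar_year": "calendar_year",
}
#: Multiplier from per-unit slope to reporting units.
UNIT_SCALE = {"age": 100.0, "calendar_year": 100.0, "height": 10.0, "diameter": 10.0, "cii": 1.0}
UNIT_LABEL = {
    "age": "ppm (100 yr)^-1",
    "calendar_year": "ppm (100 yr)^-1",
    "height": "ppm (10 m)^-1",
    "diameter": "ppm (10 cm)^-1",
    "cii": "ppm (CII step)^-1",
}

#: Minimum records for a reported linear fit; fewer → not estimable.
MIN_N_FIT = 3


class DegenerateDesignError(ValueError):
    """The design is degenerate (too few points or constant predictor)."""


def significance_stars(p: float) -> str:
    """Conventional star coding: * <0.05, ** <0.01, *** <0.001, else NS."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


@dataclass(frozen=True)
class TrendFit:
    """A linear trend of Wi against one predictor, in reporting units."""

    predictor: str
    slope: float
    slope_se: float
    p_value: float
    r_squared: float
    n: int
    subset_rule: str = "full range"
    estimable: bool = True
    slope_raw: float = float("nan")
    units: str = ""

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)

    @classmethod
    def not_estimable(cls, predictor: str, n: int, subset_rule: str) -> "TrendFit":
        nan = float("nan")
        return cls(predictor, nan, nan, nan, nan, n, subset_rule, estimable=False,
                   slope_raw=nan, units=UNIT_LABEL.get(predictor, ""))


@dataclass
class SmoothFit:
    """A penalized-spline mean curve with pointwise standard errors."""

    grid: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    smoothing: str
    spline: BSpline | None = None
    group_offsets: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ModelSelectionResult:
    """All-subsets AIC comparison of main-effects linear models for Wi.

    ``candidates`` lists (predictor tuple, AIC, R²) ranked by AIC.
    ``selected`` is the most parsimonious adequate model: the smallest
    predictor set within ``parsimony_delta`` AIC units of the minimum
    (ties broken towards the smaller, then lexicographically earlier set);
    ``min_aic`` is the strict AIC minimizer.
    """

    per_predictor_r2: dict
    candidates: tuple
    selected: tuple
    selected_r2: float
    min_aic: tuple
    min_aic_value: float
    parsimony_delta: float
    n: int


def _clean_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def linear_trend(x, y, predictor: str = "age", subset_rule: str = "full range") -> TrendFit:
    """Ordinary least-squares trend of Wi on one predictor.

    Slope, SE, two-sided p and R² from standard linear-model theory, with
    the slope rescaled into reporting units (see :data:`UNIT_SCALE`).
    """
    if predictor not in UNIT_SCALE:
        raise ValueError(f"unknown predictor kind {predictor!r}")
    x, y = _clean_xy(x, y)
    if len(x) < MIN_N_FIT:
        raise DegenerateDesignError(f"need n >= {MIN_N_FIT}, got {len(x)}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError(f"predictor {predictor!r} is constant")
    scale = UNIT_SCALE[predictor]
    if np.ptp(y) == 0:
        # flat response: slope exactly 0, no evidence against it
        return TrendFit(
            predictor=predictor, slope=0.0, slope_se=0.0, p_value=1.0,
            r_squared=0.0, n=len(x), subset_rule=subset_rule, slope_raw=0.0,
            units=UNIT_LABEL[predictor],
        )
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    return TrendFit(
        predictor=predictor,
        slope=res.slope * scale,
        slope_se=res.stderr * scale,
        p_value=float(res.pvalue),
        r_squared=float(r2),
        n=len(x),
        subset_rule=subset_rule,
        slope_raw=float(res.slope),
        units=UNIT_LABEL[predictor],
    )


def threshold_subset_trends(
    data: pd.DataFrame,
    predictor: str,
    thresholds,
    y_col: str = "wi_ppm",
    min_n: int = MIN_N_FIT,
) -> list[TrendFit]:
    """Linear trends restricted to records with predictor strictly above each threshold.

    Emulates the "excluding earlier life stages" ladders (age > 25, 50 … yr;
    height > 1, 2.5 … m). Subsets with fewer than ``min_n`` usable records
    (or a constant predictor) are reported as not-estimable rather than
    silently dropped.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    col = PREDICTOR_COLUMNS[predictor]
    fits: list[TrendFit] = []
    for thr in thresholds:
        rule = f"{predictor} > {thr:g}"
        sub = data[data[col] > thr]
        x, y = _clean_xy(sub[col], sub[y_col])
        if len(x) < max(min_n, MIN_N_FIT) or np.ptp(x) == 0:
            fits.append(TrendFit.not_estimable(predictor, len(x), rule))
            continue
        fits.append(linear_trend(x, y, predictor, subset_rule=rule))
    return fits


def exclude_small_trees(data: pd.DataFrame, min_height_m: float = 1.0) -> pd.DataFrame:
    """Drop trees strictly shorter than ``min_height_m``.

    Small trees sit inside the soil-respiration gradient, so the
    developmental (age) trend analysis excludes them; the boundary itself is
    kept ("lower than 1 m" is a strict inequality).
    """
    kept = data[data["height_m"] >= min_height_m]
    n_removed = len(data) - len(kept)
    if n_removed:
        warnings.warn(
            f"excluded {n_removed} tree(s) below {min_height_m} m", stacklevel=2
        )
    if kept.empty:
        warnings.warn("height exclusion removed every record", stacklevel=2)
    return kept


# ---------------------------------------------------------------------------
# Penalized-spline smoother (P-spline: cubic B-spline basis, second-difference
# coefficient penalty, GCV-selected penalty weight).


def _bspline_design(x: np.ndarray, n_segments: int, degree: int = 3):
    lo, hi = float(np.min(x)), float(np.max(x))
    pad = (hi - lo) * 1e-9 + 1e-12
    inner = np.linspace(lo - pad, hi + pad, n_segments + 1)
    step = inner[1] - inner[0]
    knots = np.concatenate(
        [inner[0] - step * np.arange(degree, 0, -1), inner,
         inner[-1] + step * np.arange(1, degree + 1)]
    )
    B = BSpline.design_matrix(x, knots, degree).toarray()
    return B, knots


def _pspline_fit(
    x: np.ndarray,
    y: np.ndarray,
    n_segments: int,
    lam_grid: np.ndarray | None = None,
):
    """Fit a GCV-tuned P-spline; returns (coef, knots, lam, edf, sigma2)."""
    B, knots = _bspline_design(x, n_segments)
    nb = B.shape[1]
    D = np.diff(np.eye(nb), n=2, axis=0)
    P = D.T @ D
    BtB = B.T @ B
    Bty = B.T @ y
    n = len(y)
    if lam_grid is None:
        # descending so that among equal-GCV fits the smoothest wins
        lam_grid = np.logspace(8, -4, 25)
    best = None
    for lam in lam_grid:
        M = BtB + lam * P
        try:
            coef = np.linalg.solve(M, Bty)
            Minv_BtB = np.linalg.solve(M, BtB)
        except np.linalg.LinAlgError:
            continue
        edf = float(np.trace(Minv_BtB))
        resid = y - B @ coef
        rss = float(resid @ resid)
        denom = max(n - edf, 1e-8)
        gcv = n * rss / denom**2
        if best is None or gcv < best[0] - 1e-12:
            best = (gcv, lam, coef, edf, rss)
    if best is None:
        raise np.linalg.LinAlgError("penalized spline system singular at all penalties")
    _, lam, coef, edf, rss = best
    sigma2 = rss / max(n - edf, 1e-8)
    return coef, knots, lam, edf, sigma2, B, P


def _pspline_se(grid, knots, B, P, lam, sigma2):
    Bg = BSpline.design_matrix(
        np.clip(grid, knots[3] + 1e-12, knots[-4] - 1e-12), knots, 3
    ).toarray()
    M = B.T @ B + lam * P
    A = Bg @ np.linalg.solve(M, B.T)
    return np.sqrt(np.maximum(sigma2 * np.sum(A**2, axis=1), 1e-300))


def smooth_trend(
    x,
    y,
    groups=None,
    grid: np.ndarray | None = None,
    n_grid: int = 100,
    n_segments: int | None = None,
) -> SmoothFit:
    """Penalized-spline mean curve of Wi against a continuous predictor.

    When ``groups`` are supplied, a per-group constant offset is absorbed by
    backfitting before smoothing (a random-intercept surrogate), so the
    returned curve is the group-level mean shape. Penalty weight is chosen by
    generalized cross-validation and recorded on the fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    groups = None if groups is None else np.asarray(groups)[ok]
    if len(np.unique(x)) < 10:
        raise DegenerateDesignError(
            "fewer than 10 distinct predictor values; use linear_trend instead"
        )
    if n_segments is None:
        n_segments = int(np.clip(len(np.unique(x)) // 4, 5, 20))

    offsets: dict = {}
    y_work = y.copy()
    if groups is not None:
        labels = np.unique(groups)
        off = {g: 0.0 for g in labels}
        for _ in range(5):
            y_adj = y - np.array([off[g] for g in groups])
            coef, knots, lam, edf, sigma2, B, P = _pspline_fit(x, y_adj, n_segments)
            fitted = B @ coef
            resid = y_adj - fitted
            for g in labels:
                off[g] += float(np.mean(resid[groups == g]))
            center = float(np.mean(list(off.values())))
            off = {g: v - center for g, v in off.items()}
        offsets = off
        y_work = y - np.array([off[g] for g in groups])

    coef, knots, lam, edf, sigma2, B, P = _pspline_fit(x, y_work, n_segments)
    if grid is None:
        grid = np.linspace(float(np.min(x)), float(np.max(x)), n_grid)
    grid = np.asarray(grid, dtype=float)
    spline = BSpline(knots, coef, 3, extrapolate=True)
    mean = spline(grid)
    se = _pspline_se(grid, knots, B, P, lam, sigma2)
    return SmoothFit(
        grid=grid,
        mean=np.asarray(mean, dtype=float),
        se=se,
        smoothing=f"pspline(segments={n_segments}, lam={lam:.4g}, edf={edf:.2f}, gcv)",
        spline=spline,
        group_offsets=offsets,
    )


# ---------------------------------------------------------------------------
# Predictor comparison and model selection


def per_predictor_r2(data: pd.DataFrame, y_col: str = "wi_ppm") -> dict:
    """Univariate R² (and p, n) of Wi against each developmental predictor."""
    out: dict = {}
    for name in ("age", "diameter", "height", "cii"):
        col = PREDICTOR_COLUMNS[name]
        if col not in data.columns:
            continue
        x, y = _clean_xy(data[col], data[y_col])
        if len(x) < MIN_N_FIT or np.ptp(x) == 0:
            out[name] = {"r_squared": float("nan"), "p_value": float("nan"),
                         "n": len(x), "estimable": False, "stars": "NS"}
            continue
        res = stats.linregress(x, y)
        out[name] = {
            "r_squared": float(res.rvalue**2),
            "p_value": float(res.pvalue),
            "n": len(x),
            "estimable": True,
            "stars": significance_stars(float(res.pvalue)),
        }
    return out


def _gaussian_aic(rss: float, n: int, n_params: int) -> float:
    # up to an additive constant common to all models on the same data
    return n * np.log(rss / n) + 2 * (n_params + 1)


def model_selection_aic(
    data: pd.DataFrame,
    predictors: tuple[str, ...] = ("age", "diameter", "height", "cii"),
    y_col: str = "wi_ppm",
    parsimony_delta: float = 2.0,
) -> ModelSelectionResult:
    """All-subsets AIC comparison of main-effects linear models for Wi.

    Fits every subset of the candidate predictors (including the
    intercept-only model) on the complete-case rows, ranks by AIC, and
    selects the most parsimonious adequate model: the smallest set whose AIC
    is within ``parsimony_delta`` of the minimum, ties broken towards fewer
    predictors and then lexicographically.
    """
    cols = [PREDICTOR_COLUMNS[p] for p in predictors]
    sub = data[cols + [y_col]].dropna()
    n = len(sub)
    if n < 10:
        raise DegenerateDesignError(f"need n >= 10 complete cases, got {n}")
    y = sub[y_col].to_numpy(dtype=float)
    X_all = {p: sub[PREDICTOR_COLUMNS[p]].to_numpy(dtype=float) for p in predictors}

    from itertools import combinations

    candidates = []
    for k in range(len(predictors) + 1):
        for combo in combinations(predictors, k):
            X = np.column_stack([np.ones(n)] + [X_all[p] for p in combo])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            rss = float(resid @ resid)
            tss = float(np.sum((y - y.mean()) ** 2))
            r2 = 0.0 if tss == 0 else 1.0 - rss / tss
            candidates.append((combo, _gaussian_aic(rss, n, X.shape[1]), r2))
    candidates.sort(key=lambda c: (c[1], len(c[0]), c[0]))
    min_combo, min_aic, _ = candidates[0]
    adequate = [c for c in candidates if c[1] <= min_aic + parsimony_delta]
    adequate.sort(key=lambda c: (len(c[0]), c[0]))
    selected, _, selected_r2 = adequate[0]
    return ModelSelectionResult(
        per_predictor_r2=per_predictor_r2(data, y_col),
        candidates=tuple(candidates),
        selected=selected,
        selected_r2=selected_r2,
        min_aic=min_combo,
        min_aic_value=min_aic,
        parsimony_delta=parsimony_delta,
        n=n,
    )


def mixed_effects_all_species(
    data: pd.DataFrame,
    predictors: tuple[str, ...] = ("age", "diameter", "height", "cii"),
    y_col: str = "wi_ppm",
    group_col: str = "species",
) -> pd.DataFrame:
    """Cross-species mixed model: Wi on the four predictors, species random intercepts.

    Restricted maximum likelihood via statsmodels MixedLM; returns a frame of
    fixed-effect estimates with t- and p-values, plus the random-intercept
    variance as metadata in ``DataFrame.attrs``. With a single group the
    model degenerates to OLS (with a warning).
    """
    import statsmodels.api as sm

    cols = [PREDICTOR_COLUMNS[p] for p in predictors]
    sub = data[cols + [y_col, group_col]].dropna()
    groups = sub[group_col]
    y = sub[y_col].to_numpy(dtype=float)
    X = sm.add_constant(sub[cols].to_numpy(dtype=float))
    names = ["intercept"] + list(predictors)

    if groups.nunique() < 2:
        warnings.warn(
            "single species: falling back to a fixed-effects (OLS) model",
            stacklevel=2,
        )
        res = sm.OLS(y, X).fit()
        out = pd.DataFrame(
            {"estimate": res.params, "t_value": res.tvalues, "p_value": res.pvalues},
            index=names,
        )
        out.attrs["random_intercept_var"] = 0.0
        out.attrs["model"] = "ols-fallback"
        return out

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups.to_numpy())
        res = model.fit(reml=True)
    k = len(names)
    out = pd.DataFrame(
        {
            "estimate": res.params[:k],
            "t_value": res.tvalues[:k],
            "p_value": res.pvalues[:k],
        },
        index=names,
    )
    out.attrs["random_intercept_var"] = float(np.asarray(res.cov_re)[0, 0])
    out.attrs["model"] = "mixedlm-reml"
    return out


# ---------------------------------------------------------------------------
# Backward-looking time trends


@dataclass
class TimeTrendResult:
    """Pooled time trend across ring series, with per-series detail."""

    trend: TrendFit
    smooth: SmoothFit | None
    per_series: dict


def time_trend(
    data: pd.DataFrame,
    atmos,
    weights: dict | None = None,
    y_col: str = "wi_ppm",
) -> TimeTrendResult:
    """Reconstruct the apparent Wi time trend from per-tree ring series.

    ``data`` needs columns ``tree_id``, ``calendar_year`` and either
    ``wi_ppm`` or ``d13c_permil`` (converted per-ring against the
    year-matched atmosphere). The combined linear trend is the
    weighted mean of per-series OLS slopes, with weights proportional to the
    supplied study-site counts (default 1 per series) — so equal weights
    reproduce the unweighted mean of series slopes exactly. A pooled
    penalized-spline curve (per-series offsets absorbed) is returned when
    enough distinct years exist.
    """
    from .isotope import discrimination, wi_from_discrimination

    df = data.copy()
    if y_col not in df.columns:
        if "d13c_permil" not in df.columns:
            raise ValueError("need a wi_ppm or d13c_permil column")
        ca = np.empty(len(df))
        d13c_air = np.empty(len(df))
        for i, yr in enumerate(df["calendar_year"].to_numpy()):
            try:
                ca[i], d13c_air[i] = atmos.lookup(yr)
            except LookupError as exc:
                tid = df["tree_id"].iloc[i]
                raise LookupError(f"series {tid!r}: {exc}") from None
        delta = discrimination(df["d13c_permil"].to_numpy(dtype=float), d13c_air)
        df[y_col] = wi_from_discrimination(delta, ca)

    per_series: dict = {}
    slopes, ses, ws, r2s, ns = [], [], [], [], []
    for tid, grp in df.groupby("tree_id"):
        if len(grp) < 3:
            raise DegenerateDesignError(
                f"series {tid!r} has {len(grp)} observations; need >= 3"
            )
        fit = linear_trend(
            grp["calendar_year"], grp[y_col], "calendar_year",
            subset_rule=f"series {tid}",
        )
        per_series[tid] = fit
        w = 1.0 if weights is None else float(weights.get(tid, 1.0))
        slopes.append(fit.slope)
        ses.append(fit.slope_se)
        r2s.append(fit.r_squared)
        ws.append(w)
        ns.append(fit.n)
    slopes, ses, ws = map(np.asarray, (slopes, ses, ws))
    wsum = ws.sum()
    slope = float(np.sum(ws * slopes) / wsum)
    se = float(np.sqrt(np.sum(ws**2 * ses**2)) / wsum)
    z = slope / se if se > 0 else np.inf * np.sign(slope or 1)
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    trend = TrendFit(
        predictor="calendar_year",
        slope=slope,
        slope_se=se,
        p_value=p,
        r_squared=float(np.average(r2s, weights=ws)),
        n=int(np.sum(ns)),
        subset_rule=f"{len(per_series)} series, weighted",
        slope_raw=slope / UNIT_SCALE["calendar_year"],
        units=UNIT_LABEL["calendar_year"],
    )
    smooth = None
    if df["calendar_year"].nunique() >= 10:
        smooth = smooth_trend(
            df["calendar_year"], df[y_col], groups=df["tree_id"]
        )
    return TimeTrendResult(trend=trend, smooth=smooth, per_series=per_series)


def spline_smooth_series(years, values, lam: float | None = None) -> np.ndarray:
    """Cubic smoothing spline of an annual series, evaluated at its own years.

    Display-grade smoothing; ``lam=None`` selects the penalty by GCV. Fewer
    than 4 points pass through unchanged with a warning.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(years) < 4:
        warnings.warn("fewer than 4 points: returning series unsmoothed", stacklevel=2)
        return values.copy()
    order = np.argsort(years)
    sp = make_smoothing_spline(years[order], values[order], lam=lam)
    return np.asarray(sp(years), dtype=float)
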