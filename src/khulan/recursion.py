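"""Residence/recursion metrics, censored survival curves, and model selection.

For every GPS fix ("focal location") a 200-m circle is centred on it and
three quantities are read off the hourly location series:

* residence time - consecutive hours spent inside the circle around the
  focal fix;
* recursion time - hours spent beyond the circle before the next return,
  right-censored at the window end when the animal never returns;
* number of visits - count of distinct entries into the circle over the
  whole analysis window.

Median recursion times come from Kaplan-Meier survival curves of the
censored durations.  A 24-h periodicity in the pooled recursion-time
distribution is tested by fitting a family of Poisson GLMs to the counts
of durations per integer hour t:

    M1   log lambda = a0 + a1*t
    M2   log lambda = a0 + a1*log(t)
    M3   log lambda = a0 + a1*t + a2*log(t)
    M4-k log lambda = a0 + a1*t + a2*log(t) + a3*cos(2*pi*(t+k)/24)
    M5-k log lambda = a0 + a1*t + a2*log(t) + a3*log(cos(2*pi*(t+k)/24) + 2)

scanned over the integer phase k = 0..23 and ranked by AIC (the phase is a
scanned constant, not a counted parameter, so M4-k and M5-k have 4 df).  A
fitted periodic model with phase k has lambda maxima at t = 24 - k, 48 - k,
... : recursion peaks "every 24 h minus k hours".

Finally, the mean number of visits per location (n-tilde) is related to
home-range size A through Gaussian random-intercept models of log(n-tilde)
(one intercept per animal), ranked by small-sample AICc; the inverse-
proportionality hypothesis enters as models with a fixed -log(A) offset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from scipy import optimize

from .trajectory import Trajectory

__all__ = [
    "RecursionConfig",
    "RecursionRecord",
    "KMCurve",
    "PeriodicModelSpec",
    "PeriodicityFit",
    "VisitsHRModelFit",
    "model_lambda",
    "MODEL_DF",
    "focal_visit_decomposition",
    "recursion_table",
    "km_curve",
    "fit_poisson_periodicity",
    "fit_visits_vs_hr",
]

#: Degrees of freedom of the periodic Poisson family (the scanned phase k
#: is not a counted parameter).
MODEL_DF = {"M1": 2, "M2": 2, "M3": 3, "M4": 4, "M5": 4}


@dataclass(frozen=True)
class RecursionConfig:
    radius_m: float = 200.0
    fit_t_max_h: int = 168
    k_range: tuple = tuple(range(24))
    min_durations: int = 50
    #: bridge gaps flanked by in-circle fixes (see module docs); strict mode
    #: treats every unobserved hour as out-of-circle.
    bridge_gaps: bool = True

    def __post_init__(self) -> None:
        if self.radius_m <= 0:
            raise ValueError("radius must be positive")
        if self.fit_t_max_h < 24:
            raise ValueError("fit_t_max_h must cover at least one day")


@dataclass(frozen=True)
class RecursionRecord:
    animal_id: str
    focal_index: int
    residence_h: int
    recursion_h: int
    recursion_censored: bool
    n_visits: int


@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    median_h: float  # NaN when survival never reaches 0.5


@dataclass(frozen=True)
class PeriodicModelSpec:
    """A member of the periodic Poisson family with fixed coefficients."""

    model_id: str  # M1 .. M5
    alphas: tuple[float, ...]  # (a0, a1[, a2[, a3]])
    k: int = 0


@dataclass
class PeriodicityFit:
    model_id: str
    k: int | None
    alphas: np.ndarray
    loglik: float
    aic: float
    df: int
    converged: bool
    fitted_lambda: np.ndarray = field(repr=False, default=None)

    @property
    def label(self) -> str:
        return self.model_id if self.k is None else f"{self.model_id}-{self.k}"


@dataclass
class VisitsHRModelFit:
    model_id: str
    fixed_names: tuple[str, ...]
    fixed: np.ndarray
    intercept_var: float
    residual_var: float
    loglik: float
    df: int
    aic: float
    aicc: float


# ---------------------------------------------------------------------------
# Periodic Poisson model family
# ---------------------------------------------------------------------------

def _design_columns(model_id: str, t: np.ndarray, k: int) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    ones = np.ones_like(t)
    if model_id == "M1":
        cols = [ones, t]
    elif model_id == "M2":
        cols = [ones, np.log(t)]
    elif model_id == "M3":
        cols = [ones, t, np.log(t)]
    elif model_id == "M4":
        cols = [ones, t, np.log(t), np.cos(2 * np.pi * (t + k) / 24.0)]
    elif model_id == "M5":
        cols = [ones, t, np.log(t), np.log(np.cos(2 * np.pi * (t + k) / 24.0) + 2.0)]
    else:
        raise ValueError(f"unknown model id {model_id!r}")
    return np.column_stack(cols)


def model_lambda(spec: PeriodicModelSpec, t) -> np.ndarray:
    """Poisson rate lambda(t) of a family member at (integer) hours t >= 1."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 1):
        raise ValueError("t must be >= 1 hour")
    X = _design_columns(spec.model_id, t, spec.k)
    alphas = np.asarray(spec.alphas, dtype=float)
    if X.shape[1] != alphas.size:
        raise ValueError(
            f"{spec.model_id} expects {X.shape[1]} coefficients, got {alphas.size}"
        )
    eta = X @ alphas
    if np.any(eta > 60):
        bad_t = t[np.argmax(eta)]
        raise OverflowError(f"lambda overflows at t={bad_t:g}")
    return np.exp(eta)


# ---------------------------------------------------------------------------
# Focal residence / recursion / visits
# ---------------------------------------------------------------------------

def _hour_index(traj: Trajectory) -> np.ndarray:
    """Integer hours of each fix since the window start (cadence units)."""
    rel = (traj.times.asi8 - traj.window.start.value) / 3.6e12
    return np.rint(rel).astype(int)


def _in_circle_runs(hour_idx: np.ndarray, inside: np.ndarray, bridge: bool):
    """Maximal in-circle runs as (entry_hour, exit_hour) pairs.

    With ``bridge=True`` a cadence gap between two in-circle fixes does not
    split the run (the animal plausibly never left); in strict mode every
    unobserved hour breaks the run.
    """
    runs = []
    start = None
    prev_h = None
    for h, is_in in zip(hour_idx, inside):
        if is_in:
            if start is None:
                start = h
            elif not bridge and h - prev_h > 1:
                runs.append((start, prev_h))
                start = h
            prev_h = h
        else:
            if start is not None:
                runs.append((start, prev_h))
                start = None
    if start is not None:
        runs.append((start, prev_h))
    return runs


def focal_visit_decomposition(
    traj: Trajectory, focal_index: int, cfg: RecursionConfig = RecursionConfig()
) -> RecursionRecord:
    """Residence, recursion and visit count for one focal fix.

    All times are in cadence hours.  Residence spans the maximal in-circle
    run containing the focal fix (inclusive of both ends); recursion is the
    number of hours spent outside before the next entry, censored at the
    window end when the animal never returns.
    """
    n = len(traj)
    if not 0 <= focal_index < n:
        raise IndexError("focal_index out of range")
    d = np.hypot(traj.x - traj.x[focal_index], traj.y - traj.y[focal_index])
    inside = d <= cfg.radius_m
    hour_idx = _hour_index(traj)
    runs = _in_circle_runs(hour_idx, inside, cfg.bridge_gaps)
    focal_h = hour_idx[focal_index]
    run_i = next(i for i, (s, e) in enumerate(runs) if s <= focal_h <= e)
    s, e = runs[run_i]
    residence = int(e - s + 1)
    window_hours = int(math.floor(traj.window.hours)) - 1  # last nominal fix hour
    if run_i + 1 < len(runs):
        next_entry = runs[run_i + 1][0]
        recursion = int(next_entry - e - 1)
        censored = False
    else:
        recursion = int(window_hours - e)
        censored = True
    return RecursionRecord(
        animal_id=traj.animal_id,
        focal_index=focal_index,
        residence_h=residence,
        recursion_h=recursion,
        recursion_censored=censored,
        n_visits=len(runs),
    )


def recursion_table(
    traj: Trajectory, cfg: RecursionConfig = RecursionConfig()
) -> pd.DataFrame:
    """Per-fix recursion records for a whole trajectory (tidy frame).

    Columns: animal, season, focal_index, residence_h, recursion_h,
    censored, n_visits.  The animal-season summary statistic n-tilde is
    the mean of ``n_visits`` over all rows.
    """
    n = len(traj)
    if n == 0:
        raise ValueError("empty trajectory")
    hour_idx = _hour_index(traj)
    window_hours = int(math.floor(traj.window.hours)) - 1
    # pairwise in-circle membership, one row per focal fix
    dx = traj.x[None, :] - traj.x[:, None]
    dy = traj.y[None, :] - traj.y[:, None]
    inside_all = (dx * dx + dy * dy) <= cfg.radius_m**2

    rows = []
    for i in range(n):
        runs = _in_circle_runs(hour_idx, inside_all[i], cfg.bridge_gaps)
        focal_h = hour_idx[i]
        run_i = next(j for j, (s, e) in enumerate(runs) if s <= focal_h <= e)
        s, e = runs[run_i]
        if run_i + 1 < len(runs):
            rec = int(runs[run_i + 1][0] - e - 1)
            cens = False
        else:
            rec = int(window_hours - e)
            cens = True
        rows.append(
            {
                "animal": traj.animal_id,
                "season": traj.window.season_label,
                "focal_index": i,
                "residence_h": int(e - s + 1),
                "recursion_h": rec,
                "censored": cens,
                "n_visits": len(runs),
            }
        )
    return pd.DataFrame(rows)


def mean_visits_per_location(table: pd.DataFrame) -> float:
    """n-tilde: mean number of visits per focal location."""
    return float(table["n_visits"].mean())


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_curve(durations, censored=None) -> KMCurve:
    """Product-limit survival curve of (possibly right-censored) durations.

    The median is the smallest time at which survival is <= 0.5, NaN when
    the curve never drops that far.
    """
    durations = np.asarray(durations, dtype=float)
    if durations.size == 0:
        raise ValueError("no durations")
    if censored is None:
        censored = np.zeros(durations.shape, dtype=bool)
    censored = np.asarray(censored, dtype=bool)
    observed = ~censored
    if np.all(censored & (durations <= 0)):
        raise ValueError("all durations censored at time zero")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    below = np.nonzero(surv <= 0.5)[0]
    median = float(times[below[0]]) if below.size else float("nan")
    n_at_risk = np.array(
        [int((durations >= t).sum()) for t in times], dtype=int
    )
    return KMCurve(times=times, survival=surv, n_at_risk=n_at_risk, median_h=median)


# ---------------------------------------------------------------------------
# Periodic Poisson fits with AIC phase scan
# ---------------------------------------------------------------------------

def duration_counts(durations, t_max: int) -> np.ndarray:
    """Counts of integer-hour durations over t = 1..t_max (zeros included)."""
    d = np.asarray(durations)
    d = d[(d >= 1) & (d <= t_max)]
    return np.bincount(d.astype(int), minlength=t_max + 1)[1:]


def _fit_one(counts: np.ndarray, t: np.ndarray, model_id: str, k: int) -> PeriodicityFit:
    X = _design_columns(model_id, t, k)
    df = MODEL_DF[model_id]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(counts, X, family=sm.families.Poisson()).fit(
                maxiter=200, tol=1e-10
            )
        converged = bool(res.converged)
        ll = float(res.llf)
        alphas = np.asarray(res.params, dtype=float)
        lam = np.asarray(res.mu, dtype=float)
        # cos(2*pi*(t+k+12)/24) = -cos(2*pi*(t+k)/24): M4-k and M4-(k+12)
        # are the same model with the amplitude sign flipped.  Report the
        # canonical a3 >= 0 form, whose phase marks the rate maxima.
        if model_id == "M4" and alphas[3] < 0:
            alphas = alphas.copy()
            alphas[3] = -alphas[3]
            k = (k + 12) % 24
    except Exception:
        converged = False
        ll = -np.inf
        alphas = np.full(X.shape[1], np.nan)
        lam = np.full(t.shape, np.nan)
    return PeriodicityFit(
        model_id=model_id,
        k=None if model_id in ("M1", "M2", "M3") else k,
        alphas=alphas,
        loglik=ll,
        aic=2 * df - 2 * ll,
        df=df,
        converged=converged,
        fitted_lambda=lam,
    )


def fit_poisson_periodicity(
    durations, cfg: RecursionConfig = RecursionConfig()
) -> tuple[list[PeriodicityFit], PeriodicityFit]:
    """Fit the M1-M5 family to pooled recursion durations; return all fits
    and the AIC-best one.

    Durations (integer hours) are binned into counts over t = 1..fit_t_max;
    each model is fit by Poisson maximum likelihood (log link); the periodic
    models are scanned over every integer phase k in ``cfg.k_range``.  AIC
    ties break toward fewer df, then smaller k.
    """
    durations = np.asarray(durations)
    if durations.size < cfg.min_durations:
        raise ValueError(
            f"need at least {cfg.min_durations} durations, got {durations.size}"
        )
    counts = duration_counts(durations, cfg.fit_t_max_h)
    t = np.arange(1, cfg.fit_t_max_h + 1, dtype=float)
    fits: list[PeriodicityFit] = []
    for mid in ("M1", "M2", "M3"):
        fits.append(_fit_one(counts, t, mid, 0))
    for mid in ("M4", "M5"):
        for k in cfg.k_range:
            fits.append(_fit_one(counts, t, mid, int(k)))
    ranked = [f for f in fits if f.converged]
    if not ranked:
        raise RuntimeError("no periodicity model converged")
    dropped = len(fits) - len(ranked)
    if dropped:
        warnings.warn(f"{dropped} periodicity fit(s) failed to converge; excluded")
    best = min(ranked, key=lambda f: (f.aic, f.df, f.k if f.k is not None else -1))
    return fits, best


def periodicity_table(fits: list[PeriodicityFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        rows.append(
            {
                "model": f.label,
                "df": f.df,
                "k": f.k,
                "loglik": f.loglik,
                "aic": f.aic,
                "converged": f.converged,
                **{f"alpha_{i}": a for i, a in enumerate(f.alphas)},
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Visits vs home-range size: Gaussian random-intercept models R1-R8
# ---------------------------------------------------------------------------

_R_MODELS = {
    # model -> (season intercepts?, slope kind, offset -log A?)
    "R1": (True, "season", False),
    "R2": (False, "season", False),
    "R3": (True, "common", False),
    "R4": (True, None, True),
    "R5": (True, None, False),
    "R6": (False, "common", False),
    "R7": (False, None, True),
    "R8": (False, None, False),
}


def _r_design(model_id: str, season: np.ndarray, log_a: np.ndarray):
    season_levels = sorted(pd.unique(season))
    per_season, slope, offset = _R_MODELS[model_id]
    cols, names = [], []
    if per_season:
        for lev in season_levels:
            cols.append((season == lev).astype(float))
            names.append(f"intercept[{lev}]")
    else:
        cols.append(np.ones(len(season)))
        names.append("intercept")
    if slope == "season":
        for lev in season_levels:
            cols.append(np.where(season == lev, log_a, 0.0))
            names.append(f"log_A[{lev}]")
    elif slope == "common":
        cols.append(log_a)
        names.append("log_A")
    X = np.column_stack(cols)
    off = -log_a if offset else np.zeros(len(season))
    return X, tuple(names), off


def _lmm_ml(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    """Direct ML fit of a Gaussian random-intercept model.

    Marginal covariance V = s2*I + t2 * (same-group indicator).  Fixed
    effects are profiled out by GLS; (t2, s2) maximize the marginal
    likelihood via Nelder-Mead on the log scale.
    """
    n = len(y)
    glist = [np.nonzero(groups == g)[0] for g in pd.unique(groups)]

    def neg_ll(theta):
        t2, s2 = np.exp(theta)
        V = s2 * np.eye(n)
        for idx in glist:
            V[np.ix_(idx, idx)] += t2
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        Xi = np.linalg.solve(L, X)
        yi = np.linalg.solve(L, y)
        beta, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
        resid = yi - Xi @ beta
        logdet = 2 * np.log(np.diag(L)).sum()
        return 0.5 * (n * np.log(2 * np.pi) + logdet + resid @ resid)

    var0 = max(float(np.var(y)), 1e-6)
    best = None
    for t2_0 in (var0 / 2, var0 / 10):
        res = optimize.minimize(
            neg_ll,
            x0=np.log([max(t2_0, 1e-8), max(var0 / 2, 1e-8)]),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    t2, s2 = np.exp(best.x)
    # recover profiled beta
    V = s2 * np.eye(n)
    for idx in glist:
        V[np.ix_(idx, idx)] += t2
    L = np.linalg.cholesky(V)
    Xi = np.linalg.solve(L, X)
    yi = np.linalg.solve(L, y)
    beta, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
    return beta, t2, s2, -best.fun


def fit_visits_vs_hr(rows: pd.DataFrame, hr_col: str = "area_km2"):
    """Fit the R1-R8 family relating mean visits per location to home-range
    size; return all fits and the AICc-best one.

    ``rows`` needs columns animal, season, n_tilde and a home-range-size
    column (default ``area_km2``).  Both n-tilde and A are log-transformed;
    the animal is a random intercept; models are fit by maximum likelihood
    and ranked by AICc = AIC + 2p(p+1)/(n-p-1).  Offset models (R4, R7)
    constrain the log A coefficient to -1.
    """
    req = {"animal", "season", "n_tilde", hr_col}
    if not req <= set(rows.columns):
        raise ValueError(f"rows must have columns {sorted(req)}")
    if len(rows) < 4:
        raise ValueError("need at least 4 animal-season rows")
    if (rows["n_tilde"] <= 0).any() or (rows[hr_col] <= 0).any():
        raise ValueError("n_tilde and home-range size must be positive")
    y = np.log(rows["n_tilde"].to_numpy(dtype=float))
    log_a = np.log(rows[hr_col].to_numpy(dtype=float))
    season = rows["season"].to_numpy()
    groups = rows["animal"].to_numpy()
    n = len(y)

    fits: list[VisitsHRModelFit] = []
    for mid in _R_MODELS:
        X, names, off = _r_design(mid, season, log_a)
        beta, t2, s2, ll = _lmm_ml(y - off, X, groups)
        p = X.shape[1] + 2  # fixed coefficients + two variance components
        aic = 2 * p - 2 * ll
        denom = n - p - 1
        aicc = aic + (2 * p * (p + 1) / denom) if denom > 0 else np.inf
        fits.append(
            VisitsHRModelFit(
                model_id=mid,
                fixed_names=names,
                fixed=np.asarray(beta, dtype=float),
                intercept_var=float(t2),
                residual_var=float(s2),
                loglik=float(ll),
                df=p,
                aic=float(aic),
                aicc=float(aicc),
            )
        )
    best = min(fits, key=lambda f: (f.aicc, f.df))
    return fits, best


def visits_hr_table(fits: list[VisitsHRModelFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model": f.model_id,
                "df": f.df,
                "loglik": f.loglik,
                "aic": f.aic,
                "aicc": f.aicc,
                "intercept_var": f.intercept_var,
                "residual_var": f.residual_var,
                "fixed": "; ".join(
                    f"{n}={v:.4g}" for n, v in zip(f.fixed_names, f.fixed)
                ),
            }
            for f in fits
        ]
    )
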