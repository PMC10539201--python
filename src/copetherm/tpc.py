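"""Cardinal-temperature thermal performance curve (TPC) for egg production.

Egg-production rate R (eggs ind^-1 d^-1) as a function of test temperature T
follows the cardinal-temperature model with inflexion (Lobry-Rosso-Flandrois
family):

    R(T) = Rmax * (T - Tmax)(T - Tmin)^2 /
           [ (Topt - Tmin) * ( (Topt - Tmin)(T - Topt)
                               - (Topt - Tmax)(Topt + Tmin - 2T) ) ]

for Tmin <= T <= Tmax and 0 elsewhere, with the three cardinal identities
R(Tmin) = R(Tmax) = 0 and R(Topt) = Rmax.  CTmax, the temperature at which
the modelled rate reaches zero at the upper limit, equals the fitted Tmax.

Fitting is nonlinear least squares on per-bottle rates with multi-start
initialisation; 95% confidence intervals come from case-resampling bootstrap
(bottles resampled with replacement within each test-temperature cell).
Model selection across curve families (cardinal, Gaussian, quadratic by
default; the registry is extensible) uses AIC = n*ln(RSS/n) + 2k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .errors import InsufficientDataError, MissingCIError, ParameterError
from .resampling import percentile_ci

__all__ = [
    "TPCParams",
    "TPCFit",
    "EstimateCI",
    "tpc_predict",
    "fit_tpc",
    "select_model",
    "thermal_breadth",
    "safety_margin",
    "compare_by_ci",
    "MODEL_REGISTRY",
    "EGG_RATE_SCHEMA",
]

#: Required columns for an egg-rate record table.
EGG_RATE_SCHEMA = ("rearing_temp", "test_temp", "bottle_id", "rate")


@dataclass(frozen=True)
class TPCParams:
    """Cardinal temperatures and maximum rate of the TPC.

    ``Tmin < Topt < Tmax`` is enforced; ``Rmax`` is the rate at ``Topt``.
    """

    rmax: float
    topt: float
    tmin: float
    tmax: float

    def __post_init__(self) -> None:
        vals = [self.rmax, self.topt, self.tmin, self.tmax]
        if not np.isfinite(vals).all():
            raise ParameterError("TPC parameters must be finite")
        if self.rmax <= 0:
            raise ParameterError(f"Rmax must be > 0, got {self.rmax}")
        if not self.tmin < self.topt < self.tmax:
            raise ParameterError(
                f"require Tmin < Topt < Tmax, got {self.tmin}, {self.topt}, {self.tmax}"
            )


def _predict_raw(rmax: float, topt: float, tmin: float, tmax: float, T: np.ndarray) -> np.ndarray:
    """Cardinal-model rate without parameter validation (fit inner loop)."""
    out = np.zeros_like(T)
    inside = (T >= tmin) & (T <= tmax)
    t = T[inside]
    num = rmax * (t - tmax) * (t - tmin) ** 2
    den = (topt - tmin) * (
        (topt - tmin) * (t - topt) - (topt - tmax) * (topt + tmin - 2.0 * t)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den != 0.0, num / den, 0.0)
    out[inside] = np.clip(np.nan_to_num(r, nan=0.0), 0.0, None)
    return out


def tpc_predict(params: TPCParams | tuple, T) -> np.ndarray | float:
    """Predicted egg-production rate at temperature ``T`` (degC).

    Zero outside [Tmin, Tmax]; predictions clamped at >= 0 inside.
    """
    p = params if isinstance(params, TPCParams) else TPCParams(*params)
    T = np.asarray(T, dtype=float)
    scalar = T.ndim == 0
    out = _predict_raw(p.rmax, p.topt, p.tmin, p.tmax, np.atleast_1d(T))
    return float(out[0]) if scalar else out


@dataclass
class TPCFit:
    """Fitted TPC for one rearing line, with derived thermal metrics."""

    rearing_temp: float
    rmax: float
    topt: float
    tmin: float
    tmax: float
    converged: bool
    message: str = ""
    model_name: str = "cardinal"
    aic: float = np.nan
    rss: float = np.nan
    n_obs: int = 0
    #: CTmax equals the fitted Tmax (rate closest to zero at the upper limit).
    ctmax: float = np.nan
    breadth_low: float = np.nan
    breadth_high: float = np.nan
    breadth_width: float = np.nan
    safety_margin: float = np.nan
    ci95: dict[str, tuple[float, float]] | None = None
    n_bootstrap: int = 0
    n_boot_failed: int = 0

    @property
    def params(self) -> TPCParams:
        return TPCParams(self.rmax, self.topt, self.tmin, self.tmax)

    def predict(self, T):
        return tpc_predict(self.params, T)


class EstimateCI(NamedTuple):
    """A point estimate with its 95% confidence interval."""

    estimate: float
    lo: float
    hi: float


# ---------------------------------------------------------------------------
# fitting (internal parametrisation enforces Tmin < Topt < Tmax smoothly:
# theta = (rmax, topt, dlow, dhigh) with tmin = topt - dlow, tmax = topt + dhigh)
# ---------------------------------------------------------------------------

def _theta_to_params(theta: np.ndarray) -> TPCParams:
    rmax, topt, dlow, dhigh = theta
    return TPCParams(rmax, topt, topt - dlow, topt + dhigh)


def _theta_resid(theta: np.ndarray, T: np.ndarray, y: np.ndarray) -> np.ndarray:
    rmax, topt, dlow, dhigh = theta
    return _predict_raw(rmax, topt, topt - dlow, topt + dhigh, T) - y


def _cell_means(T: np.ndarray, y: np.ndarray):
    uT, inv = np.unique(T, return_inverse=True)
    return uT, np.bincount(inv, weights=y) / np.bincount(inv)


def _tpc_starts(T: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    uT, means = _cell_means(T, y)
    j = int(np.argmax(means))
    rmax0 = max(means[j], 1e-3)
    topt0 = uT[j]
    pos = uT[means > 0]
    tmax0 = (pos.max() if pos.size else uT.max()) + 1.0
    tmin0 = uT.min() - 2.0
    dlow0 = max(topt0 - tmin0, 1.0)
    dhigh0 = max(tmax0 - topt0, 0.5)
    starts = [np.array([rmax0, topt0, dlow0, dhigh0])]
    # alternates hedge against a plateau mis-locating Topt
    starts.append(np.array([rmax0, topt0 - 1.5, dlow0, dhigh0 + 1.5]))
    starts.append(np.array([rmax0 * 1.2, topt0 + 1.0, dlow0 + 5.0, max(dhigh0 - 1.0, 0.5)]))
    return starts


def _fit_tpc_ls(T: np.ndarray, y: np.ndarray, starts: list[np.ndarray]):
    span = T.max() - T.min()
    lo = np.array([1e-6, T.min() - 5.0, 0.5, 0.1])
    hi = np.array([max(y.max(), 1.0) * 5.0, T.max() + 5.0, span + 40.0, 30.0])

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
        try:
            sol = least_squares(
                _theta_resid, x0, args=(T, y), bounds=(lo, hi), method="trf"
            )
        except Exception:  # noqa: BLE001
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    return best


def fit_tpc(
    records: pd.DataFrame,
    line: float,
    boot_n: int = 1999,
    seed: int = 0,
    breadth_level: float = 0.8,
) -> TPCFit:
    """Fit the cardinal TPC to one rearing line's per-bottle egg rates.

    Populates the fitted cardinal temperatures, CTmax (= Tmax), the thermal
    breadth at ``breadth_level`` of Rmax, and the thermal safety margin
    (Topt minus the rearing temperature), with percentile-bootstrap 95% CIs
    unless ``boot_n`` is 0.

    Raises
    ------
    InsufficientDataError
        Fewer than 5 distinct test temperatures.
    """
    sub = records[records["rearing_temp"] == line].copy()
    n_temps = sub["test_temp"].nunique()
    if n_temps < 5:
        raise InsufficientDataError(
            f"need >=5 distinct test temperatures, got {n_temps}"
        )
    T = sub["test_temp"].to_numpy(float)
    y = sub["rate"].to_numpy(float)

    best = _fit_tpc_ls(T, y, _tpc_starts(T, y))
    if best is None:
        return TPCFit(
            rearing_temp=line, rmax=np.nan, topt=np.nan, tmin=np.nan,
            tmax=np.nan, converged=False, message="no start converged",
            n_obs=int(len(sub)),
        )
    p = _theta_to_params(best.x)
    rss = float(2 * best.cost)
    n = len(sub)
    fit = TPCFit(
        rearing_temp=line,
        rmax=p.rmax, topt=p.topt, tmin=p.tmin, tmax=p.tmax,
        converged=True, message=best.message,
        aic=_aic(rss, n, 4), rss=rss, n_obs=n,
        ctmax=p.tmax, safety_margin=p.topt - line,
    )
    lo_b, hi_b, width = thermal_breadth(p, breadth_level)
    fit.breadth_low, fit.breadth_high, fit.breadth_width = lo_b, hi_b, width

    if boot_n > 0:
        fit.ci95, fit.n_bootstrap, fit.n_boot_failed = _bootstrap_tpc(
            sub, best.x, line, boot_n, seed, breadth_level
        )
    return fit


def _boot_stats(theta: np.ndarray, line: float, level: float) -> dict[str, float]:
    p = _theta_to_params(theta)
    lo, hi, width = thermal_breadth(p, level)
    return {
        "rmax": p.rmax, "topt": p.topt, "tmin": p.tmin, "tmax": p.tmax,
        "ctmax": p.tmax, "safety_margin": p.topt - line,
        "breadth_low": lo, "breadth_high": hi, "breadth_width": width,
    }


def _bootstrap_tpc(sub, x_hat, line, boot_n, seed, level):
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    keys = list(_boot_stats(x_hat, line, level))
    stats: dict[str, list[float]] = {k: [] for k in keys}
    n_failed = 0
    T = sub["test_temp"].to_numpy(float)
    y = sub["rate"].to_numpy(float)
    _, inv = np.unique(T, return_inverse=True)
    cells = [np.flatnonzero(inv == j) for j in range(inv.max() + 1)]
    for _ in range(boot_n):
        idx = np.concatenate(
            [c[rng.integers(0, len(c), size=len(c))] for c in cells]
        )
        sol = _fit_tpc_ls(T[idx], y[idx], [x_hat])
        if sol is None:
            n_failed += 1
            continue
        for k, v in _boot_stats(sol.x, line, level).items():
            stats[k].append(v)
    point = _boot_stats(x_hat, line, level)
    ci = {k: percentile_ci(np.array(v), point[k]) for k, v in stats.items()}
    return ci, boot_n, n_failed


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def _aic(rss: float, n: int, k: int) -> float:
    return n * np.log(max(rss, 1e-300) / n) + 2 * k


def _fit_gaussian(T, y):
    uT, means = _cell_means(T, y)
    j = int(np.argmax(means))
    x0 = np.array([max(means[j], 1e-3), uT[j], max((uT.max() - uT.min()) / 4, 0.5)])
    lo = np.array([1e-6, uT.min() - 10.0, 0.1])
    hi = np.array([max(y.max(), 1.0) * 5.0, uT.max() + 10.0, 50.0])

    def resid(th):
        rmax, topt, width = th
        return rmax * np.exp(-0.5 * ((T - topt) / width) ** 2) - y

    sol = least_squares(resid, np.clip(x0, lo, hi), bounds=(lo, hi), method="trf")
    if not sol.success:
        raise RuntimeError(sol.message)
    return float(2 * sol.cost)


def _fit_quadratic(T, y):
    coef = np.polyfit(T, y, 2)
    rss = float(np.sum((np.polyval(coef, T) - y) ** 2))
    return rss


def _fit_cardinal_rss(T, y):
    sol = _fit_tpc_ls(T, y, _tpc_starts(T, y))
    if sol is None:
        raise RuntimeError("cardinal fit did not converge")
    return float(2 * sol.cost)


#: Curve-family registry for AIC model selection: name -> (rss_fitter, n_params).
#: Extensible: register a family by adding an entry mapping to a callable
#: (T, y) -> residual sum of squares and its parameter count.
MODEL_REGISTRY: dict[str, tuple[Callable, int]] = {
    "cardinal": (_fit_cardinal_rss, 4),
    "gaussian": (_fit_gaussian, 3),
    "quadratic": (_fit_quadratic, 3),
}


def select_model(
    records: pd.DataFrame,
    line: float,
    candidates: dict[str, tuple[Callable, int]] | None = None,
) -> pd.DataFrame:
    """Rank candidate TPC families on one line's data by AIC.

    AIC = n*ln(RSS/n) + 2k on the per-bottle rates; ties broken by fewer
    parameters, then by name for determinism.  A family whose fit fails is
    reported with status ``failed`` rather than dropped.  The ranking does
    not depend on the order in which candidates are registered.
    """
    cand = candidates if candidates is not None else MODEL_REGISTRY
    if len(cand) < 2:
        raise ParameterError("need at least 2 candidate families")
    sub = records[records["rearing_temp"] == line]
    T = sub["test_temp"].to_numpy(float)
    y = sub["rate"].to_numpy(float)
    n = len(y)
    rows = []
    for name in sorted(cand):
        fitter, k = cand[name]
        try:
            rss = fitter(T, y)
            rows.append(
                {"model_name": name, "n_params": k, "rss": rss,
                 "aic": _aic(rss, n, k), "status": "ok"}
            )
        except Exception as exc:  # noqa: BLE001 - reported, not dropped
            rows.append(
                {"model_name": name, "n_params": k, "rss": np.nan,
                 "aic": np.nan, "status": f"failed: {exc}"}
            )
    tab = pd.DataFrame(rows)
    ok = tab["status"] == "ok"
    tab = pd.concat(
        [
            tab[ok].sort_values(["aic", "n_params", "model_name"]),
            tab[~ok].sort_values("model_name"),
        ],
        ignore_index=True,
    )
    tab["delta_aic"] = tab["aic"] - tab["aic"].min()
    return tab


# ---------------------------------------------------------------------------
# derived metrics
# ---------------------------------------------------------------------------

def thermal_breadth(
    fit: TPCFit | TPCParams | tuple, level: float = 0.8
) -> tuple[float, float, float]:
    """Temperature interval where performance is at least ``level`` of Rmax.

    Returns ``(lower, upper, width)`` in degC.  Endpoints solve
    R(T) = level * Rmax by bracketed root-finding on (Tmin, Topt) and
    (Topt, Tmax); Topt always lies inside the interval.
    """
    if isinstance(fit, TPCFit):
        p = fit.params
    elif isinstance(fit, TPCParams):
        p = fit
    else:
        p = TPCParams(*fit)
    if not 0 < level < 1:
        raise ParameterError(f"level must be in (0, 1), got {level}")
    target = level * p.rmax

    def f(t):
        return tpc_predict(p, t) - target

    eps = 1e-12 * max(abs(p.tmin), abs(p.tmax), 1.0)
    lo = brentq(f, p.tmin + eps, p.topt, xtol=1e-9)
    hi = brentq(f, p.topt, p.tmax - eps, xtol=1e-9)
    return float(lo), float(hi), float(hi - lo)


def safety_margin(fit: TPCFit | TPCParams, rearing_temp: float) -> float:
    """Thermal safety margin: Topt minus the rearing temperature (may be < 0)."""
    topt = fit.topt
    return float(topt - rearing_temp)


def compare_by_ci(q1: EstimateCI | tuple, q2: EstimateCI | tuple) -> bool:
    """Two estimates differ significantly iff their 95% CIs do not overlap."""
    q1, q2 = EstimateCI(*q1), EstimateCI(*q2)
    for q in (q1, q2):
        if q.lo is None or q.hi is None or not np.isfinite([q.lo, q.hi]).all():
            raise MissingCIError("both estimates need finite confidence intervals")
    return bool(q1.hi < q2.lo or q2.hi < q1.lo)
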