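"""Sigmoidal heat-survival modelling and lethal-temperature extraction.

The survival of adult copepods after a fixed exposure duration is modelled as
a descending logistic curve of test temperature ``T``:

    S(T) = c / (1 + exp(a * (T - b)))

where ``c`` is the maximum (plateau) survival proportion at benign
temperatures, ``b`` the temperature at which survival halves relative to
``c``, and ``a > 0`` the steepness of the descending phase.  Lethal
temperatures are defined relative to the plateau: LT50 is the temperature at
which survival drops to ``c / 2`` (so ``LT50 = b``) and more generally the
temperature of mortality fraction ``m`` is

    LT(m) = b + ln(m / (1 - m)) / a.

Fits are ordinary least squares on per-bottle alive fractions, with
case-resampling bootstrap confidence intervals (bottles resampled with
replacement within each test-temperature cell).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    ParameterError,
)
from .resampling import percentile_ci

__all__ = [
    "SurvivalParams",
    "SurvivalFit",
    "survival_predict",
    "lt_from_params",
    "fit_survival",
    "SURVIVAL_SCHEMA",
]

#: Required columns for a survival record table.
SURVIVAL_SCHEMA = (
    "rearing_temp",
    "test_temp",
    "duration_h",
    "bottle_id",
    "n_started",
    "n_alive",
)


@dataclass(frozen=True)
class SurvivalParams:
    """Parameters of the descending logistic survival curve.

    Attributes
    ----------
    a : float
        Slope of the descending phase (per degC); must be positive.
    b : float
        Temperature (degC) of 50% mortality relative to the plateau ``c``.
    c : float
        Maximum survival proportion, in (0, 1].
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.a, self.b, self.c]).all():
            raise ParameterError("survival parameters must be finite")
        if self.a <= 0:
            raise ParameterError(f"slope a must be > 0, got {self.a}")
        if not 0 < self.c <= 1:
            raise ParameterError(f"plateau c must be in (0, 1], got {self.c}")


def survival_predict(params: SurvivalParams | tuple, T) -> np.ndarray | float:
    """Survival proportion at temperature ``T`` (degC).

    Accepts a scalar or array of temperatures; non-finite temperatures are
    rejected.  The curve is strictly decreasing in ``T`` with asymptotes
    ``c`` (cold) and 0 (hot).
    """
    p = params if isinstance(params, SurvivalParams) else SurvivalParams(*params)
    T = np.asarray(T, dtype=float)
    if not np.isfinite(T).all():
        raise ParameterError("temperature must be finite")
    # exp overflow for very cold T is harmless (S -> c); clip the argument
    z = np.clip(p.a * (T - p.b), -700.0, 700.0)
    out = p.c / (1.0 + np.exp(z))
    return out if out.ndim else float(out)


def lt_from_params(params: SurvivalParams | tuple, mortality_fraction: float) -> float:
    """Temperature causing ``mortality_fraction`` mortality relative to the plateau.

    Solves S(T) = (1 - m) * c in closed form:
    ``T = b + ln(m / (1 - m)) / a``.  LT50 is ``b`` exactly; LT90 exceeds
    LT50 by ``ln(9) / a``.
    """
    p = params if isinstance(params, SurvivalParams) else SurvivalParams(*params)
    m = float(mortality_fraction)
    if not 0 < m < 1:
        raise ParameterError(f"mortality fraction must be in (0, 1), got {m}")
    return p.b + np.log(m / (1.0 - m)) / p.a


@dataclass
class SurvivalFit:
    """Result of fitting the survival curve for one rearing line x duration."""

    rearing_temp: float
    duration_h: float
    a: float
    b: float
    c: float
    lt50: float
    lt90: float
    converged: bool
    message: str = ""
    #: 95% percentile-bootstrap CIs keyed by quantity name, or None if boot_n=0.
    ci95: dict[str, tuple[float, float]] | None = None
    n_bootstrap: int = 0
    n_boot_failed: int = 0
    n_bottles: int = 0
    rss: float = np.nan
    n_obs: int = 0

    @property
    def params(self) -> SurvivalParams:
        return SurvivalParams(self.a, self.b, self.c)

    def predict(self, T):
        return survival_predict(self.params, T)


def _alive_fractions(df: pd.DataFrame) -> pd.DataFrame:
    frac = df["n_alive"] / df["n_started"]
    return df.assign(fraction=frac)


def _initial_guesses(T: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Multi-start initial parameter vectors (a, b, c)."""
    order = np.argsort(T)
    Ts, ys = T[order], y[order]
    # mean fraction per distinct temperature
    uT, inv = np.unique(Ts, return_inverse=True)
    means = np.bincount(inv, weights=ys) / np.bincount(inv)
    c0 = float(np.clip(means.max(), 0.05, 1.0))
    if len(uT) >= 2:
        drops = means[:-1] - means[1:]
        j = int(np.argmax(drops))
        b0 = float(0.5 * (uT[j] + uT[j + 1]))
    else:  # pragma: no cover - guarded by the >=3 temperatures check
        b0 = float(uT[0])
    return [np.array([a0, b0, c0]) for a0 in (0.5, 2.0, 5.0)]


def _fit_ols(T: np.ndarray, y: np.ndarray, starts: list[np.ndarray]):
    lo = np.array([1e-6, T.min() - 5.0, 1e-6])
    hi = np.array([50.0, T.max() + 5.0, 1.0])

    def resid(theta):
        a, b, c = theta
        z = np.clip(a * (T - b), -700.0, 700.0)
        return c / (1.0 + np.exp(z)) - y

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf")
        except Exception:  # noqa: BLE001 - a failed start is not fatal
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    return best


def fit_survival(
    records: pd.DataFrame,
    line: float,
    duration: float,
    boot_n: int = 1999,
    seed: int = 0,
) -> SurvivalFit:
    """Fit the survival curve for one rearing line and exposure duration.

    Parameters
    ----------
    records : DataFrame
        Survival table with columns ``rearing_temp, test_temp, duration_h,
        bottle_id, n_started, n_alive`` (other lines/durations are ignored).
    line : float
        Rearing temperature (degC) selecting the line to fit.
    duration : float
        Exposure duration (hours) selecting the records to fit.
    boot_n : int
        Number of case-resampling bootstrap replicates for 95% CIs
        (0 disables the bootstrap: point estimates only).
    seed : int
        Seed for the bootstrap resampling stream.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 distinct test temperatures.
    DegenerateDataError
        All individuals alive or all dead (transition not observed).
    """
    sub = records[
        (records["rearing_temp"] == line) & (records["duration_h"] == duration)
    ].copy()
    if sub.empty:
        raise InsufficientDataError(
            f"no records for line {line} degC at duration {duration} h"
        )
    n_temps = sub["test_temp"].nunique()
    if n_temps < 3:
        raise InsufficientDataError(
            f"need >=3 distinct test temperatures, got {n_temps}"
        )
    if (sub["n_alive"] == sub["n_started"]).all():
        raise DegenerateDataError("all individuals alive: mortality transition not observed")
    if (sub["n_alive"] == 0).all():
        raise DegenerateDataError("all individuals dead: survival plateau not observed")

    sub = _alive_fractions(sub)
    T = sub["test_temp"].to_numpy(float)
    y = sub["fraction"].to_numpy(float)

    best = _fit_ols(T, y, _initial_guesses(T, y))
    if best is None:
        return SurvivalFit(
            rearing_temp=line, duration_h=duration,
            a=np.nan, b=np.nan, c=np.nan, lt50=np.nan, lt90=np.nan,
            converged=False, message="no start converged",
            n_bottles=int(len(sub)), n_obs=int(len(sub)),
        )
    a, b, c = best.x
    params = SurvivalParams(a, b, c)
    fit = SurvivalFit(
        rearing_temp=line, duration_h=duration,
        a=float(a), b=float(b), c=float(c),
        lt50=lt_from_params(params, 0.5),
        lt90=lt_from_params(params, 0.9),
        converged=True, message=best.message,
        n_bottles=int(len(sub)), rss=float(2 * best.cost), n_obs=int(len(sub)),
    )
    if boot_n > 0:
        fit.ci95, fit.n_bootstrap, fit.n_boot_failed = _bootstrap(
            sub, best.x, boot_n, seed
        )
    return fit


def _bootstrap(sub: pd.DataFrame, x_hat: np.ndarray, boot_n: int, seed: int):
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    stats: dict[str, list[float]] = {k: [] for k in ("a", "b", "c", "lt50", "lt90")}
    n_failed = 0
    Tall = sub["test_temp"].to_numpy(float)
    yall = sub["fraction"].to_numpy(float)
    _, inv = np.unique(Tall, return_inverse=True)
    cells = [np.flatnonzero(inv == j) for j in range(inv.max() + 1)]
    for _ in range(boot_n):
        idx = np.concatenate(
            [c[rng.integers(0, len(c), size=len(c))] for c in cells]
        )
        T, y = Tall[idx], yall[idx]
        sol = _fit_ols(T, y, [x_hat])
        if sol is None:
            n_failed += 1
            continue
        a, b, c = sol.x
        stats["a"].append(a)
        stats["b"].append(b)
        stats["c"].append(c)
        stats["lt50"].append(b)
        stats["lt90"].append(b + np.log(9.0) / a)
    point = {
        "a": x_hat[0], "b": x_hat[1], "c": x_hat[2],
        "lt50": x_hat[1], "lt90": x_hat[1] + np.log(9.0) / x_hat[0],
    }
    ci = {k: percentile_ci(np.array(v), point[k]) for k, v in stats.items()}
    return ci, boot_n, n_failed
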