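"""Derived thermal metrics: Q10 coefficients, recruitment, egg diameters.

Q10 — the fold change of a rate per 10 degC warming — is computed from the
slope of a linear regression of ln(predicted egg-production rate) on
temperature over a phase window, as ``Q10 = exp(10 * slope)``.  Three phase
windows are defined relative to the rearing temperature and the curve
optimum:

* ``global``  — lowest tested temperature up to Topt (min. rate to max. rate);
* ``cooling`` — lowest tested temperature up to the rearing temperature;
* ``warming`` — rearing temperature up to Topt.

Potential recruitment — the fitness proxy — is the product of the adult
survival proportion after 7 days and the per-female egg-production rate,
both taken from the fitted curves, on a regular temperature grid; the
warm/control ratio of recruitment is the fold-change profile.

Egg diameter follows a negative exponential of temperature,
``D(T) = D0 * exp(-k T)``; a per-line fit is least squares on ln(diameter)
vs temperature, and the two lines are compared ANCOVA-style through one
pooled linear model with a line indicator and a line x temperature
interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InsufficientDataError, ParameterError
from .survival import SurvivalFit, survival_predict
from .tpc import TPCFit, tpc_predict

__all__ = [
    "Q10Result",
    "RecruitmentProfile",
    "EggDiameterFit",
    "EggDiameterComparison",
    "q10",
    "q10_from_rates",
    "recruitment_profile",
    "fit_egg_diameter",
    "compare_egg_diameter",
    "EGG_DIAMETER_SCHEMA",
]

#: Required columns for an egg-diameter record table.
EGG_DIAMETER_SCHEMA = ("rearing_temp", "test_temp", "egg_id", "diameter_um")

PHASES = ("global", "cooling", "warming")


@dataclass(frozen=True)
class Q10Result:
    phase: str
    slope: float                      # d ln(rate) / dT, per degC
    q10: float                        # = exp(10 * slope)
    temperature_window: tuple[float, float]
    n_points: int
    n_excluded: int = 0               # non-positive predicted rates dropped


def _phase_window(phase: str, fit: TPCFit, rearing_temp: float, eval_temps) -> tuple[float, float]:
    t_low = float(min(eval_temps))
    if phase == "global":
        return (t_low, fit.topt)
    if phase == "cooling":
        return (t_low, float(rearing_temp))
    if phase == "warming":
        return (float(rearing_temp), fit.topt)
    raise ParameterError(f"unknown phase {phase!r}; expected one of {PHASES}")


def q10_from_rates(temps, rates) -> tuple[float, float]:
    """Slope of ln(rate) on temperature and the implied Q10 = exp(10*slope).

    Requires at least two strictly positive rates at distinct temperatures.
    """
    temps = np.asarray(temps, float)
    rates = np.asarray(rates, float)
    if len(temps) < 2 or np.unique(temps).size < 2:
        raise InsufficientDataError("need >= 2 distinct temperatures")
    if (rates <= 0).any():
        raise ParameterError("rates must be positive for the ln-regression")
    slope = float(np.polyfit(temps, np.log(rates), 1)[0])
    return slope, float(np.exp(10.0 * slope))


def q10(
    fit: TPCFit,
    phase: str,
    rearing_temp: float,
    eval_temps,
) -> Q10Result:
    """Q10 of the fitted egg-production curve over one phase window.

    Rates are curve predictions at the experimental test temperatures that
    fall inside the window, with the window endpoints themselves included
    (so the rate at Topt — the maximum — anchors the warming phase even
    though Topt is not a tested temperature).  Non-positive predictions are
    excluded from the ln-regression rather than floored.
    """
    lo, hi = _phase_window(phase, fit, rearing_temp, eval_temps)
    if not lo < hi:
        raise ParameterError(
            f"degenerate {phase} window [{lo}, {hi}] for rearing temp {rearing_temp}"
        )
    temps = [t for t in map(float, eval_temps) if lo <= t <= hi]
    for endpoint in (lo, hi):
        if not any(abs(endpoint - t) < 1e-9 for t in temps):
            temps.append(endpoint)
    temps = np.sort(np.asarray(temps))
    rates = np.asarray([tpc_predict(fit.params, t) for t in temps])
    keep = rates > 0
    n_excluded = int((~keep).sum())
    temps, rates = temps[keep], rates[keep]
    if len(temps) < 2:
        raise InsufficientDataError(
            f"{phase} window has {len(temps)} positive-rate points; need >= 2"
        )
    slope, q10_value = q10_from_rates(temps, rates)
    return Q10Result(
        phase=phase,
        slope=slope,
        q10=q10_value,
        temperature_window=(float(lo), float(hi)),
        n_points=int(len(temps)),
        n_excluded=n_excluded,
    )


@dataclass
class RecruitmentProfile:
    """Temperature-indexed survival x fecundity product and warm/control fold."""

    table: pd.DataFrame  # temperature, recruitment_control, recruitment_warm, fold_change
    grid_step: float
    fold_floor: float

    def fold_at(self, T: float) -> float:
        i = int(np.argmin(np.abs(self.table["temperature"].to_numpy() - T)))
        return float(self.table["fold_change"].iloc[i])


def _check_fit(fit, name):
    if fit is None or not getattr(fit, "converged", False):
        raise ParameterError(f"recruitment profile requires a converged {name} fit")


def recruitment_profile(
    survival_fit_control: SurvivalFit,
    survival_fit_warm: SurvivalFit,
    tpc_control: TPCFit,
    tpc_warm: TPCFit,
    grid_step: float = 0.1,
    fold_floor: float = 1e-3,
) -> RecruitmentProfile:
    """Potential recruitment S(T) * R(T) per line and its warm/control fold.

    Computed on a regular grid over the overlap of the two TPC domains.
    Fold-change is NaN (explicitly undefined) wherever control recruitment
    does not exceed ``fold_floor`` (eggs ind^-1 d^-1).
    """
    for fit, name in (
        (survival_fit_control, "control survival"),
        (survival_fit_warm, "warm survival"),
        (tpc_control, "control TPC"),
        (tpc_warm, "warm TPC"),
    ):
        _check_fit(fit, name)
    if grid_step <= 0:
        raise ParameterError("grid_step must be positive")
    lo = max(tpc_control.tmin, tpc_warm.tmin)
    hi = min(tpc_control.tmax, tpc_warm.tmax)
    if not lo < hi:
        raise ParameterError("TPC domains do not overlap")
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    rec_c = survival_predict(survival_fit_control.params, grid) * tpc_predict(
        tpc_control.params, grid
    )
    rec_w = survival_predict(survival_fit_warm.params, grid) * tpc_predict(
        tpc_warm.params, grid
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(rec_c > fold_floor, rec_w / rec_c, np.nan)
    table = pd.DataFrame(
        {
            "temperature": grid,
            "recruitment_control": rec_c,
            "recruitment_warm": rec_w,
            "fold_change": fold,
        }
    )
    return RecruitmentProfile(table=table, grid_step=grid_step, fold_floor=fold_floor)


# ---------------------------------------------------------------------------
# egg diameter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EggDiameterFit:
    """Per-line exponential decay fit of egg diameter on temperature."""

    rearing_temp: float
    intercept: float   # ln(um) at 0 degC
    slope: float       # per degC (negative for decay)
    d0: float          # exp(intercept), um
    k: float           # -slope, per degC
    n: int
    r_squared: float


@dataclass(frozen=True)
class EggDiameterComparison:
    """ANCOVA-style comparison of the two lines' ln-diameter regressions."""

    interaction_f: float
    interaction_df: tuple[int, int]
    interaction_p: float
    offset_f: float
    offset_df: tuple[int, int]
    offset_p: float

    def format_interaction(self) -> str:
        d1, d2 = self.interaction_df
        return f"F_{d1},{d2} = {self.interaction_f:.2f}; P = {self.interaction_p:.2g}"


def _clean_diameters(records: pd.DataFrame) -> pd.DataFrame:
    if (records["diameter_um"] <= 0).any():
        raise ParameterError("non-positive egg diameters are not admissible")
    return records


def fit_egg_diameter(records: pd.DataFrame, line: float) -> EggDiameterFit:
    """Least squares of ln(diameter) on temperature for one rearing line."""
    sub = _clean_diameters(records[records["rearing_temp"] == line])
    if sub["test_temp"].nunique() < 3:
        raise InsufficientDataError("need >= 3 distinct temperatures per line")
    x = sm.add_constant(sub["test_temp"].to_numpy(float))
    res = sm.OLS(np.log(sub["diameter_um"].to_numpy(float)), x).fit()
    intercept, slope = res.params
    return EggDiameterFit(
        rearing_temp=float(line),
        intercept=float(intercept),
        slope=float(slope),
        d0=float(np.exp(intercept)),
        k=float(-slope),
        n=int(res.nobs),
        r_squared=float(res.rsquared),
    )


def compare_egg_diameter(records: pd.DataFrame) -> EggDiameterComparison:
    """Test whether the two lines share slope and intercept on the ln scale.

    A single pooled linear model ln(D) ~ T + line + T:line is compared
    against its nested reductions by F-tests: the interaction term tests for
    unequal slopes; with a common slope, the line indicator tests for an
    intercept offset.
    """
    recs = _clean_diameters(records)
    lines = np.sort(recs["rearing_temp"].unique())
    if len(lines) != 2:
        raise ParameterError(f"expected exactly 2 rearing lines, got {len(lines)}")
    T = recs["test_temp"].to_numpy(float)
    ind = (recs["rearing_temp"].to_numpy(float) == lines[1]).astype(float)
    y = np.log(recs["diameter_um"].to_numpy(float))
    X_full = sm.add_constant(np.column_stack([T, ind, T * ind]))
    X_add = sm.add_constant(np.column_stack([T, ind]))
    X_common = sm.add_constant(T)
    full = sm.OLS(y, X_full).fit()
    add = sm.OLS(y, X_add).fit()
    common = sm.OLS(y, X_common).fit()
    f_int, p_int, df_int = full.compare_f_test(add)
    f_off, p_off, df_off = add.compare_f_test(common)
    return EggDiameterComparison(
        interaction_f=float(f_int),
        interaction_df=(int(df_int), int(full.df_resid)),
        interaction_p=float(p_int),
        offset_f=float(f_off),
        offset_df=(int(df_off), int(add.df_resid)),
        offset_p=float(p_off),
    )
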