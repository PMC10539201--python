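"""Synthetic experiment generator with known ground truth.

Emulates the bottle-incubation design of a multigenerational copepod warming
experiment: two rearing lines (19 degC control, 25 degC warm), a fixed grid
of 13 test temperatures, replicate bottles of 20 females, survival checks at
24 h and 7 d, per-bottle egg-production rates and per-egg diameter
measurements.  Every generator is deterministic under a fixed seed, and the
random stream is split per (line, duration, temperature, bottle) so adding
bottles or cells never perturbs the draws of existing ones.

Generating processes
--------------------
* mortality: ``n_alive ~ Binomial(n_females, S(T))`` with S the descending
  logistic survival curve (per line and exposure duration);
* egg rates: ``max(0, R(T) + N(0, sd))`` with R the cardinal TPC (per line);
* egg diameters: ``D0 * exp(-k T) + N(0, sd)``, floored at a small positive
  value.

The default truth parameters are the study conditions the package targets:
survival curves whose LT50/LT90 sit at the reported acute (24 h) and chronic
(7 d) lethal temperatures, TPC cardinal parameters at the reported estimates
(with Tmin = 6 degC, inside the species' viable range, since no lower limit
is reported), and egg diameters decaying exponentially with temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError
from .survival import SurvivalParams, survival_predict
from .tpc import TPCParams, tpc_predict

__all__ = [
    "PAPER_GRID",
    "ExperimentDesign",
    "EggDiameterTruth",
    "TruthParameters",
    "default_truth",
    "generate_survival",
    "generate_egg_rates",
    "generate_egg_diameters",
    "write_dataset",
]

#: The 13-temperature incubation grid (degC) of the study design.
PAPER_GRID: tuple[float, ...] = (
    11.0, 15.0, 19.0, 22.0, 25.0, 27.0, 29.0, 30.0, 31.0, 31.5, 32.0, 33.0, 34.0
)

_LN9 = float(np.log(9.0))


@dataclass(frozen=True)
class ExperimentDesign:
    """Incubation design: which cells exist and how many animals per bottle."""

    test_temperatures: tuple[float, ...] = PAPER_GRID
    rearing_temperatures: tuple[float, ...] = (19.0, 25.0)
    n_bottles_per_cell: int = 4
    n_females_per_bottle: int = 20
    exposure_durations: tuple[float, ...] = (24.0, 168.0)

    def __post_init__(self) -> None:
        temps = np.asarray(self.test_temperatures, float)
        if temps.size < 1 or not np.all(np.diff(temps) > 0):
            raise ParameterError("test_temperatures must be strictly increasing")
        if self.n_bottles_per_cell < 1:
            raise ParameterError("n_bottles_per_cell must be >= 1")
        if self.n_females_per_bottle < 1:
            raise ParameterError("n_females_per_bottle must be >= 1")


@dataclass(frozen=True)
class EggDiameterTruth:
    """Exponential temperature decay of egg diameter: D(T) = D0 * exp(-k T)."""

    d0: float = 80.0  # diameter (um) extrapolated to 0 degC
    k: float = 0.004  # decay rate per degC
    sd: float = 1.5   # measurement noise (um)

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ParameterError("D0 must be positive")
        if self.sd < 0:
            raise ParameterError("noise sd must be >= 0")


@dataclass(frozen=True)
class TruthParameters:
    """Ground-truth parameter sets for every generating process.

    ``survival`` maps (rearing_temp, duration_h) to survival-curve
    parameters; ``tpc`` maps rearing_temp to cardinal TPC parameters.
    """

    survival: Mapping[tuple[float, float], SurvivalParams]
    tpc: Mapping[float, TPCParams]
    egg_rate_noise_sd: float = 8.0
    egg_diameter: EggDiameterTruth = field(default_factory=EggDiameterTruth)

    def __post_init__(self) -> None:
        if self.egg_rate_noise_sd < 0:
            raise ParameterError("egg_rate_noise_sd must be >= 0")
        for key, p in self.survival.items():
            if not isinstance(p, SurvivalParams):
                object.__setattr__(
                    self, "survival",
                    {k: SurvivalParams(*v) if not isinstance(v, SurvivalParams) else v
                     for k, v in self.survival.items()},
                )
                break
        if any(not isinstance(p, TPCParams) for p in self.tpc.values()):
            object.__setattr__(
                self, "tpc",
                {k: TPCParams(*v) if not isinstance(v, TPCParams) else v
                 for k, v in self.tpc.items()},
            )


def default_truth() -> TruthParameters:
    """Truth parameters matching the study's reported point estimates.

    Survival slopes are chosen so that LT90 - LT50 = ln(9)/a reproduces the
    reported spacing between the two lethal temperatures for each line and
    duration; plateaus are 0.98 (24 h, near-complete survival at benign
    temperatures) and 0.85 (7 d, the reported maximum).  TPC parameters are
    the reported Rmax/Topt/CTmax per line with Tmin = 6 degC.
    """
    return TruthParameters(
        survival={
            # (rearing_temp, duration_h): a = ln9 / (LT90 - LT50), b = LT50
            (19.0, 24.0): SurvivalParams(a=_LN9 / 0.5, b=32.5, c=0.98),
            (25.0, 24.0): SurvivalParams(a=_LN9 / 0.8, b=33.5, c=0.98),
            (19.0, 168.0): SurvivalParams(a=_LN9 / 0.8, b=31.1, c=0.85),
            (25.0, 168.0): SurvivalParams(a=_LN9 / 1.3, b=31.4, c=0.85),
        },
        tpc={
            19.0: TPCParams(rmax=98.2, topt=26.4, tmin=6.0, tmax=32.1),
            25.0: TPCParams(rmax=83.5, topt=26.9, tmin=6.0, tmax=32.4),
        },
    )


def _cell_rng(seed: int, stream: int, *key_floats: float) -> np.random.Generator:
    """Independent generator for one design cell.

    The spawn key encodes (stream, *cell coordinates in milli-degC), so each
    (line, duration, temperature, bottle) owns a fixed substream regardless
    of how many other cells are generated.
    """
    key = (stream,) + tuple(int(round(1000 * v)) % 2**32 for v in key_floats)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def generate_survival(
    design: ExperimentDesign, truth: TruthParameters, seed: int
) -> pd.DataFrame:
    """Simulate per-bottle survival counts for every design cell.

    Returns a table with one row per (line, duration, temperature, bottle):
    columns ``rearing_temp, test_temp, duration_h, bottle_id, n_started,
    n_alive``.
    """
    rows = []
    for line in design.rearing_temperatures:
        for dur in design.exposure_durations:
            try:
                p = truth.survival[(line, dur)]
            except KeyError as exc:
                raise ParameterError(
                    f"no survival truth for line {line} at {dur} h"
                ) from exc
            for T in design.test_temperatures:
                s = survival_predict(p, T)
                for k in range(design.n_bottles_per_cell):
                    rng = _cell_rng(seed, 1, line, dur, T, float(k))
                    n_alive = int(rng.binomial(design.n_females_per_bottle, s))
                    rows.append(
                        {
                            "rearing_temp": line,
                            "test_temp": T,
                            "duration_h": dur,
                            "bottle_id": f"L{line:g}-D{dur:g}-T{T:g}-b{k + 1}",
                            "n_started": design.n_females_per_bottle,
                            "n_alive": n_alive,
                        }
                    )
    return pd.DataFrame(rows)


def generate_egg_rates(
    design: ExperimentDesign, truth: TruthParameters, seed: int
) -> pd.DataFrame:
    """Simulate per-bottle egg-production rates (eggs ind^-1 d^-1).

    One row per (line, temperature, bottle); additive Gaussian noise on the
    TPC prediction, truncated at zero.
    """
    rows = []
    for line in design.rearing_temperatures:
        try:
            p = truth.tpc[line]
        except KeyError as exc:
            raise ParameterError(f"no TPC truth for line {line}") from exc
        for T in design.test_temperatures:
            r = tpc_predict(p, T)
            for k in range(design.n_bottles_per_cell):
                rng = _cell_rng(seed, 2, line, T, float(k))
                noise = rng.normal(0.0, truth.egg_rate_noise_sd) if truth.egg_rate_noise_sd > 0 else 0.0
                rows.append(
                    {
                        "rearing_temp": line,
                        "test_temp": T,
                        "bottle_id": f"L{line:g}-T{T:g}-b{k + 1}",
                        "rate": max(0.0, r + noise),
                    }
                )
    return pd.DataFrame(rows)


def generate_egg_diameters(
    design: ExperimentDesign,
    truth: TruthParameters,
    n_eggs_per_cell: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-egg diameter measurements (um), one row per egg."""
    if n_eggs_per_cell < 1:
        raise ParameterError("n_eggs_per_cell must be >= 1")
    ed = truth.egg_diameter
    rows = []
    for line in design.rearing_temperatures:
        for T in design.test_temperatures:
            mean = ed.d0 * np.exp(-ed.k * T)
            rng = _cell_rng(seed, 3, line, T)
            noise = rng.normal(0.0, ed.sd, size=n_eggs_per_cell) if ed.sd > 0 else np.zeros(n_eggs_per_cell)
            d = np.maximum(mean + noise, 1e-3)
            for j in range(n_eggs_per_cell):
                rows.append(
                    {
                        "rearing_temp": line,
                        "test_temp": T,
                        "egg_id": f"L{line:g}-T{T:g}-e{j + 1}",
                        "diameter_um": d[j],
                    }
                )
    return pd.DataFrame(rows)


def write_dataset(
    out_dir,
    design: ExperimentDesign,
    truth: TruthParameters,
    seed: int,
    n_eggs_per_cell: int = 30,
):
    """Write the three record tables as CSV plus a truth sidecar (YAML).

    The sidecar echoes every truth parameter so recovery tests can compare
    fitted values against the generating ones without re-deriving them.
    """
    import pathlib

    import yaml

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "survival": out / "survival.csv",
        "egg_rates": out / "egg_rates.csv",
        "egg_diameters": out / "egg_diameters.csv",
        "truth": out / "truth.yaml",
    }
    generate_survival(design, truth, seed).to_csv(paths["survival"], index=False)
    generate_egg_rates(design, truth, seed).to_csv(paths["egg_rates"], index=False)
    generate_egg_diameters(design, truth, n_eggs_per_cell, seed).to_csv(
        paths["egg_diameters"], index=False
    )
    sidecar = {
        "seed": int(seed),
        "design": {
            "test_temperatures": list(map(float, design.test_temperatures)),
            "rearing_temperatures": list(map(float, design.rearing_temperatures)),
            "n_bottles_per_cell": design.n_bottles_per_cell,
            "n_females_per_bottle": design.n_females_per_bottle,
            "exposure_durations": list(map(float, design.exposure_durations)),
        },
        "survival_truth": {
            f"{line:g}C_{dur:g}h": {"a": p.a, "b": p.b, "c": p.c}
            for (line, dur), p in truth.survival.items()
        },
        "tpc_truth": {
            f"{line:g}C": {"rmax": p.rmax, "topt": p.topt, "tmin": p.tmin, "tmax": p.tmax}
            for line, p in truth.tpc.items()
        },
        "egg_rate_noise_sd": truth.egg_rate_noise_sd,
        "egg_diameter_truth": {
            "d0": truth.egg_diameter.d0,
            "k": truth.egg_diameter.k,
            "sd": truth.egg_diameter.sd,
        },
    }
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)
    return paths
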