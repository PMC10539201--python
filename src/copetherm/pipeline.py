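"""End-to-end orchestration: inputs (or simulation) -> fits -> report bundle.

``run_full_analysis`` reads the three record tables (survival counts, egg
rates, egg diameters) or simulates them from a design + truth block, fits
the survival curve per (line, duration) and the TPC per line, computes Q10
coefficients, the recruitment profile and the egg-diameter comparison, and
writes parameter tables shaped for direct side-by-side comparison with the
study's reporting format, plus a JSON manifest recording the seed, a config
hash and convergence diagnostics.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .errors import EmptyInputError, ParameterError, SchemaError
from .metrics import (
    EGG_DIAMETER_SCHEMA,
    PHASES,
    compare_egg_diameter,
    fit_egg_diameter,
    q10,
    recruitment_profile,
)
from .survival import SURVIVAL_SCHEMA, fit_survival
from .tpc import EGG_RATE_SCHEMA, fit_tpc

__all__ = [
    "RunConfig",
    "ReportBundle",
    "ValidationReport",
    "run_full_analysis",
    "validate_input",
    "load_config",
]

log = logging.getLogger("copetherm")

SCHEMAS: dict[str, tuple[str, ...]] = {
    "survival": SURVIVAL_SCHEMA,
    "egg_rates": EGG_RATE_SCHEMA,
    "egg_diameters": EGG_DIAMETER_SCHEMA,
}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``inputs`` (paths to the three CSV tables) or
    ``simulate`` (design overrides for the synthetic generator; an empty
    dict means study defaults) must be provided.
    """

    inputs: dict[str, str] | None = None
    simulate: dict[str, Any] | None = None
    seed: int = 0
    boot_n: int = 1999
    grid_step: float = 0.1
    fold_floor: float = 1e-3
    breadth_level: float = 0.8
    n_eggs_per_cell: int = 30
    out_dir: str | None = None
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ParameterError(
                "exactly one of 'inputs' and 'simulate' must be configured"
            )
        if self.boot_n < 0:
            raise ParameterError("boot_n must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


@dataclass
class ValidationReport:
    path: str
    schema_name: str
    n_rows: int
    n_rejected: int
    problems: list[tuple[int, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.n_rejected == 0


def validate_input(path, schema_name: str) -> ValidationReport:
    """Validate one CSV table against its declared schema.

    Row-level checks (0-based row numbers reported):
    survival — counts non-negative, ``n_alive <= n_started``;
    egg_rates — rate >= 0; egg_diameters — diameter > 0.
    Missing columns raise :class:`SchemaError`; an empty table raises
    :class:`EmptyInputError`.
    """
    if schema_name not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema_name!r}")
    df = pd.read_csv(path)
    missing = [c for c in SCHEMAS[schema_name] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    problems: list[tuple[int, str]] = []
    if schema_name == "survival":
        for i, row in df.iterrows():
            if row["n_started"] < 0 or row["n_alive"] < 0:
                problems.append((int(i), "negative count"))
            elif row["n_alive"] > row["n_started"]:
                problems.append(
                    (int(i), "n_alive exceeds n_started (violates 0 <= n_alive <= n_started)")
                )
    elif schema_name == "egg_rates":
        for i in df.index[df["rate"] < 0]:
            problems.append((int(i), "negative egg-production rate"))
    elif schema_name == "egg_diameters":
        for i in df.index[df["diameter_um"] <= 0]:
            problems.append((int(i), "non-positive egg diameter"))
    return ValidationReport(
        path=str(path),
        schema_name=schema_name,
        n_rows=int(len(df)),
        n_rejected=len(problems),
        problems=problems,
    )


@dataclass
class ReportBundle:
    """All output tables of one pipeline run plus the run manifest."""

    survival_table: pd.DataFrame
    tpc_table: pd.DataFrame
    q10_table: pd.DataFrame
    recruitment: pd.DataFrame
    egg_diameter_table: pd.DataFrame
    manifest: dict

    def write(self, out_dir) -> dict[str, pathlib.Path]:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in (
            "survival_table", "tpc_table", "q10_table", "recruitment",
            "egg_diameter_table",
        ):
            p = out / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False, float_format="%.10g")
            paths[name] = p
        mp = out / "manifest.json"
        with open(mp, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        paths["manifest"] = mp
        return paths


def _ci_cols(ci: dict | None, key: str) -> tuple[float, float]:
    if ci is None or key not in ci:
        return (np.nan, np.nan)
    return ci[key]


def _survival_row(fit) -> dict:
    row = {
        "rearing_temp": fit.rearing_temp,
        "duration_h": fit.duration_h,
        "converged": fit.converged,
        "a": fit.a, "b": fit.b, "c": fit.c,
        "lt50": fit.lt50, "lt90": fit.lt90,
        "n_bootstrap": fit.n_bootstrap,
        "n_boot_failed": fit.n_boot_failed,
    }
    for key in ("a", "b", "c", "lt50", "lt90"):
        lo, hi = _ci_cols(fit.ci95, key)
        row[f"{key}_ci_low"], row[f"{key}_ci_high"] = lo, hi
    return row


#: quantities reported per line in the TPC parameter table (study Table-I layout)
TPC_QUANTITIES = (
    ("rmax", "Rmax (eggs ind-1 d-1)"),
    ("topt", "Topt"),
    ("tmin", "Tmin"),
    ("ctmax", "CTmax"),
    ("safety_margin", "Thermal safety margin"),
    ("breadth_width", "Thermal breadth"),
)


def _tpc_rows(fit) -> list[dict]:
    rows = []
    for key, label in TPC_QUANTITIES:
        lo, hi = _ci_cols(fit.ci95, key)
        rows.append(
            {
                "rearing_temp": fit.rearing_temp,
                "parameter": label,
                "estimate": getattr(fit, key),
                "ci_low": lo,
                "ci_high": hi,
                "converged": fit.converged,
            }
        )
    return rows


def _coerce_truth(raw) -> synthetic.TruthParameters:
    """Accept a TruthParameters, a sidecar-style mapping, or None (defaults)."""
    if raw is None:
        return synthetic.default_truth()
    if isinstance(raw, synthetic.TruthParameters):
        return raw
    from .survival import SurvivalParams
    from .tpc import TPCParams

    surv = {
        (float(k.split("C_")[0]), float(k.split("C_")[1].rstrip("h"))): SurvivalParams(**v)
        for k, v in raw["survival_truth"].items()
    }
    tpc = {float(k.rstrip("C")): TPCParams(**v) for k, v in raw["tpc_truth"].items()}
    ed = synthetic.EggDiameterTruth(**raw.get("egg_diameter_truth", {}))
    return synthetic.TruthParameters(
        survival=surv,
        tpc=tpc,
        egg_rate_noise_sd=raw.get("egg_rate_noise_sd", 8.0),
        egg_diameter=ed,
    )


def run_full_analysis(config: RunConfig) -> ReportBundle:
    """Run the complete analysis described by ``config``.

    Deterministic given (inputs, seed).  Fit failures do not abort the run:
    the affected tables carry the failure flag and the manifest records it.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    failures: list[str] = []

    if config.simulate is not None:
        design = synthetic.ExperimentDesign(**config.simulate.get("design", {}))
        truth = _coerce_truth(config.simulate.get("truth"))
        surv = synthetic.generate_survival(design, truth, config.seed)
        rates = synthetic.generate_egg_rates(design, truth, config.seed)
        diam = synthetic.generate_egg_diameters(
            design, truth, config.n_eggs_per_cell, config.seed
        )
        source = {"simulated": True, "seed": config.seed}
    else:
        tables = {}
        for name in ("survival", "egg_rates", "egg_diameters"):
            path = config.inputs[name]
            report = validate_input(path, name)
            if not report.ok:
                for row, msg in report.problems[:20]:
                    log.warning("%s row %d: %s", path, row, msg)
            df = pd.read_csv(path)
            keep = np.ones(len(df), bool)
            for row, _ in report.problems:
                keep[row] = False
            tables[name] = df[keep].reset_index(drop=True)
        surv, rates, diam = (
            tables["survival"], tables["egg_rates"], tables["egg_diameters"]
        )
        source = {"simulated": False, "inputs": dict(config.inputs)}

    lines = np.sort(surv["rearing_temp"].unique())
    durations = np.sort(surv["duration_h"].unique())

    # --- survival fits per (line, duration) --------------------------------
    surv_fits: dict[tuple[float, float], Any] = {}
    surv_rows = []
    for li, line in enumerate(lines):
        for di, dur in enumerate(durations):
            try:
                fit = fit_survival(
                    surv, line, dur, boot_n=config.boot_n,
                    seed=config.seed + 1000 + 10 * li + di,
                )
            except Exception as exc:  # noqa: BLE001 - surfaced in manifest
                failures.append(f"survival line {line} {dur}h: {exc}")
                continue
            surv_fits[(line, dur)] = fit
            surv_rows.append(_survival_row(fit))
            if not fit.converged:
                failures.append(f"survival line {line} {dur}h: {fit.message}")
            log.info(
                "survival %gC %gh: converged=%s LT50=%.3f boot_failed=%d/%d",
                line, dur, fit.converged, fit.lt50,
                fit.n_boot_failed, fit.n_bootstrap,
            )

    # --- TPC fits per line -------------------------------------------------
    tpc_fits: dict[float, Any] = {}
    tpc_rows = []
    for li, line in enumerate(lines):
        try:
            fit = fit_tpc(
                rates, line, boot_n=config.boot_n,
                seed=config.seed + 2000 + li,
                breadth_level=config.breadth_level,
            )
        except Exception as exc:  # noqa: BLE001
            failures.append(f"tpc line {line}: {exc}")
            continue
        tpc_fits[line] = fit
        tpc_rows.extend(_tpc_rows(fit))
        if not fit.converged:
            failures.append(f"tpc line {line}: {fit.message}")
        log.info(
            "tpc %gC: converged=%s Topt=%.3f Rmax=%.2f boot_failed=%d/%d",
            line, fit.converged, fit.topt, fit.rmax,
            fit.n_boot_failed, fit.n_bootstrap,
        )

    # --- Q10 table (phase x line) -----------------------------------------
    test_temps = np.sort(rates["test_temp"].unique())
    q10_rows = []
    for line, fit in tpc_fits.items():
        if not fit.converged:
            continue
        for phase in PHASES:
            try:
                res = q10(fit, phase, line, test_temps)
            except Exception as exc:  # noqa: BLE001
                failures.append(f"q10 {phase} line {line}: {exc}")
                continue
            q10_rows.append(
                {
                    "rearing_temp": line,
                    "phase": phase,
                    "window_low": res.temperature_window[0],
                    "window_high": res.temperature_window[1],
                    "slope": res.slope,
                    "q10": res.q10,
                    "n_points": res.n_points,
                    "n_excluded": res.n_excluded,
                }
            )

    # --- recruitment profile (7-day survival x fecundity) ------------------
    rec_df = pd.DataFrame(
        columns=["temperature", "recruitment_control", "recruitment_warm", "fold_change"]
    )
    chronic = durations.max()
    if (
        len(lines) == 2
        and (lines[0], chronic) in surv_fits
        and (lines[1], chronic) in surv_fits
        and all(line in tpc_fits for line in lines)
    ):
        try:
            prof = recruitment_profile(
                surv_fits[(lines[0], chronic)], surv_fits[(lines[1], chronic)],
                tpc_fits[lines[0]], tpc_fits[lines[1]],
                grid_step=config.grid_step, fold_floor=config.fold_floor,
            )
            rec_df = prof.table
        except Exception as exc:  # noqa: BLE001
            failures.append(f"recruitment: {exc}")
    else:
        failures.append("recruitment: missing a prerequisite fit")

    # --- egg diameters ------------------------------------------------------
    egg_rows = []
    for line in lines:
        try:
            efit = fit_egg_diameter(diam, line)
        except Exception as exc:  # noqa: BLE001
            failures.append(f"egg diameter line {line}: {exc}")
            continue
        egg_rows.append(
            {
                "rearing_temp": line,
                "intercept_ln_um": efit.intercept,
                "slope_per_degC": efit.slope,
                "d0_um": efit.d0,
                "k_per_degC": efit.k,
                "n": efit.n,
                "r_squared": efit.r_squared,
            }
        )
    comparison = None
    if len(lines) == 2:
        try:
            comparison = compare_egg_diameter(diam)
        except Exception as exc:  # noqa: BLE001
            failures.append(f"egg diameter comparison: {exc}")

    from . import __version__

    manifest = {
        "package": "copetherm",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "source": source,
        "failures": failures,
        "egg_diameter_comparison": (
            None
            if comparison is None
            else {
                "interaction_f": comparison.interaction_f,
                "interaction_df": list(comparison.interaction_df),
                "interaction_p": comparison.interaction_p,
                "offset_f": comparison.offset_f,
                "offset_df": list(comparison.offset_df),
                "offset_p": comparison.offset_p,
                "formatted": comparison.format_interaction(),
            }
        ),
    }

    bundle = ReportBundle(
        survival_table=pd.DataFrame(surv_rows),
        tpc_table=pd.DataFrame(tpc_rows),
        q10_table=pd.DataFrame(q10_rows),
        recruitment=rec_df,
        egg_diameter_table=pd.DataFrame(egg_rows),
        manifest=manifest,
    )
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle
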