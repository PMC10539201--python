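"""Case-resampling bootstrap shared by the survival and TPC fitters.

The experimental unit is the replicate bottle.  Resampling is stratified:
bottles are drawn with replacement *within* each test-temperature cell, so
every bootstrap replicate retains the full temperature coverage of the
incubation design (an unstratified draw could lose the entire mortality
transition and produce degenerate refits).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["resample_within_cells", "percentile_ci"]


def resample_within_cells(
    df: pd.DataFrame, cell_cols: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    """Resample rows with replacement within each cell defined by ``cell_cols``."""
    parts = []
    for _, g in df.groupby(cell_cols, sort=True):
        idx = rng.integers(0, len(g), size=len(g))
        parts.append(g.iloc[idx])
    return pd.concat(parts, ignore_index=True)


def percentile_ci(
    samples: np.ndarray, point: float, level: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap CI, widened if needed to contain the point estimate.

    Percentile intervals from a finite resample can in rare cases exclude the
    point estimate; the interval is expanded to include it so that every
    reported CI brackets the value it qualifies.
    """
    if samples.size == 0:
        return (np.nan, np.nan)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [alpha, 1.0 - alpha])
    return (float(min(lo, point)), float(max(hi, point)))
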