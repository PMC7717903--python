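"""Survival-time distributions by numerical inversion of a loss curve.

A fitted loss curve Y(t) is the complement of the cumulative distribution of
single-spine survival times: F(t) = 1 − Y(t)/100.  Since the two-stage curve
has no closed-form inverse, the inverse CDF is tabulated numerically:

1. evaluate Y on a dense uniform time grid from 0 to ``horizon_factor`` times
   the longest time constant (defaults: 10⁷ points, 30·τ_max);
2. partition fractional survival (0, 1] into ``n_fraction_bins`` equal-width
   bins (default 10⁵) and, for each non-empty bin, average the grid times
   whose survival lands in it — that mean time is the survival time at
   quantile 1 − (bin center);
3. the resulting equal-probability-mass values yield order-statistic
   percentiles and a histogram built from consecutive blocks of
   ``histogram_block`` sorted values (default 100).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Tuple

import numpy as np
import pandas as pd

from .models import DecayModel, survival

__all__ = ["SurvivalTimeDistribution", "derive_survival_times", "percentile"]

_PERCENTILE_LEVELS = (10, 25, 50, 75, 90)


@dataclass(frozen=True)
class SurvivalTimeDistribution:
    """Equal-probability-mass survival times derived from a loss curve.

    ``survival_times`` are sorted ascending; each carries probability mass
    ``1/n_fraction_bins`` (up to skipped empty bins).  ``quantiles`` gives the
    CDF position (1 − bin center) of each value.
    """

    survival_times: np.ndarray
    quantiles: np.ndarray
    percentiles: Mapping[int, float]
    histogram: Tuple[np.ndarray, np.ndarray]
    source_model: DecayModel
    n_fraction_bins: int

    @property
    def median(self) -> float:
        return self.percentiles[50]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"quantile": self.quantiles, "survival_time_days": self.survival_times}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def derive_survival_times(
    model: DecayModel,
    n_time_points: int = 10**7,
    horizon_factor: float = 30.0,
    n_fraction_bins: int = 10**5,
    histogram_block: int = 100,
) -> SurvivalTimeDistribution:
    """Tabulate the inverse loss curve of ``model`` as equal-mass times."""
    if n_time_points < 2 or n_fraction_bins < 1 or histogram_block < 1:
        raise ValueError("resolutions must be positive (n_time_points >= 2)")
    tau_max = max(model.tau_spine, getattr(model, "tau_sp", 0.0))
    t_start = min(0.0, getattr(model, "offset", 0.0))
    t = np.linspace(t_start, horizon_factor * tau_max, n_time_points)
    y = np.asarray(survival(model, t), dtype=float) / 100.0
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("survival curve produced non-finite values")

    # bin k covers fractional survival (k/B, (k+1)/B]; Y=1 lands in the top bin
    idx = np.clip((y * n_fraction_bins).astype(np.int64), 0, n_fraction_bins - 1)
    sums = np.bincount(idx, weights=t, minlength=n_fraction_bins)
    counts = np.bincount(idx, minlength=n_fraction_bins)
    nonempty = counts > 0
    mean_times = sums[nonempty] / counts[nonempty]
    bin_centers = (np.flatnonzero(nonempty) + 0.5) / n_fraction_bins
    # high survival <-> early times: reverse for ascending survival times
    times = mean_times[::-1]
    quantiles = 1.0 - bin_centers[::-1]

    percentiles = {
        q: float(np.percentile(times, q)) for q in _PERCENTILE_LEVELS
    }

    n = len(times)
    block_starts = np.arange(0, n, histogram_block)
    edges = np.append(times[block_starts], times[-1])
    freqs = np.diff(np.append(block_starts, n)) / n

    return SurvivalTimeDistribution(
        survival_times=times,
        quantiles=quantiles,
        percentiles=percentiles,
        histogram=(edges, freqs),
        source_model=model,
        n_fraction_bins=n_fraction_bins,
    )


def percentile(dist: SurvivalTimeDistribution, q: float) -> float:
    """Order-statistic percentile (days) of the derived survival times."""
    if not 0.0 < q < 100.0:
        raise ValueError(f"q must be in (0, 100), got {q}")
    return float(np.percentile(dist.survival_times, q))
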