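"""Posterior summaries: credible curve bands, time-point tables, comparisons.

The 95% confidence region of a fitted condition is represented as a
pointwise band of posterior methane curves: a seeded subsample of retained
draws (300 by default) is evaluated on a time grid and the band is the
pointwise central quantile envelope.  Time-point summaries report the
posterior median of M(t) and its 95% deviation (half the central-interval
width) at the comparison times t20, t60 and t120; condition-versus-control
contrasts are percent changes of the central estimates, with a difference
called supported only when the two 95% intervals are disjoint.

All quantiles are empirical order-statistic quantiles with linear
interpolation, so bands are bit-reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError
from .mcmc import PosteriorDraws
from .model import gompertz_curve_batch

__all__ = [
    "DEFAULT_TIMEPOINTS",
    "CurveBand",
    "PointEstimate",
    "TimePointSummary",
    "ComparisonResult",
    "credible_band",
    "summarize_timepoints",
    "compare_conditions",
]

#: Comparison times (h) spanning lag, early production and the plateau.
DEFAULT_TIMEPOINTS = (20.0, 60.0, 120.0)

DEFAULT_BAND_SAMPLES = 300


@dataclass(frozen=True)
class CurveBand:
    """Pointwise quantile envelope of posterior methane curves."""

    time: np.ndarray
    lower: np.ndarray
    median: np.ndarray
    upper: np.ndarray
    level: float
    n_samples: int

    def __post_init__(self) -> None:
        if not (
            np.all(self.lower <= self.median) and np.all(self.median <= self.upper)
        ):
            raise ValidationError("band quantiles must satisfy lower <= median <= upper")


@dataclass(frozen=True)
class PointEstimate:
    """Posterior median and central interval of M(t) at one time point."""

    median: float
    lower: float
    upper: float

    @property
    def deviation(self) -> float:
        """Half-width of the central interval, mmol/L."""
        return 0.5 * (self.upper - self.lower)

    def overlaps(self, other: "PointEstimate") -> bool:
        return self.lower <= other.upper and other.lower <= self.upper


@dataclass(frozen=True)
class TimePointSummary:
    """Per-condition cumulative methane at the comparison time points."""

    condition_id: str
    times: tuple[float, ...]
    estimates: dict[float, PointEstimate]
    level: float = 0.95


@dataclass(frozen=True)
class ComparisonResult:
    """Treatment-versus-control contrast at one time point.

    percent_change is 100*(M_b - M_a)/M_a from the central estimates; a
    negative value means condition_b produced less methane than
    condition_a.  A difference is reported as supported only when
    ``intervals_overlap`` is False.
    """

    condition_a: str
    condition_b: str
    time: float
    percent_change: float
    intervals_overlap: bool


def _curve_matrix(draws: PosteriorDraws, grid: np.ndarray,
                  rows: Optional[np.ndarray] = None) -> np.ndarray:
    s = draws.samples if rows is None else draws.samples[rows]
    return gompertz_curve_batch(grid, s[:, 0], s[:, 1], s[:, 2])


def credible_band(
    draws: PosteriorDraws,
    grid: Sequence[float],
    level: float = 0.95,
    n_samples: int = DEFAULT_BAND_SAMPLES,
    seed: Optional[int] = None,
) -> CurveBand:
    """Pointwise ``level`` band from ``n_samples`` posterior curves.

    Draws are subsampled without replacement (seeded) from the pooled
    retained draws, each evaluated on ``grid``, and the band is the
    pointwise ((1-level)/2, 0.5, (1+level)/2) empirical quantiles.
    """
    if not (0.0 < level < 1.0):
        raise ConfigurationError(f"level must be in (0, 1), got {level}")
    if n_samples > draws.n_draws:
        raise ConfigurationError(
            f"n_samples={n_samples} exceeds the {draws.n_draws} retained draws"
        )
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    rows = rng.choice(draws.n_draws, size=n_samples, replace=False)
    curves = _curve_matrix(draws, grid, rows)
    alpha = (1.0 - level) / 2.0
    lo, med, hi = np.quantile(curves, [alpha, 0.5, 1.0 - alpha], axis=0)
    return CurveBand(
        time=grid, lower=lo, median=med, upper=hi, level=level, n_samples=n_samples
    )


def summarize_timepoints(
    draws: PosteriorDraws,
    condition_id: str,
    times: Sequence[float] = DEFAULT_TIMEPOINTS,
    level: float = 0.95,
) -> TimePointSummary:
    """Posterior median and central ``level`` interval of M(t) at each time.

    Every retained draw contributes, so the summary matches a band built
    from all draws evaluated on the same grid.
    """
    if draws.n_draws == 0:
        raise ValidationError("posterior draws are empty")
    times = tuple(float(t) for t in times)
    curves = _curve_matrix(draws, np.asarray(times))
    alpha = (1.0 - level) / 2.0
    lo, med, hi = np.quantile(curves, [alpha, 0.5, 1.0 - alpha], axis=0)
    estimates = {
        t: PointEstimate(median=float(med[i]), lower=float(lo[i]), upper=float(hi[i]))
        for i, t in enumerate(times)
    }
    return TimePointSummary(
        condition_id=condition_id, times=times, estimates=estimates, level=level
    )


def compare_conditions(
    a: TimePointSummary, b: TimePointSummary, time: float
) -> ComparisonResult:
    """Percent change of condition ``b`` relative to ``a`` at ``time`` hours."""
    time = float(time)
    for s in (a, b):
        if time not in s.estimates:
            raise KeyError(
                f"time point {time} h not summarised for condition "
                f"{s.condition_id!r} (available: {s.times})"
            )
    ea, eb = a.estimates[time], b.estimates[time]
    if ea.median == 0.0:
        raise ValidationError(
            f"reference condition {a.condition_id!r} has zero methane at t={time}"
        )
    return ComparisonResult(
        condition_a=a.condition_id,
        condition_b=b.condition_id,
        time=time,
        percent_change=100.0 * (eb.median - ea.median) / ea.median,
        intervals_overlap=ea.overlaps(eb),
    )


def plot_band(band: CurveBand, series=None, ax=None, **kwargs):
    """Plot a credible band (and optionally the observations) — visual aid only."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.fill_between(band.time, band.lower, band.upper, alpha=0.3,
                    label=f"{band.level:.0%} band", **kwargs)
    ax.plot(band.time, band.median, label="posterior median")
    if series is not None:
        ax.scatter(series.times, series.methane, s=12, c="k", label="observed")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("cumulative CH$_4$ (mmol/L)")
    ax.legend()
    return ax
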