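"""Log-uniform prior support for the kinetic parameters and noise scale.

The prior is uniform on a box in log-parameter space (a log-uniform prior on
the natural scale).  Bounds are derived from the observed series so that any
plausible maximum-likelihood estimate lies strictly inside the box:

* ``ln P``      in [ln(f_lo * max M_obs), ln(f_hi * max M_obs)]
* ``ln Rm``     in [ln(g_lo * s_max),     ln(g_hi * s_max)] where ``s_max``
  is the largest finite-difference slope of the observed series
* ``ln lambda`` in [ln(lambda_min),        ln(t_max)]
* ``ln sigma``  in [ln(sigma_min),         ln(max M_obs)]

The factors are configurable; the derived bounds are recorded in run
metadata so every fit is reproducible from its log alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import AssayTimeSeries
from .errors import ConfigurationError, DegenerateDataError

__all__ = ["PriorFactors", "PriorSpec", "max_observed_slope"]

PARAM_NAMES = ("P", "Rm", "lambda", "sigma")


@dataclass(frozen=True)
class PriorFactors:
    """Multipliers used to widen data-derived scales into prior bounds."""

    p_lower: float = 0.5
    p_upper: float = 10.0
    rm_lower: float = 0.01
    rm_upper: float = 100.0
    lambda_min_h: float = 1e-3
    sigma_min: float = 1e-3


def max_observed_slope(series: AssayTimeSeries) -> float:
    """Largest per-replicate finite-difference slope, mmol/(L*h)."""
    best = -np.inf
    for rep in sorted(set(series.replicate_ids)):
        mask = np.array([r == rep for r in series.replicate_ids])
        t = series.times[mask]
        m = series.methane[mask]
        order = np.argsort(t)
        t, m = t[order], m[order]
        slopes = np.diff(m) / np.diff(t)
        if slopes.size:
            best = max(best, float(np.max(slopes)))
    if not np.isfinite(best) or best <= 0:
        raise DegenerateDataError(
            f"condition {series.condition_id!r}: no positive finite-difference "
            "slope; the series carries no kinetic signal"
        )
    return best


@dataclass(frozen=True)
class PriorSpec:
    """Box support in log space, ordered (ln P, ln Rm, ln lambda, ln sigma)."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        if lower.shape != (4,) or upper.shape != (4,):
            raise ConfigurationError("prior bounds must be length-4 vectors")
        if not np.all(np.isfinite(lower)) or not np.all(np.isfinite(upper)):
            raise ConfigurationError("prior bounds must be finite")
        if not np.all(lower < upper):
            raise ConfigurationError(
                f"prior lower bounds must be strictly below upper bounds "
                f"(got lower={lower}, upper={upper})"
            )
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @classmethod
    def from_series(
        cls, series: AssayTimeSeries, factors: PriorFactors = PriorFactors()
    ) -> "PriorSpec":
        m_max = float(np.max(series.methane))
        if m_max <= 0:
            raise DegenerateDataError(
                f"condition {series.condition_id!r}: all methane readings are zero"
            )
        s_max = max_observed_slope(series)
        t_max = float(np.max(series.times))
        lower = np.log(
            [
                factors.p_lower * m_max,
                factors.rm_lower * s_max,
                factors.lambda_min_h,
                factors.sigma_min,
            ]
        )
        upper = np.log(
            [factors.p_upper * m_max, factors.rm_upper * s_max, t_max, m_max]
        )
        return cls(lower=lower, upper=upper)

    def contains(self, v: np.ndarray) -> bool:
        """True when the full log-vector (length 4) lies inside the box."""
        v = np.asarray(v, dtype=float)
        return bool(np.all(v >= self.lower) and np.all(v <= self.upper))

    @property
    def kinetic_lower(self) -> np.ndarray:
        """Bounds for (ln P, ln Rm, ln lambda) only."""
        return self.lower[:3]

    @property
    def kinetic_upper(self) -> np.ndarray:
        return self.upper[:3]

    @property
    def sigma_bounds(self) -> tuple[float, float]:
        """(sigma_min, sigma_max) on the natural scale."""
        return float(np.exp(self.lower[3])), float(np.exp(self.upper[3]))

    def to_dict(self) -> dict:
        return {
            "lower_log": [float(x) for x in self.lower],
            "upper_log": [float(x) for x in self.upper],
            "names": list(PARAM_NAMES),
        }
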