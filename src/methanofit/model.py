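"""Modified Gompertz model for cumulative methane production.

The three-parameter sigmoid

    M(t) = P * exp(-exp((Rm * e / P) * (lambda - t) + 1))

describes cumulative product formation in a batch assay: ``P`` (mmol/L) is
the methane production potential (the plateau), ``Rm`` (mmol/(L*h)) is the
maximum production rate (the slope at the inflection point), and ``lambda``
(h) is the lag time before production accelerates.  ``e`` is Euler's number.

All downstream inference works on the natural logarithms of the parameters,
which enforces strict positivity structurally; this module owns the
transform between the two representations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

from .errors import ValidationError

__all__ = [
    "GompertzParams",
    "gompertz_curve",
    "gompertz_curve_batch",
    "to_log",
    "from_log",
    "curve_properties",
]

_E = math.e

# Inner exponent is clamped before exponentiation; exp(-700) is still
# representable, so the lower clamp never changes a value by more than
# ~1e-300, and the upper clamp only avoids a spurious overflow warning on
# curves that are identically zero at double precision anyway.
_INNER_FLOOR = -700.0
_INNER_CEIL = 700.0


@dataclass(frozen=True)
class GompertzParams:
    """Kinetic parameter triple (P, Rm, lambda), all strictly positive.

    Attributes
    ----------
    P : float
        Methane production potential (plateau), mmol/L.
    Rm : float
        Maximum production rate, mmol/(L*h).
    lam : float
        Lag time, h.
    """

    P: float
    Rm: float
    lam: float

    def __post_init__(self) -> None:
        for name, value in (("P", self.P), ("Rm", self.Rm), ("lam", self.lam)):
            if not math.isfinite(value) or value <= 0.0:
                raise ValidationError(
                    f"Gompertz parameter {name} must be finite and > 0, got {value!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.P, self.Rm, self.lam], dtype=float)


def _curve(t: np.ndarray, P, Rm, lam) -> np.ndarray:
    """Vectorised curve evaluation; broadcasts parameters against ``t``."""
    inner = (Rm * _E / P) * (lam - t) + 1.0
    return P * np.exp(-np.exp(np.clip(inner, _INNER_FLOOR, _INNER_CEIL)))


def gompertz_curve(
    t: Union[float, np.ndarray], params: GompertzParams
) -> Union[float, np.ndarray]:
    """Evaluate cumulative methane M(t) at time(s) ``t`` (hours).

    Returns values in mmol/L, strictly between 0 and ``params.P`` for
    finite ``t``, and strictly increasing in ``t``.
    """
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValidationError("time values must be finite")
    if np.any(t_arr < 0.0):
        raise ValidationError("time values must be non-negative")
    out = _curve(t_arr, params.P, params.Rm, params.lam)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def gompertz_curve_batch(t: np.ndarray, P: np.ndarray, Rm: np.ndarray,
                         lam: np.ndarray) -> np.ndarray:
    """Evaluate many parameter sets on one time grid.

    Parameters are 1-D arrays of equal length S; ``t`` is a 1-D grid of
    length T.  Returns an (S, T) matrix of curves.  No domain validation is
    performed: this is the hot path used by fitting, sampling and bands.
    """
    return _curve(
        np.asarray(t, dtype=float)[None, :],
        np.asarray(P, dtype=float)[:, None],
        np.asarray(Rm, dtype=float)[:, None],
        np.asarray(lam, dtype=float)[:, None],
    )


def to_log(params: GompertzParams) -> np.ndarray:
    """Map (P, Rm, lambda) to the log-parameter vector (ln P, ln Rm, ln lambda)."""
    return np.log(params.as_array())


def from_log(v: np.ndarray) -> GompertzParams:
    """Inverse of :func:`to_log`; raises on non-finite input."""
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValidationError(f"log-parameter vector must have length 3, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValidationError("log-parameter vector must be finite")
    p = np.exp(v)
    return GompertzParams(P=float(p[0]), Rm=float(p[1]), lam=float(p[2]))


def curve_properties(params: GompertzParams) -> tuple[float, float]:
    """Closed-form curve landmarks: (inflection time, maximum slope).

    The inflection of the modified Gompertz curve sits at
    ``t = lambda + P / (Rm * e)``, where ``M = P / e`` and the slope attains
    its maximum value ``Rm``.
    """
    t_inflection = params.lam + params.P / (params.Rm * _E)
    return t_inflection, params.Rm
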