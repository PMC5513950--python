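"""Observational data model and delimited-text input/output.

The interchange format is a long-format, comma-separated, UTF-8 table with a
mandatory header and the columns::

    condition, replicate, time_h, ch4_mmol_per_l

Time is always hours and methane always mmol per litre of liquid; no unit
inference happens at this boundary.  Validation is total: every malformed
input yields a typed error from :mod:`methanofit.errors`, never a partially
constructed object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import (
    DuplicateKeyError,
    InsufficientDataError,
    SchemaError,
    ValidationError,
)

__all__ = [
    "REQUIRED_COLUMNS",
    "SUBSTRATES",
    "Observation",
    "AssayTimeSeries",
    "read_timeseries",
    "write_timeseries",
    "write_band_csv",
    "write_draws_csv",
    "write_summary_table",
    "read_summary_table",
]

REQUIRED_COLUMNS = ("condition", "replicate", "time_h", "ch4_mmol_per_l")

#: Metabolic route of the assayed culture; fixes the substrate stoichiometry.
SUBSTRATES = ("hydrogenotrophic", "aceticlastic")

MIN_TIMES_PER_REPLICATE = 4  # 3 kinetic parameters + noise scale


@dataclass(frozen=True)
class Observation:
    """One gas-chromatography reading from one vial.

    time is hours since inoculation; methane is cumulative, mmol/L.
    """

    time: float
    methane: float
    replicate_id: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise ValidationError(f"time must be finite and >= 0, got {self.time!r}")
        if not np.isfinite(self.methane) or self.methane < 0:
            raise ValidationError(f"methane must be finite and >= 0, got {self.methane!r}")
        if not str(self.replicate_id):
            raise ValidationError("replicate_id must be non-empty")


@dataclass(frozen=True)
class AssayTimeSeries:
    """All observations for one assay condition (its duplicate vials pooled).

    Observations are kept sorted by (replicate, time); duplicate
    (replicate, time) pairs and replicates with fewer than four distinct
    sampling times are rejected at construction.
    """

    condition_id: str
    observations: tuple[Observation, ...]
    substrate: Optional[str] = None

    def __post_init__(self) -> None:
        if not str(self.condition_id):
            raise ValidationError("condition_id must be non-empty")
        if self.substrate is not None and self.substrate not in SUBSTRATES:
            raise ValidationError(
                f"substrate must be one of {SUBSTRATES}, got {self.substrate!r}"
            )
        obs = tuple(
            sorted(self.observations, key=lambda o: (str(o.replicate_id), o.time))
        )
        keys = [(o.replicate_id, o.time) for o in obs]
        if len(set(keys)) != len(keys):
            dup = next(k for i, k in enumerate(keys) if k in keys[:i])
            raise DuplicateKeyError(
                f"condition {self.condition_id!r}: duplicate (replicate, time) "
                f"pair {dup}"
            )
        per_rep: dict[str, set[float]] = {}
        for o in obs:
            per_rep.setdefault(str(o.replicate_id), set()).add(o.time)
        for rep, times in per_rep.items():
            if len(times) < MIN_TIMES_PER_REPLICATE:
                raise InsufficientDataError(
                    f"condition {self.condition_id!r} replicate {rep!r} has "
                    f"{len(times)} distinct time points; at least "
                    f"{MIN_TIMES_PER_REPLICATE} are required"
                )
        object.__setattr__(self, "observations", obs)

    # -- array views used by the numerical stages ---------------------------

    @property
    def times(self) -> np.ndarray:
        """Pooled sampling times (h), in (replicate, time) order."""
        return np.array([o.time for o in self.observations], dtype=float)

    @property
    def methane(self) -> np.ndarray:
        """Pooled methane readings (mmol/L), aligned with :attr:`times`."""
        return np.array([o.methane for o in self.observations], dtype=float)

    @property
    def replicate_ids(self) -> tuple[str, ...]:
        return tuple(str(o.replicate_id) for o in self.observations)

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.condition_id,
                "replicate": self.replicate_ids,
                "time_h": self.times,
                "ch4_mmol_per_l": self.methane,
            }
        )

    @classmethod
    def from_arrays(
        cls,
        condition_id: str,
        replicate: Sequence[str],
        time_h: Sequence[float],
        methane: Sequence[float],
        substrate: Optional[str] = None,
    ) -> "AssayTimeSeries":
        obs = tuple(
            Observation(time=float(t), methane=float(m), replicate_id=str(r))
            for r, t, m in zip(replicate, time_h, methane, strict=True)
        )
        return cls(condition_id=condition_id, observations=obs, substrate=substrate)


def read_timeseries(
    path: Union[str, Path],
    condition_id: str,
    substrate: Optional[str] = None,
) -> AssayTimeSeries:
    """Read one condition's series from a long-format CSV file.

    Raises :class:`SchemaError` when a required column is absent,
    :class:`ValidationError` (citing the 1-based file row) for negative or
    non-numeric values, :class:`DuplicateKeyError` for repeated
    (replicate, time) pairs and :class:`InsufficientDataError` when a
    replicate has fewer than four time points.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    # header occupies file row 1
    df = df.assign(_row=df.index + 2)
    sel = df[df["condition"].astype(str) == str(condition_id)]
    if sel.empty:
        raise ValidationError(
            f"condition {condition_id!r} not present in {path} "
            f"(found: {sorted(df['condition'].astype(str).unique())})"
        )
    obs = []
    for row, rep, t_raw, m_raw in zip(
        sel["_row"], sel["replicate"], sel["time_h"], sel["ch4_mmol_per_l"]
    ):
        try:
            t = float(t_raw)
            m = float(m_raw)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path} row {row}: non-numeric value ({exc})") from exc
        try:
            obs.append(Observation(time=t, methane=m, replicate_id=str(rep)))
        except ValidationError as exc:
            raise ValidationError(f"{path} row {row}: {exc}") from exc
    return AssayTimeSeries(
        condition_id=str(condition_id), observations=tuple(obs), substrate=substrate
    )


def write_timeseries(
    series: Union[AssayTimeSeries, Iterable[AssayTimeSeries]],
    path: Union[str, Path],
) -> None:
    """Write one or several conditions to a long-format CSV file."""
    if isinstance(series, AssayTimeSeries):
        series = [series]
    frames = [s.to_frame() for s in series]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6g")


def write_band_csv(band, path: Union[str, Path]) -> None:
    """Write a credible curve band as (time_h, lower, median, upper)."""
    pd.DataFrame(
        {
            "time_h": band.time,
            "lower": band.lower,
            "median": band.median,
            "upper": band.upper,
        }
    ).to_csv(path, index=False, float_format="%.6g")


def write_draws_csv(draws, path: Union[str, Path]) -> None:
    """Write retained posterior draws with chain and iteration provenance."""
    draws.to_frame().to_csv(path, index=False, float_format="%.10g")


def _summary_columns(times: Sequence[float]) -> list[str]:
    cols = ["condition"]
    for t in times:
        label = f"{t:g}"
        cols += [f"M{label}_mmol_per_l", f"dev95_t{label}"]
    return cols


def write_summary_table(summaries, path: Union[str, Path]) -> None:
    """Write time-point summaries, one row per condition.

    Columns are ``condition`` then, per time point, the central estimate of
    M(t) and its 95% deviation (half the central-interval width), both in
    mmol/L.  All summaries must share the same time-point set.
    """
    summaries = list(summaries)
    if summaries:
        times = summaries[0].times
        for s in summaries[1:]:
            if tuple(s.times) != tuple(times):
                raise ValidationError(
                    "summaries have heterogeneous time-point sets: "
                    f"{tuple(times)} vs {tuple(s.times)}"
                )
    else:
        times = (20.0, 60.0, 120.0)
    rows = []
    for s in summaries:
        row: dict[str, object] = {"condition": s.condition_id}
        for t in times:
            est = s.estimates[t]
            label = f"{t:g}"
            row[f"M{label}_mmol_per_l"] = est.median
            row[f"dev95_t{label}"] = est.deviation
        rows.append(row)
    pd.DataFrame(rows, columns=_summary_columns(times)).to_csv(
        path, index=False, float_format="%.4f"
    )


def read_summary_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read back a summary table written by :func:`write_summary_table`."""
    df = pd.read_csv(path)
    if "condition" not in df.columns:
        raise SchemaError(f"missing required column 'condition' in {path}")
    return df
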