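"""Synthetic batch-assay generator and calibration experiments.

Emulates the design of duplicate-vial methanogenic activity assays: each
condition has a known Gompertz truth, each vial (replicate) is sampled on a
common schedule within a ~6-day incubation, and readings are the true curve
plus additive Gaussian noise truncated at zero (methane concentrations
cannot be negative).  For aceticlastic scenarios the plateau is capped at
20 mmol/L, the stoichiometric ceiling of 20 mM acetate converted 1:1 to
methane.

The module also owns the two desk-scale calibration experiments:
``coverage_experiment`` (do nominal central credible intervals cover the
truth at their nominal rate?) and ``recovery_experiment`` (bias and RMSE of
posterior medians).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .dataio import AssayTimeSeries
from .errors import ConfigurationError, ValidationError
from .fit import OptimizerConfig, fit_mle
from .mcmc import REDUCED_MCMC, MCMCConfig, run_mcmc
from .model import GompertzParams, gompertz_curve
from .priors import PARAM_NAMES

__all__ = [
    "SyntheticScenario",
    "default_scenario",
    "aceticlastic_scenario",
    "simulate_dataset",
    "CoverageResult",
    "coverage_experiment",
    "RecoveryResult",
    "recovery_experiment",
]

ACETICLASTIC_P_CEILING = 20.0  # mmol/L, from 20 mM acetate at 1:1 stoichiometry

#: 12 sampling times (h) over a ~6-day incubation.
DEFAULT_SCHEDULE = tuple(np.linspace(4.0, 150.0, 12).round(1))

KINETIC_NAMES = PARAM_NAMES[:3]  # ("P", "Rm", "lambda")


@dataclass(frozen=True)
class SyntheticScenario:
    """Known-truth description of one simulated assay campaign."""

    truths: Mapping[str, GompertzParams]
    sigma: float
    replicates: int = 2
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE
    substrate: str = "hydrogenotrophic"

    def __post_init__(self) -> None:
        if not self.truths:
            raise ConfigurationError("scenario needs at least one condition truth")
        if self.sigma < 0 or not np.isfinite(self.sigma):
            raise ConfigurationError(f"sigma must be finite and >= 0, got {self.sigma}")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        sched = tuple(float(t) for t in self.schedule)
        if len(sched) == 0:
            raise ConfigurationError("schedule must be non-empty")
        if any(b <= a for a, b in zip(sched, sched[1:])):
            raise ConfigurationError("schedule must be strictly increasing")
        if self.substrate == "aceticlastic":
            for cond, p in self.truths.items():
                if p.P > ACETICLASTIC_P_CEILING:
                    raise ValidationError(
                        f"condition {cond!r}: P={p.P} exceeds the "
                        f"{ACETICLASTIC_P_CEILING} mmol/L stoichiometric ceiling "
                        "of 20 mM acetate"
                    )
        object.__setattr__(self, "schedule", sched)


def default_scenario(sigma_frac: float = 0.02) -> SyntheticScenario:
    """Single-condition hydrogenotrophic scenario with study-shaped defaults.

    Truth (P=30 mmol/L, Rm=0.6 mmol/(L*h), lambda=5 h) with noise
    sigma = 2% of P, duplicate vials, 12 sampling times over 150 h.
    """
    truth = GompertzParams(P=30.0, Rm=0.6, lam=5.0)
    return SyntheticScenario(
        truths={"Control": truth},
        sigma=sigma_frac * truth.P,
        replicates=2,
        substrate="hydrogenotrophic",
    )


def aceticlastic_scenario(sigma_frac: float = 0.02) -> SyntheticScenario:
    """Single-condition acetate scenario (P=18, Rm=0.25, lambda=10)."""
    truth = GompertzParams(P=18.0, Rm=0.25, lam=10.0)
    return SyntheticScenario(
        truths={"Control": truth},
        sigma=sigma_frac * truth.P,
        replicates=2,
        substrate="aceticlastic",
    )


def simulate_dataset(
    scenario: SyntheticScenario, seed: Optional[int] = None
) -> dict[str, AssayTimeSeries]:
    """Draw one dataset per condition; deterministic given the seed.

    methane(t, replicate) = M(t; truth) + N(0, sigma), truncated at zero.
    """
    if seed is None:
        raise ConfigurationError("simulate_dataset requires an explicit seed")
    rng = np.random.default_rng(seed)
    t = np.asarray(scenario.schedule, dtype=float)
    out = {}
    for cond, truth in scenario.truths.items():
        clean = gompertz_curve(t, truth)
        reps, times, values = [], [], []
        for r in range(1, scenario.replicates + 1):
            noisy = clean + rng.normal(0.0, scenario.sigma, size=t.size) \
                if scenario.sigma > 0 else clean.copy()
            noisy = np.maximum(noisy, 0.0)
            reps += [f"R{r}"] * t.size
            times += list(t)
            values += list(noisy)
        out[cond] = AssayTimeSeries.from_arrays(
            cond, reps, times, values, substrate=scenario.substrate
        )
    return out


def _single_truth(scenario: SyntheticScenario) -> tuple[str, GompertzParams]:
    if len(scenario.truths) != 1:
        raise ConfigurationError(
            "calibration experiments need a single-condition scenario"
        )
    return next(iter(scenario.truths.items()))


def _pipeline_intervals(
    series: AssayTimeSeries,
    level: float,
    mcmc_config: MCMCConfig,
    optimizer: OptimizerConfig,
    fit_seed: int,
    mcmc_seed: int,
):
    """fit_mle -> run_mcmc -> central interval + median per kinetic parameter."""
    mle = fit_mle(series, config=optimizer, seed=fit_seed)
    draws = run_mcmc(series, mle, config=mcmc_config, seed=mcmc_seed)
    alpha = (1.0 - level) / 2.0
    intervals, medians = {}, {}
    for name in KINETIC_NAMES:
        x = draws.parameter(name)
        lo, med, hi = np.quantile(x, [alpha, 0.5, 1.0 - alpha])
        intervals[name] = (float(lo), float(hi))
        medians[name] = float(med)
    converged = mle.converged and not draws.warnings
    return intervals, medians, converged


@dataclass(frozen=True)
class CoverageResult:
    """Empirical coverage (%) of central credible intervals per parameter."""

    level: float
    n_datasets: int
    n_used: int
    n_excluded: int
    coverage_pct: dict[str, float]
    mc_standard_error_pct: float

    @property
    def mean_coverage_pct(self) -> float:
        return float(np.mean(list(self.coverage_pct.values())))


def coverage_experiment(
    scenario: SyntheticScenario,
    n_datasets: int = 200,
    level: float = 0.95,
    mcmc_config: MCMCConfig = REDUCED_MCMC,
    seed: Optional[int] = None,
    optimizer: OptimizerConfig = OptimizerConfig(),
    min_datasets: int = 50,
) -> CoverageResult:
    """Interval-calibration experiment on repeated simulated assays.

    For each of ``n_datasets`` simulated datasets the full pipeline
    (hybrid MLE, then MCMC under the log-uniform prior) is run and the
    central ``level`` interval per kinetic parameter is checked against the
    known truth.  Datasets whose fit or sampler raised a convergence
    warning are excluded and counted.
    """
    if seed is None:
        raise ConfigurationError("coverage_experiment requires an explicit seed")
    if n_datasets < min_datasets:
        raise ConfigurationError(f"n_datasets must be >= {min_datasets}")
    _, truth = _single_truth(scenario)
    truth_by_name = dict(zip(KINETIC_NAMES, truth.as_array()))

    ss = np.random.SeedSequence(seed)
    hits = {name: 0 for name in KINETIC_NAMES}
    n_used = 0
    for child in ss.spawn(n_datasets):
        s_data, s_fit, s_mcmc = (int(s.generate_state(1)[0] % 2**31) for s in child.spawn(3))
        series = next(iter(simulate_dataset(scenario, seed=s_data).values()))
        intervals, _, converged = _pipeline_intervals(
            series, level, mcmc_config, optimizer, s_fit, s_mcmc
        )
        if not converged:
            continue
        n_used += 1
        for name, (lo, hi) in intervals.items():
            if lo <= truth_by_name[name] <= hi:
                hits[name] += 1

    if n_used == 0:
        raise ConfigurationError("every simulated dataset was excluded")
    coverage = {name: 100.0 * hits[name] / n_used for name in KINETIC_NAMES}
    mc_se = 100.0 * float(np.sqrt(level * (1 - level) / n_used))
    return CoverageResult(
        level=level,
        n_datasets=n_datasets,
        n_used=n_used,
        n_excluded=n_datasets - n_used,
        coverage_pct=coverage,
        mc_standard_error_pct=mc_se,
    )


@dataclass(frozen=True)
class RecoveryResult:
    """Relative bias and RMSE of posterior medians versus the truth."""

    n_datasets: int
    n_used: int
    n_excluded: int
    relative_bias: dict[str, float]
    relative_rmse: dict[str, float]


def recovery_experiment(
    scenario: SyntheticScenario,
    n_datasets: int = 50,
    mcmc_config: MCMCConfig = REDUCED_MCMC,
    seed: Optional[int] = None,
    optimizer: OptimizerConfig = OptimizerConfig(),
    min_datasets: int = 20,
) -> RecoveryResult:
    """Parameter-recovery experiment: posterior medians against known truth."""
    if seed is None:
        raise ConfigurationError("recovery_experiment requires an explicit seed")
    if n_datasets < min_datasets:
        raise ConfigurationError(f"n_datasets must be >= {min_datasets}")
    _, truth = _single_truth(scenario)
    truth_by_name = dict(zip(KINETIC_NAMES, truth.as_array()))

    ss = np.random.SeedSequence(seed)
    rel_errors: dict[str, list[float]] = {name: [] for name in KINETIC_NAMES}
    for child in ss.spawn(n_datasets):
        s_data, s_fit, s_mcmc = (int(s.generate_state(1)[0] % 2**31) for s in child.spawn(3))
        series = next(iter(simulate_dataset(scenario, seed=s_data).values()))
        _, medians, converged = _pipeline_intervals(
            series, 0.95, mcmc_config, optimizer, s_fit, s_mcmc
        )
        if not converged:
            continue
        for name in KINETIC_NAMES:
            rel_errors[name].append(
                (medians[name] - truth_by_name[name]) / truth_by_name[name]
            )

    n_used = len(rel_errors[KINETIC_NAMES[0]])
    if n_used == 0:
        raise ConfigurationError("every simulated dataset was excluded")
    bias = {k: float(np.mean(v)) for k, v in rel_errors.items()}
    rmse = {k: float(np.sqrt(np.mean(np.square(v)))) for k, v in rel_errors.items()}
    return RecoveryResult(
        n_datasets=n_datasets,
        n_used=n_used,
        n_excluded=n_datasets - n_used,
        relative_bias=bias,
        relative_rmse=rmse,
    )
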