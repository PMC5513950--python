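"""Credible bands, time-point summaries and condition comparisons."""

import numpy as np
import pytest

import methanofit as mf
from methanofit.errors import ConfigurationError
from methanofit.report import PointEstimate, TimePointSummary

from conftest import make_draws


def _point_mass(params=(10.0, 2.0, 5.0, 0.3), n=400):
    return make_draws(np.tile(np.asarray(params), (n, 1)))


def test_point_mass_posterior_gives_zero_width_band():
    draws = _point_mass()
    grid = np.linspace(0, 150, 31)
    band = mf.credible_band(draws, grid, n_samples=300, seed=0)
    expected = mf.gompertz_curve(grid, mf.GompertzParams(10, 2, 5))
    np.testing.assert_allclose(band.lower, expected, rtol=1e-12)
    np.testing.assert_allclose(band.upper, expected, rtol=1e-12)
    np.testing.assert_allclose(band.median, expected, rtol=1e-12)


def test_point_mass_timepoint_values():
    """Direct curve evaluation for (P=10, Rm=2, lambda=5) at t20/t60/t120."""
    summary = mf.summarize_timepoints(_point_mass(), "C")
    assert summary.estimates[20.0].median == pytest.approx(9.992, abs=5e-4)
    assert summary.estimates[60.0].median == pytest.approx(10.000, abs=5e-4)
    assert summary.estimates[120.0].median == pytest.approx(10.000, abs=5e-4)
    assert all(e.deviation == 0.0 for e in summary.estimates.values())


def test_bands_nest_across_levels(reduced_draws):
    grid = np.linspace(0, 150, 51)
    b50 = mf.credible_band(reduced_draws, grid, level=0.50, n_samples=300, seed=4)
    b95 = mf.credible_band(reduced_draws, grid, level=0.95, n_samples=300, seed=4)
    assert np.all(b95.lower <= b50.lower)
    assert np.all(b50.upper <= b95.upper)


def test_band_determinism(reduced_draws):
    grid = np.linspace(0, 150, 11)
    a = mf.credible_band(reduced_draws, grid, n_samples=300, seed=4)
    b = mf.credible_band(reduced_draws, grid, n_samples=300, seed=4)
    np.testing.assert_array_equal(a.lower, b.lower)
    np.testing.assert_array_equal(a.upper, b.upper)


def test_band_asymptote_reduces_to_p_quantiles():
    """When only P varies, the band at t=1e6 h is P's own quantile spread."""
    rng = np.random.default_rng(3)
    P = rng.uniform(8, 12, 500)
    samples = np.column_stack([P, np.full(500, 2.0), np.full(500, 5.0),
                               np.full(500, 0.3)])
    draws = make_draws(samples)
    band = mf.credible_band(draws, [1e6], level=0.95, n_samples=500, seed=0)
    lo, hi = np.quantile(P, [0.025, 0.975])
    assert band.lower[0] == pytest.approx(lo, abs=1e-6)
    assert band.upper[0] == pytest.approx(hi, abs=1e-6)


def test_band_consistent_with_timepoint_summary(reduced_draws):
    """With all draws used, band quantiles equal the summary at the same t."""
    times = (20.0, 60.0, 120.0)
    band = mf.credible_band(reduced_draws, times,
                            n_samples=reduced_draws.n_draws, seed=0)
    summary = mf.summarize_timepoints(reduced_draws, "C", times=times)
    for i, t in enumerate(times):
        est = summary.estimates[t]
        assert band.lower[i] == pytest.approx(est.lower, rel=1e-12)
        assert band.median[i] == pytest.approx(est.median, rel=1e-12)
        assert band.upper[i] == pytest.approx(est.upper, rel=1e-12)


def test_summary_medians_monotone_in_time(reduced_draws):
    summary = mf.summarize_timepoints(reduced_draws, "C")
    meds = [summary.estimates[t].median for t in summary.times]
    assert meds == sorted(meds)


def test_band_rejects_oversized_subsample(reduced_draws):
    with pytest.raises(ConfigurationError):
        mf.credible_band(reduced_draws, [0, 10], n_samples=reduced_draws.n_draws + 1)
    with pytest.raises(ConfigurationError):
        mf.credible_band(reduced_draws, [0, 10], level=1.5, n_samples=10)


def _fixed_summary(cond, med, dev):
    return TimePointSummary(
        condition_id=cond, times=(120.0,),
        estimates={120.0: PointEstimate(med, med - dev, med + dev)},
    )


def test_compare_percent_change():
    """Control 30.0 vs treatment 18.0 at t120 is a 40% reduction."""
    res = mf.compare_conditions(
        _fixed_summary("Control", 30.0, 2.0), _fixed_summary("Ni-H-8", 18.0, 2.0),
        120.0,
    )
    assert res.percent_change == pytest.approx(-40.0)


def test_compare_identity_overlaps():
    s = _fixed_summary("Control", 30.0, 2.0)
    res = mf.compare_conditions(s, s, 120.0)
    assert res.percent_change == 0.0
    assert res.intervals_overlap


def test_compare_disjoint_intervals():
    a = _fixed_summary("A", 11.0, 1.0)   # [10, 12]
    b = _fixed_summary("B", 14.0, 1.0)   # [13, 15]
    res = mf.compare_conditions(a, b, 120.0)
    assert not res.intervals_overlap


def test_compare_missing_timepoint_raises():
    a = _fixed_summary("A", 11.0, 1.0)
    with pytest.raises(KeyError):
        mf.compare_conditions(a, a, 60.0)
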