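"""Input validation and round-trip behaviour of the delimited-text layer."""

import numpy as np
import pandas as pd
import pytest

import methanofit as mf
from methanofit.dataio import (
    read_summary_table,
    read_timeseries,
    write_summary_table,
    write_timeseries,
)
from methanofit.errors import (
    DuplicateKeyError,
    InsufficientDataError,
    SchemaError,
    ValidationError,
)
from methanofit.report import PointEstimate, TimePointSummary


def _csv(tmp_path, rows, header="condition,replicate,time_h,ch4_mmol_per_l"):
    path = tmp_path / "assay.csv"
    path.write_text("\n".join([header] + rows) + "\n")
    return path


TIMES = [2, 20, 40, 60, 90, 120]


def _well_formed_rows():
    rows = []
    for rep in ("R1", "R2"):
        for i, t in enumerate(TIMES):
            rows.append(f"Control,{rep},{t},{1.5 * i + 0.25}")
    return rows


def test_read_preserves_all_rows(tmp_path):
    path = _csv(tmp_path, _well_formed_rows())
    series = read_timeseries(path, "Control")
    assert series.n_obs == 12
    assert sorted(set(series.replicate_ids)) == ["R1", "R2"]
    # sorted by (replicate, time)
    assert list(series.times[:6]) == TIMES


def test_negative_methane_cites_file_row(tmp_path):
    rows = _well_formed_rows()
    rows[5] = "Control,R1,120,-0.1"  # file row 7 (header is row 1)
    with pytest.raises(ValidationError, match="row 7"):
        read_timeseries(_csv(tmp_path, rows), "Control")


def test_duplicate_replicate_time_pair_rejected(tmp_path):
    rows = _well_formed_rows()
    rows[3] = rows[2]
    with pytest.raises(DuplicateKeyError):
        read_timeseries(_csv(tmp_path, rows), "Control")


def test_missing_column_named_in_error(tmp_path):
    path = _csv(
        tmp_path,
        ["Control,R1,0,0.1"],
        header="condition,replicate,time_h,methane",
    )
    with pytest.raises(SchemaError, match="ch4_mmol_per_l"):
        read_timeseries(path, "Control")


def test_too_few_time_points_rejected(tmp_path):
    rows = [f"Control,R1,{t},{v}" for t, v in [(0, 0.1), (10, 1.0), (20, 2.0)]]
    with pytest.raises(InsufficientDataError):
        read_timeseries(_csv(tmp_path, rows), "Control")


def test_unknown_condition_rejected(tmp_path):
    path = _csv(tmp_path, _well_formed_rows())
    with pytest.raises(ValidationError, match="Ni-H-8"):
        read_timeseries(path, "Ni-H-8")


def test_timeseries_roundtrip(tmp_path, noisy_series):
    path = tmp_path / "out.csv"
    write_timeseries(noisy_series, path)
    back = read_timeseries(path, noisy_series.condition_id)
    np.testing.assert_allclose(back.times, noisy_series.times)
    np.testing.assert_allclose(back.methane, noisy_series.methane, rtol=1e-5)


def _summary(cond, values):
    times = (20.0, 60.0, 120.0)
    return TimePointSummary(
        condition_id=cond,
        times=times,
        estimates={
            t: PointEstimate(v, v - 0.5, v + 0.5) for t, v in zip(times, values)
        },
    )


def test_summary_table_shape_and_roundtrip(tmp_path):
    path = tmp_path / "summary.csv"
    summaries = [
        _summary("Control", (5.0, 20.0, 29.5)),
        _summary("Ni-H-8", (3.0, 12.0, 17.7)),
        _summary("Co-H-30", (2.0, 10.0, 17.0)),
    ]
    write_summary_table(summaries, path)
    df = read_summary_table(path)
    assert df.shape == (3, 7)  # condition + (value, deviation) x 3 time points
    assert df.loc[0, "M120_mmol_per_l"] == pytest.approx(29.5, abs=1e-4)
    assert df.loc[1, "dev95_t60"] == pytest.approx(0.5, abs=1e-4)


def test_summary_table_empty_is_header_only(tmp_path):
    path = tmp_path / "summary.csv"
    write_summary_table([], path)
    df = pd.read_csv(path)
    assert len(df) == 0
    assert df.columns[0] == "condition"


def test_summary_table_rejects_mixed_time_sets(tmp_path):
    a = _summary("Control", (5.0, 20.0, 29.5))
    b = TimePointSummary(
        condition_id="X",
        times=(10.0, 60.0, 120.0),
        estimates={t: PointEstimate(1, 0.5, 1.5) for t in (10.0, 60.0, 120.0)},
    )
    with pytest.raises(ValidationError):
        write_summary_table([a, b], tmp_path / "summary.csv")


def test_observation_invariants():
    with pytest.raises(ValidationError):
        mf.Observation(time=-1.0, methane=0.0, replicate_id="R1")
    with pytest.raises(ValidationError):
        mf.Observation(time=0.0, methane=-0.1, replicate_id="R1")
    with pytest.raises(ValidationError):
        mf.Observation(time=0.0, methane=0.1, replicate_id="")
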