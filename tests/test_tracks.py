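import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pigmove import tracks
from pigmove.tracks import (
    Burst,
    FixFormatError,
    assign_season,
    clean,
    compute_steps,
    parse_fixes,
    regularize,
)


def _csv(text, tmp_path, name="fixes.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


def _hourly_fixes(n, start="2014-03-01T00:00:00Z", animal="A1", step=100.0):
    t = pd.date_range(start, periods=n, freq="1h", tz="UTC")
    return pd.DataFrame(
        {"animal_id": animal, "t": t, "x": np.arange(n) * step, "y": 0.0}
    )


class TestParse:
    def test_well_formed(self, tmp_path):
        p = _csv(
            "animal_id,timestamp,x,y\n"
            "A1,2014-01-05T00:00:00Z,100,200\n"
            "A1,2014-01-05T01:00:00Z,150,220\n"
            "A1,2014-01-05T02:00:00Z,170,240\n",
            tmp_path,
        )
        out = parse_fixes(p)
        assert len(out) == 3
        assert out["t"].dt.tz is not None
        assert out.attrs["rejected_rows"] == []

    def test_missing_column_named(self, tmp_path):
        p = _csv("animal_id,timestamp,x\nA1,2014-01-05T00:00:00Z,1\n", tmp_path)
        with pytest.raises(FixFormatError, match="y"):
            parse_fixes(p)

    def test_bad_timestamp_row_rejected(self, tmp_path):
        p = _csv(
            "animal_id,timestamp,x,y\n"
            "A1,2014-01-05T00:00:00Z,1,2\n"
            "A1,not-a-date,3,4\n"
            "A1,2014-01-05T02:00:00Z,5,6\n",
            tmp_path,
        )
        out = parse_fixes(p)
        assert len(out) == 2
        assert out.attrs["rejected_rows"] == [1]


class TestClean:
    def test_48h_halfopen_rule(self):
        fixes = _hourly_fixes(100)
        track = clean(fixes, deploy_time=fixes["t"].iloc[0])
        # hours 0..47 dropped, hour 48 (exactly deploy + 48 h) retained
        assert len(track) == 52
        assert track.log.n_acclimation == 48
        assert track.fixes["t"].iloc[0] == fixes["t"].iloc[48]

    def test_duplicate_timestamps_first_kept(self):
        fixes = _hourly_fixes(60)
        dup = fixes.iloc[[55]].assign(x=999.0)
        fixes = pd.concat([fixes, dup], ignore_index=True)
        track = clean(fixes, deploy_time=fixes["t"].min())
        assert track.log.n_duplicates == 1
        kept = track.fixes.loc[
            track.fixes["t"] == dup["t"].iloc[0], "x"
        ].iloc[0]
        assert kept == 55 * 100.0

    def test_mortality_cutoff(self):
        fixes = _hourly_fixes(100)
        mt = fixes["t"].iloc[79]  # fix 80 of 100 (1-based)
        track = clean(fixes, deploy_time=fixes["t"].iloc[0], mortality_time=mt)
        assert track.log.n_post_mortality == 21
        assert track.fixes["t"].max() < mt

    def test_empty_result_is_signal_not_crash(self):
        fixes = _hourly_fixes(10)
        track = clean(fixes, deploy_time=fixes["t"].iloc[0])
        assert track.empty

    def test_idempotent(self):
        fixes = _hourly_fixes(120)
        t1 = clean(fixes, deploy_time=fixes["t"].iloc[0])
        t2 = clean(
            t1.fixes.assign(animal_id="A1"),
            deploy_time=fixes["t"].iloc[0],
        )
        pd.testing.assert_frame_equal(t1.fixes, t2.fixes)


class TestRegularize:
    def _track(self, df):
        return clean(df, deploy_time=df["t"].min() - pd.Timedelta(hours=49))

    def test_30min_thinned_to_hourly(self):
        t = pd.date_range("2014-03-05", periods=10, freq="30min", tz="UTC")
        df = pd.DataFrame({"animal_id": "A1", "t": t, "x": np.arange(10.0), "y": 0.0})
        bursts = regularize(self._track(df))
        assert len(bursts) == 1
        assert len(bursts[0]) == 5
        dt = bursts[0].fixes["t"].diff().dropna().dt.total_seconds()
        assert (dt == 3600).all()

    def test_gap_splits_bursts(self):
        t = list(pd.date_range("2014-03-05", periods=5, freq="1h", tz="UTC"))
        t += list(pd.date_range(t[-1] + pd.Timedelta(hours=3), periods=5, freq="1h", tz="UTC"))
        df = pd.DataFrame({"animal_id": "A1", "t": t, "x": np.arange(10.0), "y": 0.0})
        bursts = regularize(self._track(df))
        assert len(bursts) == 2
        assert [len(b) for b in bursts] == [5, 5]

    def test_short_fragment_discarded(self):
        t = list(pd.date_range("2014-03-05", periods=6, freq="1h", tz="UTC"))
        t += list(pd.date_range(t[-1] + pd.Timedelta(hours=5), periods=2, freq="1h", tz="UTC"))
        df = pd.DataFrame({"animal_id": "A1", "t": t, "x": np.arange(8.0), "y": 0.0})
        bursts = regularize(self._track(df))
        assert len(bursts) == 1
        assert len(bursts[0]) == 6


class TestSeason:
    def test_boundaries(self):
        assert assign_season("2014-04-30T23:00:00Z") == "low_forage"
        assert assign_season("2014-05-01T00:00:00Z") == "high_forage"
        assert assign_season("2019-12-15T12:00:00Z") == "high_forage"

    def test_partition_of_all_months(self):
        seasons = {
            assign_season(pd.Timestamp(2015, m, 15)) for m in range(1, 13)
        }
        assert seasons == {"low_forage", "high_forage"}
        low = [m for m in range(1, 13)
               if assign_season(pd.Timestamp(2015, m, 15)) == "low_forage"]
        assert low == [1, 2, 3, 4]


def _burst_from_xy(xy, start="2014-02-01T05:30:00Z"):
    n = len(xy)
    t = pd.date_range(start, periods=n, freq="1h", tz="UTC")
    df = pd.DataFrame({"t": t, "x": [p[0] for p in xy], "y": [p[1] for p in xy]})
    return Burst("A1", 0, df, 3600.0)


class TestComputeSteps:
    def test_collinear_path(self):
        s = compute_steps(_burst_from_xy([(0, 0), (100, 0), (200, 0)]))
        np.testing.assert_allclose(s.steps, [100.0, 100.0])
        assert np.isnan(s.turns[0])
        assert s.turns[1] == pytest.approx(0.0, abs=1e-12)
        assert s.hours[0] == pytest.approx(5.5)  # fractional clock hour

    def test_reversal_gives_positive_pi(self):
        s = compute_steps(_burst_from_xy([(0, 0), (100, 0), (0, 0)]))
        assert s.turns[1] == pytest.approx(np.pi)

    def test_left_turn_positive(self):
        s = compute_steps(_burst_from_xy([(0, 0), (100, 0), (100, 100)]))
        assert s.turns[1] == pytest.approx(np.pi / 2)

    def test_too_short_burst(self):
        with pytest.raises(ValueError):
            compute_steps(_burst_from_xy([(0, 0), (1, 1)]))

    @given(
        angle=st.floats(0, 2 * np.pi),
        dx=st.floats(-1e4, 1e4),
        dy=st.floats(-1e4, 1e4),
    )
    def test_rigid_motion_invariance(self, angle, dx, dy):
        rng = np.random.default_rng(99)
        xy = rng.uniform(0, 1000, (6, 2))
        base = compute_steps(_burst_from_xy(xy))
        R = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        moved = xy @ R.T + [dx, dy]
        out = compute_steps(_burst_from_xy(moved))
        np.testing.assert_allclose(out.steps, base.steps, rtol=1e-8, atol=1e-6)
        np.testing.assert_allclose(out.turns[1:], base.turns[1:], atol=1e-8)

    def test_count_invariants(self, short_series):
        for s in short_series:
            assert np.isnan(s.turns[0])
            assert np.sum(~np.isnan(s.turns)) == len(s.steps) - 1


class TestPreprocess:
    def test_full_pipeline_counts(self, tmp_path):
        fixes = _hourly_fixes(120)
        p = tmp_path / "f.csv"
        fixes.rename(columns={"t": "timestamp"}).to_csv(p, index=False)
        parsed = parse_fixes(p)
        series = tracks.preprocess(parsed)
        # 120 hourly fixes, 48 dropped for acclimation -> 72 fixes, 71 steps
        assert sum(len(s) for s in series) == 71
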