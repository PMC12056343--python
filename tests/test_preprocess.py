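"""Raw-detection parsing and signal-differential computation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dielscope import compute_signal_differential, read_detections, window_coverage
from dielscope.preprocess import DetectionFormatError, snap_to_grid

T0 = pd.Timestamp("2020-03-10 00:00", tz="UTC")


def _det_frame(rows):
    df = pd.DataFrame(rows, columns=["tag_id", "receiver_id", "timestamp", "signal_dB"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    df["slot"] = snap_to_grid(df["timestamp"])
    return df


def _slots(*indices):
    return [T0 + pd.Timedelta(seconds=180 * i) for i in indices]


class TestReadDetections:
    def test_empty_file_with_header(self, tmp_path, caplog):
        p = tmp_path / "det.csv"
        p.write_text("tag_id,receiver_id,timestamp,signal_dB\n")
        with caplog.at_level("WARNING"):
            out = read_detections(p)
        assert len(out) == 0
        assert any("empty" in r.message for r in caplog.records)

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "det.csv"
        p.write_text("tag_id,receiver_id,timestamp\nb,r,2020-03-10T00:00:00+00:00\n")
        with pytest.raises(DetectionFormatError, match="signal_dB"):
            read_detections(p)

    def test_duplicate_slot_keeps_strongest_signal(self, tmp_path):
        p = tmp_path / "det.csv"
        p.write_text(
            "tag_id,receiver_id,timestamp,signal_dB\n"
            "b1,r1,2020-03-10T00:00:10+00:00,-80\n"
            "b1,r1,2020-03-10T00:01:30+00:00,-70\n"
        )
        out = read_detections(p)
        assert len(out) == 1
        assert out.signal_dB.iloc[0] == -70

    def test_malformed_rows_counted_and_dropped(self, tmp_path, caplog):
        lines = ["tag_id,receiver_id,timestamp,signal_dB"]
        for i in range(11):
            lines.append(f"b1,r1,2020-03-10T{i:02d}:00:00+00:00,-{70 + i}")
        lines.append("b1,r1,not-a-timestamp,-80")
        p = tmp_path / "det.csv"
        p.write_text("\n".join(lines) + "\n")
        with caplog.at_level("WARNING"):
            out = read_detections(p)
        assert len(out) == 11
        assert any("1 malformed" in r.message for r in caplog.records)

    def test_snapping_floors_to_grid(self):
        ts = pd.Series(pd.to_datetime(
            ["2020-03-10 00:02:59+00:00", "2020-03-10 00:03:00+00:00"], utc=True))
        snapped = snap_to_grid(ts)
        assert snapped[0] == pd.Timestamp("2020-03-10 00:00", tz="UTC")
        assert snapped[1] == pd.Timestamp("2020-03-10 00:03", tz="UTC")


class TestSignalDifferential:
    def test_single_receiver_by_definition(self):
        df = _det_frame(
            [("b", "r1", t, s) for t, s in zip(_slots(0, 1, 2, 3), [-80, -80, -70, -75])]
        )
        series = compute_signal_differential(df, "b", "site")
        d = series.d_site.dropna().to_numpy()
        assert np.allclose(d, [0.0, 10.0, 5.0])

    def test_two_receivers_site_mean(self):
        rows = [("b", "r1", t, s) for t, s in zip(_slots(0, 1), [-80, -70])]
        rows += [("b", "r2", t, s) for t, s in zip(_slots(0, 1), [-90, -70])]
        series = compute_signal_differential(_det_frame(rows), "b", "site")
        assert series.d_site.iloc[1] == pytest.approx(15.0)  # mean of 10 and 20

    def test_missing_receiver_slot_uses_available_one(self):
        rows = [("b", "r1", t, s) for t, s in zip(_slots(0, 1, 2), [-80, -70, -70])]
        rows += [("b", "r2", t, s) for t, s in zip(_slots(0, 2), [-90, -60])]
        series = compute_signal_differential(_det_frame(rows), "b", "site")
        # r2 missing slot 1: site value at slot 1 is r1's differential alone;
        # and the gap breaks r2's pair at slot 2 (no differencing across gaps)
        assert series.d_site.iloc[1] == pytest.approx(10.0)
        assert series.data["d_r2"].isna().all()
        assert series.d_site.iloc[2] == pytest.approx(0.0)

    def test_unknown_bird_is_lookup_error(self):
        df = _det_frame([("b", "r1", _slots(0)[0], -80)])
        with pytest.raises(KeyError):
            compute_signal_differential(df, "nope", "site")

    @given(offset=st.floats(min_value=-50, max_value=50))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_baseline_shift_invariance(self, offset):
        """Adding a constant to one receiver's signals leaves d_t unchanged."""
        sig = [-80.0, -75.0, -90.0, -88.0, -60.0]
        base = _det_frame([("b", "r1", t, s) for t, s in zip(_slots(*range(5)), sig)])
        shifted = _det_frame(
            [("b", "r1", t, s + offset) for t, s in zip(_slots(*range(5)), sig)]
        )
        d0 = compute_signal_differential(base, "b", "s").d_site
        d1 = compute_signal_differential(shifted, "b", "s").d_site
        assert np.allclose(d0.dropna(), d1.dropna())

    def test_site_mean_bounded_by_receiver_range(self):
        rng = np.random.default_rng(0)
        rows = []
        for r in ("r1", "r2", "r3"):
            sig = rng.uniform(-100, -60, size=20)
            rows += [("b", r, t, s) for t, s in zip(_slots(*range(20)), sig)]
        series = compute_signal_differential(_det_frame(rows), "b", "s")
        per_rx = series.data[[f"d_{r}" for r in series.receivers]]
        ok = series.d_site.notna()
        assert (series.d_site[ok] >= per_rx[ok].min(axis=1) - 1e-12).all()
        assert (series.d_site[ok] <= per_rx[ok].max(axis=1) + 1e-12).all()


class TestWindowCoverage:
    def _series(self, present):
        rows = [("b", "r1", t, -80.0) for i, t in enumerate(_slots(*range(len(present))))
                if present[i]]
        return compute_signal_differential(_det_frame(rows), "b", "s")

    def test_full_coverage(self):
        s = self._series([True] * 10)
        win = (T0, T0 + pd.Timedelta(seconds=180 * 10))
        # slot 0 has no differential (no predecessor), so 9/10
        assert window_coverage(s, win) == pytest.approx(0.9)

    def test_boundary_three_quarters(self):
        """Exactly 75% coverage fails the strict more-than-75% retention rule."""
        present = [True] * 91 + [False] * 30  # slots 1..90 have pairs: 90/120
        s = self._series(present)
        win = (T0, T0 + pd.Timedelta(seconds=180 * 120))
        cov = window_coverage(s, win)
        assert cov == pytest.approx(0.75)
        assert not cov > 0.75

    def test_empty_window_rejected(self):
        s = self._series([True] * 5)
        with pytest.raises(ValueError):
            window_coverage(s, (T0, T0))

    def test_coverage_monotone_in_receivers(self):
        """Adding a receiver can only add scored slots, never remove them."""
        rng = np.random.default_rng(1)
        keep1 = rng.random(40) < 0.7
        keep2 = rng.random(40) < 0.7
        rows1 = [("b", "r1", t, -80.0) for i, t in enumerate(_slots(*range(40))) if keep1[i]]
        rows2 = [("b", "r2", t, -85.0) for i, t in enumerate(_slots(*range(40))) if keep2[i]]
        win = (T0, T0 + pd.Timedelta(seconds=180 * 40))
        c1 = window_coverage(compute_signal_differential(_det_frame(rows1), "b", "s"), win)
        c12 = window_coverage(
            compute_signal_differential(_det_frame(rows1 + rows2), "b", "s"), win
        )
        assert c12 >= c1
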