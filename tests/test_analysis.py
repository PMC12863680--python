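"""Spike detection, rates, DB metrics, classification and flip counting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dbflip.analysis import (FICurve, FULL_DB_MAX_SPIKES, SpikeTrain,
                             ap_features, build_fi_curve, build_fus_map,
                             classify_cell, count_flips, detect_spikes,
                             find_db_entry, step_firing_rate)
from dbflip.membrane import Trace


def synthetic_trace(spike_times, peak=20.0, base=-70.0, dt=0.05,
                    total=500.0, width=1.0):
    """Triangular spikes of given base width on a flat baseline."""
    t = np.arange(0.0, total, dt)
    v = np.full_like(t, base)
    for ts in spike_times:
        mask = np.abs(t - ts) < width / 2
        v[mask] = base + (peak - base) * (1 - np.abs(t[mask] - ts) / (width / 2))
    return Trace(t, v)


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        tr = Trace(np.arange(0, 100, 0.05), np.full(2000, -70.0))
        assert detect_spikes(tr, -10.0).count == 0

    def test_counts_separated_crossings(self):
        tr = synthetic_trace([50.0, 150.0, 300.0])
        sp = detect_spikes(tr, -10.0)
        assert sp.count == 3
        assert np.allclose(sp.times, [49.83, 149.83, 299.83], atol=0.1)

    def test_refractory_merges_close_crossings(self):
        tr = synthetic_trace([100.0, 101.0], width=0.6)
        assert detect_spikes(tr, -10.0, refractory=2.0).count == 1
        assert detect_spikes(tr, -10.0, refractory=0.5).count == 2

    def test_transient_discard(self):
        tr = synthetic_trace([50.0, 300.0])
        assert detect_spikes(tr, -10.0, t_min=200.0).count == 1

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_spikes(Trace(np.array([0.0]), np.array([0.0])))

    def test_undersampled_trace_rejected(self):
        tr = Trace(np.arange(0, 100, 1.0), np.zeros(100))
        with pytest.raises(ValueError):
            detect_spikes(tr)


class TestRates:
    @pytest.mark.parametrize("count,expected", [(6, 12.0), (0, 0.0), (1, 2.0)])
    def test_count_over_window(self, count, expected):
        sp = SpikeTrain(np.linspace(10, 400, count) if count else np.array([]))
        assert step_firing_rate(sp, 500.0) == pytest.approx(expected)


class TestClassify:
    @pytest.mark.parametrize("f,label", [(7.5, "LFC"), (22.9, "HFC"),
                                         (12.0, "HFC"), (11.99, "LFC")])
    def test_split_at_12_hz(self, f, label):
        assert classify_cell(f) == label

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            classify_cell(-1.0)


class TestDBEntry:
    def test_half_maximum_scan(self):
        curve = FICurve(np.arange(100, 700, 100),
                        np.array([10, 20, 24, 12, 6, 2.0]))
        db = find_db_entry(curve, g_in=5.0)
        assert db.u_db == 400.0
        assert db.f_max == 24.0
        assert db.u_db_over_gin == pytest.approx(80.0)

    def test_monotone_curve_has_no_db(self):
        curve = FICurve(np.arange(5), np.array([0, 5, 10, 15, 20.0]))
        assert not find_db_entry(curve, 5.0).defined

    def test_all_zero_curve_flagged_not_raised(self):
        curve = FICurve(np.arange(3), np.zeros(3))
        db = find_db_entry(curve, 5.0)
        assert not db.defined and db.f_max == 0.0

    def test_normalization_arithmetic(self):
        curve = FICurve(np.array([100.0, 200.0, 300.0]),
                        np.array([10.0, 20.0, 4.0]))
        assert find_db_entry(curve, 5.0).u_db_over_gin == pytest.approx(60.0)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(1, 25), st.integers(0, 30), st.data())
    def test_matches_exhaustive_scan_on_unimodal_curves(self, n_up, peak, data):
        """Oracle: direct exhaustive scan over random unimodal curves."""
        up = sorted(data.draw(st.lists(st.integers(0, peak), min_size=n_up,
                                       max_size=n_up)))
        down = sorted(data.draw(st.lists(st.integers(0, peak), min_size=0,
                                         max_size=20)), reverse=True)
        f = np.array(up + down, float)
        u = np.arange(f.size, dtype=float)
        db = find_db_entry(FICurve(u, f), 1.0)
        # oracle
        if f.max() <= 0:
            assert not db.defined
            return
        i_peak = int(np.argmax(f))
        expect = next((u[i] for i in range(i_peak + 1, f.size)
                       if f[i] <= f.max() / 2), None)
        assert db.u_db == expect


class TestCountFlips:
    @pytest.mark.parametrize("counts,n", [
        ([3, 5, 8, 1, 1, 6, 7, 1, 0], 1),
        ([4, 1, 5, 1, 6, 1], 2),
        ([1, 3, 5, 7, 0, 0], 0),
        ([0, 0, 0], 0),
        ([5, 5, 5], 0),
    ])
    def test_reference_sequences(self, counts, n):
        assert count_flips(counts).n_flips == n

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            count_flips([])

    def test_trailing_db_steps_do_not_change_count(self):
        base = [4, 1, 5, 1, 6]
        r = count_flips(base)
        assert count_flips(base + [0, 1, 2]).n_flips == r.n_flips

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 10), min_size=1, max_size=40))
    def test_matches_bruteforce_label_transitions(self, counts):
        """Oracle: enumerate DB->spiking transitions after arming."""
        labels = ["DB" if c <= FULL_DB_MAX_SPIKES else "S" for c in counts]
        armed_from = None
        for i in range(1, len(labels)):
            if labels[i] == "DB" and "S" in labels[:i]:
                armed_from = i
                break
        expected = 0
        if armed_from is not None:
            for i in range(armed_from, len(labels) - 1):
                if labels[i] == "DB" and labels[i + 1] == "S":
                    expected += 1
        assert count_flips(counts).n_flips == expected


class TestAPFeatures:
    def test_triangular_spike_geometry(self):
        tr = synthetic_trace([100.0], peak=20.0, base=-70.0, width=2.0)
        f = ap_features(tr, 99.0, rmp=-70.0)
        assert f.peak == pytest.approx(20.0, abs=0.5)
        assert f.amplitude == pytest.approx(90.0, abs=0.5)
        # symmetric triangle: half-width is half the base width
        assert f.half_width == pytest.approx(1.0, abs=0.1)

    def test_amplitude_definition(self):
        tr = synthetic_trace([100.0], peak=52.46, base=-75.89)
        f = ap_features(tr, 99.5, rmp=-75.89)
        assert f.amplitude == pytest.approx(52.46 - (-75.89), abs=0.5)

    def test_flat_trace_raises(self):
        tr = Trace(np.arange(0, 100, 0.05), np.full(2000, -70.0))
        with pytest.raises(ValueError):
            ap_features(tr, 50.0, rmp=-70.0)


class TestCurvesAndMaps:
    def _trace(self, u, s, spike_times):
        tr = synthetic_trace(spike_times)
        tr.meta.update({"u": u, "s": s})
        return tr

    def test_all_subthreshold_map_is_zero(self):
        traces = [self._trace(u, s, []) for u in (0, 100) for s in (0, 2)]
        m = build_fus_map(traces, g_in=5.0)
        assert np.all(m.f == 0)

    def test_row_extraction_equals_fi_curve(self):
        traces = [self._trace(u, 2.0, [50.0 * k for k in range(1, u // 100 + 1)])
                  for u in (100, 200, 300)]
        m = build_fus_map(traces + [self._trace(u, 0.0, []) for u in
                                    (100, 200, 300)], g_in=5.0)
        row = m.row(2.0)
        curve = build_fi_curve(traces, g_in=5.0)
        assert np.array_equal(row.f, curve.f)

    def test_missing_grid_points_reported(self):
        traces = [self._trace(0, 0.0, []), self._trace(100, 2.0, [])]
        with pytest.raises(ValueError, match="missing"):
            build_fus_map(traces, g_in=5.0)

    def test_axes_scaled_by_input_conductance(self):
        traces = [self._trace(u, 0.0, []) for u in (0, 100)]
        m = build_fus_map(traces, g_in=5.0)
        assert np.allclose(m.u_over_gin, [0.0, 20.0])
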