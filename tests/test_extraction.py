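"""Preprocessing chain, spike detection, waveform features, duplicate pruning."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from engramephys import extraction, synthetic
from engramephys.core import UnitSpikeTrain, ValidationError, VoltageTrace
from engramephys.experiments import dedup_bruteforce_oracle
from engramephys.extraction import FeatureUndefinedError

FS = 30_000.0


class TestCommonMedian:
    def test_identical_channels_become_zero(self, rng):
        x = rng.normal(0, 1, 1000)
        trace = VoltageTrace(np.tile(x, (5, 1)), FS)
        out = extraction.subtract_common_median(trace)
        assert np.allclose(out.samples, 0)

    def test_constant_channels_keep_offset_pattern(self):
        trace = VoltageTrace(np.array([[1.0] * 10, [2.0] * 10, [3.0] * 10]), FS)
        out = extraction.subtract_common_median(trace)
        assert np.allclose(out.samples, np.array([[-1.0] * 10, [0.0] * 10, [1.0] * 10]))

    def test_output_median_is_zero(self, rng):
        trace = VoltageTrace(rng.normal(0, 1, (7, 500)), FS)
        out = extraction.subtract_common_median(trace)
        assert np.allclose(np.median(out.samples, axis=0), 0)

    def test_single_channel_warns_and_passes_through(self, rng):
        trace = VoltageTrace(rng.normal(0, 1, (1, 100)), FS)
        with pytest.warns(UserWarning):
            out = extraction.subtract_common_median(trace)
        assert np.array_equal(out.samples, trace.samples)


class TestBandpass:
    def make_tone(self, freq, duration=1.0):
        t = np.arange(int(duration * FS)) / FS
        return VoltageTrace(np.sin(2 * np.pi * freq * t)[None, :], FS)

    def test_passband_tone_barely_attenuated(self):
        out = extraction.bandpass(self.make_tone(1000.0))
        mid = out.samples[0, 10_000:20_000]
        assert np.max(np.abs(mid)) > 0.95

    def test_dc_removed(self):
        trace = VoltageTrace(np.full((1, 30_000), 3.0), FS)
        out = extraction.bandpass(trace)
        assert abs(np.mean(out.samples)) < 1e-3

    def test_50hz_strongly_attenuated(self):
        out = extraction.bandpass(self.make_tone(50.0))
        mid = out.samples[0, 10_000:20_000]
        assert np.max(np.abs(mid)) < 0.1

    def test_band_edge_above_nyquist_rejected(self):
        with pytest.raises(ValidationError):
            extraction.bandpass(self.make_tone(100.0), high=20_000.0)


class TestDetect:
    def test_all_zero_trace_no_events(self):
        trace = VoltageTrace(np.zeros((2, 1000)), FS)
        assert extraction.detect_spikes(trace) == []

    def test_gaussian_noise_essentially_no_events(self, rng):
        # threshold 9xMAD ~ 6.07 sigma; expected crossings over 60 s << 1
        trace = VoltageTrace(rng.normal(0, 1, (1, int(60 * FS))), FS)
        events = extraction.detect_spikes(trace)
        assert len(events) <= 1

    def test_embedded_templates_recovered(self):
        cfg = synthetic.SimConfig(noise_sigma=1.0, seed=4)
        times = np.sort(np.random.default_rng(4).uniform(0.01, 4.99, 25))
        times = times[np.concatenate(([True], np.diff(times) > 0.005))]
        trace, inserted = synthetic.generate_voltage_trace(
            {"u": times}, cfg, 5.0, n_channels=1, amplitude_sigma=10.0, seed=5
        )
        events = extraction.detect_spikes(trace)
        det = np.array([e.time for e in events])
        hits = sum(np.min(np.abs(det - t)) <= 0.0005 for t in inserted["u"])
        assert hits >= 0.99 * inserted["u"].size


class TestWaveformFeatures:
    def test_triangular_trough_half_width(self):
        # symmetric triangular trough, total width 0.4 ms -> half-amplitude 0.2 ms
        n_half = int(0.0002 * FS)
        down = np.linspace(0, -1, n_half + 1)
        up = np.linspace(-1, 0, n_half + 1)[1:]
        w = np.concatenate([np.zeros(10), down, up, np.full(10, 0.2)])
        half_amp, _ = extraction.waveform_features(w, FS)
        assert half_amp == pytest.approx(0.2, abs=1000 / FS)

    def test_designed_trough_to_peak_recovered(self):
        tpl = synthetic.biphasic_template(0.35, 0.60, 1.0, FS)
        half_amp, t2p = extraction.waveform_features(tpl, FS)
        assert t2p == pytest.approx(0.60, abs=1000 / FS)
        assert half_amp == pytest.approx(0.35, abs=2 * 1000 / FS)

    def test_amplitude_scale_invariance(self):
        tpl = synthetic.biphasic_template(0.30, 0.50, 1.0, FS)
        assert extraction.waveform_features(tpl, FS) == extraction.waveform_features(5 * tpl, FS)

    def test_monotone_snippet_rejected(self):
        with pytest.raises(FeatureUndefinedError):
            extraction.waveform_features(np.linspace(0, -1, 50), FS)


def make_unit(uid, times, refractory_target=0.0):
    """Unit with a controlled fraction of refractory-period ISI violations."""
    times = np.asarray(times, dtype=float)
    if refractory_target > 0:
        n_bad = max(1, int(round(refractory_target * (times.size - 1))))
        extra = times[:n_bad] + 0.001
        times = np.sort(np.concatenate([times, extra]))
    return UnitSpikeTrain(unit_id=uid, spike_times=np.unique(times))


class TestRemoveDuplicates:
    def test_identical_trains_higher_refractory_removed(self):
        base = np.arange(0.0, 10.0, 0.01)
        a = UnitSpikeTrain("a", np.sort(np.concatenate([base, [5.0015, 7.0015]])))
        b = UnitSpikeTrain("b", np.sort(np.concatenate([base, [1.0015, 3.0015, 5.0015, 8.0015]])))
        assert a.refractory_fraction < b.refractory_fraction
        kept = extraction.remove_duplicates([a, b])
        assert [u.unit_id for u in kept] == ["a"]

    def test_disjoint_trains_both_retained(self):
        a = UnitSpikeTrain("a", np.arange(0.0, 5.0, 0.02))
        b = UnitSpikeTrain("b", np.arange(0.011, 5.0, 0.02))
        kept = extraction.remove_duplicates([a, b])
        assert len(kept) == 2

    def test_twenty_percent_overlap_removes_dirtier_unit(self, rng):
        b_times = np.sort(rng.uniform(0, 100, 500))
        b_times = b_times[np.concatenate(([True], np.diff(b_times) > 0.003))]
        shared = b_times[:: 5]  # 20% of A's spikes coincide with B
        own = np.sort(rng.uniform(0, 100, shared.size * 4)) + 0.0011
        a_times = np.unique(np.concatenate([shared, own]))
        a = make_unit("a", a_times, refractory_target=0.01)
        b = make_unit("b", b_times, refractory_target=0.001)
        frac = extraction.coincident_fraction(a.spike_times, b.spike_times)
        assert frac > 0.10
        kept = extraction.remove_duplicates([a, b])
        assert [u.unit_id for u in kept] == ["b"]

    def test_matches_bruteforce_oracle_on_random_sets(self, rng):
        for trial in range(10):
            units = []
            base = np.sort(rng.uniform(0, 20, 150))
            base = base[np.concatenate(([True], np.diff(base) > 0.003))]
            for i in range(4):
                frac_shared = rng.uniform(0, 0.4)
                n_shared = int(frac_shared * base.size)
                own = np.sort(rng.uniform(0, 20, 100 + i * 10))
                t = np.unique(np.concatenate([base[:n_shared], own]))
                units.append(make_unit(f"u{i}", t, refractory_target=rng.uniform(0, 0.02)))
            fast = extraction.remove_duplicates(units)
            slow = dedup_bruteforce_oracle(units)
            assert [u.unit_id for u in fast] == [u.unit_id for u in slow]

    def test_idempotent(self, rng):
        units = [
            make_unit(f"u{i}", np.sort(rng.uniform(0, 10, 200)), refractory_target=0.01 * i)
            for i in range(3)
        ]
        once = extraction.remove_duplicates(units)
        twice = extraction.remove_duplicates(once)
        assert [u.unit_id for u in once] == [u.unit_id for u in twice]

    def test_empty_input(self):
        assert extraction.remove_duplicates([]) == []


@given(
    a=st.lists(st.floats(0, 10, allow_nan=False), min_size=0, max_size=40, unique=True),
    b=st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=40, unique=True),
)
def test_coincident_fraction_matches_double_loop(a, b):
    a, b = np.sort(a), np.sort(b)
    fast = extraction.coincident_fraction(a, b, 0.0005)
    small, large = (a, b) if a.size <= b.size else (b, a)
    if small.size == 0:
        assert fast == 0.0
        return
    slow = np.mean([any(abs(t - u) <= 0.0005 for u in large) for t in small])
    assert fast == pytest.approx(slow)
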