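"""The generator must match its own analytic expectations, or nothing
downstream is testable."""

import numpy as np
import pytest

from engramephys import synthetic
from engramephys.core import ValidationError
from engramephys.synthetic import SimConfig


def union_length(intervals):
    """Brute-force union length of a set of intervals."""
    total = 0.0
    for on, off in sorted(map(tuple, intervals)):
        total += off - on
    return total


class TestEpisodeTimeline:
    def test_zero_duty_gives_empty_timeline(self):
        tl = synthetic.generate_episode_timeline("freezing", 300.0, 5.0, 0.0, seed=0)
        assert len(tl) == 0
        assert tl.covered_time == 0.0

    @pytest.mark.parametrize("duty,mean_len", [(1.0, 5.0), (1.5, 5.0), (0.3, 0.0), (0.3, -1.0)])
    def test_invalid_parameters_rejected(self, duty, mean_len):
        with pytest.raises(ValidationError):
            synthetic.generate_episode_timeline("freezing", 300.0, mean_len, duty, seed=0)

    def test_intervals_sorted_disjoint_within_session(self):
        tl = synthetic.generate_episode_timeline("nocifensive", 300.0, 5.0, 0.3, seed=42)
        iv = tl.intervals
        assert np.all(iv[:, 0] < iv[:, 1])
        assert np.all(iv[1:, 0] >= iv[:-1, 1])
        assert iv[0, 0] >= 0 and iv[-1, 1] <= 300.0
        # covered time equals the brute-force interval-union length
        assert tl.covered_time == pytest.approx(union_length(iv))

    def test_mean_coverage_matches_duty(self):
        # coverage of one 300-s session fluctuates; its mean over replicates
        # must sit at the duty cycle (s.e. of the mean ~ 0.006 here)
        covers = [
            synthetic.generate_episode_timeline("freezing", 300.0, 5.0, 0.3, seed=s).covered_time
            / 300.0
            for s in range(100)
        ]
        assert np.mean(covers) == pytest.approx(0.3, abs=3 * np.std(covers) / 10)

    def test_different_seeds_different_intervals_same_statistics(self):
        a = synthetic.generate_episode_timeline("freezing", 300.0, 5.0, 0.3, seed=1)
        b = synthetic.generate_episode_timeline("freezing", 300.0, 5.0, 0.3, seed=2)
        assert a.intervals.shape != b.intervals.shape or not np.allclose(a.intervals, b.intervals)
        assert abs(a.covered_time - b.covered_time) < 0.5 * 300.0


class TestUnitSessions:
    def test_deterministic_under_fixed_seed(self):
        e1 = synthetic.generate_unit_sessions(SimConfig(n_units=10, seed=7))
        e2 = synthetic.generate_unit_sessions(SimConfig(n_units=10, seed=7))
        for session in e1.spikes:
            for uid in e1.spikes[session]:
                assert np.array_equal(e1.spikes[session][uid], e2.spikes[session][uid])
        assert e1.truth.equals(e2.truth)

    def test_spike_times_strictly_increasing_and_refractory(self):
        exp = synthetic.generate_unit_sessions(SimConfig(n_units=10, seed=3))
        for session, trains in exp.spikes.items():
            for t in trains.values():
                if t.size > 1:
                    assert np.all(np.diff(t) >= 0.002 - 1e-12)

    def test_matched_units_gain_inside_episodes(self):
        # a fear-specific unit at gain 3 fires ~3x faster inside freezing bouts
        cfg = SimConfig(
            n_units=40,
            class_fractions={
                "fear_specific": 1.0,
                "pain_specific": 0.0,
                "common": 0.0,
                "unspecific": 0.0,
            },
            base_rate_range=(4.0, 6.0),
            episode_gain=3.0,
            seed=5,
        )
        exp = synthetic.generate_unit_sessions(cfg)
        tl = exp.timelines["fear"]
        t_in = tl.covered_time
        t_out = cfg.session_durations["fear"] - t_in
        n_in = n_out = 0
        for t in exp.spikes["fear"].values():
            inside = tl.contains(t)
            n_in += inside.sum()
            n_out += (~inside).sum()
        ratio = (n_in / t_in) / (n_out / t_out)
        assert ratio == pytest.approx(3.0, rel=0.12)

    def test_gain_one_log_ratios_centered_on_zero(self):
        cfg = SimConfig(n_units=100, episode_gain=1.0, base_rate_range=(3.0, 8.0), seed=9)
        exp = synthetic.generate_unit_sessions(cfg)
        dur = cfg.session_durations
        L = []
        for uid in exp.spikes["baseline"]:
            rb = exp.spikes["baseline"][uid].size / dur["baseline"]
            rf = exp.spikes["fear"][uid].size / dur["fear"]
            L.append(np.log(rf / rb))
        assert abs(np.mean(L)) < 3 * np.std(L) / 10


class TestVoltageTrace:
    def test_noise_only_mad_recovers_sigma_within_2pct(self):
        cfg = SimConfig(noise_sigma=1.0, seed=0)
        trace, _ = synthetic.generate_voltage_trace({}, cfg, duration=10.0, n_channels=1, seed=0)
        from scipy.stats import median_abs_deviation

        sigma_hat = median_abs_deviation(trace.samples[0], scale="normal")
        assert sigma_hat == pytest.approx(1.0, rel=0.02)

    def test_template_peaks_exceed_nine_mad(self):
        cfg = SimConfig(noise_sigma=1.0, seed=1)
        times = np.arange(0.05, 4.0, 0.05)
        trace, inserted = synthetic.generate_voltage_trace(
            {"u": times}, cfg, duration=4.0, n_channels=1, amplitude_sigma=10.0, seed=1
        )
        from scipy.stats import median_abs_deviation

        thr = 9 * median_abs_deviation(trace.samples[0])
        idx = np.round(inserted["u"] * cfg.fs).astype(int)
        assert np.all(np.abs(trace.samples[0, idx]) > thr)

    def test_zero_duration_empty_trace(self):
        trace, inserted = synthetic.generate_voltage_trace(
            {"u": np.array([1.0])}, SimConfig(seed=0), duration=0.0
        )
        assert trace.n_samples == 0
        assert inserted["u"].size == 0

    def test_nonpositive_amplitude_rejected(self):
        with pytest.raises(ValidationError):
            synthetic.generate_voltage_trace({}, SimConfig(), 1.0, amplitude_sigma=0.0)


class TestCountTable:
    DENSITIES = {"fos": 5935.0, "tag": 3028.0, "dapi": 50_000.0}

    def test_independence_matches_analytic_expectation(self):
        # E[double] = n_dapi * p_fos * p_tag when true_overlap = 0
        vol = 0.5
        doubles = [
            synthetic.generate_count_table(self.DENSITIES, 0.0, vol, seed=s).n_double
            for s in range(200)
        ]
        p = (self.DENSITIES["fos"] / 5e4) * (self.DENSITIES["tag"] / 5e4)
        expect = p * self.DENSITIES["dapi"] * vol
        se = np.std(doubles) / np.sqrt(len(doubles))
        assert np.mean(doubles) == pytest.approx(expect, abs=3 * se)

    def test_reference_scale_densities_reproduced(self):
        # single-label densities (~5,935 Fos+ and ~3,028 tag+ per mm^3) come
        # back as the empirical means over replicates
        vol = 0.5
        tabs = [synthetic.generate_count_table(self.DENSITIES, 0.2, vol, seed=s) for s in range(100)]
        fos = [t.n_fos / vol for t in tabs]
        tag = [t.n_tag / vol for t in tabs]
        assert np.mean(fos) == pytest.approx(5935, abs=3 * np.std(fos) / 10)
        assert np.mean(tag) == pytest.approx(3028, abs=3 * np.std(tag) / 10)

    def test_zero_volume_all_counts_zero(self):
        t = synthetic.generate_count_table(self.DENSITIES, 0.3, 0.0, seed=0)
        assert (t.n_fos, t.n_tag, t.n_double, t.n_dapi) == (0, 0, 0, 0)

    def test_negative_density_rejected(self):
        with pytest.raises(ValidationError):
            synthetic.generate_count_table({"fos": -1, "tag": 1, "dapi": 10}, 0.0, 1.0, seed=0)

    def test_invariants_hold(self):
        for s in range(20):
            t = synthetic.generate_count_table(self.DENSITIES, 0.5, 0.3, seed=s)
            assert t.n_double <= min(t.n_fos, t.n_tag)
            assert max(t.n_fos, t.n_tag) <= t.n_dapi


class TestFeatureMixture:
    def test_requested_separation_achieved(self):
        df = synthetic.generate_feature_mixture(4000, separation=3.0, seed=0)
        for col in ("trough_to_peak_ms", "mean_rate_hz"):
            a = df.loc[df.phenotype == "principal", col]
            b = df.loc[df.phenotype == "interneuron", col]
            pooled_sd = 0.5 * (a.std() + b.std())
            assert abs(a.mean() - b.mean()) / pooled_sd == pytest.approx(3.0, rel=0.1)


def test_config_validation_rejects_bad_fractions():
    cfg = SimConfig(
        class_fractions={"fear_specific": 0.5, "pain_specific": 0.5, "common": 0.5, "unspecific": -0.5}
    )
    with pytest.raises(ValidationError):
        cfg.validate()
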