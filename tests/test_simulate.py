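"""Synthetic cohort generator: band content, determinism, STA draws."""

import numpy as np
import pytest
from scipy import signal as sps

from eegstress import (
    SYNTH_BAND_EDGES,
    SimulationConfig,
    STARecord,
    make_band_signal,
    one_over_f_noise,
    simulate_cohort,
    simulate_recording,
)
from eegstress.simulate import simulate_sta_cohort


def band_energy_fraction(x, fs, lo, hi):
    f, p = sps.welch(x, fs=fs, nperseg=min(len(x), 1024))
    inside = p[(f >= lo) & (f <= hi)].sum()
    return inside / p.sum()


class TestMakeBandSignal:
    @pytest.mark.parametrize("band", sorted(SYNTH_BAND_EDGES))
    def test_energy_concentrates_in_band(self, band, rng):
        x = make_band_signal(band, 2.0, 256.0, 10.0, rng)
        assert len(x) == 512
        lo, hi = SYNTH_BAND_EDGES[band]
        assert band_energy_fraction(x, 256.0, lo, hi) > 0.9

    def test_zero_rms_gives_zeros(self, rng):
        assert not np.any(make_band_signal("delta", 3.0, 256.0, 0.0, rng))

    def test_rms_calibration(self, rng):
        x = make_band_signal("gamma", 4.0, 256.0, 5.0, rng)
        assert x.std() == pytest.approx(5.0, rel=0.10)

    def test_unknown_band_names_valid_ones(self, rng):
        with pytest.raises(ValueError, match="delta"):
            make_band_signal("sigma", 1.0, 256.0, 1.0, rng)

    def test_negative_rms_rejected(self, rng):
        with pytest.raises(ValueError):
            make_band_signal("alpha", 1.0, 256.0, -1.0, rng)

    def test_pure_tone_mode_is_narrowband(self, rng):
        x = make_band_signal("alpha", 4.0, 256.0, 10.0, rng, pure_tone=True)
        assert x.std() == pytest.approx(10.0, rel=0.05)
        assert band_energy_fraction(x, 256.0, 8, 15) > 0.95


def test_one_over_f_noise_slope(rng):
    x = one_over_f_noise(256 * 64, 256.0, 1.0, 5.0, rng)
    f, p = sps.welch(x, fs=256.0, nperseg=4096)
    keep = (f >= 1) & (f <= 60)
    slope = np.polyfit(np.log(f[keep]), np.log(p[keep]), 1)[0]
    assert slope == pytest.approx(-1.0, abs=0.25)
    assert x.std() == pytest.approx(5.0, rel=1e-6)


class TestSimulateRecording:
    def test_shape_and_metadata(self):
        cfg = SimulationConfig()
        rec = simulate_recording(cfg, "s01", "male", "baseline")
        assert rec.data.shape == (14, 30720)
        assert rec.subject_id == "s01" and rec.condition == "baseline"
        assert np.all(np.isfinite(rec.data))

    def test_powerline_peak_present(self, tiny_config):
        from dataclasses import replace
        cfg = replace(tiny_config, powerline_amplitude=20.0)
        rec = simulate_recording(cfg, "s01", "male", "baseline")
        for ch in range(rec.n_channels):
            f, p = sps.welch(rec.data[ch], fs=256.0, nperseg=2048)
            peak = f[np.argmax(p * ((f > 40) & (f < 64)))]
            assert abs(peak - 50.0) <= 0.5

    def test_deterministic_given_seed(self, tiny_config):
        a = simulate_recording(tiny_config, "s01", "male", "MI-1")
        b = simulate_recording(tiny_config, "s01", "male", "MI-1")
        np.testing.assert_array_equal(a.data, b.data)

    def test_unknown_condition_rejected(self, tiny_config):
        with pytest.raises(ValueError, match="condition"):
            simulate_recording(tiny_config, "s01", "male", "MI-9")

    def test_single_band_recording_is_narrowband(self):
        amps = {("male", "baseline"): {"alpha": 10.0}}
        cfg = SimulationConfig(
            n_per_group=1, conditions=("baseline",), band_amplitude=amps,
            noise_rms=0.0, powerline_amplitude=0.0, segment_duration=30.0,
        )
        rec = simulate_recording(cfg, "s01", "male", "baseline")
        frac = band_energy_fraction(rec.data[0], 256.0, 8, 15)
        assert frac > 0.9


class TestSimulateCohort:
    def test_default_counts(self, tiny_config):
        recs, stas = simulate_cohort(tiny_config)
        assert len(recs) == 2 * 2 * 2  # groups x subjects x conditions
        assert len(stas) == 4

    def test_single_subject_counts(self):
        cfg = SimulationConfig(n_per_group=1, segment_duration=10.0)
        recs, stas = simulate_cohort(cfg)
        assert len(recs) == 10 and len(stas) == 2

    def test_sta_parameter_recovery_large_n(self):
        cfg = SimulationConfig(n_per_group=500, segment_duration=10.0, seed=5)
        stas = simulate_sta_cohort(cfg)
        for group, sd_true, mean_true in (("male", 7.12, 10.0),
                                          ("female", 6.38, 5.5)):
            diffs = np.array(
                [r.sta1 - r.sta2 for r in stas if r.group == group]
            )
            assert diffs.std(ddof=1) == pytest.approx(sd_true, rel=0.10)
            assert diffs.mean() == pytest.approx(mean_true, rel=0.10)

    def test_sta_scores_clipped_to_scale(self):
        cfg = SimulationConfig(
            n_per_group=200, segment_duration=10.0, seed=3,
            sta_reduction_mean={"male": 40.0, "female": 40.0},
            sta_reduction_sd={"male": 15.0, "female": 15.0},
        )
        for r in simulate_sta_cohort(cfg):
            assert 20.0 <= r.sta1 <= 80.0
            assert 20.0 <= r.sta2 <= 80.0


class TestConfigValidation:
    def test_rejects_low_sampling_rate(self):
        with pytest.raises(ValueError, match="fs"):
            SimulationConfig(fs=100.0)

    def test_rejects_empty_conditions(self):
        with pytest.raises(ValueError):
            SimulationConfig(conditions=())

    def test_rejects_negative_amplitude(self):
        amps = {("male", "baseline"): {"alpha": -1.0}}
        with pytest.raises(ValueError):
            SimulationConfig(conditions=("baseline",), band_amplitude=amps)

    def test_sta_record_range_enforced(self):
        with pytest.raises(ValueError):
            STARecord("s01", "male", 90.0, 50.0)

    def test_with_band_ratio_scales_one_cell(self):
        cfg = SimulationConfig().with_band_ratio("delta", 4.0, group="male")
        base = cfg.band_amplitude[("female", "MI-1")]["delta"]
        assert cfg.band_amplitude[("male", "MI-1")]["delta"] == 4.0 * base
        assert cfg.band_amplitude[("male", "baseline")]["delta"] == base
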