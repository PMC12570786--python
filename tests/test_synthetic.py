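"""Ground-truth generator: environment, schedules, waveforms, datasets."""

from dataclasses import replace
from datetime import date

import numpy as np
import pandas as pd
import pytest

from antelopy import features, synthetic


class TestLabels:
    def test_twelve_raw_labels_total_mapping(self):
        assert len(synthetic.RAW_LABELS) == 12
        assert set(synthetic.ANALYSIS_CLASS_OF) == set(synthetic.RAW_LABELS)
        assert set(synthetic.ANALYSIS_CLASS_OF.values()) <= set(synthetic.ANALYSIS_CLASSES)
        assert synthetic.ANALYSIS_CLASS_OF["browsing"] == "feeding-head-up"
        assert synthetic.ANALYSIS_CLASS_OF["grazing"] == "feeding-head-down"
        assert synthetic.ANALYSIS_CLASS_OF["foraging"] == "feeding-head-down"
        assert synthetic.ANALYSIS_CLASS_OF["sleeping"] == "resting"


class TestEnvSeries:
    def test_zero_amplitude_gives_constant_baseline(self):
        cfg = synthetic.SimConfig(seed=1, ndvi_amplitude=0.0)
        env = synthetic.generate_env_series(cfg)
        assert np.allclose(env.ndvi, cfg.ndvi_base)

    def test_same_seed_identical(self):
        cfg = synthetic.SimConfig(seed=5)
        a = synthetic.generate_env_series(cfg)
        b = synthetic.generate_env_series(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_annual_ndvi_peak_in_feb_apr(self):
        """The configured double-logistic, evaluated at all dates, peaks in
        the Feb-Apr window."""
        cfg = synthetic.SimConfig(seed=1)
        env = synthetic.generate_env_series(cfg)
        peak_month = pd.Timestamp(env.loc[env.ndvi.idxmax(), "date"]).month
        assert peak_month in (2, 3, 4)
        assert env.ndvi.between(-1, 1).all()

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            synthetic.SimConfig(seed=1, start=date(2021, 5, 1), end=date(2021, 4, 1))


class TestScheduleProbabilities:
    def test_lunar_shift_is_additive_before_clamping(self):
        """Full-moon (k~1) minus new-moon (k~0) nocturnal feeding
        probability equals lunar_effect, by the generator's formula."""
        cfg = synthetic.SimConfig(seed=1, lunar_effect=0.10)
        hours = np.zeros(4)
        night = np.ones(4, bool)
        off = np.zeros(len(synthetic.ANALYSIS_CLASSES))
        p_full = synthetic.slot_class_probabilities(cfg, 0.3, off, hours, night, 1.0)
        p_new = synthetic.slot_class_probabilities(cfg, 0.3, off, hours, night, 0.0)
        feed_full = p_full[0, 0] + p_full[0, 1]
        feed_new = p_new[0, 0] + p_new[0, 1]
        assert feed_full - feed_new == pytest.approx(0.10, abs=1e-12)
        assert np.allclose(p_full.sum(axis=1), 1.0)

    def test_no_lunar_effect_identical_probabilities(self):
        cfg = synthetic.SimConfig(seed=1, lunar_effect=0.0)
        hours = np.zeros(2)
        night = np.ones(2, bool)
        off = np.zeros(6)
        p1 = synthetic.slot_class_probabilities(cfg, 0.3, off, hours, night, 1.0)
        p0 = synthetic.slot_class_probabilities(cfg, 0.3, off, hours, night, 0.0)
        assert np.allclose(p1, p0)

    def test_zero_individual_sd_identical_offsets(self):
        cfg = synthetic.SimConfig(seed=9, individual_sd=0.0, n_individuals=4)
        off = cfg.individual_offsets()
        assert np.allclose(off, 0.0)


class TestSchedule:
    @pytest.fixture(scope="class")
    def small(self):
        cfg = synthetic.SimConfig(
            seed=21, n_individuals=2, start=date(2021, 6, 1), end=date(2021, 6, 30)
        )
        env = synthetic.generate_env_series(cfg)
        return cfg, env, synthetic.generate_behaviour_schedule(cfg, env)

    def test_one_row_per_slot_timestamps_increasing(self, small):
        cfg, env, sched = small
        assert len(sched) == cfg.n_individuals * 30 * 288
        for _, grp in sched.groupby("individual_id"):
            ts = pd.to_datetime(grp.burst_start_utc)
            assert ts.is_monotonic_increasing and ts.is_unique

    def test_class_frequencies_match_flat_profile(self):
        """With a flat diel profile, no coupling, no offsets and no lunar
        effect, 30-day class frequencies match the uniform expectation
        within 3 binomial standard errors."""
        flat = {c: np.ones(24) for c in synthetic.ANALYSIS_CLASSES}
        cfg = synthetic.SimConfig(
            seed=22,
            n_individuals=1,
            start=date(2021, 6, 1),
            end=date(2021, 6, 30),
            diel_profile=flat,
            seasonal_coupling={c: 0.0 for c in synthetic.ANALYSIS_CLASSES},
            individual_sd=0.0,
            lunar_effect=0.0,
        )
        env = synthetic.generate_env_series(cfg)
        sched = synthetic.generate_behaviour_schedule(cfg, env)
        n = len(sched)
        p = 1.0 / len(synthetic.ANALYSIS_CLASSES)
        se = np.sqrt(p * (1 - p) / n)
        freqs = sched.label_class.value_counts(normalize=True)
        for c in synthetic.ANALYSIS_CLASSES:
            assert abs(freqs.get(c, 0.0) - p) <= 3 * se

    def test_determinism(self):
        cfg = synthetic.SimConfig(
            seed=23, n_individuals=1, start=date(2021, 6, 1), end=date(2021, 6, 3)
        )
        env = synthetic.generate_env_series(cfg)
        a = synthetic.generate_behaviour_schedule(cfg, env)
        b = synthetic.generate_behaviour_schedule(cfg, env)
        pd.testing.assert_frame_equal(a, b)

    def test_markov_stickiness_increases_persistence(self):
        cfg0 = synthetic.SimConfig(
            seed=24, n_individuals=1, start=date(2021, 6, 1), end=date(2021, 6, 10)
        )
        cfg1 = replace(cfg0, markov_stickiness=0.8)
        env = synthetic.generate_env_series(cfg0)

        def persistence(sched):
            lbl = sched.label_class.to_numpy()
            return float((lbl[1:] == lbl[:-1]).mean())

        p0 = persistence(synthetic.generate_behaviour_schedule(cfg0, env))
        p1 = persistence(synthetic.generate_behaviour_schedule(cfg1, env))
        assert p1 > p0 + 0.3


class TestBurstSynthesis:
    def test_resting_pure_gravity(self):
        cfg = synthetic.SimConfig(seed=1, noise_sd_g=0.0)
        sig = dict(cfg.signal_params)
        sig["low-activity"] = synthetic.BehaviourSignal(0.0)
        cfg = replace(cfg, signal_params=sig)
        b = synthetic.synthesize_burst("low-activity", cfg, cfg.rng(99))
        assert b.shape == (3, 109)
        assert np.all(b[0] == 2048) and np.all(b[1] == 2048)
        assert np.all(b[2] == 2048 + 512)  # 1 G on the heave axis

    def test_all_samples_in_range(self):
        cfg = synthetic.SimConfig(seed=2)
        rng = cfg.rng(98)
        for label in synthetic.RAW_LABELS:
            b = synthetic.synthesize_burst(label, cfg, rng)
            assert b.min() >= 0 and b.max() <= 4095

    def test_walking_dominant_frequency_near_2hz(self):
        """FFT oracle: walking's dominant spectral frequency is within one
        bin of the configured 2 Hz."""
        cfg = synthetic.SimConfig(seed=3, noise_sd_g=0.0, freq_jitter=0.0)
        b = synthetic.synthesize_burst("walking", cfg, cfg.rng(97))
        x = (b[0] - 2048.0) / 512.0
        spec = np.abs(np.fft.rfft(x - x.mean()))
        k = int(np.argmax(spec[1:])) + 1
        f = k * 33.0 / 109
        assert abs(f - 2.0) <= 33.0 / 109

    def test_unknown_label_rejected(self):
        cfg = synthetic.SimConfig(seed=1)
        with pytest.raises(ValueError, match="unknown"):
            synthetic.synthesize_burst("flying", cfg, cfg.rng(1))

    def test_head_down_pitch_below_threshold(self):
        cfg = synthetic.SimConfig(seed=4, noise_sd_g=0.0)
        for label, side in (("grazing", "down"), ("browsing", "up")):
            b = synthetic.synthesize_burst(label, cfg, cfg.rng(5))
            x_mean = (b[0].mean() - 2048.0) / 512.0
            pitch = np.degrees(np.arcsin(np.clip(x_mean, -1, 1)))
            assert (pitch < -30) == (side == "down")

    def test_noise_free_resting_magnitude_one_g(self):
        cfg = synthetic.SimConfig(seed=5, noise_sd_g=0.0)
        b = synthetic.synthesize_burst("sleeping", cfg, cfg.rng(6))
        g = (b.astype(float) - 2048.0) / 512.0
        mag = np.sqrt((g**2).sum(axis=0))
        assert np.all(np.abs(mag - 1.0) <= 3.0 / 512)  # quantisation per axis


class TestReferenceOrientation:
    def test_unflipped_sign_matches_pitch_weighted_sign(self, sim_config):
        xm, ym, zm = synthetic.make_reference_orientation(sim_config)
        expected_sign = np.sign(
            sum(np.sin(np.radians(s.pitch_deg)) for s in sim_config.signal_params.values())
        )
        assert np.sign(xm - 2048.0) == expected_sign

    def test_flipped_individual_has_opposite_x_mean(self, sim_config):
        rng = sim_config.rng(77)
        plain = synthetic._synthesize_many("grazing", 50, sim_config, rng)
        flipped = synthetic._synthesize_many(
            "grazing", 50, sim_config, rng, synthetic.Orientation(flip_x=True)
        )
        m_plain = plain[:, 0].mean() - 2048.0
        m_flip = flipped[:, 0].mean() - 2048.0
        assert np.sign(m_plain) == -np.sign(m_flip)

    def test_empty_individual_set_rejected(self):
        with pytest.raises(ValueError):
            synthetic.make_reference_orientation(
                synthetic.SimConfig(seed=1, n_individuals=0)
            )


class TestWriteDataset:
    def test_round_trip_and_row_counts(self, tmp_path):
        """1 individual x 1 day -> 288 rows; integers survive the CSV."""
        from antelopy import io

        cfg = synthetic.SimConfig(
            seed=31, n_individuals=1, start=date(2021, 7, 1), end=date(2021, 7, 1)
        )
        env = synthetic.generate_env_series(cfg)
        sched = synthetic.generate_behaviour_schedule(cfg, env)
        assert len(sched) == 288
        bursts = synthetic.synthesize_schedule_bursts(sched, cfg)
        acc, envp, lab = tmp_path / "acc.csv", tmp_path / "env.csv", tmp_path / "lab.csv"
        synthetic.write_dataset(sched, bursts, env, acc, envp, labels_path=lab)
        read, rejects = io.read_acc_csv(acc)
        assert len(rejects) == 0 and len(read) == 288
        i = 17
        np.testing.assert_array_equal(read[i].x, bursts[i][0])
        np.testing.assert_array_equal(read[i].y, bursts[i][1])
        np.testing.assert_array_equal(read[i].z, bursts[i][2])
        lab_df = pd.read_csv(lab)
        assert "behaviour" in lab_df.columns
        acc_df = pd.read_csv(acc)
        assert "behaviour" not in acc_df.columns
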