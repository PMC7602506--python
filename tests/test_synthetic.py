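"""Generator contracts: determinism, analytic power/RMSSD, ground-truth fidelity."""

import json

import numpy as np
import pytest

from navload import (
    TrialConfig,
    generate_eda,
    generate_eeg,
    generate_ibi,
    generate_trial,
    read_annotations,
    read_container,
    rmssd,
)
from navload.cognitive import band_power
from navload.preprocess import DEFAULT_BANDS


def quiet_config(**kw):
    """A config with every stochastic component off unless overridden."""
    defaults = dict(
        duration=10.0, noise_sd=0.0, blink_rate=0.0, spontaneous_scr_rate=0.0,
        eda_noise_sd=0.0, tonic_drift=0.0, ibi_jitter_sd=0.0,
        band_amplitudes={b: 0.0 for b in DEFAULT_BANDS if b != "alpha"},
        seed=0,
    )
    defaults.update(kw)
    defaults["band_amplitudes"].pop("alpha", None)
    return TrialConfig(**defaults)


class TestEEG:
    def test_sample_count(self):
        rec = generate_eeg(TrialConfig(duration=10.0, seed=1))
        assert rec.n_samples == 5120
        assert rec.n_channels == 16

    def test_single_tone_rms(self):
        """Noise-free single alpha1 component of amplitude a has RMS a/sqrt(2)."""
        amps = {b: 0.0 for b in ("delta", "theta", "alpha2", "beta", "gamma")}
        amps[("O1", "alpha1")] = 3.0
        amps["alpha1"] = 0.0
        config = TrialConfig(duration=10.0, noise_sd=0.0, blink_rate=0.0,
                             band_amplitudes=amps, seed=2)
        rec = generate_eeg(config)
        assert np.sqrt(np.mean(rec.channel("O1") ** 2)) == pytest.approx(
            3.0 / np.sqrt(2), rel=1e-3)
        assert np.allclose(rec.channel("O2"), 0.0)

    def test_symmetric_noise_has_unit_alpha_ratio(self):
        """With all ratios 1 and noise only, left/right alpha power ratio ~ 1."""
        ratios = []
        for seed in range(20):
            config = TrialConfig(
                duration=8.0, channel_labels=["F3", "F4"], noise_sd=2.0,
                blink_rate=0.0, seed=seed,
                band_amplitudes={b: 0.0 for b in
                                 ("delta", "theta", "alpha1", "alpha2", "beta", "gamma")},
            )
            rec = generate_eeg(config)
            power = band_power(rec, [DEFAULT_BANDS["alpha"]], window=1.0)
            ratios.append(np.log(np.nanmean(power.get("F3", "alpha")))
                          - np.log(np.nanmean(power.get("F4", "alpha"))))
        assert abs(np.mean(ratios)) < 0.1

    def test_injected_asymmetry_power_ratio(self):
        """Homologous band-power ratios match asym_ratios (noise-free: exact-ish)."""
        for ratio in (0.125, 0.5, 2.0, 8.0):
            config = TrialConfig(duration=6.0, channel_labels=["O1", "O2"],
                                 noise_sd=0.0, blink_rate=0.0,
                                 asym_ratios={"alpha1": ratio}, seed=3)
            rec = generate_eeg(config)
            p1 = np.mean(rec.channel("O1") ** 2)  # mixed bands: use alpha1 only
            power = band_power(rec, [DEFAULT_BANDS["alpha1"]], window=1.0)
            measured = (np.nanmean(power.get("O1", "alpha1"))
                        / np.nanmean(power.get("O2", "alpha1")))
            assert measured == pytest.approx(ratio, rel=0.1)
            assert p1 > 0

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="XX9"):
            TrialConfig(channel_labels=["O1", "XX9"])

    def test_blinks_on_prefrontal_only(self):
        config = TrialConfig(duration=10.0, noise_sd=0.0, blink_rate=30.0,
                             blink_amplitude=200.0, seed=4,
                             band_amplitudes={b: 0.0 for b in
                                              ("delta", "theta", "alpha1", "alpha2",
                                               "beta", "gamma")})
        rec = generate_eeg(config)
        assert rec.channel("Fp1").max() > 100.0
        assert np.allclose(rec.channel("P3"), 0.0)


class TestEDA:
    def test_constant_when_quiet(self):
        rec, truth = generate_eda(quiet_config(tonic_level=3.5))
        np.testing.assert_allclose(rec.values, 3.5)
        assert truth["scr_times"] == []

    def test_injected_scr_count(self):
        config = quiet_config(scr_times=(1.0, 4.0, 7.0),
                              scr_amplitudes=(0.2, 0.2, 0.2))
        rec, truth = generate_eda(config)
        assert len(truth["scr_times"]) == 3
        assert rec.values.max() >= 5.0 + 0.18  # near-unit-peak kernel rises ~0.2

    def test_negative_tonic_rejected(self):
        with pytest.raises(ValueError):
            quiet_config(tonic_level=-1.0)

    def test_determinism(self):
        config = TrialConfig(duration=10.0, seed=9)
        a, _ = generate_eda(config)
        b, _ = generate_eda(TrialConfig(duration=10.0, seed=9))
        np.testing.assert_array_equal(a.values, b.values)


class TestIBI:
    def test_zero_jitter_zero_rmssd(self):
        ibi = generate_ibi(quiet_config(duration=30.0))
        assert rmssd(ibi) == 0.0

    def test_alternating_mode_rmssd_2d(self):
        ibi = generate_ibi(quiet_config(duration=60.0, ibi_jitter_sd=15.0,
                                        ibi_pattern="alternating"))
        assert rmssd(ibi) == pytest.approx(30.0)

    def test_beat_count(self):
        ibi = generate_ibi(quiet_config(duration=80.0, mean_ibi=800.0))
        assert len(ibi) == pytest.approx(100, abs=2)

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ValueError, match="nonpositive"):
            generate_ibi(quiet_config(duration=30.0, mean_ibi=50.0,
                                      ibi_jitter_sd=200.0, seed=1))


class TestTrial:
    def test_round_trip(self, trial_dir):
        d, config, truth = trial_dir
        streams = read_container(d / "trial.h5")
        eeg = next(s for s in streams if s.name == "eeg")
        regenerated = generate_eeg(config)
        np.testing.assert_array_equal(eeg.values, regenerated.values.T)
        assert eeg.labels == regenerated.labels
        eda = next(s for s in streams if s.name == "eda")
        regenerated_eda, _ = generate_eda(config)
        np.testing.assert_array_equal(eda.values[:, 0], regenerated_eda.values)

    def test_annotation_rows_match_schedule(self, trial_dir):
        d, config, _ = trial_dir
        log = read_annotations(d / "events.csv")
        assert len(log) == len(config.event_schedule)
        assert log.count("Collision") == 2

    def test_ground_truth_file_consistent(self, trial_dir):
        d, config, truth = trial_dir
        gt = json.loads((d / "ground_truth.json").read_text())
        assert gt["scr_count"] == 3
        assert gt["asym_ratios"]["alpha1"] == 2.0
        assert gt["event_counts"]["Collision"] == 2

    def test_missing_stop_rejected(self, tmp_path):
        config = TrialConfig(duration=10.0,
                             event_schedule=[("Start", 0.0), ("Collision", 5.0)])
        with pytest.raises(ValueError, match="Stop"):
            generate_trial(config, tmp_path / "bad")

    def test_identical_seeds_identical_files(self, tmp_path):
        for sub in ("a", "b"):
            generate_trial(TrialConfig(duration=8.0, seed=21), tmp_path / sub)
        assert ((tmp_path / "a/events.csv").read_bytes()
                == (tmp_path / "b/events.csv").read_bytes())
        assert ((tmp_path / "a/ground_truth.json").read_bytes()
                == (tmp_path / "b/ground_truth.json").read_bytes())
        sa = read_container(tmp_path / "a/trial.h5")
        sb = read_container(tmp_path / "b/trial.h5")
        for x, y in zip(sa, sb):
            np.testing.assert_array_equal(x.values, y.values)
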