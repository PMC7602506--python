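"""Band power, asymmetry index, cognitive-load summaries and envelopes."""

import numpy as np
import pytest

from conftest import tone
from navload import (
    DEFAULT_BANDS,
    EEGRecording,
    EventLog,
    PowerSeries,
    asymmetry_envelope,
    asymmetry_index,
    asymmetry_series,
    band_power,
    cl_index,
    global_cl,
    normalize_log_power,
    total_cl,
    vc_asymmetry,
)

DISJOINT = [DEFAULT_BANDS[n] for n in
            ("delta", "theta", "alpha1", "alpha2", "beta", "gamma")]


def make_power(channels, powers, bands=("alpha1",), n_windows=4):
    """PowerSeries with constant per-channel powers (per band if 2-D)."""
    powers = np.atleast_2d(np.asarray(powers, dtype=float))
    if powers.shape[0] == 1 and len(bands) == 1:
        powers = powers.T
    arr = np.tile(powers[None, :, :], (n_windows, 1, 1))
    windows = np.column_stack([np.arange(n_windows) * 1.0,
                               np.arange(n_windows) * 1.0 + 1.0])
    return PowerSeries(windows, list(channels), list(bands), arr)


class TestBandPower:
    def test_unit_tone_power_half(self):
        power = band_power(tone(9.0, duration=12.0), DISJOINT, window=1.0)
        assert np.nanmean(power.get("O1", "alpha1")) == pytest.approx(0.5, rel=0.05)

    def test_zero_signal_zero_power(self):
        rec = EEGRecording(np.zeros((1, 5120)), 512.0, ["O1"])
        power = band_power(rec, DISJOINT)
        assert np.nanmax(power.powers) == pytest.approx(0.0, abs=1e-12)

    def test_white_noise_power_tracks_bandwidth(self):
        rng = np.random.default_rng(5)
        rec = EEGRecording(rng.standard_normal((1, 512 * 60)), 512.0, ["O1"])
        power = band_power(rec, DISJOINT, window=1.0)
        ratio = {b.name: np.nanmean(power.get("O1", b.name)) / (b.hi - b.lo)
                 for b in DISJOINT}
        mean_ratio = np.mean(list(ratio.values()))
        for r in ratio.values():
            assert r == pytest.approx(mean_ratio, rel=0.15)

    def test_window_longer_than_recording_rejected(self):
        with pytest.raises(ValueError, match="window"):
            band_power(tone(9.0, duration=2.0), DISJOINT, window=5.0)

    def test_mostly_missing_windows_dropped(self):
        rec = tone(9.0, duration=10.0)
        rec.values[0, :2000] = np.nan
        power = band_power(rec, [DEFAULT_BANDS["alpha1"]], window=1.0)
        vals = power.get("O1", "alpha1")
        assert np.isnan(vals[0])          # fully-missing window invalid
        assert np.isfinite(vals[-1])      # clean window kept


class TestAsymmetryIndex:
    def test_hand_value(self):
        # (ln e^2 - ln e) / ln(e^2 + e) = 1 / (2 + ln(1 + 1/e))
        expected = 1.0 / np.log(np.e**2 + np.e)
        assert asymmetry_index(np.e**2, np.e) == pytest.approx(expected, abs=5e-5)
        assert round(asymmetry_index(np.e**2, np.e), 4) == 0.4323

    def test_symmetric_case_zero(self):
        assert asymmetry_index(3.7, 3.7) == pytest.approx(0.0)

    def test_exact_antisymmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(0.1, 50.0, 50), rng.uniform(0.1, 50.0, 50)
        np.testing.assert_array_equal(asymmetry_index(a, b), -asymmetry_index(b, a))

    def test_nonpositive_power_rejected(self):
        with pytest.raises(ValueError):
            asymmetry_index(0.0, 1.0)

    def test_unit_total_power_singularity_invalid(self):
        assert np.isnan(asymmetry_index(0.5, 0.5))

    def test_not_scale_invariant(self):
        """Regression: rescaling both powers changes the index (denominator moves)."""
        assert asymmetry_index(4.0, 2.0) != pytest.approx(asymmetry_index(40.0, 20.0))


class TestCLIndex:
    def test_zero_asymmetry_zero_cl(self):
        power = make_power(["F3", "F4"], [2.0, 2.0])
        cl = cl_index(asymmetry_series(power, ("F3", "F4"), "alpha1"))
        np.testing.assert_allclose(cl.values, 0.0)

    def test_cl_is_negative_magnitude(self):
        power = make_power(["F3", "F4"], [8.0, 2.0])
        series = asymmetry_series(power, ("F3", "F4"), "alpha1")
        cl = cl_index(series)
        np.testing.assert_allclose(cl.values, -np.abs(series.values))
        assert np.all(cl.values <= 0)

    def test_stronger_ratio_more_negative(self):
        weak = cl_index(asymmetry_series(make_power(["F3", "F4"], [2.0, 2.0]),
                                         ("F3", "F4"), "alpha1"))
        strong = cl_index(asymmetry_series(make_power(["F3", "F4"], [8.0, 2.0]),
                                           ("F3", "F4"), "alpha1"))
        assert np.mean(strong.values) < np.mean(weak.values)

    def test_non_frontal_pair_rejected(self):
        power = make_power(["O1", "O2"], [2.0, 2.0])
        with pytest.raises(ValueError, match="frontal"):
            cl_index(asymmetry_series(power, ("O1", "O2"), "alpha1"))

    def test_non_homologous_pair_rejected(self):
        power = make_power(["F3", "O2"], [2.0, 2.0])
        with pytest.raises(ValueError, match="homologous"):
            asymmetry_series(power, ("F3", "O2"), "alpha1")


class TestTotalCL:
    def test_task_equals_rest_zero(self):
        p = make_power(["O1"], [3.0])
        assert total_cl(p, "O1", p) == pytest.approx(0.0)

    def test_e_fold_increase_gives_one(self):
        rest = make_power(["O1"], [3.0])
        task = make_power(["O1"], [3.0 * np.e])
        assert total_cl(task, "O1", rest) == pytest.approx(1.0)

    def test_missing_electrode_rejected(self):
        p = make_power(["O1"], [3.0])
        with pytest.raises(KeyError):
            total_cl(p, "Cz", p)


class TestGlobalCL:
    def test_identical_tcls_zero_iqr(self):
        task = make_power(["F3", "F4", "O1"], [2.0, 2.0, 2.0])
        rest = make_power(["F3", "F4", "O1"], [1.0, 1.0, 1.0])
        summary = global_cl(task, rest)
        assert summary.q3 - summary.q1 == pytest.approx(0.0)

    def test_quartiles_of_known_tcls(self):
        # TCLs {1,2,3,4,5}: task power = rest * e^i per channel
        chans = ["Fp1", "F3", "C3", "P3", "O1"]
        rest = make_power(chans, [1.0] * 5)
        task = make_power(chans, list(np.exp([1.0, 2.0, 3.0, 4.0, 5.0])))
        summary = global_cl(task, rest)
        assert summary.median == pytest.approx(3.0)
        assert summary.q1 == pytest.approx(2.0)
        assert summary.q3 == pytest.approx(4.0)
        assert summary.whisker_lo == pytest.approx(1.0)
        assert summary.whisker_hi == pytest.approx(5.0)

    def test_symmetric_sample_zero_skewness(self):
        chans = ["Fp1", "F3", "C3", "P3", "O1"]
        rest = make_power(chans, [1.0] * 5)
        task = make_power(chans, list(np.exp([1.0, 2.0, 3.0, 4.0, 5.0])))
        assert global_cl(task, rest).skewness == pytest.approx(0.0, abs=1e-12)


class TestNormalizeLogPower:
    def test_resting_on_itself_zero_mean(self):
        rng = np.random.default_rng(2)
        arr = rng.uniform(1.0, 5.0, (10, 2, 1))
        windows = np.column_stack([np.arange(10.0), np.arange(10.0) + 1])
        p = PowerSeries(windows, ["O1", "O2"], ["alpha1"], arr)
        out = normalize_log_power(p, p)
        np.testing.assert_allclose(np.nanmean(out.powers, axis=0), 0.0, atol=1e-12)

    def test_missing_channel_named(self):
        task = make_power(["O1", "O2"], [1.0, 1.0])
        rest = make_power(["O1"], [1.0])
        with pytest.raises(ValueError, match="O2"):
            normalize_log_power(task, rest)


class TestEnvelope:
    def _series(self, values, dt=0.5):
        power = make_power(["F3", "F4"], [2.0, 2.0], n_windows=len(values))
        s = asymmetry_series(power, ("F3", "F4"), "alpha1")
        s.values = np.asarray(values, dtype=float)
        s.times = np.arange(len(values)) * dt
        return s

    def test_constant_series_flat_envelope(self):
        env = asymmetry_envelope(self._series([0.3] * 10))
        np.testing.assert_allclose(env.values, 0.3)

    def test_envelope_dominates_at_local_maxima(self):
        rng = np.random.default_rng(3)
        s = self._series(rng.standard_normal(50))
        env = asymmetry_envelope(s)
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(s.values)
        assert np.all(env.values[peaks] >= s.values[peaks] - 1e-12)

    def test_tracks_slow_modulator(self):
        t = np.arange(0, 60.0, 0.1)
        modulator = 2.0 + np.sin(2 * np.pi * 0.02 * t)
        series = self._series(modulator * np.abs(np.sin(2 * np.pi * 0.5 * t)), dt=0.1)
        env = asymmetry_envelope(series)
        inner = (t > 5) & (t < 55)
        rel_err = np.abs(env.values[inner] - modulator[inner]) / modulator[inner]
        assert np.percentile(rel_err, 95) <= 0.05

    def test_collision_marker_at_nearest_window(self):
        s = self._series([0.1, 0.5, 0.2, 0.4, 0.3], dt=1.0)  # centers 0..4
        log = EventLog(["Start", "Collision", "Stop"], [0.0, 2.3, 4.0])
        env = asymmetry_envelope(s, log)
        assert env.markers == [("Collision", 2.0)]

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="3 windows"):
            asymmetry_envelope(self._series([0.1, 0.2]))


class TestVCAsymmetry:
    def test_equal_powers_zero(self):
        power = make_power(["O1", "O2"], [2.0, 2.0])
        series, tcl = vc_asymmetry(power, power)
        np.testing.assert_allclose(series.values, 0.0)
        assert tcl["O1"] == pytest.approx(0.0)

    def test_swap_flips_sign(self):
        p_fwd = make_power(["O1", "O2"], [6.0, 1.0])
        p_rev = make_power(["O1", "O2"], [1.0, 6.0])
        s1, _ = vc_asymmetry(p_fwd, p_fwd)
        s2, _ = vc_asymmetry(p_rev, p_rev)
        np.testing.assert_allclose(s1.values, -s2.values)

    def test_known_ratio_ln_recovered(self):
        power = make_power(["O1", "O2"], [6.0, 1.0])
        ln_ratio = np.nanmean(np.log(power.get("O1", "alpha1"))
                              - np.log(power.get("O2", "alpha1")))
        assert ln_ratio == pytest.approx(np.log(6.0))

    def test_missing_occipital_rejected(self):
        power = make_power(["O1", "F3"], [1.0, 1.0])
        with pytest.raises(ValueError, match="O2"):
            vc_asymmetry(power, power)
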