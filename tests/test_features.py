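"""Signal chain: PD combination, quasi-DC block means, absorbance, slope features."""

import numpy as np
import pandas as pd
import pytest

from ppgvo2.features import (
    PPGRecord,
    VO2Trace,
    absorbance,
    build_feature_table,
    channel_name,
    combine_pd_groups,
    downsample_dc,
    read_ppg_csv,
    window_slopes,
    write_ppg_csv,
)
from ppgvo2.spectra import mixture_coefficient


def _raw_record(n=200, rate=100.0, channels=("w670_pd1", "w670_pd2")):
    rng = np.random.default_rng(0)
    sig = {c: rng.uniform(1.0, 2.0, n) for c in channels}
    return PPGRecord(
        t=np.arange(n) / rate, signal=pd.DataFrame(sig), sampling_rate_hz=rate
    )


class TestCombinePdGroups:
    def test_mean_of_member_diodes(self):
        n = 50
        a = np.linspace(1, 2, n)
        b = np.linspace(3, 1, n)
        raw = PPGRecord(
            t=np.arange(n) / 100.0,
            signal=pd.DataFrame({"w670_da": a, "w670_db": b}),
            sampling_rate_hz=100.0,
        )
        out = combine_pd_groups(raw, {"pd1": ["da", "db"]})
        np.testing.assert_allclose(out.signal["w670_pd1"], (a + b) / 2)

    def test_identical_diodes_pass_through(self):
        n = 30
        a = np.full(n, 1.5)
        raw = PPGRecord(
            t=np.arange(n) / 100.0,
            signal=pd.DataFrame({"w810_da": a, "w810_db": a}),
            sampling_rate_hz=100.0,
        )
        out = combine_pd_groups(raw, {"pd2": ["da", "db"]})
        np.testing.assert_array_equal(out.signal["w810_pd2"], a)

    def test_single_member_group_is_identity(self):
        raw = _raw_record()
        out = combine_pd_groups(raw)  # default: pd1/pd2 map to themselves
        pd.testing.assert_frame_equal(out.signal, raw.signal[out.signal.columns])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="no member"):
            combine_pd_groups(_raw_record(), {"pd1": []})


class TestDownsampleDc:
    def test_output_length_and_rate(self):
        rec = _raw_record(n=60_000)
        out = downsample_dc(rec, window_s=10.0)
        assert out.n_samples == 60
        assert out.sampling_rate_hz == pytest.approx(0.1)

    def test_constant_signal_preserved(self):
        n = 3000
        rec = PPGRecord(
            t=np.arange(n) / 100.0,
            signal=pd.DataFrame({"w670_pd1": np.full(n, 4.2)}),
            sampling_rate_hz=100.0,
        )
        out = downsample_dc(rec)
        np.testing.assert_allclose(out.signal["w670_pd1"], 4.2)

    def test_block_means_match_loop_oracle(self):
        n, rate, w = 2500, 100.0, 5.0
        ramp = np.linspace(0.0, 7.0, n) ** 2
        rec = PPGRecord(
            t=np.arange(n) / rate,
            signal=pd.DataFrame({"w670_pd1": ramp}),
            sampling_rate_hz=rate,
        )
        out = downsample_dc(rec, window_s=w)
        n_per = int(w * rate)
        expected = [ramp[k * n_per : (k + 1) * n_per].mean() for k in range(n // n_per)]
        np.testing.assert_allclose(out.signal["w670_pd1"], expected, rtol=1e-12)

    def test_mean_conservation(self):
        rec = _raw_record(n=4000)
        out = downsample_dc(rec, window_s=10.0)
        included = rec.signal.iloc[: 4000 // 1000 * 1000]
        np.testing.assert_allclose(
            out.signal.mean().to_numpy(), included.mean().to_numpy(), rtol=1e-12
        )

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError, match="shorter than one"):
            downsample_dc(_raw_record(n=500), window_s=10.0)


class TestAbsorbance:
    def test_equal_intensities_give_zero(self):
        assert absorbance(3.0, 3.0) == 0.0

    def test_one_efold_gives_unity(self):
        assert absorbance(3.0 / np.e, 3.0) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("i,i0", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0)])
    def test_nonpositive_inputs_rejected(self, i, i0):
        with pytest.raises(ValueError):
            absorbance(i, i0)

    def test_error_reports_sample_index(self):
        arr = np.array([1.0, 1.0, -2.0, 1.0])
        with pytest.raises(ValueError, match=r"\[2\]"):
            absorbance(arr, 1.0)


class TestWindowSlopes:
    def test_forward_model_consistency(self, forward_record, spectrum, calib):
        """Slope of measured absorbance equals c_tot*l times the extinction slope."""
        sats = np.array([0.4, 0.6, 0.8])
        c_tot, path = 2.3e-3, 0.3
        rec = forward_record(sats, c_tot=c_tot, path_cm=path)
        out = window_slopes(rec, calib)
        lam = np.array(spectrum.wavelengths_nm, dtype=float)
        for k, s in enumerate(sats):
            eps = np.array(
                [mixture_coefficient(spectrum, s, wl) for wl in spectrum.wavelengths_nm]
            )
            expected = c_tot * path * np.polyfit(lam, eps, 1)[0]
            assert out["m1"][k] == pytest.approx(expected, rel=1e-8)
            assert out["m2"][k] == pytest.approx(expected, rel=1e-8)

    def test_intensity_equal_to_reference_gives_zero_slope(self, calib):
        from ppgvo2.calibration import reference_intensity

        cols = {
            channel_name(wl, g): np.full(3, reference_intensity(calib, wl, g))
            for wl in (670, 770, 810, 850, 950)
            for g in ("pd1", "pd2")
        }
        rec = PPGRecord(
            t=5.0 + 10.0 * np.arange(3), signal=pd.DataFrame(cols), sampling_rate_hz=0.1
        )
        out = window_slopes(rec, calib)
        np.testing.assert_allclose(out[["m1", "m2"]].to_numpy(), 0.0, atol=1e-14)

    def test_identical_windows_identical_slopes(self, forward_record, calib):
        rec = forward_record([0.7, 0.7])
        out = window_slopes(rec, calib)
        assert out["m1"][0] == out["m1"][1]
        assert out["m2"][0] == out["m2"][1]

    def test_common_intensity_scale_cancels(self, forward_record, calib):
        """Multiplying all I by a constant shifts absorbance, not its slope."""
        base = window_slopes(forward_record([0.5, 0.9]), calib)
        scaled = window_slopes(forward_record([0.5, 0.9], scale=1.7), calib)
        np.testing.assert_allclose(
            base[["m1", "m2"]], scaled[["m1", "m2"]], rtol=1e-9
        )

    def test_slope_monotone_in_saturation(self, forward_record, calib):
        sats = np.linspace(0.2, 1.0, 17)
        out = window_slopes(forward_record(sats), calib)
        assert np.all(np.diff(out["m1"]) > 0)

    def test_three_wavelength_subset(self, forward_record, spectrum, calib):
        rec = forward_record([0.6])
        out = window_slopes(rec, calib, wavelength_subset=[670, 810, 950])
        lam = np.array([670.0, 810.0, 950.0])
        eps = np.array([mixture_coefficient(spectrum, 0.6, int(w)) for w in lam])
        expected = 2.3e-3 * 0.3 * np.polyfit(lam, eps, 1)[0]
        assert out["m1"][0] == pytest.approx(expected, rel=1e-8)

    def test_nonpositive_intensity_strict_vs_clip(self, forward_record, calib, caplog):
        rec = forward_record([0.5, 0.6])
        rec.signal.loc[0, "w670_pd1"] = -1.0
        with pytest.raises(ValueError, match="w670_pd1"):
            window_slopes(rec, calib)
        with caplog.at_level("WARNING"):
            out = window_slopes(rec, calib, nonpositive="clip")
        assert np.all(np.isfinite(out[["m1", "m2"]].to_numpy()))
        assert any("clipped" in r.message for r in caplog.records)


class TestFeatureTable:
    def _slopes(self, n=3):
        return pd.DataFrame(
            {"t_center_s": 5.0 + 10.0 * np.arange(n), "m1": 0.1 * np.arange(n),
             "m2": 0.2 * np.arange(n)}
        )

    META = {"s01": {"height_cm": 170.0, "weight_kg": 70.0}}

    def test_single_reference_sample_per_window(self):
        ref = VO2Trace(t=np.array([2.0, 12.0, 22.0]), vo2=np.array([5.0, 6.0, 7.0]))
        out = build_feature_table(self._slopes(), "s01", self.META, ref)
        np.testing.assert_array_equal(out["vo2_ref"], [5.0, 6.0, 7.0])
        assert list(out.columns[:2]) == ["subject_id", "t_center_s"]

    def test_window_averages_multiple_breaths(self):
        ref = VO2Trace(t=np.array([1.0, 4.0, 9.0]), vo2=np.array([4.0, 6.0, 8.0]))
        out = build_feature_table(self._slopes(1), "s01", self.META, ref)
        assert out["vo2_ref"][0] == pytest.approx(6.0)

    def test_windows_without_reference_are_dropped(self):
        ref = VO2Trace(t=np.array([12.0]), vo2=np.array([6.0]))
        out = build_feature_table(self._slopes(3), "s01", self.META, ref)
        assert len(out) == 1
        assert out["t_center_s"][0] == 15.0

    def test_boundary_sample_belongs_to_right_window(self):
        # half-open [start, end): a breath exactly at t=10 is in the second window
        ref = VO2Trace(t=np.array([10.0, 12.0]), vo2=np.array([5.0, 7.0]))
        out = build_feature_table(self._slopes(2), "s01", self.META, ref)
        assert len(out) == 1
        assert out["vo2_ref"][0] == pytest.approx(6.0)

    def test_missing_anthropometrics_names_subject(self):
        with pytest.raises(KeyError, match="s99"):
            build_feature_table(self._slopes(), "s99", self.META, None)

    def test_no_reference_keeps_all_windows_with_nan_target(self):
        out = build_feature_table(self._slopes(4), "s01", self.META, None)
        assert len(out) == 4
        assert out["vo2_ref"].isna().all()


def test_ppg_csv_round_trip(tmp_path, forward_record):
    rec = forward_record([0.5, 0.7, 0.9])
    path = tmp_path / "rec.csv"
    write_ppg_csv(rec, path)
    back = read_ppg_csv(path, subject_id=rec.subject_id)
    assert back.signal.columns.tolist() == rec.signal.columns.tolist()
    np.testing.assert_allclose(back.signal.to_numpy(), rec.signal.to_numpy(), rtol=1e-9)
    np.testing.assert_allclose(back.t, rec.t)
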