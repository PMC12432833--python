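import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as ss

from fcoi_nirs.core import (
    ChannelMask,
    ConcentrationSeries,
    EventBlock,
    ExtinctionTable,
    PreprocessConfig,
    REASON_OK,
    RunRecording,
    ValidationError,
)
from fcoi_nirs.preprocess import (
    ODSeries,
    bandpass_filter,
    bandpass_gain,
    correct_motion_tddr,
    detrend_linear,
    intensity_to_od,
    od_to_concentration,
    preprocess_run,
    prune_channels,
    remove_global_pca,
)
from fcoi_nirs.simulate import adult_like_scenario, make_design, simulate_conc, conc_to_intensity

FS = 11.0


def _recording(intensity, montage):
    return RunRecording("s", "language", 1, intensity, [], montage)


def _odseries(x):
    """Wrap a [time, channel] array as single-wavelength OD."""
    return ODSeries(np.asarray(x)[:, :, None], FS)


class TestPrune:
    def test_out_of_range_low(self, adult_montage, config):
        intensity = np.full((100, adult_montage.n_channels, 2), 1e5)
        intensity[:, 0, 0] = 5e2
        mask = prune_channels(_recording(intensity, adult_montage), config)
        assert not mask.kept[0]
        assert mask.reason[0] == "out_of_range"
        assert mask.kept[1:].all()

    def test_out_of_range_high(self, adult_montage, config):
        intensity = np.full((100, adult_montage.n_channels, 2), 1e5)
        intensity[:, 2, 1] = 2e7
        mask = prune_channels(_recording(intensity, adult_montage), config)
        assert mask.reason[2] == "out_of_range"

    def test_constant_channel_kept(self, adult_montage, config):
        intensity = np.full((100, adult_montage.n_channels, 2), 1e5)
        mask = prune_channels(_recording(intensity, adult_montage), config)
        assert mask.kept.all()

    def test_snr_exactly_four_pruned(self, adult_montage, config):
        rng = np.random.default_rng(0)
        intensity = np.full((10000, adult_montage.n_channels, 2), 1e5)
        intensity += rng.standard_normal(intensity.shape)  # huge SNR elsewhere
        wobble = np.sin(np.linspace(0, 400 * np.pi, 10000))
        intensity[:, 3, 0] = 1e5 + 2.5e4 * np.sqrt(2) * wobble  # SD = 2.5e4 -> SNR 4
        mask = prune_channels(_recording(intensity, adult_montage), config)
        assert not mask.kept[3]
        assert mask.reason[3] == "low_snr"

    def test_manual_exclusion(self, adult_montage):
        cfg = PreprocessConfig(manual_exclude_ids=(adult_montage.channel_ids[1],))
        intensity = np.full((50, adult_montage.n_channels, 2), 1e5)
        mask = prune_channels(_recording(intensity, adult_montage), cfg)
        assert not mask.kept[1]
        assert mask.reason[1] == "no_cardiac_manual"

    def test_all_pruned_flagged_not_raised(self, adult_montage, config):
        intensity = np.full((50, adult_montage.n_channels, 2), 1e2)
        mask = prune_channels(_recording(intensity, adult_montage), config)
        assert not mask.any_kept


class TestIntensityToOd:
    def test_constant_is_zero(self, adult_montage):
        n_ch = adult_montage.n_channels
        intensity = np.full((50, n_ch, 2), 1e5)
        mask = ChannelMask(np.ones(n_ch, bool), [REASON_OK] * n_ch)
        od = intensity_to_od(_recording(intensity, adult_montage), mask)
        np.testing.assert_allclose(od.od, 0.0, atol=1e-15)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(5)
        base = 1e5 * np.exp(0.05 * rng.standard_normal((80, 1, 1)))
        mask = ChannelMask(np.array([True]), [REASON_OK])

        class FakeRec:
            intensity = base
            montage = type("M", (), {"sampling_rate_hz": FS})

        od1 = intensity_to_od(FakeRec, mask)
        FakeRec.intensity = base * scale
        od2 = intensity_to_od(FakeRec, mask)
        np.testing.assert_allclose(od1.od, od2.od, atol=1e-12)

    def test_two_level_log_ratio(self):
        a = 2.0e4
        x = np.full((100, 1, 1), a)
        x[50:, 0, 0] = a * np.exp(-0.1)
        mask = ChannelMask(np.array([True]), [REASON_OK])

        class FakeRec:
            intensity = x
            montage = type("M", (), {"sampling_rate_hz": FS})

        od = intensity_to_od(FakeRec, mask)
        diff = od.od[60, 0, 0] - od.od[10, 0, 0]
        np.testing.assert_allclose(diff, 0.1, rtol=1e-12)

    def test_nonpositive_sample_error(self):
        x = np.full((10, 1, 1), 1e5)
        x[3, 0, 0] = -1.0
        mask = ChannelMask(np.array([True]), [REASON_OK])

        class FakeRec:
            intensity = x
            montage = type("M", (), {"sampling_rate_hz": FS})

        with pytest.raises(ValidationError, match="sample 3"):
            intensity_to_od(FakeRec, mask)


class TestDetrend:
    def test_annihilates_line(self):
        t = np.arange(200, dtype=float)
        x = (3.0 + 0.25 * t)[:, None]
        out = detrend_linear(_odseries(x))
        np.testing.assert_allclose(out.od, 0.0, atol=1e-9)

    def test_matches_normal_equations_oracle(self):
        t = np.arange(300, dtype=float)
        x = np.sin(2 * np.pi * t / 50) + 0.01 * t + 2.0
        out = detrend_linear(_odseries(x[:, None])).od[:, 0, 0]
        # independent normal-equations solve
        design = np.column_stack([np.ones_like(t), t])
        beta = np.linalg.solve(design.T @ design, design.T @ x)
        np.testing.assert_allclose(out, x - design @ beta, atol=1e-10)

    def test_output_orthogonal_to_basis(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((150, 3))
        out = detrend_linear(_odseries(x)).od[:, :, 0]
        t = np.arange(150, dtype=float)
        assert np.all(np.abs(out.sum(axis=0)) < 1e-8)
        assert np.all(np.abs(t @ out) < 1e-5)

    def test_too_short(self):
        with pytest.raises(ValidationError):
            detrend_linear(_odseries(np.zeros((2, 1))))


def _smooth_signal(n=2200, amp=1e-3):
    """Deterministic smooth in-band signal with integer cycle counts (no net
    drift, since TDDR's robust centering removes residual linear trend)."""
    t = np.arange(n) / FS
    dur = n / FS
    f1, f2 = 6 / dur, 2 / dur  # 0.03 and 0.01 Hz for the default length
    return amp * (np.sin(2 * np.pi * f1 * t) + 0.5 * np.sin(2 * np.pi * f2 * t))


def _robust_sd(x):
    return 1.4826 * np.median(np.abs(x - np.median(x)))


class TestTddr:
    def test_smooth_signal_preserved(self):
        x = _smooth_signal()
        out = correct_motion_tddr(_odseries(x[:, None])).od[:, 0, 0]
        r = np.corrcoef(out, x)[0, 1]
        assert r > 0.99

    def test_spike_suppressed_blocks_intact(self):
        x = _smooth_signal()
        t = np.arange(x.size) / FS
        sigma = _robust_sd(x)
        spike_t = 72.7
        amp = 10 * sigma
        spiky = x + amp * np.exp(-0.5 * ((t - spike_t) / 0.8) ** 2)
        out = correct_motion_tddr(_odseries(spiky[:, None])).od[:, 0, 0]
        resid = out - x
        i0 = int(spike_t * FS)
        assert np.abs(resid[i0 - 30:i0 + 30]).max() < 0.1 * amp
        # block-window means away from the spike shift by < 5 % of the
        # injected artifact amplitude
        for lo, hi in ((100, 300), (400, 600), (1400, 1600)):
            assert abs(out[lo:hi].mean() - x[lo:hi].mean()) <= 0.05 * amp

    def test_step_shift_suppressed(self):
        x = _smooth_signal()
        sigma = _robust_sd(x)
        step_at = 900
        shifted = x.copy()
        shifted[step_at:] += 5 * sigma
        out = correct_motion_tddr(_odseries(shifted[:, None])).od[:, 0, 0]
        step_before = 5 * sigma
        step_after = np.median(out[step_at + 20:step_at + 240] - x[step_at + 20:step_at + 240]) \
            - np.median(out[step_at - 240:step_at - 20] - x[step_at - 240:step_at - 20])
        assert abs(step_after) < 0.2 * step_before

    def test_split_frequency_guard(self, config):
        with pytest.raises(ValidationError):
            correct_motion_tddr(ODSeries(np.zeros((100, 1, 1)), 0.9), config=config)


class TestBandpass:
    def _gain(self, freq, n=22000):
        t = np.arange(n) / FS
        x = np.sin(2 * np.pi * freq * t)
        out = bandpass_filter(_odseries(x[:, None])).od[:, 0, 0]
        trim = slice(n // 4, 3 * n // 4)
        return np.sqrt(np.mean(out[trim] ** 2)) / np.sqrt(np.mean(x[trim] ** 2))

    def test_passband_0p03(self, config):
        empirical = self._gain(0.03)
        analytic = bandpass_gain(0.03, config, FS)
        assert abs(empirical - analytic) <= 0.10 * analytic
        assert abs(empirical - 1.0) <= 0.10

    def test_cardiac_band_rejected(self, config):
        empirical = self._gain(1.2)
        analytic = bandpass_gain(1.2, config, FS)
        assert empirical < 0.01
        assert analytic < 0.01

    def test_dc_killed(self):
        x = np.full((4000, 1), 3.3)
        out = bandpass_filter(_odseries(x)).od[:, 0, 0]
        assert abs(out.mean()) < 1e-6 * 3.3

    def test_zero_phase_symmetric_impulse_response(self):
        n, mid = 8001, 4000
        x = np.zeros((n, 1))
        x[mid, 0] = 1.0
        y = bandpass_filter(_odseries(x)).od[:, 0, 0]
        k = np.arange(1, 1500)
        np.testing.assert_allclose(y[mid - k], y[mid + k], atol=1e-5 * np.abs(y).max())

    def test_cutoff_above_nyquist_rejected(self):
        cfg = PreprocessConfig(high_cut_hz=6.0)
        with pytest.raises(ValidationError):
            bandpass_filter(_odseries(np.zeros((100, 1))), cfg)


class TestBeerLambert:
    def test_zero_od_zero_conc(self, adult_montage, adult_extinction, config):
        n_ch = adult_montage.n_channels
        mask = ChannelMask(np.ones(n_ch, bool), [REASON_OK] * n_ch)
        od = ODSeries(np.zeros((20, n_ch, 2)), FS)
        conc = od_to_concentration(od, adult_montage, adult_extinction, config, mask)
        np.testing.assert_allclose(conc.hbo, 0.0)
        np.testing.assert_allclose(conc.hbr, 0.0)

    def test_two_wavelength_round_trip_exact(self, adult_montage, adult_extinction, config):
        rng = np.random.default_rng(4)
        n_ch = adult_montage.n_channels
        hbo = 1e-6 * rng.standard_normal((60, n_ch))
        hbr = 1e-6 * rng.standard_normal((60, n_ch))
        e = adult_extinction.matrix()
        d_cm = adult_montage.separation_mm / 10.0
        od = (hbo[:, :, None] * e[None, None, :, 0] + hbr[:, :, None] * e[None, None, :, 1])
        od *= d_cm[None, :, None] * config.ppf
        mask = ChannelMask(np.ones(n_ch, bool), [REASON_OK] * n_ch)
        conc = od_to_concentration(ODSeries(od, FS), adult_montage, adult_extinction,
                                   config, mask)
        np.testing.assert_allclose(conc.hbo, hbo, rtol=1e-12, atol=1e-18)
        np.testing.assert_allclose(conc.hbr, hbr, rtol=1e-12, atol=1e-18)

    def test_three_wavelength_least_squares_matches_normal_equations(
        self, toddler_montage, config
    ):
        rng = np.random.default_rng(5)
        ext = ExtinctionTable.for_wavelengths(toddler_montage.wavelengths_nm)
        n_ch = toddler_montage.n_channels
        hbo = 1e-6 * rng.standard_normal((40, n_ch))
        hbr = 1e-6 * rng.standard_normal((40, n_ch))
        e = ext.matrix()
        d_cm = toddler_montage.separation_mm / 10.0
        od = (hbo[:, :, None] * e[None, None, :, 0] + hbr[:, :, None] * e[None, None, :, 1])
        od *= d_cm[None, :, None]
        od += 1e-6 * rng.standard_normal(od.shape)  # small OD noise
        mask = ChannelMask(np.ones(n_ch, bool), [REASON_OK] * n_ch)
        conc = od_to_concentration(ODSeries(od, FS), toddler_montage, ext, config, mask)
        # independent normal-equations solve per channel
        ete_inv = np.linalg.inv(e.T @ e)
        for c in range(0, n_ch, 5):
            scaled = od[:, c, :] / d_cm[c]
            expect = scaled @ e @ ete_inv
            np.testing.assert_allclose(conc.hbo[:, c], expect[:, 0], atol=1e-10)
            np.testing.assert_allclose(conc.hbr[:, c], expect[:, 1], atol=1e-10)


class TestGlobalPca:
    def _series(self, x, montage):
        n_ch = montage.n_channels
        mask = ChannelMask(np.ones(n_ch, bool), [REASON_OK] * n_ch)
        return ConcentrationSeries(x, -x / 3, mask, FS, montage.channel_ids)

    def test_uniform_global_removed(self, adult_montage):
        t = np.arange(900) / FS
        g = 1e-6 * np.sin(2 * np.pi * 0.04 * t)
        x = np.tile(g[:, None], (1, adult_montage.n_channels))
        out = remove_global_pca(self._series(x, adult_montage),
                                adult_montage.channel_positions)
        resid = np.sqrt(np.mean(out.hbo**2))
        assert resid < 0.1 * np.sqrt(np.mean(g**2))

    def test_focal_signal_retained(self, adult_montage):
        t = np.arange(900) / FS
        focal = 1e-6 * np.sin(2 * np.pi * 0.04 * t)
        x = np.zeros((900, adult_montage.n_channels))
        k = adult_montage.index_of(70)
        x[:, k] = focal
        out = remove_global_pca(self._series(x, adult_montage),
                                adult_montage.channel_positions)
        assert np.linalg.norm(out.hbo[:, k]) >= 0.8 * np.linalg.norm(focal)

    def test_zero_in_zero_out(self, adult_montage):
        x = np.zeros((100, adult_montage.n_channels))
        out = remove_global_pca(self._series(x, adult_montage),
                                adult_montage.channel_positions)
        np.testing.assert_allclose(out.hbo, 0.0)

    def test_linearity(self, adult_montage):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((200, adult_montage.n_channels))
        out1 = remove_global_pca(self._series(x, adult_montage),
                                 adult_montage.channel_positions)
        out3 = remove_global_pca(self._series(3.0 * x, adult_montage),
                                 adult_montage.channel_positions)
        np.testing.assert_allclose(out3.hbo, 3.0 * out1.hbo, rtol=1e-8, atol=1e-10)

    def test_fewer_than_three_kept_passthrough(self, adult_montage):
        n_ch = adult_montage.n_channels
        kept = np.zeros(n_ch, bool)
        kept[:2] = True
        reasons = ["ok" if k else "low_snr" for k in kept]
        x = np.random.default_rng(7).standard_normal((50, n_ch))
        conc = ConcentrationSeries(x.copy(), -x / 3, ChannelMask(kept, reasons), FS,
                                   adult_montage.channel_ids)
        out = remove_global_pca(conc, adult_montage.channel_positions)
        np.testing.assert_allclose(out.hbo[:, :2], conc.hbo[:, :2])


class TestPreprocessRun:
    def test_provenance_lists_eight_ordered_steps(self, tiny_cohort):
        _, _, prov = preprocess_run(tiny_cohort.recordings[0])
        assert [p["step"] for p in prov] == [
            "prune_channels",
            "negative_intensity_guard",
            "intensity_to_od",
            "detrend_linear",
            "correct_motion_tddr",
            "bandpass_filter",
            "od_to_concentration",
            "remove_global_pca",
        ]

    def test_per_run_isolation(self, tiny_cohort):
        rec = tiny_cohort.recordings[0]
        a, _, _ = preprocess_run(rec)
        _ = preprocess_run(tiny_cohort.recordings[1])
        b, _, _ = preprocess_run(rec)
        np.testing.assert_array_equal(np.nan_to_num(a.hbo), np.nan_to_num(b.hbo))

    def test_shape_preserved_and_pruning_respected(self, tiny_cohort):
        rec = tiny_cohort.recordings[0]
        conc, mask, _ = preprocess_run(rec)
        assert conc.hbo.shape == (rec.n_time, rec.montage.n_channels)
        assert np.isnan(conc.hbo[:, ~mask.kept]).all() or mask.kept.all()

    def test_noise_free_recovery_matches_filtered_oracle(self):
        """With the simulator's noise off, the chain (TDDR idle) recovers the
        filtered convolution oracle almost exactly; relative to the unfiltered
        oracle, the in-band loss of the specified band-pass + spatial filter
        stays bounded."""
        from dataclasses import replace

        from fcoi_nirs.blocks import baseline_correct_block, block_mean
        from fcoi_nirs.simulate import ExtinctionTable as _ET

        scenario = adult_like_scenario(
            n_subjects=1, n_extra_channels=46, white_sd_um=0.0, drift_sd_um=0.0,
            cardiac_amp_um=0.0, respiration_amp_um=0.0, mayer_amp_um=0.0,
            global_amp_um=0.0, spike_rate_per_min=0.0, shift_rate_per_min=0.0,
        )
        montage = scenario.montage()
        fs = montage.sampling_rate_hz
        truth = scenario.build_truth(montage, 0)
        design = scenario.language_design
        task = design.task
        events = make_design(design, 0, 1)
        n_time = int(round(design.run_duration_s * fs))
        clean = simulate_conc(truth, events, task, n_time, fs)
        ext = ExtinctionTable.for_wavelengths(montage.wavelengths_nm)
        rec = conc_to_intensity(clean, montage, ext, 1e5, subject_id="s",
                                task_id="language", run_index=1, events=events)
        idx = montage.index_of(70)

        def contrast(conc):
            per = {}
            for cond in task.condition_labels:
                vals = []
                for ev in [e for e in events if e.condition == cond]:
                    seg = baseline_correct_block(conc, ev, 2.0)
                    vals.append(block_mean(seg[0], fs, task.analysis_window)[idx])
                per[cond] = np.mean(vals)
            return per["intact"] - per["degraded"]

        oracle = contrast(clean)
        cfg = replace(PreprocessConfig(), enable_tddr=False)
        conc, _, _ = preprocess_run(rec, cfg)
        recovered = contrast(conc)

        # filtered oracle: the clean series pushed through the same linear
        # detrend + band-pass + spatial filter, bypassing the optical path
        filt = detrend_linear(_odseries(clean.hbo))
        filt = bandpass_filter(filt, PreprocessConfig())
        filtered = ConcentrationSeries(
            filt.od[:, :, 0], -filt.od[:, :, 0] / 3, clean.mask, fs, clean.channel_ids
        )
        filtered = remove_global_pca(filtered, montage.channel_positions)
        expected = contrast(filtered)

        assert recovered == pytest.approx(expected, rel=0.02)
        assert abs(recovered - oracle) / abs(oracle) < 0.35

    def test_linearity_of_linear_steps(self, adult_montage, adult_extinction, config):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((600, adult_montage.n_channels, 2)) * 1e-3
        for step in (
            detrend_linear,
            lambda od: bandpass_filter(od, config),
        ):
            out1 = step(ODSeries(x.copy(), FS)).od
            out2 = step(ODSeries(2.5 * x, FS)).od
            np.testing.assert_allclose(out2, 2.5 * out1, rtol=1e-9, atol=1e-12)

    def test_cleaning_improves_contrast_z(self):
        """Across seeded runs, the windowed-contrast z-score after the full
        chain is at least as high on average as without band-pass + PCA."""
        from dataclasses import replace

        from fcoi_nirs.blocks import baseline_correct_block, block_mean
        from fcoi_nirs.simulate import add_noise_and_artifacts

        scenario = adult_like_scenario(n_subjects=1, n_extra_channels=10)
        montage = scenario.montage()
        fs = montage.sampling_rate_hz
        truth = scenario.build_truth(montage, 0)
        design = scenario.language_design
        task = design.task
        ext = ExtinctionTable.for_wavelengths(montage.wavelengths_nm)
        idx = montage.index_of(70)
        full_cfg = PreprocessConfig()
        raw_cfg = replace(full_cfg, enable_bandpass=False, enable_pca=False)

        def contrasts(conc, events):
            vals = {c: [] for c in task.condition_labels}
            for ev in events:
                seg = baseline_correct_block(conc, ev, 2.0)
                vals[ev.condition].append(block_mean(seg[0], fs, task.analysis_window)[idx])
            return vals

        z = {"full": [], "raw": []}
        for seed in range(20):
            events = make_design(design, seed, 1)
            n_time = int(round(design.run_duration_s * fs))
            clean = simulate_conc(truth, events, task, n_time, fs)
            noisy, manifest = add_noise_and_artifacts(
                clean, truth, montage.channel_positions, np.random.default_rng(seed)
            )
            rec = conc_to_intensity(noisy, montage, ext, 1e5, manifest, subject_id="s",
                                    task_id="language", run_index=1, events=events)
            for name, cfg in (("full", full_cfg), ("raw", raw_cfg)):
                conc, _, _ = preprocess_run(rec, cfg)
                vals = contrasts(conc, events)
                pooled = np.concatenate([vals["intact"], vals["degraded"]])
                spread = np.std(pooled, ddof=1)
                z[name].append(
                    (np.mean(vals["intact"]) - np.mean(vals["degraded"])) / spread
                )
        assert np.mean(z["full"]) >= np.mean(z["raw"])
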