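"""F, dF/F0, dG/R and smoothing."""

import numpy as np
import pytest

import fluopipe as fp
from fluopipe.traces import _moving_average


def session_from_values(values, n_channels=1):
    """Tiny session whose single 2x2 ROI has per-frame mean `values[t]`."""
    values = np.asarray(values, dtype=np.float64)
    stack = np.zeros((len(values), 8, 8, n_channels))
    stack[:, 2:4, 2:4, :] = values[:, None, None, None]
    session = fp.ImagingSession(stack=stack, sampling_interval=1.0)
    lab = np.zeros((8, 8), dtype=np.int32)
    lab[2:4, 2:4] = 1
    return session, fp.ROISet.from_label_image(lab)


class TestComputeF:
    def test_constant_stack_gives_constant_F(self, flat_session):
        lab = np.zeros((16, 16), dtype=np.int32)
        lab[3:6, 3:6] = 1
        lab[10:12, 10:13] = 2
        rs = fp.ROISet.from_label_image(lab)
        ts = fp.compute_F(flat_session, rs)
        assert ts.F.shape == (4, 2, 2)
        assert np.all(ts.F == 7.0)

    def test_four_pixel_mean(self):
        stack = np.zeros((1, 4, 4, 1))
        stack[0, 1, 1, 0], stack[0, 1, 2, 0] = 1, 2
        stack[0, 2, 1, 0], stack[0, 2, 2, 0] = 3, 4
        session = fp.ImagingSession(stack=stack, sampling_interval=1.0)
        lab = np.zeros((4, 4), dtype=np.int32)
        lab[1:3, 1:3] = 1
        ts = fp.compute_F(session, fp.ROISet.from_label_image(lab))
        assert ts.F[0, 0, 0] == pytest.approx(2.5)

    def test_planted_oscillation_amplitude_recovered(self):
        session, truth = fp.make_movie(n_cells=1, shape=(64, 64), radius=7.0,
                                       duration_s=10.0, fs=34.0, amplitude=0.3,
                                       cell_freqs=2.0, snr=5.0, seed=6)
        ref = fp.make_reference(session, method="average")
        rs = fp.extract_rois(fp.threshold_reference(ref), min_area=30)
        ts = fp.compute_dff(fp.compute_F(session, rs), session, rs, background="constant",
                            background_value=0.0)
        # averaging over ~150 px leaves amplitude error << planted amplitude
        est = np.sqrt(2) * ts.dff[:, 0].std()
        assert est == pytest.approx(0.3, rel=0.1)

    def test_linearity_in_the_stack(self):
        session, rs = session_from_values([10.0, 12.0, 15.0])
        ts1 = fp.compute_F(session, rs)
        scaled = fp.ImagingSession(stack=session.stack * 3.0, sampling_interval=1.0)
        ts3 = fp.compute_F(scaled, rs)
        np.testing.assert_allclose(ts3.F, 3.0 * ts1.F)


class TestDff:
    def test_worked_example(self):
        session, rs = session_from_values([10, 10, 20, 15])
        ts = fp.compute_dff(fp.compute_F(session, rs), session, rs,
                            control_range=(0, 2), background="none")
        np.testing.assert_allclose(ts.dff[:, 0], [0.0, 0.0, 1.0, 0.5])
        assert ts.F0[0] == pytest.approx(10.0)

    def test_constant_trace_gives_zero(self):
        session, rs = session_from_values([5.0] * 6)
        ts = fp.compute_dff(fp.compute_F(session, rs), session, rs, background="none")
        np.testing.assert_allclose(ts.dff, 0.0)

    def test_doubling_gives_one(self):
        session, rs = session_from_values([10, 10, 10, 20])
        ts = fp.compute_dff(fp.compute_F(session, rs), session, rs,
                            control_range=(0, 3), background="none")
        assert ts.dff[3, 0] == pytest.approx(1.0)

    def test_stack_scaling_leaves_dff_unchanged(self):
        session, rs = session_from_values([10, 11, 14, 12])
        ts = fp.compute_dff(fp.compute_F(session, rs), session, rs, background="none")
        scaled = fp.ImagingSession(stack=session.stack * 7.0, sampling_interval=1.0)
        ts2 = fp.compute_dff(fp.compute_F(scaled, rs), scaled, rs, background="none")
        np.testing.assert_allclose(ts2.dff, ts.dff)

    def test_additive_offset_removed_by_constant_background(self):
        session, rs = session_from_values([10, 10, 20, 15])
        shifted = fp.ImagingSession(stack=session.stack + 30.0, sampling_interval=1.0)
        ts = fp.compute_dff(fp.compute_F(shifted, rs), shifted, rs,
                            control_range=(0, 2), background="constant",
                            background_value=30.0)
        np.testing.assert_allclose(ts.dff[:, 0], [0.0, 0.0, 1.0, 0.5])

    def test_nonpositive_baseline_warns_not_crashes(self):
        session, rs = session_from_values([0.0, 0.0, 1.0])
        with pytest.warns(UserWarning, match="baseline"):
            ts = fp.compute_dff(fp.compute_F(session, rs), session, rs,
                                control_range=(0, 2), background="none")
        assert np.all(np.isnan(ts.dff[:, 0]))

    def test_default_control_range_is_first_tenth(self):
        assert fp.default_control_range(200) == (0, 20)
        assert fp.default_control_range(5) == (0, 1)


class TestDgr:
    def _two_channel(self, g, r):
        g, r = np.asarray(g, float), np.asarray(r, float)
        stack = np.zeros((len(g), 8, 8, 2))
        stack[:, 2:4, 2:4, 0] = g[:, None, None]
        stack[:, 2:4, 2:4, 1] = r[:, None, None]
        session = fp.ImagingSession(stack=stack, sampling_interval=1.0)
        lab = np.zeros((8, 8), dtype=np.int32)
        lab[2:4, 2:4] = 1
        return session, fp.ROISet.from_label_image(lab)

    def test_constant_green_gives_zero(self):
        session, rs = self._two_channel([50, 50, 50], [100, 100, 100])
        ts = fp.compute_dgr(fp.compute_F(session, rs), session)
        np.testing.assert_allclose(ts.dgr[:, 0], 0.0)

    def test_worked_example(self):
        session, rs = self._two_channel([50, 60], [100, 100])
        ts = fp.compute_dgr(fp.compute_F(session, rs), session)
        np.testing.assert_allclose(ts.dgr[:, 0], [0.0, 0.1])

    def test_multiplicative_artefact_attenuated_relative_to_dff(self):
        # both channels scale with s(t) and the true green signal is
        # constant: dF/F0 mirrors the artefact at full amplitude, while in
        # dG/R the red denominator (bright SR-101) attenuates it by the
        # green/red brightness ratio
        t = np.arange(50)
        s = 1.0 + 0.3 * np.sin(2 * np.pi * t / 25)
        session, rs = self._two_channel(40 * s, 400 * s)
        ts = fp.compute_F(session, rs)
        ts = fp.compute_dff(ts, session, rs, control_range=(0, 1), background="none")
        ts = fp.compute_dgr(ts, session)
        assert np.nanstd(ts.dgr[:, 0]) < 0.15 * np.nanstd(ts.dff[:, 0])

    def test_nonpositive_red_flagged(self):
        session, rs = self._two_channel([50, 60], [100, 0])
        with pytest.warns(UserWarning):
            ts = fp.compute_dgr(fp.compute_F(session, rs), session)
        assert np.isnan(ts.dgr[1, 0])


class TestSmoothing:
    def _ts(self, dff_col):
        dff = np.asarray(dff_col, float)[:, None]
        return fp.TraceSet(F=np.zeros((len(dff), 1, 1)), time_axis=np.arange(len(dff), dtype=float),
                           roi_ids=[1], dff=dff)

    def test_window_one_is_identity(self):
        ts = self._ts([1.0, 2.0, 3.0])
        out = fp.smooth_traces(ts, 1)
        np.testing.assert_array_equal(out.dff, ts.dff)

    def test_impulse_response(self):
        out = fp.smooth_traces(self._ts([0, 0, 1, 0, 0]), 3)
        np.testing.assert_allclose(out.dff[:, 0], [0, 1 / 3, 1 / 3, 1 / 3, 0])

    @pytest.mark.parametrize("window", [0, 2, 4])
    def test_even_or_zero_window_rejected(self, window):
        with pytest.raises(ValueError):
            fp.smooth_traces(self._ts([1, 2, 3, 4, 5]), window)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            fp.smooth_traces(self._ts([1, 2, 3]), 5)

    def test_white_noise_variance_reduced_fivefold(self):
        # Monte-Carlo over seeds; interior samples only, where the full
        # 5-sample window applies
        ratios = []
        for seed in range(10):
            x = np.random.default_rng(seed).standard_normal(2000)
            sm = _moving_average(x, 5)
            ratios.append(x[2:-2].var() / sm[2:-2].var())
        assert np.mean(ratios) == pytest.approx(5.0, rel=0.2)

    def test_mean_preserved_for_baseline_ended_traces(self):
        x = np.zeros(100)
        x[40:60] = np.random.default_rng(2).standard_normal(20)
        sm = _moving_average(x, 7)
        assert sm.mean() == pytest.approx(x.mean(), abs=1e-12)
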