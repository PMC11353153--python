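"""Movie/ephys loading, alignment, decimation and session round-trips."""

import numpy as np
import pytest
import tifffile

import fluopipe as fp
from fluopipe.errors import (
    AlignmentError,
    AmbiguousMarkerError,
    LoadError,
    MarkerNotFoundError,
    SessionFormatError,
)


class TestTiffLoading:
    def test_two_channel_interleaved_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        stack = rng.integers(0, 4000, size=(10, 64, 64, 2)).astype(np.uint16)
        session = fp.ImagingSession(stack=stack, sampling_interval=0.1)
        path = tmp_path / "movie.tif"
        fp.write_movie_tiff(session, path)
        loaded = fp.load_image(path, n_channels=2, sampling_interval=0.1)
        assert loaded.n_frames == 10
        assert loaded.n_channels == 2
        assert np.array_equal(loaded.stack, stack)

    def test_split_stack_dialect(self, tmp_path):
        stack = np.arange(2 * 4 * 4 * 2, dtype=np.uint16).reshape(2, 4, 4, 2)
        session = fp.ImagingSession(stack=stack, sampling_interval=1.0)
        path = tmp_path / "movie.tif"
        fp.write_movie_tiff(session, path, interleave="split")
        loaded = fp.load_image(path, n_channels=2, interleave="split")
        assert np.array_equal(loaded.stack, stack)

    def test_single_page_single_channel(self, tmp_path):
        path = tmp_path / "one.tif"
        tifffile.imwrite(path, np.ones((32, 32), dtype=np.uint16))
        loaded = fp.load_image(path)
        assert loaded.n_frames == 1
        assert loaded.n_channels == 1

    def test_truncated_file_raises_load_error(self, tmp_path):
        path = tmp_path / "movie.tif"
        tifffile.imwrite(path, np.zeros((8, 64, 64), dtype=np.uint16))
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(LoadError):
            fp.load_image(path)

    def test_more_than_two_channels_rejected(self, tmp_path):
        path = tmp_path / "rgb.tif"
        tifffile.imwrite(path, np.zeros((2, 8, 8, 3), dtype=np.uint8),
                         photometric="rgb")
        with pytest.raises(fp.UnsupportedFormatError):
            fp.load_image(path)


class TestSessionContainer:
    def test_full_state_round_trip(self, analyzed_state, tmp_path):
        path = tmp_path / "s.h5"
        fp.save_session(analyzed_state, path)
        again = fp.load_session(path)
        assert np.array_equal(again.session.stack, analyzed_state.session.stack)
        assert again.session.sampling_interval == analyzed_state.session.sampling_interval
        assert again.rois == analyzed_state.rois
        assert again.traces == analyzed_state.traces
        assert np.array_equal(again.ephys.samples, analyzed_state.ephys.samples)
        assert again.ephys.markers == analyzed_state.ephys.markers

    def test_image_only_round_trip(self, flat_session, tmp_path):
        path = tmp_path / "s.h5"
        fp.save_session(fp.SessionState(session=flat_session), path)
        again = fp.load_session(path)
        assert np.array_equal(again.session.stack, flat_session.stack)
        assert again.rois is None and again.traces is None and again.ephys is None

    def test_wrong_magic_raises_versioned_error(self, tmp_path):
        import h5py
        path = tmp_path / "bogus.h5"
        with h5py.File(path, "w") as f:
            f.attrs["magic"] = "something-else"
        with pytest.raises(SessionFormatError):
            fp.load_session(path)

    def test_garbage_file_raises(self, tmp_path):
        path = tmp_path / "garbage.h5"
        path.write_bytes(b"not hdf5 at all")
        with pytest.raises(SessionFormatError):
            fp.load_session(path)


def _session_of_duration(duration_s):
    stack = np.zeros((int(duration_s), 4, 4, 1))
    return fp.ImagingSession(stack=stack, sampling_interval=1.0)


class TestEphysLoading:
    def test_decimation_by_ten(self):
        session = _session_of_duration(60)
        raw = fp.EphysRecording(samples=np.random.default_rng(1).standard_normal(600_000),
                                sampling_rate=10_000.0)
        rec = fp.load_ephys(raw, session)
        assert len(rec.samples) == 60_000
        assert rec.sampling_rate == 1000.0
        assert rec.native_rate / rec.sampling_rate == fp.DOWNSAMPLE_FACTOR

    def test_sub_nyquist_tone_survives_decimation(self):
        # periodogram oracle: the 5 Hz peak must sit in the same bin before
        # and after the anti-aliased 10x decimation
        from scipy.signal import periodogram
        fs = 10_000.0
        t = np.arange(0, 60, 1 / fs)
        session = _session_of_duration(60)
        raw = fp.EphysRecording(samples=np.sin(2 * np.pi * 5.0 * t), sampling_rate=fs)
        rec = fp.load_ephys(raw, session)
        f_in, p_in = periodogram(raw.samples, fs)
        f_out, p_out = periodogram(rec.samples, rec.sampling_rate)
        assert abs(f_in[np.argmax(p_in)] - 5.0) < f_in[1]
        assert abs(f_out[np.argmax(p_out)] - 5.0) < f_out[1]

    def test_no_overlap_raises_alignment_error(self):
        session = _session_of_duration(10)
        raw = fp.EphysRecording(samples=np.zeros(1000), sampling_rate=100.0,
                                t0_offset=500.0)
        with pytest.raises(AlignmentError):
            fp.load_ephys(raw, session)

    def test_text_format_round_trip_with_markers(self, tmp_path):
        rec = fp.EphysRecording(samples=np.sin(np.linspace(0, 10, 2000)),
                                sampling_rate=200.0, markers=[(2.0, "s1"), (7.0, "s2")])
        path = tmp_path / "ephys.txt"
        fp.write_ephys_text(rec, path)
        back = fp.read_ephys_text(path)
        assert back.markers == [(2.0, "s1"), (7.0, "s2")]
        assert back.sampling_rate == pytest.approx(200.0, rel=1e-6)
        np.testing.assert_allclose(back.samples, rec.samples, atol=1e-8)


class TestMarkers:
    REC = fp.EphysRecording(samples=np.zeros(10), sampling_rate=1.0,
                            markers=[(2.0, "s1"), (70.0, "s2")])

    def test_segment_from_marker(self):
        assert fp.find_segment_by_marker(self.REC, "s2", 60.0) == (70.0, 130.0)

    def test_missing_tag(self):
        with pytest.raises(MarkerNotFoundError):
            fp.find_segment_by_marker(self.REC, "s3", 60.0)

    def test_duplicate_tag_lists_occurrences(self):
        rec = fp.EphysRecording(samples=np.zeros(10), sampling_rate=1.0,
                                markers=[(1.0, "s1"), (5.0, "s1")])
        with pytest.raises(AmbiguousMarkerError, match="5.0"):
            fp.find_segment_by_marker(rec, "s1", 60.0)


class TestRoiReuse:
    def _roiset(self):
        lab = np.zeros((40, 40), dtype=np.int32)
        lab[10:15, 10:15] = 1
        return fp.ROISet.from_label_image(lab)

    def test_zero_shift_is_identity(self):
        rs = self._roiset()
        shifted = fp.shift_rois(rs, 0, 0, min_area=5)
        assert np.array_equal(shifted.label_image, rs.label_image)
        assert shifted.rois[0].coords.shape == rs.rois[0].coords.shape

    def test_shift_moves_centroid_preserves_area(self):
        rs = self._roiset()
        shifted = fp.shift_rois(rs, 2, 3, min_area=5)
        assert shifted.rois[0].area == rs.rois[0].area
        assert shifted.rois[0].centroid[0] == pytest.approx(rs.rois[0].centroid[0] + 2)
        assert shifted.rois[0].centroid[1] == pytest.approx(rs.rois[0].centroid[1] + 3)

    def test_shift_inverse_for_interior_rois(self):
        rs = self._roiset()
        back = fp.shift_rois(fp.shift_rois(rs, 4, -3, min_area=5), -4, 3, min_area=5)
        assert np.array_equal(back.label_image, rs.label_image)

    def test_mostly_off_frame_flagged_clipped(self):
        rs = self._roiset()
        shifted = fp.shift_rois(rs, -14, 0, min_area=20)
        assert "clipped" in shifted.rois[0].flags
        assert shifted.rois[0].area < 25

    def test_import_requires_matching_dimensions(self, analyzed_state, tmp_path):
        path = tmp_path / "other.h5"
        fp.save_session(analyzed_state, path)
        small = fp.ImagingSession(stack=np.zeros((2, 8, 8, 1)), sampling_interval=1.0)
        with pytest.raises(fp.ROIImportError):
            fp.import_rois(small, path)
        same = fp.import_rois(analyzed_state.session, path)
        assert same == analyzed_state.rois
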