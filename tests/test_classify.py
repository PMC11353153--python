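"""Cell validation rules, astrocyte/neuron split, overrides and annotations."""

import numpy as np
import pytest

import fluopipe as fp
from conftest import disk_mask


def region_with_area(area, shape=(64, 64), origin=(20, 20)):
    """A compact region of exactly `area` pixels (raster fill of a 12-wide band)."""
    mask = np.zeros(shape, dtype=bool)
    r, c = origin
    width = 12
    full_rows, rem = divmod(area, width)
    mask[r:r + full_rows, c:c + width] = True
    if rem:
        mask[r + full_rows, c:c + rem] = True
    return mask


def ref_with(mask, inside=200.0, outside=50.0):
    img = np.full(mask.shape, outside)
    img[mask] = inside
    return fp.ReferenceImage(pixels=img, method="external")


def single_roi(mask):
    return fp.extract_rois(mask, min_area=1).rois[0]


class TestValidation:
    def test_good_disk_passes_all_criteria(self):
        mask = disk_mask((64, 64), (30, 30), 7)  # area ~150
        roi = single_roi(mask)
        ok, reasons = fp.validate_roi(roi, ref_with(mask))
        assert ok and reasons == []

    @pytest.mark.parametrize("area,valid", [(100, False), (101, True)])
    def test_area_rule_is_strictly_greater_than_100(self, area, valid):
        mask = region_with_area(area)
        roi = single_roi(mask)
        assert roi.area == area
        ok, reasons = fp.validate_roi(roi, ref_with(mask))
        assert ok is valid
        if not valid:
            assert reasons == ["area"]

    def test_elongated_roi_fails_eccentricity(self):
        rr, cc = np.mgrid[0:64, 0:64]
        ell = ((rr - 32) / 9.0) ** 2 + ((cc - 32) / 21.0) ** 2 <= 1  # ecc ~0.90
        roi = single_roi(ell)
        assert roi.eccentricity > 0.85
        ok, reasons = fp.validate_roi(roi, ref_with(ell))
        assert not ok and reasons == ["eccentricity"]

    def test_round_roi_passes_eccentricity(self):
        rr, cc = np.mgrid[0:64, 0:64]
        ell = ((rr - 32) / 12.0) ** 2 + ((cc - 32) / 14.0) ** 2 <= 1
        roi = single_roi(ell)
        assert roi.eccentricity < 0.85
        ok, _ = fp.validate_roi(roi, ref_with(ell))
        assert ok

    @pytest.mark.parametrize("inside,valid", [(99.0, False), (100.0, True)])
    def test_contrast_rule_is_inclusive_at_two(self, inside, valid):
        # vicinity mean is exactly 50, so the boundary case sits at 100
        mask = disk_mask((64, 64), (30, 30), 7)
        roi = single_roi(mask)
        ok, reasons = fp.validate_roi(roi, ref_with(mask, inside=inside, outside=50.0))
        assert ok is valid
        if not valid:
            assert reasons == ["contrast"]

    def test_raising_min_area_is_monotone(self):
        mask = disk_mask((64, 64), (30, 30), 8)
        roi = single_roi(mask)
        ref = ref_with(mask)
        verdicts = [fp.validate_roi(roi, ref, fp.ClassificationParams(min_area=a))[0]
                    for a in (50, 100, 150, 201, 250)]
        # once invalid, stays invalid as the threshold rises
        assert verdicts == sorted(verdicts, reverse=True)


def two_channel_state(ratio, seed=0):
    """One valid disk cell with a planted red/green ratio."""
    session, _ = fp.make_movie(n_cells=1, shape=(64, 64), radius=7.0, duration_s=2.0,
                               fs=10.0, astro_fraction=1.0, astro_rg_ratio=ratio,
                               snr=50.0, seed=seed)
    ref_g = fp.make_reference(session, method="average", channel="green")
    ref_r = fp.make_reference(session, method="average", channel="red")
    rs = fp.extract_rois(fp.threshold_reference(ref_g), min_area=30)
    return session, rs, ref_g, ref_r


class TestClassification:
    @pytest.mark.parametrize("ratio,expected", [
        (3.0, "astrocyte"), (0.1, "neuron"), (1.0, "unclassified"),
    ])
    def test_ratio_boundaries(self, ratio, expected):
        session, rs, ref_g, ref_r = two_channel_state(ratio)
        fp.classify_cells(session, rs, ref_g, ref_r)
        assert rs.labels[1].value == expected
        assert rs.labels[1].origin == "auto"

    def test_invalid_roi_is_not_cell_regardless_of_ratio(self):
        session, rs, ref_g, ref_r = two_channel_state(3.0)
        params = fp.ClassificationParams(min_area=rs.rois[0].area + 1)
        fp.classify_cells(session, rs, ref_g, ref_r, params)
        assert rs.labels[1].value == "not_cell"

    def test_single_channel_leaves_valid_cells_unclassified(self):
        session, truth = fp.make_movie(n_cells=1, shape=(64, 64), radius=7.0,
                                       duration_s=2.0, fs=10.0, n_channels=1,
                                       snr=50.0, seed=1)
        ref_g = fp.make_reference(session, method="average", channel="green")
        rs = fp.extract_rois(fp.threshold_reference(ref_g), min_area=30)
        fp.classify_cells(session, rs, ref_g, params=fp.ClassificationParams(min_area=50))
        assert rs.labels[1].value == "unclassified"

    def test_missing_red_reference_rejected_for_two_channels(self):
        session, rs, ref_g, _ = two_channel_state(3.0)
        with pytest.raises(ValueError):
            fp.classify_cells(session, rs, ref_g, None)

    def test_every_roi_gets_exactly_one_label(self, analyzed_state):
        from fluopipe.classify import LABEL_VALUES
        rs = analyzed_state.rois
        assert set(rs.labels) == set(rs.ids)
        assert all(lab.value in LABEL_VALUES for lab in rs.labels.values())


class TestOverride:
    def test_manual_label_survives_reclassification(self):
        session, rs, ref_g, ref_r = two_channel_state(3.0)
        fp.classify_cells(session, rs, ref_g, ref_r)
        assert rs.labels[1].value == "astrocyte"
        fp.override_label(rs, 1, "neuron")
        fp.classify_cells(session, rs, ref_g, ref_r)
        assert rs.labels[1].value == "neuron"
        assert rs.labels[1].origin == "manual"

    def test_override_to_not_cell_excludes_from_traces(self):
        session, rs, ref_g, ref_r = two_channel_state(3.0)
        fp.classify_cells(session, rs, ref_g, ref_r)
        fp.override_label(rs, 1, "not_cell")
        ts = fp.compute_F(session, rs)
        assert ts.n_rois == 0

    def test_unknown_id_raises_key_error(self):
        _, rs, _, _ = two_channel_state(3.0)
        with pytest.raises(KeyError):
            fp.override_label(rs, 99, "neuron")

    def test_manual_origin_survives_save_load(self, tmp_path):
        session, rs, ref_g, ref_r = two_channel_state(3.0)
        fp.classify_cells(session, rs, ref_g, ref_r)
        fp.override_label(rs, 1, "neuron")
        path = tmp_path / "s.h5"
        fp.save_session(fp.SessionState(session=session, rois=rs), path)
        again = fp.load_session(path)
        assert again.rois.labels[1] == fp.CellLabel("neuron", "manual")


class TestAnnotationRoundTrip:
    def _exported(self, tmp_path):
        session, truth = fp.make_movie(n_cells=3, shape=(96, 96), duration_s=2.0,
                                       fs=10.0, snr=50.0, seed=4)
        ref_g = fp.make_reference(session, method="average", channel="green")
        ref_r = fp.make_reference(session, method="average", channel="red")
        rs = fp.extract_rois(fp.threshold_reference(ref_g), min_area=30)
        manifest = fp.export_cell_images(session, rs, tmp_path / "db",
                                         ref_green=ref_g, ref_red=ref_r)
        return session, rs, manifest

    def test_export_writes_crop_per_cell_plus_manifest(self, tmp_path):
        _, rs, manifest = self._exported(tmp_path)
        crops = sorted(manifest.parent.glob("*.tif"))
        assert len(crops) == 3
        rows = manifest.read_text().strip().splitlines()
        assert len(rows) == 1 + 3  # header + one row per cell

    def test_partial_annotation_applies_only_listed_ids(self, tmp_path):
        _, rs, manifest = self._exported(tmp_path)
        ann = tmp_path / "ann.csv"
        ann.write_text("roi_id,label\n1,astrocyte\n3,neuron\n")
        fp.import_annotations(rs, ann)
        assert rs.labels[1] == fp.CellLabel("astrocyte", "imported")
        assert rs.labels[3] == fp.CellLabel("neuron", "imported")
        assert 2 not in rs.labels

    def test_unknown_id_aborts_and_is_named(self, tmp_path):
        _, rs, _ = self._exported(tmp_path)
        ann = tmp_path / "ann.csv"
        ann.write_text("roi_id,label\n7,neuron\n")
        with pytest.raises(fp.AnnotationImportError, match="7"):
            fp.import_annotations(rs, ann)
        assert 7 not in rs.labels
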