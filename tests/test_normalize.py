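import numpy as np
import pytest

from retroughness.normalize import (
    NormalizationParams,
    central_roi,
    resample,
    similarity_transform,
    target_papilla_xy,
)
from retroughness.surfaces_io import ScanGeometry
from retroughness.thickness import ThicknessMap

PARAMS = NormalizationParams()


def iso_geometry(side=512, pitch=11.7):
    return ScanGeometry(n_rows=side, n_cols=side, pixel_pitch_x=pitch, pixel_pitch_y=pitch)


def canonical_landmarks(params=PARAMS, geometry=None):
    """Landmarks already in canonical position on an isotropic grid."""
    g = geometry or iso_geometry()
    c = params.center_px
    t = target_papilla_xy(params)
    fovea = (float(c), float(c))
    papilla = (c + t.imag / g.pixel_pitch_y, c + t.real / g.pixel_pitch_x)
    return fovea, papilla, g


def make_map(values, geometry, layer=1):
    return ThicknessMap(
        layer_index=layer,
        values=values.astype(float),
        valid_mask=np.ones_like(values, dtype=bool),
        geometry=geometry,
    )


class TestSimilarityTransform:
    def test_canonical_landmarks_give_identity(self):
        fovea, papilla, g = canonical_landmarks()
        t = similarity_transform(fovea, papilla, g)
        assert t.scale == pytest.approx(1.0, abs=1e-12)
        assert t.rotation_deg == pytest.approx(0.0, abs=1e-10)

    def test_double_length_axis_halves_scale(self):
        fovea, papilla, g = canonical_landmarks()
        c = PARAMS.center_px
        far_papilla = (
            c + 2 * (papilla[0] - c),
            c + 2 * (papilla[1] - c),
        )
        t = similarity_transform(fovea, far_papilla, g)
        assert t.scale == pytest.approx(0.5, rel=1e-12)

    def test_random_landmarks_map_exactly_onto_targets(self):
        rng = np.random.default_rng(42)
        g = ScanGeometry()  # anisotropic native grid
        target = target_papilla_xy(PARAMS)
        for _ in range(20):
            fovea = tuple(rng.uniform(20, 100, 2))
            papilla = tuple(rng.uniform(150, 400, 2))
            t = similarity_transform(fovea, papilla, g)
            f_xy = np.array([fovea[1] * g.pixel_pitch_x, fovea[0] * g.pixel_pitch_y])
            p_xy = np.array([papilla[1] * g.pixel_pitch_x, papilla[0] * g.pixel_pitch_y])
            out_f = t.apply(f_xy)
            out_p = t.apply(p_xy)
            # < 1e-6 mm = 1e-3 um
            assert np.hypot(*out_f) < 1e-3
            assert np.hypot(out_p[0] - target.real, out_p[1] - target.imag) < 1e-3

    def test_coincident_landmarks_rejected(self):
        g = iso_geometry()
        with pytest.raises(ValueError, match="degenerate"):
            similarity_transform((10.0, 10.0), (10.0, 10.0), g)


class TestResample:
    def test_identity_transform_preserves_values(self):
        fovea, papilla, g = canonical_landmarks()
        rng = np.random.default_rng(1)
        tmap = make_map(rng.uniform(20, 80, g.shape), g)
        t = similarity_transform(fovea, papilla, g)
        out = resample(tmap, t, PARAMS)
        assert out.normalized
        m = out.valid_mask
        assert m.mean() > 0.95
        np.testing.assert_allclose(out.values[m], tmap.values[m], atol=1e-9)

    def test_constant_map_stays_constant_under_any_transform(self):
        g = iso_geometry(side=400)
        tmap = make_map(np.full(g.shape, 10.0), g)
        t = similarity_transform((150.0, 140.0), (210.0, 390.0), g)
        out = resample(tmap, t, PARAMS)
        assert out.valid_mask.any()
        np.testing.assert_allclose(out.values[out.valid_mask], 10.0, rtol=1e-12)

    def test_pure_rotation_of_radial_map_changes_little(self):
        params = PARAMS
        g = iso_geometry()
        c = params.center_px
        yy = (np.arange(g.n_rows)[:, None] - c) * g.pixel_pitch_y
        xx = (np.arange(g.n_cols)[None, :] - c) * g.pixel_pitch_x
        r = np.hypot(xx, yy)
        radial = 50.0 + 30.0 * np.exp(-((r / 800.0) ** 2)) + 5.0 * np.cos(r / 300.0)
        tmap = make_map(radial, g)
        # landmarks at the target axis length but rotated 25 degrees away:
        # the fitted similarity is then a pure rotation about the fovea
        length = params.target_axis_length_mm * 1000.0
        ang = np.radians(25.0)
        papilla = (c + length * np.sin(ang) / g.pixel_pitch_y,
                   c + length * np.cos(ang) / g.pixel_pitch_x)
        t = similarity_transform((float(c), float(c)), papilla, g)
        assert t.scale == pytest.approx(1.0, rel=1e-9)
        out = resample(tmap, t, params)
        roi = central_roi(out, params)
        src = make_map(radial, g)
        src.normalized = True
        src_roi = central_roi(src, params)
        m = roi.valid_mask & src_roi.valid_mask
        rms_change = np.sqrt(np.mean((roi.values[m] - src_roi.values[m]) ** 2))
        rms_map = np.sqrt(np.mean(src_roi.values[m] ** 2))
        assert rms_change < 0.01 * rms_map

    def test_invalid_source_pixels_never_contribute(self):
        g = iso_geometry(side=400)
        vals = np.full(g.shape, 10.0)
        mask = np.ones(g.shape, dtype=bool)
        vals[100:140, 150:200] = 1e9  # poison the masked region
        mask[100:140, 150:200] = False
        tmap = ThicknessMap(layer_index=1, values=vals, valid_mask=mask, geometry=g)
        t = similarity_transform((170.0, 160.0), (230.0, 395.0), g)
        out = resample(tmap, t, PARAMS)
        assert out.valid_mask.any()
        assert np.all(out.values[out.valid_mask] < 1e6)


class TestCentralRoi:
    def test_roi_side_is_218_pixels_at_default_pitch(self):
        assert PARAMS.roi_side_px == 218

    def test_roi_centered_on_fovea_within_one_pixel(self):
        fovea, papilla, g = canonical_landmarks()
        tmap = make_map(np.zeros(g.shape), g)
        t = similarity_transform(fovea, papilla, g)
        roi = central_roi(resample(tmap, t, PARAMS), PARAMS)
        assert roi.values.shape == (218, 218)
        # fovea pixel (256, 256) maps to ROI offset side//2 = 109
        assert PARAMS.center_px - (PARAMS.center_px - 218 // 2) == 109

    def test_unnormalized_map_rejected(self):
        g = iso_geometry(side=300)
        with pytest.raises(ValueError, match="normalized"):
            central_roi(make_map(np.zeros(g.shape), g), PARAMS)

    def test_too_small_map_reports_extent(self):
        g = iso_geometry(side=100)
        tmap = make_map(np.zeros(g.shape), g)
        tmap.normalized = True
        with pytest.raises(ValueError, match="not fully inside"):
            central_roi(tmap, PARAMS)


def test_end_to_end_two_subjects_related_by_similarity():
    """Two scans of the same retina differing by a similarity transform
    must yield matching ROIs after normalization."""
    params = PARAMS

    def field(x, y):  # smooth canonical thickness pattern (um)
        return (
            60.0
            + 20.0 * np.exp(-((x / 900.0) ** 2) - ((y / 700.0) ** 2))
            + 6.0 * np.cos(x / 400.0) * np.sin(y / 350.0)
        )

    g = ScanGeometry()  # native anisotropic grid
    rois = []
    for fovea, length, ang_deg in [
        ((63.0, 250.0), 4377.0, 6.766),
        ((66.0, 262.0), 4100.0, 11.0),
    ]:
        ang = np.radians(ang_deg)
        papilla = (
            fovea[0] + length * np.sin(ang) / g.pixel_pitch_y,
            fovea[1] + length * np.cos(ang) / g.pixel_pitch_x,
        )
        t = similarity_transform(fovea, papilla, g, params)
        # sample the canonical field at each source pixel's canonical position
        cols_um = np.arange(g.n_cols)[None, :] * g.pixel_pitch_x
        rows_um = np.arange(g.n_rows)[:, None] * g.pixel_pitch_y
        xy = np.stack(np.broadcast_arrays(cols_um, rows_um), axis=-1)
        can = t.apply(xy)
        tmap = make_map(field(can[..., 0], can[..., 1]), g)
        rois.append(central_roi(resample(tmap, t, params), params))
    m = rois[0].valid_mask & rois[1].valid_mask
    assert m.mean() > 0.99
    rms_diff = np.sqrt(np.mean((rois[0].values[m] - rois[1].values[m]) ** 2))
    rms_map = np.sqrt(np.mean(rois[0].values[m] ** 2))
    assert rms_diff < 0.01 * rms_map
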