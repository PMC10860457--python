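"""NCC detection: preprocessing, template matching, structure tracking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdtt.detection import (DetectionConfig, Template, _parabolic_offset,
                            detect_diaphragm, detect_markers, extract_template,
                            match_template, preprocess, propagate_sequence,
                            seed_from_truth)
from mdtt.frames import FluoroFrame, FluoroSequence
from mdtt.geometry import PixelCoord, project_point
from mdtt.phantom import NoiseParams, RoomPoint, render_frame


def _blob_image(cu, cv, shape=(120, 160), sigma=2.0, amp=200.0):
    vv, uu = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    return 50.0 + amp * np.exp(-0.5 * (((uu - cu) / sigma) ** 2
                                       + ((vv - cv) / sigma) ** 2))


class TestPreprocess:
    def test_dead_pixel_removed_by_median(self):
        img = np.full((50, 50), 30000.0)
        img[20, 20] = 0.0  # dead pixel in a bright region
        out = preprocess(img)
        assert out[20, 20] == out[10, 10]  # equals the background level
        assert out.min() == out.max()  # no extremum survives

    def test_constant_image_maps_to_zero(self):
        out = preprocess(np.full((32, 32), 12345.0))
        assert np.all(out == 0.0)

    def test_smooth_gradient_stays_monotone(self):
        img = np.tile(np.linspace(0, 65535, 64), (64, 1))
        out = preprocess(img)
        assert np.all(np.diff(out[32]) >= 0)

    def test_rescales_to_256_levels(self):
        img = np.tile(np.linspace(5000, 40000, 64), (64, 1))
        out = preprocess(img)
        assert out.min() >= 0.0 and out.max() <= 255.0


class TestMatchTemplate:
    def test_self_match_exact_with_unit_score(self):
        img = _blob_image(81.3, 55.8)
        tmpl = extract_template(img, PixelCoord(81.0, 56.0), half_size=8)
        det = match_template(img, tmpl)
        assert det.score == pytest.approx(1.0, abs=1e-9)
        assert det.position.u == pytest.approx(81.0, abs=1e-3)
        assert det.position.v == pytest.approx(56.0, abs=1e-3)

    def test_subpixel_shift_recovered(self):
        a = _blob_image(60.0, 40.0)
        b = _blob_image(63.4, 37.3)  # shift (+3.4, -2.7)
        tmpl = extract_template(a, PixelCoord(60.0, 40.0), half_size=8)
        det = match_template(b, tmpl)
        assert det.position.u - 60.0 == pytest.approx(3.4, abs=0.5)
        assert det.position.v - 40.0 == pytest.approx(-2.7, abs=0.5)

    def test_inverted_contrast_scores_minus_one(self):
        # NCC antisymmetry: at the aligned position (window pinned to the
        # template footprint) a contrast-inverted image scores exactly -1.
        img = _blob_image(50.0, 50.0)
        tmpl = extract_template(img, PixelCoord(50.0, 50.0), half_size=8)
        det = match_template(-img, tmpl, search_window=(42, 59, 42, 59))
        assert det.score == pytest.approx(-1.0, abs=1e-9)
        assert det.position.u == pytest.approx(50.0, abs=1e-9)
        assert det.position.v == pytest.approx(50.0, abs=1e-9)

    def test_window_smaller_than_template_rejected(self):
        img = _blob_image(50.0, 50.0)
        tmpl = extract_template(img, PixelCoord(50.0, 50.0), half_size=8)
        with pytest.raises(ValueError):
            match_template(img, tmpl, search_window=(50, 60, 50, 60))

    def test_constant_window_rejected(self):
        img = np.zeros((64, 64))
        img[40:50, 40:50] = 7.0
        tmpl = Template(patch=img[40:50, 40:50].copy(), anchor=(4, 4))
        with pytest.raises(ValueError):
            match_template(np.zeros((64, 64)), tmpl, search_window=(0, 30, 0, 30))

    def test_affine_intensity_invariance(self):
        img = _blob_image(70.0, 45.0)
        tmpl = extract_template(img, PixelCoord(70.0, 45.0), half_size=8)
        base = match_template(img, tmpl)
        scaled = match_template(3.7 * img + 120.0, tmpl)
        assert scaled.position.u == pytest.approx(base.position.u, abs=1e-9)
        assert scaled.position.v == pytest.approx(base.position.v, abs=1e-9)
        assert scaled.score == pytest.approx(base.score, abs=1e-9)


class TestParabolicRefinement:
    @given(st.floats(0.1, 100), st.floats(-99, 0.99), st.floats(0.1, 100))
    @settings(max_examples=200, deadline=None)
    def test_offset_never_exceeds_half_pixel(self, a, b, c):
        assert abs(_parabolic_offset(a, max(a, b, c) + 0.01, c)) <= 0.5

    def test_symmetric_neighborhood_gives_zero(self):
        assert _parabolic_offset(0.5, 1.0, 0.5) == 0.0

    def test_flat_neighborhood_gives_zero(self):
        assert _parabolic_offset(1.0, 1.0, 1.0) == 0.0


class TestStructureDetection:
    def test_markers_noiseless_subpixel(self, noiseless_session):
        sess = noiseless_session
        frame = sess.frames_a[0]
        m_tmpl, m_seeds, _, _ = seed_from_truth(sess, "A")
        dets = detect_markers(frame, m_tmpl, m_seeds)
        assert len(dets) == 3
        disp0 = sess.truth_diaphragm[0] - sess.phantom.diaphragm_com()
        for det, m in zip(dets, sess.phantom.markers):
            pc = project_point(sess.geom,
                               RoomPoint.from_array(m.as_array() + disp0), "A")
            assert abs(det.position.u - pc.u) < 0.1
            assert abs(det.position.v - pc.v) < 0.1
            assert not det.low_confidence

    def test_marker_outside_window_flagged(self, noiseless_session):
        sess = noiseless_session
        frame = sess.frames_a[0]
        m_tmpl, m_seeds, _, _ = seed_from_truth(sess, "A")
        wrong_prior = PixelCoord(m_seeds[0].u + 300, m_seeds[0].v + 200, "A")
        dets = detect_markers(frame, [m_tmpl[0]], [wrong_prior])
        assert dets[0].low_confidence

    def test_detection_unbiased_at_study_noise(self, noisy_session):
        # Signed sub-pixel errors over >= 100 marker detections should
        # average out below 0.05 px per axis.
        sess = noisy_session
        m_tmpl, m_seeds, _, _ = seed_from_truth(sess, "A")
        errs = []
        for i, frame in enumerate(sess.frames_a):
            disp = sess.truth_diaphragm[i] - sess.phantom.diaphragm_com()
            priors = [project_point(sess.geom,
                                    RoomPoint.from_array(m.as_array() + disp), "A")
                      for m in sess.phantom.markers]
            dets = detect_markers(frame, m_tmpl, priors)
            for det, pc in zip(dets, priors):
                errs.append([det.position.u - pc.u, det.position.v - pc.v])
        errs = np.array(errs)
        assert len(errs) >= 100
        assert np.all(np.abs(errs.mean(axis=0)) < 0.05)

    def test_diaphragm_points_and_com(self, noiseless_session):
        sess = noiseless_session
        frame = sess.frames_a[0]
        _, _, d_tmpl, d_seeds = seed_from_truth(sess, "A")
        det = detect_diaphragm(frame, d_tmpl, d_seeds)
        assert det.valid
        for d, s in zip(det.points, d_seeds):
            assert abs(d.position.v - s.v) < 0.2

    def test_too_few_templates_rejected(self, noiseless_session):
        sess = noiseless_session
        _, _, d_tmpl, d_seeds = seed_from_truth(sess, "A")
        with pytest.raises(ValueError):
            detect_diaphragm(sess.frames_a[0], d_tmpl[:2], d_seeds[:2])

    def test_all_windows_missing_interface_invalidates_frame(self, noiseless_session):
        sess = noiseless_session
        frame = sess.frames_a[0]
        _, _, d_tmpl, d_seeds = seed_from_truth(sess, "A")
        off = [PixelCoord(p.u, p.v + 300, "A") for p in d_seeds]
        det = detect_diaphragm(frame, d_tmpl, off, DetectionConfig(min_score=0.95))
        assert not det.valid


class TestPropagation:
    def test_noiseless_sequence_fully_confident(self, noiseless_session):
        sess = noiseless_session
        m_tmpl, m_seeds, d_tmpl, d_seeds = seed_from_truth(sess, "A")
        out = propagate_sequence(sess.frames_a, m_tmpl, m_seeds, d_tmpl, d_seeds)
        assert not out.lost
        assert out.n_invalid == 0
        assert all(not d.low_confidence
                   for dets in out.marker_detections for d in dets)

    def test_reversed_sequence_still_tracks(self, noiseless_session):
        # No forward-time assumption: propagation from the last frame
        # backwards tracks equally well (seeded at that frame).
        sess = noiseless_session
        rev = FluoroSequence(frames=list(sess.frames_a)[::-1], imager_id="A")
        cfg = DetectionConfig()
        from mdtt.detection import extract_template as ext
        img_last = preprocess(rev[0], cfg.median_filter_size)
        disp = sess.truth_diaphragm[-1] - sess.phantom.diaphragm_com()
        m_seeds = [project_point(sess.geom,
                                 RoomPoint.from_array(m.as_array() + disp), "A")
                   for m in sess.phantom.markers]
        d_seeds = [project_point(sess.geom, RoomPoint.from_array(p + disp), "A")
                   for p in sess.phantom.interface_points()]
        m_tmpl = [ext(img_last, pc, cfg.template_half_size, "marker")
                  for pc in m_seeds]
        d_tmpl = [ext(img_last, pc, cfg.template_half_size, "diaphragm_point")
                  for pc in d_seeds]
        out = propagate_sequence(rev, m_tmpl, m_seeds, d_tmpl, d_seeds, cfg)
        assert not out.lost
        assert out.n_invalid == 0


def test_template_anchor_must_be_inside_patch():
    with pytest.raises(ValueError):
        Template(patch=np.zeros((5, 5)), anchor=(7.0, 2.0))
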