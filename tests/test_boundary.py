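import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maskfer import boundary, infinity, pipeline
from oracles import oracle_dda_line, oracle_peaks


class TestRasterize:
    def test_horizontal_line(self):
        pts = boundary.rasterize_segment((0, 0), (3, 0))
        assert pts.tolist() == [[0, 0], [1, 0], [2, 0], [3, 0]]

    def test_degenerate_single_pixel(self):
        assert boundary.rasterize_segment((5, 5), (5, 5)).tolist() == [[5, 5]]

    def test_reversal_yields_reversed_list(self, rng):
        for _ in range(50):
            p0 = tuple(rng.integers(0, 60, 2))
            p1 = tuple(rng.integers(0, 60, 2))
            fwd = boundary.rasterize_segment(p0, p1)
            rev = boundary.rasterize_segment(p1, p0)
            assert np.array_equal(fwd, rev[::-1])

    def test_matches_dda_oracle_within_8_connectivity(self, rng):
        cases = [((0, 0), (5, 3))] + [
            (tuple(rng.integers(0, 40, 2)), tuple(rng.integers(0, 40, 2)))
            for _ in range(100)
        ]
        for p0, p1 in cases:
            got = boundary.rasterize_segment(p0, p1)
            ref = oracle_dda_line(p0, p1)
            assert len(got) == len(ref)
            assert got[0].tolist() == list(p0) and got[-1].tolist() == list(p1)
            for (gx, gy), (rx, ry) in zip(got, ref):
                assert max(abs(gx - rx), abs(gy - ry)) <= 1
            # consecutive pixels 8-connected
            steps = np.abs(np.diff(got, axis=0)).max(axis=1)
            assert (steps == 1).all()


class TestExtractProfile:
    def test_collinear_horizontal_triple_reads_row(self, rng):
        img = rng.integers(0, 256, (10, 20))
        triple = np.array([[2, 4], [6, 4], [10, 4]])
        prof = boundary.extract_profile(img, triple)
        assert np.array_equal(prof.samples, img[4, 2:11])

    def test_constant_image_gives_constant_profile(self):
        img = np.full((20, 20), 9)
        prof = boundary.extract_profile(img, np.array([[0, 0], [10, 5], [19, 19]]))
        assert (prof.samples == 9).all()

    def test_midpoint_deduplicated_once(self):
        img = np.zeros((30, 30))
        triple = np.array([[1, 1], [12, 7], [25, 28]])
        seg1 = boundary.rasterize_segment((1, 1), (12, 7))
        seg2 = boundary.rasterize_segment((12, 7), (25, 28))
        prof = boundary.extract_profile(img, triple)
        assert len(prof.samples) == len(seg1) + len(seg2) - 1

    def test_out_of_bounds_rejected(self):
        img = np.zeros((10, 10))
        with pytest.raises(ValueError):
            boundary.extract_profile(img, np.array([[0, 0], [5, 5], [10, 9]]))


class TestFindProfilePeaks:
    def test_single_spike(self):
        peaks = boundary.find_profile_peaks(np.array([0.0, 5.0, 0.0]))
        assert len(peaks) == 1
        pk = peaks[0]
        assert (pk.apex_index, pk.prominence, pk.left_base) == (1, 5.0, 0)

    def test_monotone_profile_has_no_peaks(self):
        assert boundary.find_profile_peaks(np.arange(10.0)) == []

    def test_agrees_with_bruteforce_oracle_on_random_profiles(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 65))
            x = rng.integers(0, 256, n).astype(float)
            got = boundary.find_profile_peaks(x)
            ref = oracle_peaks(x)
            assert len(got) == len(ref)
            for g, r in zip(got, ref):
                assert g.apex_index == r["apex"]
                assert g.left_base == r["left_base"]
                assert g.prominence == pytest.approx(r["prominence"])
                assert g.width == pytest.approx(r["width"])

    @given(st.lists(st.integers(0, 4), min_size=3, max_size=30))
    @settings(max_examples=300, deadline=None)
    def test_oracle_equivalence_property(self, values):
        x = np.array(values, dtype=float)
        got = boundary.find_profile_peaks(x)
        ref = oracle_peaks(x)
        assert [(g.apex_index, g.left_base) for g in got] == [
            (r["apex"], r["left_base"]) for r in ref
        ]
        for g, r in zip(got, ref):
            assert g.prominence == pytest.approx(r["prominence"])
            assert g.width == pytest.approx(r["width"])


def _placed_curve(image):
    curve = infinity.generate_infinity_points()
    h, w = image.shape
    rx, ry = infinity.ranges_for_image(curve, w, h)
    normalized = infinity.normalize_points(curve, rx, ry)
    return infinity.place_at_seed(normalized, w // 2, h // 2, w, h)


class TestDetectLandmarks:
    def test_uniform_image_yields_no_landmarks(self):
        img = np.full((96, 236), 128, np.uint8)
        placed = _placed_curve(img)
        assert boundary.detect_landmarks(img, placed) == []

    def test_raising_thresholds_never_adds_landmarks(self, default_face):
        img = default_face.image
        placed = _placed_curve(img)
        counts = [
            len(boundary.detect_landmarks(img, placed, boundary.PeakThresholds(p, w)))
            for p, w in [(10, 2), (25.5, 3), (40, 3), (40, 6), (80, 8)]
        ]
        assert counts == sorted(counts, reverse=True)

    def test_landmarks_lie_on_rasterized_traces(self, default_face):
        img = default_face.image
        placed = _placed_curve(img)
        trace_pixels = set()
        pts = placed.points
        for i in range(len(pts) - 2):
            prof = boundary.extract_profile(img, pts[i : i + 3], i)
            trace_pixels.update(map(tuple, prof.pixel_trace))
        for lm in boundary.detect_landmarks(img, placed):
            assert (lm.x, lm.y) in trace_pixels

    def test_landmarks_deduplicated(self, default_face):
        img = default_face.image
        placed = _placed_curve(img)
        lms = boundary.detect_landmarks(img, placed)
        coords = [(lm.x, lm.y) for lm in lms]
        assert len(coords) == len(set(coords))

    def test_recovery_on_synthetic_ground_truth(self, face_batch):
        from scipy.ndimage import distance_transform_edt

        hits = total = 0
        for face in face_batch:
            lms, _, _ = pipeline.extract_image_features(face.image)
            dist = distance_transform_edt(~face.boundary_mask)
            d = np.array([dist[lm.y, lm.x] for lm in lms])
            hits += int((d <= 3).sum())
            total += len(d)
        assert total > 0
        assert hits / total >= 0.70

    def test_inversion_changes_detected_polarity(self, default_face):
        img = default_face.image
        placed = _placed_curve(img)
        normal = boundary.detect_landmarks(img, placed)
        inverted = boundary.detect_landmarks(img, placed, invert=True)
        # bright-peak landmarks and dark-valley landmarks are different sets
        assert set((l.x, l.y) for l in normal) != set((l.x, l.y) for l in inverted)

    def test_too_few_points_rejected(self, default_face):
        ps = infinity.InfinityPointSet(
            np.array([[1, 1], [5, 5]]), infinity.InfinityConfig(), frame="placed"
        )
        with pytest.raises(ValueError):
            boundary.detect_landmarks(default_face.image, ps)
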