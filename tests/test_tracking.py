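"""NCC matching, peak localization, PSR and sequence tracking."""

import numpy as np
import pytest

from trackrel.config import AcquisitionSpec, MotionSpec, PhantomSpec, TrackConfig
from trackrel.ground_truth import phantom_gt
from trackrel.synthetic import generate_sequence
from trackrel.tracking import (
    Template,
    locate_peak,
    ncc_surface,
    psr,
    synthetic_template,
    template_from_image,
    track_sequence,
)


def ncc_bruteforce(image, template):
    """Double-loop masked zero-normalized cross-correlation oracle."""
    th, tw = template.patch.shape
    m = template.mask
    p = template.patch[m]
    pt = p - p.mean()
    out = np.zeros((image.shape[0] - th + 1, image.shape[1] - tw + 1))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            q = image[i : i + th, j : j + tw][m]
            qt = q - q.mean()
            den = np.linalg.norm(pt) * np.linalg.norm(qt)
            out[i, j] = 0.0 if den == 0 else float(np.dot(pt, qt) / den)
    return out


class TestNccSurface:
    def test_matches_bruteforce_oracle_on_random_instances(self, rng):
        """>=100 random small instances agree with the double-loop oracle."""
        for _ in range(100):
            h, w = rng.integers(6, 12, size=2)
            th, tw = rng.integers(2, 5, size=2)
            img = rng.normal(size=(h, w))
            mask = rng.uniform(size=(th, tw)) < 0.8
            mask.flat[rng.integers(mask.size)] = True
            patch = rng.normal(size=(th, tw))
            while np.ptp(patch[mask]) == 0:
                patch = rng.normal(size=(th, tw))
            tpl = Template(patch=patch, mask=mask, origin_offset_px=(0, 0))
            surf = ncc_surface(img, tpl)
            np.testing.assert_allclose(
                surf.values, ncc_bruteforce(img, tpl), atol=1e-10
            )

    def test_self_match_peaks_at_one(self, rng):
        img = rng.normal(size=(20, 20))
        tpl = template_from_image(img, (10, 10), 3)
        surf = ncc_surface(img, tpl)
        (r, c), score = locate_peak(surf.values)
        assert score == pytest.approx(1.0)
        assert (r + 3, c + 3) == (10, 10)

    def test_anticorrelation_reaches_minus_one(self, rng):
        img = rng.normal(size=(15, 15))
        tpl = template_from_image(img, (7, 7), 2)
        surf = ncc_surface(-img, tpl)
        assert surf.values.min() == pytest.approx(-1.0)
        assert surf.values[5, 5] == pytest.approx(-1.0)

    def test_translation_equivariance(self, rng):
        img = rng.normal(size=(30, 30))
        tpl = template_from_image(img, (12, 12), 3)
        shifted = np.roll(img, (4, 2), axis=(0, 1))
        (r0, c0), _ = locate_peak(ncc_surface(img, tpl).values)
        (r1, c1), _ = locate_peak(ncc_surface(shifted, tpl).values)
        assert (r1 - r0, c1 - c0) == (4, 2)

    def test_template_must_fit_window(self, rng):
        img = rng.normal(size=(10, 10))
        tpl = template_from_image(img, (5, 5), 3)
        with pytest.raises(ValueError):
            ncc_surface(img, tpl, (slice(0, 4), slice(0, 4)))


class TestLocatePeak:
    def test_exhaustive_argmax_oracle(self, rng):
        for _ in range(100):
            s = rng.normal(size=rng.integers(2, 9, size=2))
            (r, c), v = locate_peak(s)
            assert v == s.max()
            flat = np.argwhere(s == s.max())
            assert (r, c) == tuple(flat[np.lexsort((flat[:, 1], flat[:, 0]))][0])

    def test_tie_breaks_to_smallest_row_then_col(self):
        s = np.zeros((5, 5))
        s[3, 1] = s[1, 3] = s[1, 1] = 1.0
        (r, c), _ = locate_peak(s)
        assert (r, c) == (1, 1)

    def test_flat_surface_is_missing_signal(self):
        assert locate_peak(np.ones((4, 4))) is None

    def test_subpixel_refinement_stays_within_half_pixel(self):
        s = np.exp(-0.5 * ((np.arange(9) - 4.3) ** 2))[None, :] * np.exp(
            -0.5 * ((np.arange(9)[:, None] - 3.8) ** 2)
        )
        (r, c), _ = locate_peak(s, subpixel=True)
        assert r == pytest.approx(3.8, abs=0.1)
        assert c == pytest.approx(4.3, abs=0.1)


class TestPsr:
    def test_large_sample_limit_equals_peak_height(self, rng):
        """Sidelobe ~ N(0,1): mean -> 0, std -> 1, so PSR -> peak."""
        n = 100
        s = rng.standard_normal((n, n))
        s[50, 50] = 5.0
        val, flagged = psr(s, (50, 50), exclusion_radius_px=2)
        assert not flagged
        assert val == pytest.approx(5.0, rel=0.05)

    def test_duplicate_peak_in_sidelobe_lowers_psr(self):
        s = np.zeros((9, 9))
        s[4, 4] = 1.0
        base, _ = psr(s, (4, 4), exclusion_radius_px=1)
        s2 = s.copy()
        s2[0, 0] = 1.0  # duplicate peak inside the sidelobe
        dup, _ = psr(s2, (4, 4), exclusion_radius_px=1)
        assert dup < base

    def test_zero_sidelobe_std_capped_and_flagged(self):
        s = np.zeros((7, 7))
        s[3, 3] = 1.0
        val, flagged = psr(s, (3, 3), exclusion_radius_px=2, cap=123.0)
        assert flagged and val == 123.0

    def test_noise_monotonicity(self):
        """Median PSR non-increasing as i.i.d. noise variance grows."""
        base = np.zeros((41, 41))
        base[20, 20] = 10.0
        medians = []
        for sigma in (0.1, 0.5, 1.5):
            vals = []
            for seed in range(50):
                r = np.random.default_rng(seed)
                s = base + r.normal(0.0, sigma, base.shape)
                vals.append(psr(s, (20, 20), exclusion_radius_px=3)[0])
            medians.append(np.median(vals))
        assert medians[0] >= medians[1] >= medians[2]


class TestTrackSequence:
    def test_noiseless_no_bone_tracking_subpixel_accuracy(self):
        """Without bone overlap every frame tracks to < 1 px at isocenter."""
        ph = PhantomSpec(rib_thickness_mm=0.0, spine_thickness_mm=0.0)
        acq = AcquisitionSpec(n_frames=30, noise_model="none")
        motion = MotionSpec()
        seq = generate_sequence(ph, motion, acq)
        tpl = synthetic_template(ph, acq, "SE")
        ts = track_sequence(seq, tpl, TrackConfig(), modality="SE",
                            reference_px=ph.tumor_center)
        assert ts.n_missing == 0
        ref = phantom_gt(motion, ts.t_s)
        err = np.linalg.norm(ts.positions_mm - ref.positions_mm, axis=1)
        mm_per_px = ph.pixel_spacing_mm / acq.magnification
        assert err.max() < mm_per_px

    def test_pure_noise_frames_all_missing(self, rng):
        from trackrel.synthetic import FrameMeta, ImageSequence

        frames = rng.normal(10.0, 1.0, size=(6, 64, 64)).astype(np.float32)
        seq = ImageSequence(
            frames=frames,
            meta=[FrameMeta(i, i / 7.5, "DE") for i in range(6)],
            pixel_spacing_mm=0.776, sdd_cm=150, sad_cm=100,
        )
        ph = PhantomSpec(image_shape=(64, 64))
        tpl = synthetic_template(ph, AcquisitionSpec(), "DE")
        ts = track_sequence(
            seq, tpl, TrackConfig(min_score=0.5, search_half_px=10), modality="DE"
        )
        assert ts.n_missing == len(ts)

    def test_se_stream_spacing_is_pair_interval(self, phantom, slow_motion):
        acq = AcquisitionSpec(frame_rate_fps=15.0, n_frames=20, noise_model="none")
        seq = generate_sequence(phantom, slow_motion, acq)
        tpl = synthetic_template(phantom, acq, "SE")
        ts = track_sequence(seq, tpl, TrackConfig(), modality="SE",
                            reference_px=phantom.tumor_center)
        assert ts.effective_dt_s == pytest.approx(2.0 / 15.0)

    def test_empty_sequence_rejected(self, phantom):
        from trackrel.synthetic import ImageSequence

        seq = ImageSequence(
            frames=np.zeros((0, 8, 8)), meta=[],
            pixel_spacing_mm=0.776, sdd_cm=150, sad_cm=100,
        )
        tpl = Template(
            patch=np.arange(9.0).reshape(3, 3),
            mask=np.ones((3, 3), bool), origin_offset_px=(1, 1),
        )
        with pytest.raises(ValueError):
            track_sequence(seq, tpl, TrackConfig(), modality="DE")


class TestBoneOverlapDegradation:
    def test_se_degrades_on_overlap_frames_more_than_de(self, slow_motion):
        """Frames where the tumor crosses a rib score lower on SE; the DE
        stream's degradation is smaller (the bone-suppression mechanism)."""
        from trackrel.config import WlsConfig
        from trackrel.dual_energy import subtract_sequence

        # one rib near peak inhale: the 5 mm tumor crosses it only at the
        # top of the breathing cycle
        ph = PhantomSpec(image_shape=(96, 96), tumor_diameter_mm=5.0,
                         rib_rows=(60.0,))
        acq = AcquisitionSpec(n_frames=40, noise_model="none")
        seq = generate_sequence(ph, slow_motion, acq)
        mag = acq.magnification
        rib_rows = np.asarray(ph.rib_rows)
        radius_px = ph.tumor_diameter_mm / 2.0 * mag / ph.pixel_spacing_mm

        rel = {}
        for modality in ("SE", "DE"):
            stream = (
                seq if modality == "SE"
                else subtract_sequence(seq, WlsConfig(ws=ph.ws_oracle, max_shift_px=2))
            )
            tpl = synthetic_template(ph, acq, modality, ws=ph.ws_oracle)
            ts = track_sequence(stream, tpl, TrackConfig(search_half_px=18),
                                modality=modality, reference_px=ph.tumor_center)
            true_rows = 48.0 + phantom_gt(slow_motion, ts.t_s).positions_mm[:, 1] * (
                mag / ph.pixel_spacing_mm
            )
            dist = np.min(np.abs(true_rows[:, None] - rib_rows[None, :]), axis=1)
            overlap = dist < ph.rib_halfwidth_px + radius_px / 2.0
            clear = dist > radius_px + ph.rib_halfwidth_px
            ok = ~ts.missing
            med = lambda sel: np.median(ts.match_score[sel & ok])
            rel[modality] = (med(overlap), med(clear))
        se_on, se_off = rel["SE"]
        de_on, de_off = rel["DE"]
        assert se_on < se_off  # SE scores drop under bone overlap
        assert (se_off - se_on) > (de_off - de_on)  # DE degradation smaller
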