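"""Backbone-trace statistics: contour, tangent correlation, loops, volume."""
import math

import numpy as np
import pytest

from gp32filament.afm import (
    AFMImage,
    BackboneTrace,
    fit_persistence_2d,
    integrated_volume,
    longest_loopfree_segment,
    resample_trace,
    tangent_correlation,
    trace_contour_length,
    trace_image,
    TangentCorrelationProfile,
)
from gp32filament.errors import FitFailureError
from gp32filament.synthetic import GeneratorSpec, gen_afm_image, gen_chain_2d


def straight_trace(length=100.0, step=2.0):
    n = int(length / step) + 1
    return BackboneTrace(np.column_stack([np.linspace(0, length, n),
                                          np.zeros(n)]), "line")


def semicircle_trace(radius=100.0, n=1000):
    th = np.linspace(0.0, math.pi, n)
    return BackboneTrace(np.column_stack([radius * np.cos(th),
                                          radius * np.sin(th)]), "arc")


class TestContourLength:
    def test_three_point_line(self):
        tr = BackboneTrace([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        assert trace_contour_length(tr) == pytest.approx(2.0)

    def test_unit_square_path(self):
        tr = BackboneTrace([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]])
        assert trace_contour_length(tr) == pytest.approx(4.0)

    def test_semicircle_arc_length(self):
        tr = semicircle_trace()
        assert trace_contour_length(tr) == pytest.approx(math.pi * 100.0,
                                                         rel=1e-3)

    def test_resample_invariance_for_smooth_curves(self):
        tr = semicircle_trace()
        base = trace_contour_length(tr)
        for step in (2.0, 5.0, 10.0):
            rs = resample_trace(tr, step)
            assert trace_contour_length(rs) == pytest.approx(base, rel=5e-3)


class TestTangentCorrelation:
    def test_straight_line_fully_correlated(self):
        prof = tangent_correlation([straight_trace(200.0)], resample_step=5.0)
        np.testing.assert_allclose(prof.mean_cos, 1.0, atol=1e-9)

    def test_circle_gives_cosine_decay(self):
        # tangents on a circle of radius r: <cos theta>(L) = cos(L/r)
        r = 200.0
        th = np.linspace(0.0, 1.5 * math.pi, 3000)
        tr = BackboneTrace(np.column_stack([r * np.cos(th), r * np.sin(th)]))
        prof = tangent_correlation([tr], resample_step=5.0, max_separation=150.0)
        expected = np.cos(prof.separations / r)
        np.testing.assert_allclose(prof.mean_cos, expected, atol=0.01)

    def test_short_trace_skipped_with_warning(self):
        short = BackboneTrace([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        with pytest.warns(UserWarning, match="skipped"):
            prof = tangent_correlation([short, straight_trace(100.0)],
                                       resample_step=5.0)
        assert prof.mean_cos[0] == 1.0

    def test_wlc_ensemble_matches_theory_within_sem(self):
        # <cos theta>(L) = exp(-L/2p) for deposited 2-D chains
        p = 20.0
        chains = [gen_chain_2d(p, 2500.0,
                               GeneratorSpec(seed=500 + i, noise_sd=0.0,
                                             arc_step=5.0))
                  for i in range(50)]
        prof = tangent_correlation(chains, resample_step=5.0,
                                   max_separation=100.0)
        expected = np.exp(-prof.separations / (2.0 * p))
        mask = prof.separations > 0
        dev = np.abs(prof.mean_cos[mask] - expected[mask])
        assert np.all(dev <= 3.0 * prof.sem[mask])


class TestPersistenceFit:
    def test_exact_exponential_profile(self):
        L = np.arange(0.0, 100.0, 5.0)
        prof = TangentCorrelationProfile(L, np.exp(-L / 40.0),
                                         np.full(L.size, 100))
        fit = fit_persistence_2d(prof, L_max=100.0)
        assert fit.persistence == pytest.approx(20.0, rel=1e-9)
        assert not fit.unbounded

    def test_straight_profile_flagged_unbounded(self):
        L = np.arange(0.0, 100.0, 5.0)
        prof = TangentCorrelationProfile(L, np.ones(L.size),
                                         np.full(L.size, 100))
        fit = fit_persistence_2d(prof, L_max=100.0)
        assert fit.unbounded

    def test_anticorrelated_profile_rejected(self):
        L = np.arange(0.0, 50.0, 5.0)
        prof = TangentCorrelationProfile(L, -np.ones(L.size),
                                         np.full(L.size, 100))
        with pytest.raises(FitFailureError):
            fit_persistence_2d(prof, L_max=50.0)

    @pytest.mark.parametrize("p,arc_step", [(5.0, 1.0), (20.0, 5.0),
                                            (50.0, 5.0)])
    def test_chain_ensemble_recovery(self, p, arc_step):
        # generator -> correlation -> fit closes within 10%
        chains = [gen_chain_2d(p, 2500.0,
                               GeneratorSpec(seed=1000 + i, noise_sd=0.0,
                                             arc_step=arc_step))
                  for i in range(50)]
        prof = tangent_correlation(chains, resample_step=max(arc_step, p / 4.0),
                                   max_separation=5.0 * p)
        fit = fit_persistence_2d(prof, L_max=5.0 * p)
        assert fit.persistence == pytest.approx(p, rel=0.10)


class TestLoopFreeSegmentation:
    def test_straight_line_returned_whole(self):
        tr = straight_trace(200.0)
        seg = longest_loopfree_segment(tr, contact_radius=4.0)
        assert len(seg) == len(tr)

    def test_balloon_loop_keeps_loop_interior(self):
        # tails of 60 and 30 nm joined by a 126-nm loop touching at origin:
        # the loop interior is the longest contact-free piece
        tail1 = np.column_stack([np.zeros(30), np.linspace(-60, -2, 30)])
        th = np.linspace(-0.5 * math.pi, 1.5 * math.pi, 70)
        loop = np.column_stack([20 * np.cos(th), 20 + 20 * np.sin(th)])
        tail2 = np.column_stack([np.zeros(15), np.linspace(2, 30, 15)])
        tr = BackboneTrace(np.vstack([tail1, loop, tail2]), "balloon")
        seg = longest_loopfree_segment(tr, contact_radius=4.0)
        r = np.linalg.norm(seg.points - np.array([0.0, 20.0]), axis=1)
        np.testing.assert_allclose(r, 20.0, atol=1e-6)
        assert trace_contour_length(seg) > 80.0

    def test_two_crossings_bracket_short_middle(self):
        # a return path crosses the main line at x = 270 and x = 250,
        # bracketing a short middle; the long left flank survives intact
        main = np.column_stack([np.linspace(0, 300, 151), np.zeros(151)])
        down = np.column_stack([np.full(20, 270.0), np.linspace(-2, -40, 20)])
        over = np.column_stack([np.linspace(268, 252, 9), np.full(9, -40.0)])
        up = np.column_stack([np.full(30, 250.0), np.linspace(-38, 20, 30)])
        tr = BackboneTrace(np.vstack([main, down, over, up]), "double-cross")
        seg = longest_loopfree_segment(tr, contact_radius=4.0)
        assert np.all(seg.points[:, 1] == 0.0)  # entirely on the main line
        assert seg.points[:, 0].min() == 0.0
        assert seg.points[:, 0].max() >= 240.0
        assert trace_contour_length(seg) > 200.0


class TestIntegratedVolume:
    def test_flat_image_zero_volume(self):
        img = AFMImage(np.zeros((32, 32)), pixel_size=2.0, background=0.0)
        assert integrated_volume(img) == 0.0

    def test_single_pixel_volume(self):
        h = np.zeros((16, 16))
        h[8, 8] = 1.0
        img = AFMImage(h, pixel_size=2.0, background=0.0)
        assert integrated_volume(img) == pytest.approx(4.0)

    def test_additive_over_disjoint_molecules(self):
        h = np.zeros((32, 32))
        h[4, 4] = 2.0
        h[20, 20] = 3.0
        img = AFMImage(h, pixel_size=1.0, background=0.0)
        one = AFMImage(np.where(np.add.outer(np.arange(32), np.zeros(32)) < 16,
                                h, 0.0), 1.0, 0.0)
        other = AFMImage(np.where(np.add.outer(np.arange(32), np.zeros(32)) >= 16,
                                  h, 0.0), 1.0, 0.0)
        assert integrated_volume(img) == pytest.approx(
            integrated_volume(one) + integrated_volume(other))

    def test_background_offset_invariance_with_reestimation(self):
        rng = np.random.default_rng(3)
        h = rng.normal(0.0, 0.02, (64, 64))
        h[30:34, 10:50] += 2.0
        img = AFMImage(h, pixel_size=2.0)
        shifted = AFMImage(h + 5.0, pixel_size=2.0)
        v0 = integrated_volume(img, background=float(np.median(h)))
        v1 = integrated_volume(shifted,
                               background=float(np.median(h + 5.0)))
        assert v1 == pytest.approx(v0, rel=1e-9)

    def test_synthetic_image_volume_recovery(self):
        chain = gen_chain_2d(20.0, 500.0,
                             GeneratorSpec(seed=77, noise_sd=0.0, arc_step=2.0))
        img = gen_afm_image(chain, GeneratorSpec(seed=78, noise_sd=0.01),
                            molecule_height=2.0, tip_sigma=3.0, pixel_size=2.0)
        v = integrated_volume(img, background=0.0)
        assert v == pytest.approx(img.meta["injected_volume"], rel=0.05)


class TestImageTracing:
    def test_straight_molecule_skeleton_within_one_pixel(self):
        tr = straight_trace(300.0, step=2.0)
        img = gen_afm_image(tr, GeneratorSpec(seed=79, noise_sd=0.0),
                            molecule_height=2.0, tip_sigma=3.0, pixel_size=2.0)
        skel = trace_image(img)
        origin = np.array(img.meta["origin"])
        ys = skel.points[:, 1] + origin[1]
        assert np.max(np.abs(ys)) <= img.pixel_size
        xs = np.sort(skel.points[:, 0] + origin[0])
        assert xs.min() < 20.0 and xs.max() > 280.0
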