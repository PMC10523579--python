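"""Tissue-area segmentation and sarcomere length/organization recovery."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

from ectpipe.morphometry import (
    ZDiscSet,
    axial_angle_sd,
    detect_zdiscs,
    link_sarcomeres,
    segment_ect,
    summarize_sarcomeres,
)
from ectpipe.synth import gen_brightfield, gen_sarcomere_image


class TestSegmentEct:
    @pytest.mark.parametrize("axes", [(0.8, 0.4), (0.5, 0.35), (1.1, 0.55)])
    def test_area_within_2pct_of_analytic(self, axes):
        img, gt = gen_brightfield(axes_mm=axes, seed=11)
        res = segment_ect(img, px_size=gt.params["px_size"])
        assert not res.flagged
        assert res.area_mm2 == pytest.approx(gt.params["area_mm2"], rel=0.02)
        assert res.area_mm2 == pytest.approx(res.pixel_count * res.px_size**2)

    def test_blank_image_flagged(self):
        res = segment_ect(np.full((100, 100), 128.0), px_size=0.005)
        assert res.flagged
        assert res.area_mm2 is None

    def test_doubling_px_size_quadruples_area(self):
        img, gt = gen_brightfield(axes_mm=(0.6, 0.3), seed=12)
        a1 = segment_ect(img, px_size=0.005).area_mm2
        a2 = segment_ect(img, px_size=0.010).area_mm2
        assert a2 == pytest.approx(4 * a1, rel=1e-9)

    def test_vignetted_image_flagged_as_border_touching(self):
        # heavy vignetting: a dark frame around the field is picked up as the
        # largest dark component and hugs the whole border
        img = np.full((200, 200), 180.0)
        img[:15, :] = img[-15:, :] = img[:, :15] = img[:, -15:] = 60.0
        res = segment_ect(img, px_size=0.005)
        assert res.flagged
        assert res.area_mm2 is None


class TestDetectZdiscs:
    def test_blank_image_empty(self):
        assert len(detect_zdiscs(np.zeros((64, 64)))) == 0

    def test_single_stripe_orientation(self):
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        th = np.deg2rad(30.0)
        d_par = (xx - 32) * np.cos(th) + (yy - 32) * np.sin(th)
        d_perp = -(xx - 32) * np.sin(th) + (yy - 32) * np.cos(th)
        img = 100.0 * np.exp(-(d_par**2) / (2 * 36.0) - (d_perp**2) / (2 * 2.25))
        discs = detect_zdiscs(img)
        assert len(discs) == 1
        assert discs.orientations[0] == pytest.approx(30.0, abs=3.0)

    def test_lattice_stripes_matched_to_truth(self):
        img, gt = gen_sarcomere_image(spacing_um=1.72, angle_sd_deg=10.0, seed=21)
        discs = detect_zdiscs(img)
        truth = np.asarray(gt.params["centers_px"])
        dist, _ = cKDTree(discs.centers).query(truth)
        assert np.mean(dist < 2.0) >= 0.95


class TestLinkSarcomeres:
    def _two_discs(self, sep_px, ori1, ori2):
        centers = np.array([[20.0, 20.0], [20.0 + sep_px, 20.0]])
        return ZDiscSet(centers, np.array([ori1, ori2]),
                        np.zeros((40, 40), int), 2.0)

    def test_two_parallel_discs_linked(self):
        discs = self._two_discs(17.0, 90.0, 90.0)  # vertical discs, 1.7 um apart
        links = link_sarcomeres(discs, px_size_um=0.1)
        assert links.pairs == [(0, 1)]
        assert links.lengths_um[0] == pytest.approx(1.7)
        assert links.angles_deg[0] == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_discs_not_linked(self):
        discs = self._two_discs(17.0, 90.0, 0.0)
        assert link_sarcomeres(discs, px_size_um=0.1).pairs == []

    def test_out_of_range_distance_not_linked(self):
        discs = self._two_discs(40.0, 90.0, 90.0)  # 4 um apart
        assert link_sarcomeres(discs, px_size_um=0.1).pairs == []

    def test_lattice_round_trip_length_and_angle_sd(self):
        img, gt = gen_sarcomere_image(spacing_um=1.72, angle_sd_deg=10.0, seed=22)
        links = link_sarcomeres(detect_zdiscs(img), px_size_um=0.1)
        assert links.median_length == pytest.approx(1.72, abs=0.05)
        true_sd = axial_angle_sd(np.asarray(gt.params["link_angles_deg"]))
        assert links.angle_sd == pytest.approx(true_sd, abs=3.0)


class TestSummaries:
    def test_single_image_median(self):
        links = _links_from(lengths=[1.6, 1.7, 1.8], angles=[10.0, 12.0, 14.0])
        assert links.median_length == pytest.approx(1.7)

    def test_group_mean_of_image_medians(self):
        a = _links_from([1.5, 1.6, 1.7], [0.0, 5.0, 10.0])
        b = _links_from([1.8, 1.8, 1.8], [0.0, 5.0, 10.0])
        df = summarize_sarcomeres([a, b])
        row = df[df.metric == "median_length_um"].iloc[0]
        assert row["mean"] == pytest.approx((1.6 + 1.8) / 2)
        assert row["n_images"] == 2

    def test_group_summary_matches_flat_recomputation(self):
        rng = np.random.default_rng(5)
        sets = [
            _links_from(rng.uniform(1.4, 2.0, 9), rng.uniform(0, 40, 9))
            for _ in range(4)
        ]
        df = summarize_sarcomeres(sets)
        med = [np.median(s.lengths_um) for s in sets]
        sd = [axial_angle_sd(s.angles_deg) for s in sets]
        assert df[df.metric == "median_length_um"].iloc[0]["mean"] == pytest.approx(np.mean(med))
        assert df[df.metric == "angle_sd_deg"].iloc[0]["mean"] == pytest.approx(np.mean(sd))


def _links_from(lengths, angles):
    from ectpipe.morphometry import SarcomereLinkSet

    lengths = np.asarray(lengths, float)
    angles = np.asarray(angles, float)
    return SarcomereLinkSet([(i, i + 1) for i in range(len(lengths))],
                            lengths, angles, 0.1)


class TestInvariants:
    def test_rotation_equivariance(self):
        base_angle = 20.0
        img0, _ = gen_sarcomere_image(angle_mean_deg=base_angle,
                                      angle_sd_deg=3.0, seed=30)
        links0 = link_sarcomeres(detect_zdiscs(img0), px_size_um=0.1)
        phi = 35.0
        img1, _ = gen_sarcomere_image(angle_mean_deg=base_angle + phi,
                                      angle_sd_deg=3.0, seed=30)
        links1 = link_sarcomeres(detect_zdiscs(img1), px_size_um=0.1)

        def axial_mean(a):
            r = np.deg2rad(2 * np.asarray(a))
            return np.rad2deg(np.arctan2(np.sin(r).mean(), np.cos(r).mean())) / 2 % 180

        shift = (axial_mean(links1.angles_deg) - axial_mean(links0.angles_deg)) % 180
        assert min(shift, 180 - abs(shift - 0)) == pytest.approx(phi, abs=2.0) or \
            shift == pytest.approx(phi, abs=2.0)
        assert links1.median_length == pytest.approx(links0.median_length, abs=0.02)

    def test_angle_sd_recovery_monotone_in_dispersion(self):
        disp = [0.0, 5.0, 10.0, 20.0, 40.0]
        rec = []
        for sd in disp:
            img, _ = gen_sarcomere_image(angle_sd_deg=sd, seed=31)
            rec.append(link_sarcomeres(detect_zdiscs(img), px_size_um=0.1).angle_sd)
        rho = spearmanr(disp, rec).statistic
        assert rho > 0.95
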