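"""Geometry: magnification correction, disc/PPA morphometry, ROI masks."""

import numpy as np
import pytest

from fundusiod.case_io import Annotation
from fundusiod.roi_geometry import (MagnificationModel, build_roi_masks,
                                    disc_shape_metrics, etdrs_sector_means,
                                    littmann_scale, ppa_metrics)

SHAPE = (256, 256)


def make_annotation(disc_contour, fovea, ppa_contour=(), shape=SHAPE):
    return Annotation(
        disc_contour=np.asarray(disc_contour, dtype=float),
        ppa_contour=np.asarray(ppa_contour, dtype=float).reshape(-1, 2),
        fovea=fovea, vessel_mask=np.zeros(shape, dtype=bool))


def ellipse_points(center, a_px, b_px, long_axis_deg_from_vertical=0.0,
                   n=360):
    """Analytic ellipse; at 0 deg the long axis is vertical (image y)."""
    tau = np.radians(long_axis_deg_from_vertical)
    v = np.array([-np.sin(tau), -np.cos(tau)])   # long axis, pointing up
    w = np.array([-v[1], v[0]])
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return (np.asarray(center)[None, :] + np.outer(a_px * np.cos(th), v)
            + np.outer(b_px * np.sin(th), w))


class TestLittmann:
    def test_bennett_factor_reference_value(self):
        assert littmann_scale(23.82).q == pytest.approx(0.28732, abs=1e-10)

    def test_linearity_in_axial_length(self):
        q1 = littmann_scale(1.82 + 15.0).q
        q2 = littmann_scale(1.82 + 30.0).q
        assert q2 == pytest.approx(2.0 * q1, rel=1e-12)

    @pytest.mark.parametrize("al", [1.82, 14.9, 40.0, 55.0])
    def test_out_of_range_axial_length_rejected(self, al):
        with pytest.raises(ValueError):
            littmann_scale(al)

    def test_scale_monotone_in_al(self):
        scales = [littmann_scale(al).scale for al in (21.0, 24.0, 27.0, 30.0)]
        assert np.all(np.diff(scales) > 0)


class TestDiscShape:
    MAG = MagnificationModel(camera_constant=1.0, q=0.02, scale=0.02)

    def test_circle_is_isotropic_with_zero_torsion(self):
        pts = ellipse_points((128, 128), 45.0, 45.0)
        ann = make_annotation(pts, fovea=(230.0, 128.0))
        geo = disc_shape_metrics(ann, self.MAG)
        assert geo.ovality_index == pytest.approx(1.0, abs=0.02)
        assert geo.torsion_deg == 0.0

    def test_ellipse_diameters_and_ovality(self):
        # semi-axes 0.90 / 0.72 mm at 0.02 mm/px, long axis vertical
        pts = ellipse_points((128, 128), 45.0, 36.0)
        ann = make_annotation(pts, fovea=(230.0, 128.0))
        geo = disc_shape_metrics(ann, self.MAG)
        assert geo.ld_mm == pytest.approx(1.80, rel=0.02)
        assert geo.sd_mm == pytest.approx(1.44, rel=0.02)
        assert geo.ovality_index == pytest.approx(0.80, rel=0.02)
        assert geo.torsion_deg == pytest.approx(0.0, abs=2.0)

    @pytest.mark.parametrize("angle", [10.0, -10.0, 25.0])
    def test_torsion_sign_convention(self, angle):
        # positive angle tilts the superior end toward the nasal side
        # (away from the fovea at +x); tilting toward the fovea is negative
        pts = ellipse_points((128, 128), 45.0, 36.0,
                             long_axis_deg_from_vertical=angle)
        ann = make_annotation(pts, fovea=(230.0, 128.0))
        geo = disc_shape_metrics(ann, self.MAG)
        assert geo.torsion_deg == pytest.approx(angle, abs=2.0)

    def test_torsion_is_laterality_agnostic(self):
        # mirroring the whole case (contours AND fovea) produces the other
        # eye with the same anatomical torsion: superonasal stays positive
        pts = ellipse_points((128, 128), 45.0, 36.0,
                             long_axis_deg_from_vertical=10.0)
        ann = make_annotation(pts, fovea=(230.0, 128.0))
        geo = disc_shape_metrics(ann, self.MAG)
        mirrored = pts.copy()
        mirrored[:, 0] = 256.0 - mirrored[:, 0]
        ann_m = make_annotation(mirrored, fovea=(26.0, 128.0))
        geo_m = disc_shape_metrics(ann_m, self.MAG)
        assert geo_m.torsion_deg == pytest.approx(geo.torsion_deg, abs=2.0)

    def test_torsion_sign_flips_when_tilt_crosses_the_reference(self):
        # mirroring only the disc (fovea fixed) moves the superior end from
        # the nasal to the temporal side and flips the sign
        pts = ellipse_points((128, 128), 45.0, 36.0,
                             long_axis_deg_from_vertical=10.0)
        fovea = (230.0, 128.0)
        geo = disc_shape_metrics(make_annotation(pts, fovea=fovea), self.MAG)
        disc_only = pts.copy()
        disc_only[:, 0] = 256.0 - disc_only[:, 0]
        disc_only[:, 0] += 2 * (128.0 - 128.0)
        geo_m = disc_shape_metrics(make_annotation(disc_only, fovea=fovea),
                                   self.MAG)
        assert geo_m.torsion_deg == pytest.approx(-geo.torsion_deg, abs=2.0)

    def test_ovality_invariant_under_rotation_and_translation(self):
        rng = np.random.default_rng(3)
        base = ellipse_points((100, 100), 40.0, 28.0, 17.0)
        ann = make_annotation(base, fovea=(200.0, 100.0))
        ref = disc_shape_metrics(ann, self.MAG).ovality_index
        for _ in range(5):
            th = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(th), -np.sin(th)],
                          [np.sin(th), np.cos(th)]])
            shift = rng.uniform(-20, 20, 2)
            pts = (base - 100.0) @ R.T + 128.0 + shift
            fov = (np.array([200.0, 100.0]) - 100.0) @ R.T + 128.0 + shift
            moved = make_annotation(pts, fovea=tuple(fov))
            ov = disc_shape_metrics(moved, self.MAG).ovality_index
            assert ov == pytest.approx(ref, rel=0.01)

    def test_degenerate_contour_rejected(self):
        ann = make_annotation([(0, 0), (1, 0), (1, 1), (0, 1)],
                              fovea=(50.0, 50.0))
        with pytest.raises(ValueError):
            disc_shape_metrics(ann, self.MAG)


class TestPPA:
    MAG = MagnificationModel(camera_constant=1.0, q=0.02, scale=0.02)

    @staticmethod
    def half_annulus(center, r_in_px, r_out_px, n=180):
        th = np.linspace(-np.pi / 2, np.pi / 2, n)
        outer = np.column_stack([center[0] + r_out_px * np.cos(th),
                                 center[1] + r_out_px * np.sin(th)])
        inner = np.column_stack([center[0] + r_in_px * np.cos(th[::-1]),
                                 center[1] + r_in_px * np.sin(th[::-1])])
        return np.vstack([outer, inner])

    def test_empty_ppa_gives_zero_metrics_and_positive_distance(self):
        disc = ellipse_points((128, 128), 45.0, 45.0)
        ann = make_annotation(disc, fovea=(230.0, 128.0))
        geo = ppa_metrics(ann, self.MAG)
        assert (geo.area_mm2, geo.perimeter_mm, geo.width_mm) == (0, 0, 0)
        assert geo.disc_fovea_distance_mm == pytest.approx(
            (230 - 128) * 0.02, rel=1e-6)

    def test_half_annulus_crescent_area_and_width(self):
        # disc radius 0.9 mm, crescent 0.9-1.2 mm on the temporal side
        disc = ellipse_points((128, 128), 45.0, 45.0)
        ppa = self.half_annulus((128, 128), 45.0, 60.0)
        ann = make_annotation(disc, fovea=(230.0, 128.0), ppa_contour=ppa)
        geo = ppa_metrics(ann, self.MAG)
        expected_area = np.pi * (1.2 ** 2 - 0.9 ** 2) / 2
        assert geo.area_mm2 == pytest.approx(expected_area, rel=0.03)
        assert geo.width_mm == pytest.approx(0.3, rel=0.05)

    def test_dimensional_scaling_with_magnification(self):
        disc = ellipse_points((128, 128), 45.0, 45.0)
        ppa = self.half_annulus((128, 128), 45.0, 60.0)
        ann = make_annotation(disc, fovea=(230.0, 128.0), ppa_contour=ppa)
        g1 = ppa_metrics(ann, self.MAG)
        mag2 = MagnificationModel(camera_constant=1.0, q=0.04, scale=0.04)
        g2 = ppa_metrics(ann, mag2)
        assert g2.area_mm2 == pytest.approx(4 * g1.area_mm2, rel=1e-9)
        for attr in ("perimeter_mm", "width_mm", "disc_fovea_distance_mm"):
            assert getattr(g2, attr) == pytest.approx(
                2 * getattr(g1, attr), rel=1e-9)

    def test_ppa_fully_inside_disc_rejected(self):
        disc = ellipse_points((128, 128), 45.0, 45.0)
        ppa = ellipse_points((128, 128), 20.0, 20.0)
        ann = make_annotation(disc, fovea=(230.0, 128.0), ppa_contour=ppa)
        with pytest.raises(ValueError):
            ppa_metrics(ann, self.MAG)


class TestROIMasks:
    def test_partition_has_eight_disjoint_regions(self, rendered_case):
        masks = build_roi_masks(rendered_case["annotation"],
                                rendered_case["mag"], SHAPE)
        assert len(masks.ring_quadrants) == 8
        stack = np.stack(list(masks.ring_quadrants.values())
                         + [masks.disc])
        assert stack.sum(axis=0).max() <= 1  # pairwise disjoint incl. disc

    def test_inner_temporal_is_subset_of_inner_ring(self, rendered_case):
        masks = build_roi_masks(rendered_case["annotation"],
                                rendered_case["mag"], SHAPE)
        assert not (masks.inner_temporal & ~masks.inner_ring).any()
        assert not (masks.outer_temporal & masks.inner_ring).any()

    def test_rings_stay_inside_outer_circle(self, rendered_case):
        ann, mag = rendered_case["annotation"], rendered_case["mag"]
        masks = build_roi_masks(ann, mag, SHAPE)
        from fundusiod.roi_geometry import contour_centroid

        c = contour_centroid(ann.disc_contour)
        yy, xx = np.mgrid[0:SHAPE[0], 0:SHAPE[1]]
        r = np.hypot(xx - c[0], yy - c[1])
        union = np.zeros(SHAPE, bool)
        for m in masks.ring_quadrants.values():
            union |= m
        assert r[union].max() <= 3.0 / mag.scale + 0.5

    def test_vessel_exclusion_removes_exactly_those_pixels(self, rendered_case):
        ann, mag = rendered_case["annotation"], rendered_case["mag"]
        with_v = build_roi_masks(ann, mag, SHAPE, exclude_vessels=True)
        without = build_roi_masks(ann, mag, SHAPE, exclude_vessels=False)
        overlap = without.inner_temporal & ann.vessel_mask
        assert with_v.inner_temporal.sum() == \
            without.inner_temporal.sum() - overlap.sum()
        assert not (with_v.inner_temporal & ann.vessel_mask).any()

    def test_fovea_at_disc_center_rejected(self, rendered_case):
        ann = rendered_case["annotation"]
        from fundusiod.roi_geometry import contour_centroid

        c = contour_centroid(ann.disc_contour)
        bad = Annotation(disc_contour=ann.disc_contour,
                         ppa_contour=ann.ppa_contour,
                         fovea=(float(c[0]), float(c[1])),
                         vessel_mask=ann.vessel_mask)
        with pytest.raises(ValueError):
            build_roi_masks(bad, rendered_case["mag"], SHAPE)


class TestETDRS:
    MAG = MagnificationModel(camera_constant=1.0, q=0.03, scale=0.03)

    def test_constant_map_gives_constant_sector_means(self):
        vals = np.full(SHAPE, 200.0)
        means = etdrs_sector_means(vals, (128, 128), self.MAG, "macula")
        assert len(means) == 9
        assert all(v == pytest.approx(200.0) for v in means.values())

    def test_peripapillary_mode_has_four_outer_sectors(self):
        vals = np.zeros(SHAPE)
        means = etdrs_sector_means(vals, (128, 128), self.MAG,
                                   "peripapillary")
        assert sorted(means) == ["outer_inferior", "outer_nasal",
                                 "outer_superior", "outer_temporal"]

    def test_linear_gradient_matches_analytic_sector_integral(self):
        # map value = x coordinate; temporal axis +x
        vals = np.tile(np.arange(SHAPE[1], dtype=float), (SHAPE[0], 1))
        means = etdrs_sector_means(vals, (128, 128), self.MAG,
                                   "peripapillary")
        r1, r2 = 1.5 / 0.03, 3.0 / 0.03
        expected = ((r2 ** 3 - r1 ** 3) / 3 * np.sqrt(2)) \
            / ((r2 ** 2 - r1 ** 2) * np.pi / 4)
        assert means["outer_temporal"] > means["outer_nasal"]
        assert means["outer_temporal"] - 128 == pytest.approx(
            expected, rel=0.01)
        assert 128 - means["outer_nasal"] == pytest.approx(expected, rel=0.01)

    def test_grid_must_fit_in_raster(self):
        with pytest.raises(ValueError):
            etdrs_sector_means(np.zeros((64, 64)), (32, 32), self.MAG,
                               "macula")
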