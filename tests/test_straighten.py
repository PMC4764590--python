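import numpy as np
import pytest
from scipy.ndimage import map_coordinates

import untwist as ut
from untwist.model import build_model
from untwist.straighten import (map_point_to_twisted, map_point_to_untwisted,
                                map_points_to_untwisted, straighten_volume,
                                transform_annotations)


class TestStraightenVolume:
    def test_straight_phantom_is_near_identity(self, straight_phantom):
        """Straightening an already-straight worm reproduces its interior."""
        vol, lat, _, truth = straight_phantom
        m = build_model(lat, step=vol.voxel_size)
        sv = straighten_volume(vol, m)
        half = (sv.shape[1] - 1) // 2
        vin, vout = [], []
        for k, p in enumerate(m.samples):
            for j in range(sv.shape[1]):
                for i in range(sv.shape[2]):
                    x, y = (i - half) * m.step, (j - half) * m.step
                    if np.hypot(x, y) < 0.8 * truth.worm.r_head:
                        pos = (p.center + x * p.lr_axis + y * p.dv_axis) / vol.voxel_size
                        vin.append(map_coordinates(
                            vol.intensities, [[pos[2]], [pos[1]], [pos[0]]],
                            order=1)[0])
                        vout.append(sv.intensities[k, j, i])
        assert np.corrcoef(vin, vout)[0, 1] > 0.99

    def test_blobs_land_at_true_untwisted_positions(self, bent_twisted_phantom):
        vol, lat, _, truth = bent_twisted_phantom
        m = build_model(lat, step=vol.voxel_size)
        sv = straighten_volume(vol, m)
        half = (sv.shape[1] - 1) // 2
        for upos in truth.marker_untwisted:
            ei = upos[0] / m.step + half
            ej = upos[1] / m.step + half
            ek = upos[2] / m.step
            k0, j0, i0 = int(round(ek)), int(round(ej)), int(round(ei))
            patch = sv.intensities[max(k0 - 2, 0):k0 + 3,
                                   max(j0 - 2, 0):j0 + 3,
                                   max(i0 - 2, 0):i0 + 3]
            assert patch.size and patch.max() > 0.3   # a blob is present nearby
            idx = np.unravel_index(np.argmax(patch), patch.shape)
            got = np.array([max(i0 - 2, 0) + idx[2], max(j0 - 2, 0) + idx[1],
                            max(k0 - 2, 0) + idx[0]], dtype=float)
            assert np.linalg.norm(got - np.array([ei, ej, ek])) <= 1.5

    def test_narrow_width_crops_peripheral_blobs(self, bent_twisted_phantom):
        vol, lat, _, truth = bent_twisted_phantom
        m = build_model(lat, step=vol.voxel_size)
        sv = straighten_volume(vol, m, W=2.0)      # well below the 5-7 µm radius
        assert sv.shape[1] == sv.shape[2] == 5
        # seam nuclei sit at the body edge: their peak intensity must be absent
        assert sv.intensities.max() < 0.9

    def test_empty_model_is_error(self, straight_phantom, straight_lattice):
        vol, *_ = straight_phantom
        m = build_model(straight_lattice, step=1.0)
        m.samples = []
        with pytest.raises(ValueError):
            straighten_volume(vol, m)

    def test_straightening_is_idempotent(self, straight_phantom):
        """Re-straightening a straightened volume barely changes voxels."""
        vol, lat, _, truth = straight_phantom
        m = build_model(lat, step=vol.voxel_size)
        sv = straighten_volume(vol, m)
        # trivial lattice along the straightened axis
        n = sv.shape[0]
        half = (sv.shape[1] - 1) // 2
        z = np.linspace(0, (n - 1) * sv.voxel_size, 11)
        c = half * sv.voxel_size
        left = np.stack([np.full(11, c - truth.worm.r_head), np.full(11, c), z], 1)
        right = np.stack([np.full(11, c + truth.worm.r_head), np.full(11, c), z], 1)
        m2 = build_model(ut.Lattice(left, right), step=sv.voxel_size)
        sv2 = straighten_volume(sv, m2, W=sv.W)
        a, b = sv.intensities, sv2.intensities
        nz = min(a.shape[0], b.shape[0])
        a, b = a[:nz], b[:nz]
        if a.shape != b.shape:          # crop to the common in-plane window
            dy = (a.shape[1] - b.shape[1]) // 2
            dx = (a.shape[2] - b.shape[2]) // 2
            if dy >= 0 and dx >= 0:
                a = a[:, dy:dy + b.shape[1], dx:dx + b.shape[2]]
            else:
                b = b[:, -dy:-dy + a.shape[1], -dx:-dx + a.shape[2]]
        mask = a > 0.05
        rms = np.sqrt(np.mean((a[mask] - b[mask]) ** 2))
        assert rms / np.sqrt(np.mean(a[mask] ** 2)) < 0.15


class TestPointMapping:
    def test_midline_maps_to_axis(self, geometry_phantom):
        _, lat, _, truth = geometry_phantom
        m = build_model(lat, step=0.5)
        for s in [10.0, 50.0, 90.0]:
            q = map_point_to_untwisted(m, truth.worm.centerline(s))
            assert q is not None
            x, y, z = q
            assert abs(x) < 0.5 and abs(y) < 0.5
            assert z == pytest.approx(s, abs=1.0)

    def test_far_point_unclaimed(self, geometry_phantom):
        _, lat, _, _ = geometry_phantom
        m = build_model(lat, step=0.5)
        assert map_point_to_untwisted(m, [500.0, 500.0, 500.0]) is None

    def test_round_trip_error_below_step(self, geometry_phantom):
        _, lat, _, truth = geometry_phantom
        m = build_model(lat, step=0.5)
        rng = np.random.default_rng(0)
        w = truth.worm
        pts = []
        while len(pts) < 1000:
            s = rng.uniform(0, w.length)
            r = w.radius(s)
            x, y = rng.uniform(-r, r, 2)
            if np.hypot(x, y) < 0.9 * r:
                pts.append(w.point(s, x, y))
        pts = np.array(pts)
        un = map_points_to_untwisted(m, pts)
        claimed = ~np.isnan(un).any(axis=1)
        assert claimed.mean() > 0.99
        back = np.array([map_point_to_twisted(m, q) for q in un[claimed]])
        err = np.linalg.norm(back - pts[claimed], axis=1)
        assert err.max() < m.step

    def test_untwisted_axis_maps_to_midline(self, geometry_phantom):
        _, lat, _, _ = geometry_phantom
        m = build_model(lat, step=0.5)
        for s in [0.0, 33.0, 99.5]:
            p = map_point_to_twisted(m, [0.0, 0.0, s])
            np.testing.assert_allclose(p, m.midline_point(s), atol=0.6)

    def test_z_out_of_range_raises(self, geometry_phantom):
        _, lat, _, _ = geometry_phantom
        m = build_model(lat, step=0.5)
        with pytest.raises(ValueError):
            map_point_to_twisted(m, [0.0, 0.0, -1.0])


class TestTransformAnnotations:
    def test_origin_maps_to_zero_and_markers_match_truth(self, geometry_phantom):
        _, lat, ann, truth = geometry_phantom
        m = build_model(lat, step=0.5)
        out = transform_annotations(ann, m)
        np.testing.assert_allclose(out["nose"].untwisted, [0, 0, 0], atol=1e-9)
        origin_u = np.array(ut.map_point_to_untwisted(m, ann["nose"].point))
        for name, upos in zip(truth.marker_names, truth.marker_untwisted):
            got = out[name].untwisted + origin_u
            assert np.linalg.norm(got - upos) < 1.0     # within one voxel-equiv

    def test_out_of_body_row_flagged_not_dropped(self, geometry_phantom):
        _, lat, ann, _ = geometry_phantom
        m = build_model(lat, step=0.5)
        rows = ann.rows + [ut.Annotation("stray", [900.0, 0.0, 0.0])]
        out = transform_annotations(
            ut.AnnotationTable(rows=rows, origin_name="nose"), m)
        assert out["stray"].claimed is False
        assert out["stray"].untwisted is None
        assert len(out) == len(rows)

    def test_missing_origin_is_error(self, geometry_phantom):
        _, lat, ann, _ = geometry_phantom
        m = build_model(lat, step=0.5)
        no_origin = ut.AnnotationTable(rows=[r for r in ann.rows], origin_name=None)
        with pytest.raises(Exception):
            transform_annotations(no_origin, m)
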