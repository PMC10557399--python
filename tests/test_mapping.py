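"""Shaft mapping: orientation recovery, ROI cropping, sectioning,
equiangular landmarks, thickness maps and the palmar/dorsal partition."""

import numpy as np
import pytest
import trimesh

from phalanxmap import PhalanxSpec, generate_mesh_pair, taxon_preset, thickness_field
from phalanxmap import mapping
from phalanxmap.mapping import (
    CrossSection,
    ExclusionError,
    build_thickness_map,
    define_roi,
    define_roi_from_frame,
    geometric_mean_size,
    palmar_dorsal_partition,
    place_landmarks,
    scale_map,
    slice_sections,
    standard_orientation,
)

from conftest import ring_polygon, tube_spec


# ---------------------------------------------------------------------------
# orientation

class TestStandardOrientation:
    def test_canonical_phantom_maps_to_itself(self, preset_pairs):
        for name, pair in preset_pairs.items():
            oriented, info = standard_orientation(pair)
            R = info["transform"][:3, :3]
            assert np.allclose(R, np.eye(3), atol=0.03), name
            assert not info["ambiguous_dorsal"]

    def test_rotation_invariance_of_map(self, preset_pairs):
        pair = preset_pairs["gorilla"]
        p0, _ = standard_orientation(pair)
        m0 = mapping.compute_thickness_map(define_roi_from_frame(p0))
        T = trimesh.transformations.rotation_matrix(1.1, [0.3, 0.5, 0.8], point=[5, -3, 10])
        p1, _ = standard_orientation(pair.apply_transform(T))
        m1 = mapping.compute_thickness_map(define_roi_from_frame(p1))
        rms = np.sqrt(np.mean((m0.values - m1.values) ** 2)) / m0.values.mean()
        assert rms < 0.01

    def test_mirrored_mesh_flagged(self, preset_pairs):
        mirrored = preset_pairs["pan"].copy()
        mirrored.periosteal.vertices[:, 0] *= -1  # reflect without reindexing
        mirrored.endosteal.vertices[:, 0] *= -1
        _, info = standard_orientation(mirrored)
        assert info["mirrored"]

    def test_near_spherical_input_rejected(self):
        from phalanxmap.phantom import MeshPair

        ball = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
        with pytest.raises(ValueError, match="axis"):
            standard_orientation(MeshPair(ball, ball.copy()))


# ---------------------------------------------------------------------------
# ROI

class TestDefineROI:
    def test_buffered_crop_extent(self, tube_pair):
        roi = define_roi(tube_pair, 0.15, 0.85, buffer=0.02)
        span = roi.span  # unbuffered ROI
        assert np.isclose(span, 0.7 * 40.0)
        z = roi.pair.periosteal.vertices[:, 2]
        # crop extends exactly 2% of the ROI span beyond each end
        assert np.isclose(z.min(), roi.z_start - 0.02 * span, atol=0.3)
        assert np.isclose(z.max(), roi.z_end + 0.02 * span, atol=0.3)

    def test_zero_buffer_crops_at_fractions(self, tube_pair):
        roi = define_roi(tube_pair, 0.2, 0.8, buffer=0.0)
        z = roi.pair.periosteal.vertices[:, 2]
        assert z.min() >= roi.z_start - 1e-6
        assert z.max() <= roi.z_end + 1e-6

    def test_too_short_roi_rejected(self, tube_pair):
        with pytest.raises(ValueError, match="short"):
            define_roi(tube_pair, 0.50, 0.52)

    def test_self_declared_roi_avoids_caps(self, preset_rois):
        # first and last sections must cut shaft geometry: one loop each
        for name, roi in preset_rois.items():
            secs = slice_sections(roi, levels=[0.02, 0.98])
            for s in secs:
                assert s.periosteal_outline.shape[0] >= 3
                assert s.endosteal_outline.shape[0] >= 3


# ---------------------------------------------------------------------------
# sections

class TestSliceSections:
    def test_exactly_97_sections(self, tube_roi):
        assert len(slice_sections(tube_roi)) == 97

    def test_cylinder_section_areas(self, tube_roi):
        from phalanxmap.csg import polygon_moments

        for sec in slice_sections(tube_roi, levels=[0.1, 0.5, 0.9]):
            a, _, _, _ = polygon_moments(sec.periosteal_outline)
            assert np.isclose(a, np.pi * 25.0, rtol=0.005)

    def test_tilted_input_matches_after_orientation(self, tube_pair):
        base = slice_sections(define_roi_from_frame(tube_pair), levels=[0.5])[0]
        T = trimesh.transformations.rotation_matrix(np.radians(10), [1, 0, 0])
        tilted, _ = standard_orientation(tube_pair.apply_transform(T), dorsal_hint=[0, 1, 0])
        sec = slice_sections(define_roi_from_frame(tilted), levels=[0.5])[0]
        from phalanxmap.csg import polygon_moments

        a0 = polygon_moments(base.periosteal_outline)[0]
        a1 = polygon_moments(sec.periosteal_outline)[0]
        assert np.isclose(a0, a1, rtol=0.005)

    def test_missing_endosteal_loop_propagates_exclusion(self):
        spec = taxon_preset(
            "gorilla", mesh_resolution=(96, 48), lumen_fill_distal_fraction=0.4
        )
        roi = define_roi_from_frame(generate_mesh_pair(spec))
        with pytest.raises(ExclusionError, match="endosteal"):
            slice_sections(roi)


# ---------------------------------------------------------------------------
# landmarks

def make_section(outer, inner):
    from phalanxmap.mapping import _ring_centroid

    return CrossSection(
        level=0.5,
        periosteal_outline=outer,
        endosteal_outline=inner,
        centroid=_ring_centroid(outer, inner),
    )


class TestPlaceLandmarks:
    def test_concentric_annulus_thickness(self):
        sec = make_section(ring_polygon(5.0), ring_polygon(4.0))
        lm = place_landmarks(sec, k=50)
        assert np.allclose(lm.thickness, 1.0, atol=5 * (1 - np.cos(np.pi / 512)) * 9)
        # paired landmarks are collinear with the centroid along each ray
        v1 = lm.external_pts - sec.centroid
        v2 = lm.internal_pts - sec.centroid
        cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
        assert np.all(np.abs(cross) < 1e-9 * np.linalg.norm(v1, axis=1) * 10)

    def test_eccentric_annulus_matches_ray_circle_oracle(self):
        # inner circle shifted dorsally; oracle = exact ray-circle intersection
        R, r, e = 5.0, 4.0, 0.5
        outer = ring_polygon(R, n=2048)
        inner = ring_polygon(r, n=2048, center=(0.0, e))
        sec = make_section(outer, inner)
        lm = place_landmarks(sec, k=50)
        o = sec.centroid
        for j, phi in enumerate(np.radians(lm.angles_deg)):
            d = np.array([np.sin(phi), np.cos(phi)])
            # farthest t with |o + t d| = R
            b = o @ d
            t_out = -b + np.sqrt(b * b - (o @ o - R * R))
            oc = o - np.array([0.0, e])
            b2 = oc @ d
            t_in = -b2 + np.sqrt(b2 * b2 - (oc @ oc - r * r))
            assert np.isclose(lm.thickness[j], t_out - t_in, atol=2e-4), j

    def test_concave_ridge_outline_single_landmark_per_ray(self):
        # a deep ridge bump makes the outline locally concave; the
        # farthest-intersection rule must still give one landmark per ray
        th = np.linspace(0, 2 * np.pi, 1024, endpoint=False)
        bump = 1.5 * np.exp(-(((np.degrees(th) - 240) % 360 - 120) / 8.0) ** 2)
        r_out = 5.0 + bump
        outer = np.column_stack([r_out * np.sin(th), r_out * np.cos(th)])
        inner = ring_polygon(3.0)
        sec = make_section(outer, inner)
        lm = place_landmarks(sec, k=50)
        assert lm.thickness.shape == (50,)
        assert np.all(lm.thickness > 0)

    def test_ray_missing_outline_raises(self):
        # centroid far outside the small inner outline: some ray misses it
        outer = ring_polygon(5.0)
        inner = ring_polygon(0.3, center=(3.0, 0.0))
        sec = CrossSection(
            level=0.5,
            periosteal_outline=outer,
            endosteal_outline=inner,
            centroid=np.array([-3.0, 0.0]),
        )
        with pytest.raises(ValueError, match="misses"):
            place_landmarks(sec, k=50)


# ---------------------------------------------------------------------------
# thickness maps

class TestThicknessMap:
    def test_4850_measurements(self, tube_map):
        assert tube_map.values.shape == (97, 50)
        assert tube_map.n_measurements == 4850

    def test_constant_tube_statistics(self, tube_map):
        assert np.isclose(tube_map.values.mean(), 2.0, atol=1e-3)
        assert tube_map.values.std() < 0.01 * 2.0

    def test_recovers_ground_truth_field(self, preset_maps):
        spec = taxon_preset("gorilla")
        levels = preset_maps["gorilla"].levels[:, None]
        phi = preset_maps["gorilla"].angles_deg[None, :]
        truth = thickness_field(spec, levels, phi)
        rel = np.abs(preset_maps["gorilla"].values - truth) / truth
        assert np.median(rel) < 0.05
        assert rel.mean() < 0.10

    def test_pongo_argmax_in_fsr_window(self, preset_maps):
        m = preset_maps["pongo"]
        i, j = np.unravel_index(np.argmax(m.values), m.values.shape)
        spec = taxon_preset("pongo")
        phi = m.angles_deg[j]
        assert min(
            abs(phi - spec.fsr_angles_deg[0]), abs(phi - spec.fsr_angles_deg[1])
        ) <= 2 * spec.fsr_sigma_deg
        assert abs(m.levels[i] - spec.fsr_window_center) <= 2 * spec.fsr_window_sd

    def test_dimension_mismatch_rejected(self, tube_roi):
        secs = slice_sections(tube_roi, levels=[0.4, 0.6])
        lms = [place_landmarks(s) for s in secs]
        with pytest.raises(ValueError, match="count"):
            build_thickness_map(secs, lms[:1], bone_length_mm=40.0)


class TestBoneLengthAndScaling:
    def test_straight_phantom_length(self, tube_pair):
        assert np.isclose(mapping.bone_length(tube_pair), 40.0, atol=0.05)

    def test_length_scales_with_phantom(self):
        spec = tube_spec(mesh_resolution=(80, 48))
        a = generate_mesh_pair(spec)
        b = generate_mesh_pair(spec.scaled(2.0))
        assert np.isclose(mapping.bone_length(b), 2 * mapping.bone_length(a))

    def test_curved_phantom_shows_chord_effect(self):
        from phalanxmap.phantom import centerline_frame

        spec = PhalanxSpec(included_angle_deg=60.0, mesh_resolution=(120, 64))
        pair = generate_mesh_pair(spec)
        L = mapping.bone_length(pair)
        assert L < spec.length_mm  # chord is shorter than the arc
        C, _ = centerline_frame(spec, [0.0, 1.0])
        chord_z = C[1][2] - C[0][2]
        # z-extent exceeds the centerline chord only by the tilted-ring
        # overhang, bounded by r_max * sin(half the full arc angle) per end
        theta_full = np.radians(spec.included_angle_deg / spec.shaft_fractional_span)
        r_max = spec.outer_radius_mm * (1 + spec.taper / (1 - spec.taper)) * 1.3
        assert chord_z <= L <= chord_z + 2 * r_max * np.sin(theta_full / 2)

    def test_scale_map_round_trip(self, tube_map):
        s = scale_map(tube_map, 40.0)
        assert s.scaled
        assert np.allclose(s.values, tube_map.values / 40.0)
        with pytest.raises(ValueError, match="already"):
            scale_map(s, 40.0)
        with pytest.raises(ValueError):
            scale_map(tube_map, -1.0)

    def test_scaled_map_is_size_invariant(self):
        spec = taxon_preset("pan", mesh_resolution=(96, 48))
        a = generate_mesh_pair(spec)
        b = generate_mesh_pair(spec.scaled(2.0))
        ma = mapping.compute_thickness_map(define_roi_from_frame(a))
        mb = mapping.compute_thickness_map(define_roi_from_frame(b))
        sa = scale_map(ma, mapping.bone_length(a))
        sb = scale_map(mb, mapping.bone_length(b))
        assert np.allclose(sa.values, sb.values, rtol=1e-6)


class TestGeometricMeanSize:
    def test_arithmetic(self):
        assert np.isclose(
            geometric_mean_size(40, 10, 14, 12), (40 * 10 * 14 * 12) ** 0.25
        )
        assert np.isclose(geometric_mean_size(7, 7, 7, 7), 7.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            geometric_mean_size(40, 0, 14, 12)

    def test_preset_ranks_agree_under_both_scalings(self, preset_pairs, preset_rois, preset_maps):
        by_length, by_gm = {}, {}
        for name in preset_maps:
            L = mapping.bone_length(preset_pairs[name])
            gm = geometric_mean_size(
                *mapping.measure_breadths(preset_pairs[name], preset_rois[name])
            )
            by_length[name] = preset_maps[name].values.mean() / L
            by_gm[name] = preset_maps[name].values.mean() / gm
        rank = lambda d: sorted(d, key=d.get)
        assert rank(by_length) == rank(by_gm)


class TestPalmarDorsalPartition:
    def test_symmetric_phantom_ratio_one(self, tube_map):
        palmar, dorsal, ratio = palmar_dorsal_partition(tube_map)
        assert np.isclose(ratio, 1.0, atol=1e-3)

    def test_homo_phantom_dorsal_dominant(self, preset_maps):
        palmar, dorsal, ratio = palmar_dorsal_partition(preset_maps["homo"])
        assert dorsal > palmar

    def test_fsr_rays_excluded_from_sectors(self):
        base = tube_spec(mesh_resolution=(120, 96))
        with_fsr = tube_spec(fsr_amplitude=0.8, mesh_resolution=(120, 96))
        m0 = mapping.compute_thickness_map(define_roi_from_frame(generate_mesh_pair(base)))
        m1 = mapping.compute_thickness_map(
            define_roi_from_frame(generate_mesh_pair(with_fsr))
        )
        r0 = palmar_dorsal_partition(m0)[2]
        r1 = palmar_dorsal_partition(m1)[2]
        assert abs(r1 - r0) < 0.02

    def test_even_sector_size_rejected(self, tube_map):
        with pytest.raises(ValueError, match="odd"):
            palmar_dorsal_partition(tube_map, n_sector=12)


class TestRenderMap:
    def test_csv_round_trip_bit_exact(self, tube_map, tmp_path):
        csv = tmp_path / "map.csv"
        png = tmp_path / "map.png"
        mapping.render_morphometric_map(tube_map, out_png=png, out_csv=csv)
        assert png.exists()
        back = mapping.load_map_csv(csv)
        assert np.array_equal(back, tube_map.values)

    def test_gorilla_map_maxima_at_ridges(self, preset_maps):
        m = preset_maps["gorilla"]
        spec = taxon_preset("gorilla")
        col_mean = m.values.mean(axis=0)
        j = int(np.argmax(col_mean))
        phi = m.angles_deg[j]
        assert min(
            abs(phi - spec.fsr_angles_deg[0]), abs(phi - spec.fsr_angles_deg[1])
        ) <= 2 * spec.fsr_sigma_deg
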