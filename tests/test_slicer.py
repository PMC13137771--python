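"""Layer/hatch slicing, droplet clipping, time estimates, path format."""

import io
import math

import numpy as np
import pytest
import trimesh

from cytoprint import (PathParseError, SliceSpec, WatertightError,
                       clip_to_droplet, estimate_print_time, make_sphere_mesh,
                       read_path, slice_mesh, write_path)
from cytoprint.slicer import Layer, PrintPath


def unit_cube():
    box = trimesh.creation.box(extents=[1.0, 1.0, 1.0])
    box.apply_translation([0.5, 0.5, 0.5])
    return box


class TestSliceMesh:
    def test_unit_cube_closed_form(self):
        path = slice_mesh(unit_cube())
        assert len(path.layers) == 10
        for layer in path.layers:
            assert len(layer.segments) == 10
            for seg in layer.segments:
                assert abs(np.linalg.norm(seg[-1] - seg[0]) - 1.0) < 1e-9
        assert abs(path.total_length - 100.0) < 1e-6

    def test_layer_planes_at_half_offsets_top_down(self):
        path = slice_mesh(unit_cube())
        zs = [l.z for l in path.layers]
        np.testing.assert_allclose(zs, 1.0 - (np.arange(10) + 0.5) * 0.1,
                                   atol=1e-12)
        assert all(a > b for a, b in zip(zs, zs[1:]))

    def test_bottom_up_order(self):
        path = slice_mesh(unit_cube(), SliceSpec(order="bottom_up"))
        zs = [l.z for l in path.layers]
        assert all(a < b for a, b in zip(zs, zs[1:]))

    def test_flat_mesh_below_first_plane_gives_empty_path(self):
        thin = trimesh.creation.box(extents=[1.0, 1.0, 0.04])
        thin.apply_translation([0, 0, 0.02])
        with pytest.warns(UserWarning):
            path = slice_mesh(thin)
        assert len(path.layers) == 0
        assert path.total_length == 0.0

    def test_sphere_total_length_matches_volume_filling_oracle(self):
        sphere = make_sphere_mesh(10.0, 4)
        sphere.apply_translation([0, 0, 5.0])
        path = slice_mesh(sphere)
        oracle = (math.pi * 10.0 ** 3 / 6.0) / (0.1 * 0.1)
        assert abs(path.total_length - oracle) / oracle < 0.05

    def test_convex_layer_hatch_area_matches_cross_section(self):
        sphere = make_sphere_mesh(10.0, 4)
        sphere.apply_translation([0, 0, 5.0])
        path = slice_mesh(sphere)
        spec = SliceSpec()
        for layer in path.layers[20:80:10]:
            r2 = 25.0 - (layer.z - 5.0) ** 2
            area = math.pi * r2
            hatch_area = sum(np.linalg.norm(s[-1] - s[0])
                             for s in layer.segments) * spec.hatch_spacing
            assert abs(hatch_area - area) / area < 0.05

    def test_non_watertight_mesh_rejected_naming_open_edges(self):
        box = unit_cube()
        broken = trimesh.Trimesh(vertices=box.vertices, faces=box.faces[:-2],
                                 process=False)
        with pytest.raises(WatertightError, match="open edge"):
            slice_mesh(broken)

    def test_serpentine_alternates_direction(self):
        path = slice_mesh(unit_cube())
        layer = path.layers[0]
        x_starts = [seg[0, 0] for seg in layer.segments]
        assert x_starts[0] != x_starts[1]

    def test_hollow_cross_sections_fill_even_odd(self):
        from cytoprint import make_hollow_sphere_mesh
        hollow = make_hollow_sphere_mesh(6.0, 0.5)
        hollow.apply_translation([0, 0, 3.0])
        path = slice_mesh(hollow)
        mid = min(path.layers, key=lambda l: abs(l.z - 3.0))
        # every equatorial hatch line must split into wall chords, never
        # cross the cavity
        total = sum(np.linalg.norm(s[-1] - s[0]) for s in mid.segments)
        annulus = math.pi * (3.0 ** 2 - 2.5 ** 2)
        assert abs(total * 0.1 - annulus) / annulus < 0.06
        for seg in mid.segments:
            mid_pt = (seg[0] + seg[-1]) / 2.0
            # no single chord spans the cavity straight through its middle
            if abs(seg[0, 1]) < 1.0:
                assert np.linalg.norm(seg[-1] - seg[0]) < 3.0


class TestClipToDroplet:
    def test_path_inside_droplet_unchanged(self, droplet):
        small = trimesh.creation.box(extents=[2.0, 2.0, 2.0])
        small.apply_translation([0, 0, 5.0])
        path = slice_mesh(small)
        clipped = clip_to_droplet(path, droplet)
        assert abs(clipped.total_length - path.total_length) < 1e-6

    def test_path_outside_droplet_empties(self, droplet):
        far = unit_cube()
        far.apply_translation([20.0, 0.0, 0.0])
        clipped = clip_to_droplet(slice_mesh(far), droplet)
        assert clipped.total_length == 0.0

    def test_oversize_cube_clipped_to_chord_lengths(self, droplet):
        cube = trimesh.creation.box(extents=[12.0, 12.0, 12.0])
        cube.apply_translation([0, 0, 5.0])
        path = slice_mesh(cube, SliceSpec(layer_height=0.5, hatch_spacing=0.5))
        clipped = clip_to_droplet(path, droplet)
        for layer in clipped.layers:
            r2 = droplet.radius ** 2 - (layer.z - droplet.center[2]) ** 2
            for seg in layer.segments:
                y = seg[0, 1]
                chord = 2.0 * math.sqrt(max(r2 - y * y, 0.0))
                length = np.linalg.norm(seg[-1] - seg[0])
                assert abs(length - chord) < 1e-9

    def test_clipping_never_increases_length(self, droplet):
        sphere = make_sphere_mesh(12.0, 3)
        sphere.apply_translation([0, 0, 5.0])
        path = slice_mesh(sphere, SliceSpec(layer_height=0.4,
                                            hatch_spacing=0.4))
        clipped = clip_to_droplet(path, droplet)
        assert clipped.total_length <= path.total_length + 1e-9


class TestTimeEstimate:
    def test_empty_path_takes_no_time(self):
        path = PrintPath(layers=[])
        assert estimate_print_time(path) == 0.0

    def test_unit_cube_takes_10_ms(self):
        path = slice_mesh(unit_cube())
        assert abs(estimate_print_time(path) - 0.01) < 1e-6

    def test_time_scales_inversely_with_speed(self):
        t1 = slice_mesh(unit_cube(),
                        SliceSpec(scan_speed=10000.0)).estimated_time
        t2 = slice_mesh(unit_cube(),
                        SliceSpec(scan_speed=20000.0)).estimated_time
        assert abs(t2 - t1 / 2.0) < 1e-9

    def test_10um_sphere_prints_in_single_digit_seconds(self):
        sphere = make_sphere_mesh(10.0, 4)
        sphere.apply_translation([0, 0, 5.0])
        t = estimate_print_time(slice_mesh(sphere))
        assert 3.0 <= t <= 10.0

    def test_total_length_invariant_under_layer_reordering(self):
        path = slice_mesh(unit_cube())
        reordered = PrintPath(layers=list(reversed(path.layers)),
                              scan_speed=path.scan_speed)
        assert abs(reordered.total_length - path.total_length) < 1e-9


class TestPathFormat:
    def test_empty_path_writes_header_only(self):
        s = io.StringIO()
        write_path(PrintPath(layers=[]), s)
        assert s.getvalue().strip().startswith("printpath 0")

    def test_round_trip_on_random_paths(self, rng):
        for _ in range(5):
            layers = []
            z = 10.0
            for _ in range(int(rng.integers(1, 6))):
                segs = [rng.uniform(-8, 8,
                                    size=(int(rng.integers(2, 5)), 2))
                        for _ in range(int(rng.integers(1, 7)))]
                layers.append(Layer(z=z, segments=segs))
                z -= 0.1
            path = PrintPath(layers=layers, scan_speed=10000.0)
            s = io.StringIO()
            write_path(path, s)
            s.seek(0)
            back = read_path(s)
            assert len(back.layers) == len(path.layers)
            for la, lb in zip(path.layers, back.layers):
                assert abs(la.z - lb.z) < 1e-6
                assert len(la.segments) == len(lb.segments)
                for sa, sb in zip(la.segments, lb.segments):
                    np.testing.assert_allclose(sa, sb, atol=1e-6)
            assert abs(back.total_length - path.total_length) < 1e-4

    def test_cube_file_has_10_layer_headers(self, tmp_path):
        p = tmp_path / "cube.path"
        write_path(slice_mesh(unit_cube()), p)
        with open(p) as fh:
            headers = [line for line in fh if line.startswith("layer ")]
        assert len(headers) == 10

    def test_malformed_line_reports_line_number(self):
        s = io.StringIO("printpath 1 10000\nlayer 0.5 1\n1 2 3\n")
        with pytest.raises(PathParseError, match="line 3"):
            read_path(s)

    def test_missing_header_rejected(self):
        with pytest.raises(PathParseError, match="line 1"):
            read_path(io.StringIO("nonsense\n"))
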