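import numpy as np
import pytest

from axotomo.io import Volume3D
from axotomo.synthetic import SceneSpec, make_microtubule_scene, straight_mt
from axotomo.tracing import (
    CylinderTemplate,
    distance_to_polyline,
    make_region_masks,
    resample_centerline,
    trace_filaments,
)


class TestResample:
    def test_straight_line_uniform_points(self):
        pts = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 100.0]])
        tr = resample_centerline(pts, 10.0)
        assert len(tr.points) == 11
        np.testing.assert_allclose(np.diff(tr.arclength), 10.0, atol=1e-9)
        # collinear
        assert np.abs(np.cross(tr.points[1:] - tr.points[0],
                               [0.0, 0.0, 1.0])).max() < 1e-9

    def test_quarter_circle_arc_length(self):
        theta = np.linspace(0, np.pi / 2, 20)
        pts = np.column_stack([100 * np.cos(theta), 100 * np.sin(theta),
                               np.zeros_like(theta)])
        tr = resample_centerline(pts, 1.0)
        assert tr.length_nm == pytest.approx(np.pi * 100 / 2, abs=0.1)

    def test_idempotent_on_uniform_trace(self):
        theta = np.linspace(0, 1.0, 50)
        pts = np.column_stack([50 * np.cos(theta), 50 * np.sin(theta), 30 * theta])
        tr1 = resample_centerline(pts, 1.0)
        tr2 = resample_centerline(tr1, 1.0)
        assert len(tr1.points) == len(tr2.points)
        assert np.abs(tr1.points - tr2.points).max() < 1e-5

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            resample_centerline(np.zeros((5, 3)), 1.0)

    def test_spacing_within_one_percent(self):
        # a gently curving centerline, control points ~20 nm apart
        theta = np.linspace(0, 1.5, 25)
        pts = np.column_stack([120 * np.cos(theta), 120 * np.sin(theta),
                               200 * theta])
        tr = resample_centerline(pts, 2.0)
        steps = np.diff(tr.arclength)[:-1]  # final segment may be short
        assert np.all(np.abs(steps - 2.0) <= 0.02)


class TestRegionMasks:
    def test_lumen_and_shell_slice_counts_match_brute_force(self, straight_trace):
        vol = Volume3D(grid=np.zeros((110, 44, 44)))
        masks = make_region_masks(straight_trace, vol, 7.0, 15.0)
        # brute-force lattice counts in an interior slice
        yy, xx = np.mgrid[0:44, 0:44]
        d = np.hypot(yy - 21.0, xx - 21.0)
        assert masks.lumen[50].sum() == (d <= 7.0).sum() == 149
        assert masks.shell[50].sum() == ((d > 7.0) & (d <= 15.0)).sum() == 560

    def test_masks_disjoint_and_volume(self, straight_trace):
        vol = Volume3D(grid=np.zeros((110, 44, 44)))
        masks = make_region_masks(straight_trace, vol, 7.0, 15.0)
        assert not np.any(masks.lumen & masks.shell)
        assert masks.shell_volume_nm3 == masks.shell.sum() * 1.0

    def test_equal_radii_empty_shell(self, straight_trace):
        vol = Volume3D(grid=np.zeros((110, 44, 44)))
        masks = make_region_masks(straight_trace, vol, 7.0, 7.0)
        assert masks.shell.sum() == 0

    def test_trace_outside_volume_rejected(self, straight_trace):
        vol = Volume3D(grid=np.zeros((20, 10, 10)))
        with pytest.raises(ValueError, match="outside"):
            make_region_masks(straight_trace, vol)

    def test_exact_distance_against_brute_force(self):
        # a smooth helix resampled at 1 nm, the contract's domain
        rng = np.random.default_rng(7)
        theta = np.linspace(0, 3 * np.pi, 300)
        raw = np.column_stack([30 * np.cos(theta), 30 * np.sin(theta), 20 * theta])
        poly = resample_centerline(raw, 1.0).points
        queries = poly.mean(axis=0) + rng.normal(scale=25.0, size=(80, 3))
        fast = distance_to_polyline(queries, poly)
        # brute force over all segments
        from axotomo.tracing import _point_segment_distance

        brute = np.full(len(queries), np.inf)
        for i in range(len(poly) - 1):
            a = np.tile(poly[i], (len(queries), 1))
            b = np.tile(poly[i + 1], (len(queries), 1))
            brute = np.minimum(brute, _point_segment_distance(queries, a, b))
        np.testing.assert_allclose(fast, brute, atol=1e-9)


@pytest.fixture(scope="module")
def traced(noisy_mt_scene):
    vol, truth = noisy_mt_scene
    return trace_filaments(vol), truth


class TestTraceFilaments:

    def test_single_filament_recovered(self, traced):
        traces, truth = traced
        assert len(traces) == 1
        d = distance_to_polyline(traces[0].points, truth.centerlines[0])
        assert d.max() < 1.0  # within one voxel over the whole trace

    def test_pure_noise_yields_no_trace(self):
        rng = np.random.default_rng(0)
        vol = Volume3D(grid=rng.normal(0, 0.2, (128, 44, 44)).astype(np.float32))
        assert trace_filaments(vol) == []

    def test_template_larger_than_volume_rejected(self):
        vol = Volume3D(grid=np.zeros((20, 20, 20)))
        with pytest.raises(ValueError, match="template"):
            trace_filaments(vol)

    def test_two_parallel_filaments_not_merged(self):
        spec = SceneSpec(box_shape=(300, 84, 44),
                         microtubules=[straight_mt([21.5, 21.4, 5.0], [21.5, 21.4, 295.0]),
                                       straight_mt([21.5, 61.4, 5.0], [21.5, 61.4, 295.0])],
                         noise_snr=2.0, seed=5)
        vol, _ = make_microtubule_scene(spec)
        traces = trace_filaments(vol)
        assert len(traces) == 2

    def test_translation_equivariance(self):
        # the filament stays well clear of the volume faces so the roll is
        # a pure translation of everything the matched filter can see
        base = SceneSpec(box_shape=(330, 44, 44),
                         microtubules=[straight_mt([21.6, 21.4, 60.0], [21.6, 21.4, 270.0])],
                         noise_snr=None, seed=6)
        vol, _ = make_microtubule_scene(base)
        shifted = Volume3D(grid=np.roll(vol.grid, 7, axis=0))
        tr0 = trace_filaments(vol)[0]
        tr1 = trace_filaments(shifted)[0]
        # the shifted trace must lie 7 nm further along z
        d = distance_to_polyline(tr1.points - [0.0, 0.0, 7.0], tr0.points)
        assert d.max() < 1.0


def test_template_is_zero_mean_and_ordered():
    t = CylinderTemplate()
    rendered = t.render(1.0, np.array([0.3, 0.2, 0.9]))
    assert abs(rendered.mean()) < 1e-6
    with pytest.raises(ValueError):
        CylinderTemplate(lumen_radius_nm=15.0, outer_radius_nm=7.0)
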