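import numpy as np
import pytest
from scipy.signal import fftconvolve

from axotomo.synthetic import (
    ActinSpec,
    SceneSpec,
    SpiralSpec,
    actin_beads,
    apply_missing_wedge,
    make_lattice_density,
    make_microtubule_scene,
    make_rotation_table,
    make_spiral_scene,
    make_track_table,
    render_blobs,
    spiral_beads,
    straight_mt,
)


class TestMicrotubuleScene:
    def test_mip_count_follows_spacing_formula(self):
        # floor(length / spacing) + 1 particles from arc position 0
        spec = SceneSpec(box_shape=(512, 44, 44),
                         microtubules=[straight_mt([21.6, 21.4, 5.0], [21.6, 21.4, 505.0])],
                         mip_jitter_nm=0.0, seed=0)
        _, truth = make_microtubule_scene(spec)
        assert len(truth.mip_arc_nm[0]) == int(np.floor(500.0 / 18.5)) + 1
        np.testing.assert_allclose(np.diff(truth.mip_arc_nm[0]), 18.5, atol=1e-6)

    def test_protein_dark_contrast(self, noiseless_mt_scene):
        vol, truth = noiseless_mt_scene
        from axotomo.tracing import make_region_masks, resample_centerline

        trace = resample_centerline(truth.centerlines[0], 1.0)
        masks = make_region_masks(trace, vol)
        background = ~(masks.lumen | masks.shell)
        assert vol.grid[masks.shell].mean() < vol.grid[background].mean()

    def test_missing_wedge_zeroed_in_fourier_space(self):
        spec = SceneSpec(box_shape=(64, 32, 32),
                         microtubules=[straight_mt([15.0, 15.0, 5.0], [15.0, 15.0, 60.0])],
                         missing_wedge_halfangle_deg=30.0, seed=0)
        vol, _ = make_microtubule_scene(spec)
        f = np.fft.fftn(vol.grid)
        kz = np.fft.fftfreq(64)[:, None, None]
        kx = np.fft.fftfreq(32)[None, None, :]
        wedge = np.broadcast_to(np.abs(kx) < np.abs(kz) * np.tan(np.deg2rad(30.0)),
                                f.shape)
        assert np.abs(f[wedge]).max() < 1e-3 * np.abs(f).max()

    def test_deterministic_under_seed(self):
        spec = dict(box_shape=(64, 44, 44), noise_snr=2.0, seed=11)
        mts = lambda: [straight_mt([21.0, 21.0, 5.0], [21.0, 21.0, 55.0])]  # noqa: E731
        v1, _ = make_microtubule_scene(SceneSpec(microtubules=mts(), **spec))
        v2, _ = make_microtubule_scene(SceneSpec(microtubules=mts(), **spec))
        np.testing.assert_array_equal(v1.grid, v2.grid)

    def test_truth_render_cross_correlation_peaks_at_zero_lag(self, noiseless_mt_scene):
        vol, truth = noiseless_mt_scene
        ideal = render_blobs(vol.grid.shape, vol.voxel_size, vol.origin,
                             truth.mip_xyz_nm[0], sigma_nm=2.5, depth=1.0)
        corr = fftconvolve(vol.grid, ideal[::-1, ::-1, ::-1], mode="same")
        peak = np.unravel_index(np.argmax(corr), corr.shape)
        center = tuple(s // 2 for s in corr.shape)
        assert np.linalg.norm(np.subtract(peak, center)) <= 1.5


class TestSpiralScene:
    def test_closed_circle_bead_count(self):
        sp = SpiralSpec(center=np.zeros(3), normal=np.array([0.0, 0.0, 1.0]))
        beads = spiral_beads(sp)
        assert len(beads) == round(np.pi * 37.8 / 4.6) == 26

    def test_extended_string_is_collinear(self):
        sp = SpiralSpec(center=np.zeros(3), normal=np.array([1.0, 1.0, 0.0]),
                        extended=True)
        beads = spiral_beads(sp)
        d = beads[-1] - beads[0]
        cross = np.cross(beads[1:-1] - beads[0], d)
        assert np.abs(cross).max() < 1e-9

    def test_actin_control_bead_count(self):
        ac = ActinSpec(start=np.zeros(3), end=np.array([0.0, 0.0, 110.0]))
        assert len(actin_beads(ac)) == 21

    def test_unresolvable_geometry_rejected(self):
        with pytest.raises(ValueError, match="unresolvable"):
            SpiralSpec(center=np.zeros(3), normal=np.array([0.0, 0.0, 1.0]),
                       diameter_nm=6.0, width_nm=4.2)

    def test_scene_renders_all_beads_in_truth(self):
        sp = SpiralSpec(center=np.array([30.0, 30.0, 30.0]),
                        normal=np.array([0.0, 0.0, 1.0]))
        spec = SceneSpec(box_shape=(60, 60, 60), spirals=[sp], seed=0)
        vol, truth = make_spiral_scene(spec)
        beads = truth.spirals[0]["beads"]
        assert len(beads) == 26
        assert np.all(beads >= 0) and np.all(beads <= 60)
        # beads are dark in the rendered volume
        zyx = np.round(vol.nm_to_voxel(beads)).astype(int)
        assert vol.grid[zyx[:, 0], zyx[:, 1], zyx[:, 2]].max() < -0.3


class TestLatticeDensity:
    def test_truth_dimer_repeat_by_construction(self):
        _, model = make_lattice_density(83.3, intra_fraction=0.5)
        a = np.stack([model.chains["A"][r] for r in sorted(model.chains["A"])])
        c = np.stack([model.chains["C"][r] for r in sorted(model.chains["C"])])
        d = np.linalg.norm(a - c, axis=1) * 10.0
        assert np.median(d) == pytest.approx(83.3, abs=1e-9)

    def test_intra_fraction_translation(self):
        _, model = make_lattice_density(84.0, intra_fraction=0.5)
        a = model.chains["A"][10]
        b = model.chains["B"][10]
        assert np.linalg.norm(a - b) * 10.0 == pytest.approx(42.0, abs=1e-9)

    def test_repeat_outside_range_rejected(self):
        with pytest.raises(ValueError):
            make_lattice_density(60.0)


class TestRotationTable:
    def test_all_parallel_no_noise_single_rotation(self):
        table = make_rotation_table(9, parallel_fraction=1.0, angular_noise_deg=0.0, seed=0)
        assert table["rotation_deg"].nunique() == 1
        assert set(table["true_polarity"]) == {"parallel"}

    def test_polarity_offsets_are_180(self):
        table = make_rotation_table(300, parallel_fraction=0.5,
                                    angular_noise_deg=0.0, seed=1)
        rots = table["rotation_deg"].unique()
        assert len(rots) == 2
        assert abs(abs(rots[0] - rots[1]) - 180.0) < 1e-9

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            make_rotation_table(10, parallel_fraction=1.5, angular_noise_deg=0.0)


class TestTrackTable:
    def test_within_1um_mixture_bounds_net_displacement(self):
        table = make_track_table(50, {"within_1um": 1.0}, seed=0)
        for _, grp in table.groupby("track_id"):
            grp = grp.sort_values("time_s")
            net = grp["position_um"].iloc[-1] - grp["position_um"].iloc[0]
            assert abs(net) <= 1.0

    def test_deterministic_under_seed(self):
        t1 = make_track_table(100, {"anterograde_gt5": 0.5, "retrograde": 0.5}, seed=3)
        t2 = make_track_table(100, {"anterograde_gt5": 0.5, "retrograde": 0.5}, seed=3)
        assert t1.equals(t2)

    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError):
            make_track_table(10, {"within_1um": 0.5}, seed=0)

    def test_exact_counts_realize_mixture(self):
        mixture = {"anterograde_gt5": 0.39, "retrograde": 0.09,
                   "within_1um": 0.35, "intermediate": 0.17}
        table = make_track_table(200, mixture, seed=9, exact_counts=True)
        counts = table.groupby("track_id")["true_class"].first().value_counts()
        assert counts["anterograde_gt5"] == 78  # 0.39 * 200
        assert counts["retrograde"] == 18


def test_missing_wedge_identity_outside_wedge():
    rng = np.random.default_rng(0)
    g = rng.normal(size=(32, 16, 16)).astype(np.float32)
    out = apply_missing_wedge(g, 30.0)
    f_in, f_out = np.fft.fftn(g), np.fft.fftn(out)
    kz = np.fft.fftfreq(32)[:, None, None]
    kx = np.fft.fftfreq(16)[None, None, :]
    keep = np.broadcast_to(~(np.abs(kx) < np.abs(kz) * np.tan(np.deg2rad(30.0))),
                           f_in.shape)
    np.testing.assert_allclose(f_out[keep], f_in[keep], rtol=2e-5, atol=5e-3)
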