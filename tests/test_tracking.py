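import numpy as np
import pytest

from tfusplan.dti import TensorField, matrices_to_components
from tfusplan.errors import EmptyBundleError, OutOfBoundsError, ValidationError
from tfusplan.rois import BundleSpec, RegionParameterMap, ROISet, TrackingParameters
from tfusplan.tracking import (
    ProbabilityMap,
    StreamlineBundle,
    Streamline,
    probability_map,
    save_bundle_trk,
    threshold_map,
    track_bundle,
    track_streamline,
)
from tfusplan.volumes import Volume


def uniform_field(shape=(20, 20, 20), direction=(0, 1, 0), lam=(1.7e-3, 0.3e-3, 0.3e-3)):
    """Spatially constant prolate tensors with e1 along ``direction``."""
    d = np.asarray(direction, float)
    d /= np.linalg.norm(d)
    helper = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e2 = np.cross(d, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(d, e2)
    D = lam[0] * np.outer(d, d) + lam[1] * np.outer(e2, e2) + lam[2] * np.outer(e3, e3)
    tensors = np.tile(matrices_to_components(D), shape + (1,))
    return TensorField(tensors, np.ones(shape), np.ones(shape, bool), np.eye(4))


def background_atlas(shape=(20, 20, 20)):
    return Volume(np.zeros(shape, dtype=np.int16), np.eye(4))


PM = RegionParameterMap(default=TrackingParameters(min_length_mm=5.0))


class TestTrackStreamline:
    def test_straight_line_in_uniform_field(self):
        tf = uniform_field()
        sl = track_streamline(tf, [10.0, 10.0, 10.0], background_atlas(), PM)
        assert sl.status == "accepted"
        # all points share x and z; consecutive directions never bend
        np.testing.assert_allclose(sl.points[:, 0], 10.0, atol=1e-9)
        np.testing.assert_allclose(sl.points[:, 2], 10.0, atol=1e-9)
        steps = np.diff(sl.points, axis=0)
        dirs = steps / np.linalg.norm(steps, axis=1, keepdims=True)
        angles = np.arccos(np.clip(np.einsum("ij,ij->i", dirs[:-1], dirs[1:]), -1, 1))
        assert angles.max() < 1e-6

    def test_step_length_matches_local_step_size(self):
        tf = uniform_field()
        pm = RegionParameterMap(
            default=TrackingParameters(step_mm=0.7, min_length_mm=5.0)
        )
        sl = track_streamline(tf, [10.0, 10.0, 10.0], background_atlas(), pm)
        gaps = np.linalg.norm(np.diff(sl.points, axis=0), axis=1)
        np.testing.assert_allclose(gaps, 0.7, atol=1e-6)

    def test_region_override_changes_step_locally(self):
        """Crossing into an atlas region with a different step size, every
        consecutive gap still equals the locally active step."""
        tf = uniform_field()
        atlas = background_atlas()
        atlas.data[:, 10:, :] = 5
        pm = RegionParameterMap(
            default=TrackingParameters(step_mm=1.0, min_length_mm=5.0),
            overrides={5: {"step_mm": 0.5}},
        )
        sl = track_streamline(tf, [10.0, 10.0, 10.0], atlas, pm)
        gaps = np.linalg.norm(np.diff(sl.points, axis=0), axis=1)
        assert {round(g, 6) for g in gaps} == {0.5, 1.0}

    def test_arc_phantom_length_matches_analytic(self, arc_tensors, arc_phantom):
        """On the quarter-circle phantom the tracked length agrees with the
        analytic arc length R*pi/2 to 5%.  The stop threshold equals the
        FA of the boundary half-blend so termination is unbiased at the
        tube caps; the step obeys the half-voxel rule."""
        pm = RegionParameterMap(
            default=TrackingParameters(step_mm=0.5, fa_threshold=0.5)
        )
        mid = arc_phantom.centerline_points[len(arc_phantom.centerline_points) // 2]
        sl = track_streamline(arc_tensors, mid, arc_phantom.atlas, pm)
        assert sl.status == "accepted"
        assert sl.length_mm == pytest.approx(arc_phantom.analytic_length_mm, rel=0.05)

    def test_seed_in_isotropic_region_rejected_low_fa(self, straight_tensors, straight_phantom):
        sl = track_streamline(
            straight_tensors, [5.0, 5.0, 5.0], straight_phantom.atlas, PM
        )
        assert sl.status == "rejected"
        assert sl.reason == "low-FA"
        assert sl.length_mm == 0.0

    def test_seed_outside_grid_raises(self):
        tf = uniform_field()
        with pytest.raises(OutOfBoundsError):
            track_streamline(tf, [100.0, 0.0, 0.0], background_atlas(), PM)


@pytest.fixture(scope="module")
def corridor(straight_phantom, straight_tensors):
    return straight_phantom, straight_tensors, RegionParameterMap()


class TestTrackBundle:

    def test_clear_corridor_reaches_min_fibers_quickly(self, corridor):
        ph, tf, pm = corridor
        spec = BundleSpec("CST", "seed", ["waypoint", "target"], [], 100, 500)
        b = track_bundle(spec, ph.rois, tf, ph.atlas, pm, rng_seed=7)
        assert b.n_accepted >= 100
        assert b.iterations_used <= 5

    def test_blocking_exclude_rejects_everything(self, corridor):
        """An exclude ROI on the corridor kills every candidate; the loop
        runs to its iteration cap and reports (not raises) the shortfall."""
        ph, tf, pm = corridor
        spec = BundleSpec("CST", "seed", ["target"], ["waypoint"], 100, 5)
        b = track_bundle(spec, ph.rois, tf, ph.atlas, pm, rng_seed=7, batch_size=20)
        assert b.n_accepted == 0
        assert b.iterations_used == 5

    def test_unreachable_include_runs_to_cap(self, corridor):
        ph, tf, pm = corridor
        spec = BundleSpec("CST", "seed", ["off_corridor"], [], 100, 6)
        b = track_bundle(spec, ph.rois, tf, ph.atlas, pm, rng_seed=7, batch_size=10)
        assert b.n_accepted < 100
        assert b.iterations_used == spec.max_iterations

    def test_bit_exact_reproducible(self, corridor):
        ph, tf, pm = corridor
        spec = BundleSpec("CST", "seed", ["target"], [], 30, 500)
        b1 = track_bundle(spec, ph.rois, tf, ph.atlas, pm, rng_seed=123, batch_size=40)
        b2 = track_bundle(spec, ph.rois, tf, ph.atlas, pm, rng_seed=123, batch_size=40)
        assert b1.n_accepted == b2.n_accepted
        for s1, s2 in zip(b1.streamlines, b2.streamlines):
            np.testing.assert_array_equal(s1.points, s2.points)

    def test_different_seeds_differ(self, corridor):
        ph, tf, pm = corridor
        spec = BundleSpec("CST", "seed", ["target"], [], 10, 500)
        b1 = track_bundle(spec, ph.rois, tf, ph.atlas, pm, rng_seed=1, batch_size=10)
        b2 = track_bundle(spec, ph.rois, tf, ph.atlas, pm, rng_seed=2, batch_size=10)
        assert not np.array_equal(b1.streamlines[0].points, b2.streamlines[0].points)

    def test_raising_min_fibers_never_lowers_iterations(self, corridor):
        ph, tf, pm = corridor
        prev = 0
        for min_fibers in (10, 60, 150):
            spec = BundleSpec("CST", "seed", ["target"], [], min_fibers, 50)
            b = track_bundle(spec, ph.rois, tf, ph.atlas, pm, rng_seed=9, batch_size=20)
            assert b.iterations_used >= prev
            prev = b.iterations_used

    def test_empty_seed_roi_raises(self, corridor):
        ph, tf, pm = corridor
        rois = ROISet(dict(ph.rois.masks))
        rois.masks["empty"] = Volume(
            np.zeros(ph.atlas.spatial_shape, bool), ph.atlas.affine
        )
        spec = BundleSpec("CST", "empty", ["target"])
        from tfusplan.errors import EmptyMaskError

        with pytest.raises(EmptyMaskError):
            track_bundle(spec, rois, tf, ph.atlas, pm, rng_seed=0)


def _bundle_from_polylines(lines, name="CST"):
    return StreamlineBundle(
        name=name,
        streamlines=[Streamline(np.asarray(l, float), "accepted") for l in lines],
        iterations_used=1,
        rng_seed=0,
    )


class TestProbabilityMap:
    GRID = Volume(np.zeros((10, 10, 10)), np.eye(4))

    def test_identical_streamlines_give_binary_map(self):
        line = [[1.0, y, 1.0] for y in range(1, 9)]
        b = _bundle_from_polylines([line] * 10)
        p = probability_map(b, self.GRID)
        visited = p.volume.data[1, 1:9, 1]
        np.testing.assert_allclose(visited, 1.0)
        assert p.volume.data.sum() == pytest.approx(8.0)

    def test_half_shared_corridor_scales_to_half(self):
        a = [[1.0, y, 1.0] for y in range(1, 9)]
        bline = [[1.0, y, 1.0] for y in range(1, 5)] + [
            [3.0, y, 3.0] for y in range(5, 9)
        ]
        p = probability_map(_bundle_from_polylines([a, bline]), self.GRID)
        assert p.volume.data[1, 2, 1] == pytest.approx(1.0)  # shared voxel
        assert p.volume.data[1, 6, 1] == pytest.approx(0.5)  # only in a
        assert p.volume.data[3, 6, 3] == pytest.approx(0.5)  # only in b

    def test_multiple_visits_count_once(self):
        loop = [[1.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 1.0]]
        p = probability_map(_bundle_from_polylines([loop]), self.GRID)
        assert p.volume.data.max() == pytest.approx(1.0)
        assert p.volume.data.sum() == pytest.approx(2.0)

    def test_values_in_unit_interval(self, straight_phantom, straight_tensors):
        spec = BundleSpec("CST", "seed", ["target"], [], 20, 100)
        b = track_bundle(
            spec, straight_phantom.rois, straight_tensors,
            straight_phantom.atlas, RegionParameterMap(), rng_seed=3, batch_size=20,
        )
        p = probability_map(b, straight_tensors.grid())
        assert p.volume.data.min() >= 0.0
        assert p.volume.data.max() == pytest.approx(1.0)

    def test_empty_bundle_raises(self):
        b = StreamlineBundle("CST", [], 5, 0)
        with pytest.raises(EmptyBundleError):
            probability_map(b, self.GRID)


class TestThresholds:
    def _map(self, values):
        data = np.zeros((4, 4, 4))
        for i, v in enumerate(values):
            data[i, 0, 0] = v
        return ProbabilityMap(Volume(data, np.eye(4)))

    def test_aft_ml_threshold_half(self):
        out = threshold_map(self._map([0.4, 0.6]), "ML", "AFT")
        assert out.volume.data[0, 0, 0] == 0.0
        assert out.volume.data[1, 0, 0] == 0.6
        assert out.threshold == 0.5

    @pytest.mark.parametrize("bundle", ["CTT", "PTT", "CST"])
    def test_aft_targets_threshold_point_two(self, bundle):
        out = threshold_map(self._map([0.19, 0.2, 0.7]), bundle, "AFT")
        np.testing.assert_allclose(
            out.volume.data[:3, 0, 0], [0.0, 0.2, 0.7]
        )

    def test_fsl_threshold_inclusive_at_point_one(self):
        out = threshold_map(self._map([0.0999, 0.1]), "ML", "FSL")
        assert out.volume.data[0, 0, 0] == 0.0
        assert out.volume.data[1, 0, 0] == pytest.approx(0.1)

    def test_all_below_threshold_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            out = threshold_map(self._map([0.05, 0.01]), "CTT", "AFT")
        assert not np.any(out.volume.data)

    def test_unknown_bundle_rejected(self):
        with pytest.raises(ValidationError):
            threshold_map(self._map([0.5]), "XYZ")

    def test_double_thresholding_rejected(self):
        once = threshold_map(self._map([0.5]), "CTT")
        with pytest.raises(ValidationError):
            threshold_map(once, "CTT")

    def test_thresholded_corridor_is_connected(self, straight_phantom, straight_tensors):
        """The thresholded map of the straight bundle forms one connected
        corridor containing both the seed and the include ROI."""
        from scipy import ndimage

        ph = straight_phantom
        spec = BundleSpec("CST", "seed", ["target"], [], 100, 500)
        b = track_bundle(
            spec, ph.rois, straight_tensors, ph.atlas,
            RegionParameterMap(), rng_seed=5,
        )
        p = threshold_map(probability_map(b, straight_tensors.grid()), "CST")
        labels, n = ndimage.label(p.volume.data > 0)
        assert n >= 1
        corridor_label = np.argmax(np.bincount(labels[labels > 0]))
        in_seed = labels[ph.rois["seed"].data & (labels > 0)]
        in_target = labels[ph.rois["target"].data & (labels > 0)]
        assert corridor_label in in_seed
        assert corridor_label in in_target
        assert n == 1


class TestTrkExport:
    def test_trk_roundtrip_world_points(self, tmp_path):
        import nibabel.streamlines as nbs

        grid = Volume(np.zeros((10, 10, 10)), np.eye(4))
        line = np.array([[1.0, 2.0, 3.0], [1.5, 2.5, 3.5], [2.0, 3.0, 4.0]])
        b = _bundle_from_polylines([line])
        save_bundle_trk(b, grid, tmp_path / "b.trk")
        back = nbs.load(str(tmp_path / "b.trk"))
        np.testing.assert_allclose(back.streamlines[0], line, atol=1e-5)
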