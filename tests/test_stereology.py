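"""Sampling frames, probe intersection counting, fractionator and CE."""

import numpy as np
import pytest

from axonlength import (
    IntersectionTally,
    ProbeSpec,
    SegmentSet,
    build_frame,
    coefficient_of_error,
    count_plane_intersections,
    count_sphere_intersections,
    fiber_slab,
    fractionator_estimate,
    replicate_estimates,
)
from axonlength.stereology import (
    segment_plane_stack_crossings,
    segment_sphere_crossings,
)

BOX = np.array([50.0, 50.0, 50.0])


def _bbox(lo, hi):
    return np.asarray(lo, dtype=float), np.asarray(hi, dtype=float)


class TestBuildFrame:
    def test_two_sections_for_100um_extent(self):
        f = build_frame(_bbox([0, 0, 0], [100, 100, 100]), step=100, seed=0,
                        xy_phase=(0, 0), z_phase=0.0)
        assert f.n_sections == 2

    def test_four_box_columns_with_zero_phase(self):
        f = build_frame(_bbox([0, 0, 0], [200, 200, 50]), step=100, seed=0,
                        xy_phase=(0, 0), z_phase=0.0)
        assert f.n_sections == 1
        assert f.n_boxes == 4

    def test_seed_determinism(self):
        a = build_frame(_bbox([0, 0, 0], [300, 300, 120]), step=75, seed=5)
        b = build_frame(_bbox([0, 0, 0], [300, 300, 120]), step=75, seed=5)
        assert np.array_equal(a.boxes, b.boxes)

    def test_step_smaller_than_box_raises(self):
        with pytest.raises(ValueError, match="step"):
            build_frame(_bbox([0, 0, 0], [100, 100, 50]), step=40, seed=0)

    def test_thin_boxes_sit_inside_their_section(self):
        f = build_frame(_bbox([0, 0, 0], [200, 200, 160]), step=80, seed=3,
                        box_z=10.0)
        z0 = f.boxes[:, 2]
        sec = f.box_index[:, 0]
        # all boxes of one section share a z, sections are 50 um apart, and
        # the box offset within its section leaves room for box_z
        sec_z = {int(k): set(np.round(z0[sec == k], 9)) for k in np.unique(sec)}
        assert all(len(v) == 1 for v in sec_z.values())
        zs = sorted(next(iter(v)) for v in sec_z.values())
        offsets = np.array(zs) - np.arange(len(zs)) * f.section_thickness - zs[0]
        ok = (offsets >= -f.section_thickness + f.box_z - 1e-9) & \
             (offsets <= f.section_thickness - f.box_z + 1e-9)
        assert ok.all()


class TestSphereCounting:
    def test_diameter_chord_counts_two(self):
        q = segment_sphere_crossings([[-40, 25, 25]], [[120, 25, 25]],
                                     center=[25, 25, 25], radius=20.0)
        assert q.tolist() == [2]

    def test_far_segment_counts_zero(self):
        q = segment_sphere_crossings([[500, 500, 500]], [[600, 500, 500]],
                                     center=[25, 25, 25], radius=25.0)
        assert q.tolist() == [0]

    def test_single_crossing_for_endpoint_inside(self):
        q = segment_sphere_crossings([[25, 25, 25]], [[300, 25, 25]],
                                     center=[25, 25, 25], radius=10.0)
        assert q.tolist() == [1]

    def test_tangent_counts_zero(self):
        q = segment_sphere_crossings([[-50, 10, 0]], [[50, 10, 0]],
                                     center=[0, 0, 0], radius=10.0)
        assert q.tolist() == [0]

    def test_shared_vertex_not_double_counted(self):
        # vertex exactly on the surface, shared by two chained segments
        q = segment_sphere_crossings([[-30, 0, 0], [10, 0, 0]],
                                     [[10, 0, 0], [40, 0, 0]],
                                     center=[0, 0, 0], radius=10.0)
        assert int(q.sum()) == 2  # entry crossing + the shared vertex once


class TestPlaneCounting:
    def test_box_spanning_segment_crosses_ten_planes(self):
        lo = np.zeros(3)
        q = segment_plane_stack_crossings(
            [[-10, 25, 25]], [[60, 25, 25]], normal=[1, 0, 0],
            ref=2.5, spacing=5.0, box_lo=lo, box_dims=BOX)
        assert q.tolist() == [10]

    def test_parallel_segment_counts_zero(self):
        q = segment_plane_stack_crossings(
            [[5, 5, 5]], [[5, 45, 5]], normal=[1, 0, 0],
            ref=2.5, spacing=5.0, box_lo=np.zeros(3), box_dims=BOX)
        assert q.tolist() == [0]

    def test_crossings_outside_box_do_not_count(self):
        q = segment_plane_stack_crossings(
            [[60, 25, 25]], [[130, 25, 25]], normal=[1, 0, 0],
            ref=2.5, spacing=5.0, box_lo=np.zeros(3), box_dims=BOX)
        assert q.tolist() == [0]


def _dense_sphere_oracle(p0, p1, center, radius, n_steps=2000):
    t = np.linspace(0.0, 1.0, n_steps + 1)
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    sign = np.sign(np.linalg.norm(pts - center, axis=1) - radius)
    return int((np.diff(sign) != 0).sum() // 1) - int(0)


def _dense_plane_oracle(p0, p1, normal, ref, spacing, lo, dims, n_steps=4000):
    t = np.linspace(0.0, 1.0, n_steps + 1)
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    f = (pts @ normal - ref) / spacing
    k = np.floor(f)
    crossings = np.flatnonzero(np.diff(k) != 0)
    count = 0
    for i in crossings:
        # locate the crossing point by linear interpolation within the micro-step
        kk = max(k[i], k[i + 1])
        tt = t[i] + (t[i + 1] - t[i]) * (kk - f[i]) / (f[i + 1] - f[i])
        pt = p0 + tt * (p1 - p0)
        if np.all(pt >= lo) and np.all(pt < lo + dims):
            count += abs(int(k[i + 1] - k[i]))
    return count


class TestOracleEquivalence:
    """Analytic counters vs dense-walk sign-change oracles on random segments."""

    def test_sphere_counter_matches_dense_walk(self):
        rng = np.random.default_rng(8)
        center, radius = np.array([25.0, 25.0, 25.0]), 22.0
        p0 = rng.uniform(-30, 80, size=(300, 3))
        p1 = p0 + rng.normal(0, 30, size=(300, 3))
        q = segment_sphere_crossings(p0, p1, center, radius)
        for i in range(300):
            sign_changes = _dense_sphere_oracle(p0[i], p1[i], center, radius)
            assert q[i] == sign_changes, f"segment {i}"

    def test_plane_counter_matches_dense_walk(self):
        rng = np.random.default_rng(9)
        lo, dims = np.zeros(3), BOX
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        ref, spacing = 1.7, 5.0
        p0 = rng.uniform(-30, 80, size=(300, 3))
        p1 = p0 + rng.normal(0, 30, size=(300, 3))
        q = segment_plane_stack_crossings(p0, p1, n, ref, spacing, lo, dims)
        for i in range(300):
            assert q[i] == _dense_plane_oracle(p0[i], p1[i], n, ref, spacing,
                                               lo, dims), f"segment {i}"


class TestFractionator:
    def _frame(self, step):
        return build_frame(_bbox([0, 0, 0], [2 * step, 2 * step, 50]), step=step,
                           seed=0, xy_phase=(0, 0), z_phase=0.0)

    def test_zero_count_gives_zero_estimate(self):
        f = self._frame(75)
        t = IntersectionTally(np.zeros(f.n_boxes, dtype=int), f.n_boxes)
        assert fractionator_estimate(t, f, ProbeSpec("planes", spacing=5.0)) == 0.0

    def test_planes_closed_form(self):
        f = self._frame(75)
        q = np.zeros(f.n_boxes, dtype=int)
        q[0] = 100
        t = IntersectionTally(q, f.n_boxes)
        est = fractionator_estimate(t, f, ProbeSpec("planes", spacing=5.0))
        assert est == pytest.approx(2 * 100 * 5 * 75**2 / 50**2)  # 2250

    def test_spheres_closed_form(self):
        f = self._frame(100)
        q = np.zeros(f.n_boxes, dtype=int)
        q[0] = 50
        t = IntersectionTally(q, f.n_boxes)
        est = fractionator_estimate(t, f, ProbeSpec("sphere", diameter=50.0))
        assert est == pytest.approx(2 * 50 * (125_000 / (np.pi * 2500)) * 4, rel=1e-9)
        assert est == pytest.approx(6366.2, abs=0.05)

    def test_incompatible_tally_raises(self):
        f = self._frame(75)
        t = IntersectionTally(np.array([1, 2]), 2)
        with pytest.raises(ValueError, match="incompatible"):
            fractionator_estimate(t, f, ProbeSpec("planes", spacing=5.0))

    def test_probe_must_fit_box(self):
        f = self._frame(75)
        with pytest.raises(ValueError, match="diameter"):
            fractionator_estimate(
                IntersectionTally(np.zeros(f.n_boxes, dtype=int), f.n_boxes),
                f, ProbeSpec("sphere", diameter=60.0))


class TestCoefficientOfError:
    def test_hand_evaluated_uniform_counts(self):
        t = IntersectionTally(np.array([4, 4, 4, 4]), 4)
        # A=64 B=48 C=32 -> Var_SURS=32/12, Noise=16
        assert coefficient_of_error(t) == pytest.approx(
            np.sqrt(16 + 32 / 12) / 16)
        assert coefficient_of_error(t) == pytest.approx(0.2700, abs=5e-5)

    def test_single_box(self):
        t = IntersectionTally(np.array([25]), 1)
        assert coefficient_of_error(t) == pytest.approx(
            np.sqrt(25 + 3 * 625 / 12) / 25)

    def test_zero_counts_raise(self):
        with pytest.raises(ValueError, match="undefined"):
            coefficient_of_error(IntersectionTally(np.array([0, 0]), 2))


@pytest.fixture(scope="module")
def fiber():
    return fiber_slab(10_000.0, 50.0, seed=4)


class TestEstimatorBehaviour:
    """Cheap Monte-Carlo sanity checks (the tight ones live in the acceptance suite)."""

    def test_counting_through_frames_runs_and_is_reproducible(self, fiber):
        probe = ProbeSpec("planes", spacing=5.0)
        a = replicate_estimates(fiber, probe, step=75.0, n_frames=5, seed=1)
        b = replicate_estimates(fiber, probe, step=75.0, n_frames=5, seed=1)
        assert np.array_equal(a["estimate"], b["estimate"])
        assert (a["total_q"] > 0).all()

    def test_estimate_variance_shrinks_with_denser_sampling(self, fiber):
        probe = ProbeSpec("planes", spacing=5.0)
        dense = replicate_estimates(fiber, probe, step=75.0, n_frames=60, seed=2)
        sparse = replicate_estimates(fiber, probe, step=150.0, n_frames=60, seed=3)
        assert dense["estimate"].var() < sparse["estimate"].var()
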