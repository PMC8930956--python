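import dataclasses

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dmwear.cohort import GaitCycle, synthesize_gait
from dmwear.contact import solve_contact
from dmwear.implants import UHMWPE, build_bearing_mesh, cup_orientation_transform, make_implant_spec
from dmwear.kinematics import (
    LinerState,
    PartitionParams,
    head_orientations,
    head_rotation_increments,
    initial_liner_state,
    mean_orientation,
    partition_motion,
    sliding_field,
)


def make_cycle(flex, abd=None, rot=None, n=None):
    n = n or len(flex)
    zeros = np.zeros(n)
    jrf = np.tile([0.0, 800.0, -300.0], (n, 1))
    return GaitCycle(
        t=np.linspace(0, 1, n),
        flexion_extension=np.asarray(flex, float),
        abduction_adduction=zeros if abd is None else np.asarray(abd, float),
        internal_external_rotation=zeros if rot is None else np.asarray(rot, float),
        jrf=jrf,
    )


class TestHeadRotationIncrements:
    def test_constant_angles_zero_increments(self):
        cyc = make_cycle(np.full(32, 17.0))
        inc = head_rotation_increments(cyc, cup_orientation_transform(40, 15))
        np.testing.assert_allclose(inc, 0.0, atol=1e-14)

    def test_flexion_triangle_single_axis_additivity(self):
        # 0 -> 40 deg -> 0: increments share one axis, magnitudes sum to 80 deg
        n = 41
        up = np.linspace(0, 40, n // 2 + 1)
        flex = np.concatenate([up, up[-2::-1]])
        cyc = make_cycle(flex)
        cup = cup_orientation_transform(40, 15)
        inc = head_rotation_increments(cyc, cup)
        mags = np.linalg.norm(inc, axis=1)
        assert mags.sum() == pytest.approx(np.radians(80.0), rel=1e-9)
        axes = inc[mags > 1e-12] / mags[mags > 1e-12, None]
        ref = axes[0]
        assert np.abs(np.abs(axes @ ref) - 1).max() < 1e-9

    def test_path_length_matches_refined_grid(self, patient, gait_params):
        coarse = synthesize_gait(patient, gait_params, n_samples=101, seed=3)
        fine = synthesize_gait(patient, gait_params, n_samples=1001, seed=3)
        cup = cup_orientation_transform(40, 15)
        path_c = np.linalg.norm(head_rotation_increments(coarse, cup), axis=1).sum()
        path_f = np.linalg.norm(head_rotation_increments(fine, cup), axis=1).sum()
        assert path_c == pytest.approx(path_f, rel=1e-3)

    def test_closed_cycle_increments_nearly_cancel(self, gait):
        cup = cup_orientation_transform(40, 15)
        inc = head_rotation_increments(gait, cup)
        path = np.linalg.norm(inc, axis=1).sum()
        # net rotation over a closed loop is second-order small vs path length
        assert np.linalg.norm(inc.sum(axis=0)) < 0.05 * path

    def test_nan_angles_rejected(self):
        flex = np.zeros(32)
        flex[5] = np.nan
        flex[-1] = flex[0]
        cyc = make_cycle(flex)
        with pytest.raises(ValueError):
            head_rotation_increments(cyc, cup_orientation_transform(40, 15))

    def test_non_periodic_warns(self):
        cyc = make_cycle(np.zeros(32))
        cyc.flexion_extension[:] = np.linspace(0, 30, 32)  # open the loop
        with pytest.warns(UserWarning, match="not periodic"):
            head_rotation_increments(cyc, cup_orientation_transform(40, 15))


@pytest.fixture(scope="module")
def contact_states():
    """Converged small/large contact states for a 1200 N axial-ish load."""
    spec = make_implant_spec("DM22PE")
    load = np.array([100.0, -80.0, 1200.0])
    small_mesh = build_bearing_mesh(spec.small_seat_radius, 1.5, "small")
    large_mesh = build_bearing_mesh(spec.liner_outer_radius, 1.5, "large")
    small = solve_contact(
        small_mesh, UHMWPE, spec.liner_thickness_small,
        spec.small_articulation_radial_clearance, load,
    )
    large = solve_contact(
        large_mesh, UHMWPE, spec.liner_thickness_small,
        spec.large_articulation_radial_clearance, load,
    )
    return small, large


class TestPartitionMotion:
    def test_conventional_all_small(self, contact_states):
        small, _ = contact_states
        spec = make_implant_spec("SD22PE")
        inc = np.array([0.01, -0.02, 0.005])
        motion, state = partition_motion(
            inc, small, None, spec, PartitionParams()
        )
        np.testing.assert_array_equal(motion.large_rotation, np.zeros(3))
        np.testing.assert_array_equal(motion.small_rotation, inc)
        assert state is None

    def test_dual_mobility_below_threshold_all_small(self, contact_states):
        small, large = contact_states
        spec = make_implant_spec("DM22PE")
        liner = LinerState(Rotation.identity(), Rotation.identity())
        inc = np.array([0.05, 0.0, 0.0])  # ~2.9 deg, below 25 deg threshold
        motion, new = partition_motion(
            inc, small, large, spec, PartitionParams(), liner
        )
        np.testing.assert_allclose(motion.large_rotation, 0.0, atol=1e-15)
        np.testing.assert_allclose(motion.small_rotation, inc, atol=1e-12)
        assert new.excursion == pytest.approx(0.05)

    def test_friction_torque_prefers_smaller_radius(self, contact_states):
        # mu * R * sum(pA): same load integral magnitude, smaller radius wins
        small, large = contact_states
        spec = make_implant_spec("DM22PE")
        mu = PartitionParams().mu
        t_small = mu * spec.small_seat_radius * small.load_integral
        t_large = mu * spec.liner_outer_radius * large.load_integral
        assert t_small < t_large

    def test_threshold_clamp_routes_excess_to_liner(self, contact_states):
        small, large = contact_states
        spec = make_implant_spec("DM22PE")
        params = PartitionParams(theta_lim_deg=25.0)
        start = Rotation.from_rotvec([np.radians(24.0), 0, 0])
        liner = LinerState(head_in_liner=start, liner_in_shell=Rotation.identity())
        inc = np.array([np.radians(3.0), 0.0, 0.0])
        motion, new = partition_motion(inc, small, large, spec, params, liner)
        # head-liner excursion is clamped at the engagement threshold
        assert new.excursion == pytest.approx(params.theta_lim)
        assert np.linalg.norm(motion.large_rotation) == pytest.approx(
            np.radians(2.0), rel=1e-9
        )

    def test_partition_composes_exactly(self, contact_states):
        small, large = contact_states
        spec = make_implant_spec("DM22PE")
        params = PartitionParams(theta_lim_deg=25.0)
        rng = np.random.default_rng(11)
        liner = LinerState(
            Rotation.from_rotvec([np.radians(20.0), 0.05, 0.0]),
            Rotation.from_rotvec([0.01, 0.0, 0.02]),
        )
        for _ in range(20):
            inc = rng.normal(0, 0.05, 3)
            before = liner.liner_in_shell * liner.head_in_liner
            motion, liner = partition_motion(inc, small, large, spec, params, liner)
            after = liner.liner_in_shell * liner.head_in_liner
            expected = Rotation.from_rotvec(inc) * before
            assert (expected.inv() * after).magnitude() < 1e-12

    def test_missing_state_rejected(self, contact_states):
        small, large = contact_states
        spec = make_implant_spec("DM22PE")
        with pytest.raises(ValueError):
            partition_motion(np.zeros(3), None, large, spec, PartitionParams())
        with pytest.raises(ValueError):
            partition_motion(np.zeros(3), small, None, spec, PartitionParams(), None)


class TestSlidingField:
    def test_equator_arc_length(self):
        mesh = build_bearing_mesh(11.1, 0.75)
        ds = sliding_field(mesh, [0, 0, 0.01])
        equator = np.abs(mesh.node_directions[:, 2]) < 0.02
        assert equator.any()
        np.testing.assert_allclose(ds[equator], 0.111, rtol=2e-4)

    def test_on_axis_node_zero(self):
        # a node on the instantaneous rotation axis does not slide
        mesh = build_bearing_mesh(11.1, 0.75)
        j = np.argmax(mesh.node_directions[:, 2])
        ds = sliding_field(mesh, 0.01 * mesh.node_directions[j])
        assert ds[j] == pytest.approx(0.0, abs=1e-15)

    def test_half_step_composition_first_order(self, rng):
        mesh = build_bearing_mesh(11.1, 1.5)
        rv = rng.normal(0, 0.02, 3)
        full = sliding_field(mesh, rv)
        halves = 2 * sliding_field(mesh, rv / 2)
        np.testing.assert_allclose(halves, full, rtol=5e-3, atol=1e-12)


class TestLinerInit:
    def test_mean_orientation_centering(self, gait):
        cup = cup_orientation_transform(40, 15)
        orients = head_orientations(gait, cup)
        mean = mean_orientation(orients)
        state = initial_liner_state(orients[0], mean)
        # head starts within the engagement threshold of the settled liner
        assert state.excursion < np.radians(25.0)
        composed = state.liner_in_shell * state.head_in_liner
        assert (composed.inv() * orients[0]).magnitude() < 1e-12
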