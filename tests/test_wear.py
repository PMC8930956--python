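import dataclasses

import numpy as np
import pytest

from dmwear.cohort import synthesize_gait
from dmwear.contact import solve_contact
from dmwear.implants import UHMWPE, build_bearing_mesh, cup_orientation_transform, make_implant_spec
from dmwear.kinematics import (
    PartitionParams,
    head_rotation_increments,
    initial_liner_state,
    head_orientations,
    mean_orientation,
    partition_motion,
    sliding_field,
)
from dmwear.wear import (
    SimulationParams,
    WearField,
    archard_increment,
    extrapolate_wear,
    linear_wear,
    simulate_cycle,
    summarize_wear,
    volumetric_wear,
)

K_UHMWPE = 10.656e-7


class TestArchardIncrement:
    def test_reference_coefficient_unit_case(self):
        # 1 MPa over 1 m of sliding removes k_w millimetres of depth
        dh = archard_increment(np.array([1.0]), np.array([1000.0]), K_UHMWPE)
        assert dh[0] == pytest.approx(10.656e-7, rel=1e-12)

    def test_xlpe_is_one_fifth(self):
        dh = archard_increment(np.array([1.0]), np.array([1000.0]), 0.2 * K_UHMWPE)
        assert dh[0] == pytest.approx(2.1312e-7, rel=1e-12)

    def test_zero_factor_zero_wear(self):
        dh = archard_increment(np.array([0.0, 2.0]), np.array([5.0, 0.0]), K_UHMWPE)
        np.testing.assert_array_equal(dh, 0.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            archard_increment(np.array([-1.0]), np.array([1.0]), K_UHMWPE)
        with pytest.raises(ValueError):
            archard_increment(np.array([1.0]), np.array([-1.0]), K_UHMWPE)


def brute_force_cycle_volume(spec, gait, sim_params):
    """Naive per-step, per-node double loop re-deriving the cycle volume."""
    mesh = build_bearing_mesh(spec.small_seat_radius, sim_params.mesh_edge_mm, "small")
    cup = cup_orientation_transform(spec.cup_inclination, spec.cup_anteversion)
    increments = head_rotation_increments(gait, cup)
    loads = cup.inv().apply(gait.jrf)
    k_w = spec.liner_material.wear_coefficient
    total = 0.0
    for i in range(len(increments)):
        state = solve_contact(
            mesh,
            spec.liner_material,
            spec.liner_thickness_small,
            spec.small_articulation_radial_clearance,
            loads[i],
            pressure_cap=sim_params.pressure_cap,
        )
        ds = sliding_field(mesh, increments[i])
        for j in range(mesh.n_nodes):
            total += k_w * state.pressure[j] * (ds[j] / 1000.0) * mesh.node_areas[j]
    return total


class TestSimulateCycle:
    def test_zero_motion_zero_wear(self, patient, gait_params):
        import dataclasses as dc

        from dmwear.cohort import Channel

        frozen_params = dc.replace(
            gait_params,
            flexion=Channel(10.0),
            abduction=Channel(0.0),
            rotation=Channel(0.0),
        )
        gait = synthesize_gait(patient, frozen_params, n_samples=21, seed=0)
        fields = simulate_cycle(
            make_implant_spec("SD22PE"), gait, SimulationParams(mesh_edge_mm=2.0)
        )
        assert volumetric_wear(fields[0]) == 0.0
        assert linear_wear(fields[0]) == 0.0

    def test_matches_brute_force_double_loop(self, patient, gait_params):
        gait = synthesize_gait(patient, gait_params, n_samples=21, seed=4)
        spec = make_implant_spec("SD22PE")
        params = SimulationParams(mesh_edge_mm=2.5)
        fields = simulate_cycle(spec, gait, params)
        v_engine = volumetric_wear(fields[0])
        v_naive = brute_force_cycle_volume(spec, gait, params)
        assert v_engine == pytest.approx(v_naive, rel=1e-10)

    def test_material_k_ratio_dominates_pe_to_xlpe(self, patient, gait_params):
        gait = synthesize_gait(patient, gait_params, n_samples=51, seed=4)
        params = SimulationParams(mesh_edge_mm=1.5)
        v_pe = volumetric_wear(
            simulate_cycle(make_implant_spec("DM22PE"), gait, params)[0]
        )
        v_xl = volumetric_wear(
            simulate_cycle(make_implant_spec("DM22XL"), gait, params)[0]
        )
        assert v_pe / v_xl == pytest.approx(5.0, rel=0.05)

    def test_wear_linear_in_coefficient(self, patient, gait_params):
        gait = synthesize_gait(patient, gait_params, n_samples=21, seed=4)
        params = SimulationParams(mesh_edge_mm=2.0)
        base = make_implant_spec("SD22PE")
        mat3 = dataclasses.replace(
            UHMWPE, wear_coefficient=3.0 * UHMWPE.wear_coefficient
        )
        spec3 = dataclasses.replace(base, liner_material=mat3)
        f1 = simulate_cycle(base, gait, params)[0]
        f3 = simulate_cycle(spec3, gait, params)[0]
        np.testing.assert_allclose(f3.depth, 3.0 * f1.depth, rtol=1e-12)

    def test_dual_mobility_yields_two_fields(self, patient, gait_params, coarse_params):
        gait = synthesize_gait(patient, gait_params, n_samples=51, seed=4)
        fields = simulate_cycle(make_implant_spec("DM22PE"), gait, coarse_params)
        assert [f.articulation_tag for f in fields] == ["small", "large"]
        summary = summarize_wear(fields, "P", "DM22PE")
        assert summary.volumetric_wear == pytest.approx(
            summary.volumetric_small + summary.volumetric_large
        )
        # motion and wear predominate at the small articulation
        assert summary.volumetric_small > 0.95 * summary.volumetric_wear

    def test_head_size_ordering(self, patient, gait_params, coarse_params):
        gait = synthesize_gait(patient, gait_params, n_samples=51, seed=4)
        s22 = summarize_wear(
            simulate_cycle(make_implant_spec("SD22PE"), gait, coarse_params), "P", "SD22PE"
        )
        s32 = summarize_wear(
            simulate_cycle(make_implant_spec("SD32PE"), gait, coarse_params), "P", "SD32PE"
        )
        assert s32.volumetric_wear > s22.volumetric_wear
        assert s32.linear_wear < s22.linear_wear


@pytest.fixture(scope="module")
def cycle_field(patient, gait_params):
    gait = synthesize_gait(patient, gait_params, n_samples=21, seed=4)
    return simulate_cycle(
        make_implant_spec("SD22PE"), gait, SimulationParams(mesh_edge_mm=2.0)
    )[0]


class TestExtrapolateWear:
    def test_identity_at_one(self, cycle_field):
        out = extrapolate_wear(cycle_field, 1)
        np.testing.assert_array_equal(out.depth, cycle_field.depth)

    def test_million_cycles_exact_scaling(self, cycle_field):
        out = extrapolate_wear(cycle_field, 1e6)
        np.testing.assert_array_equal(out.depth, cycle_field.depth * 1e6)
        assert out.cycles_represented == 1e6

    def test_additivity_in_cycles(self, cycle_field):
        a = extrapolate_wear(cycle_field, 300.0)
        b = extrapolate_wear(cycle_field, 700.0)
        c = extrapolate_wear(cycle_field, 1000.0)
        np.testing.assert_allclose(a.depth + b.depth, c.depth, rtol=1e-12)

    def test_invalid_cycles_rejected(self, cycle_field):
        with pytest.raises(ValueError):
            extrapolate_wear(cycle_field, 0)


class TestWearReductions:
    def test_uniform_depth_analytic_volume(self):
        mesh = build_bearing_mesh(11.1, 0.75)
        field = WearField(mesh, np.full(mesh.n_nodes, 0.01), "small")
        assert volumetric_wear(field) == pytest.approx(7.741, rel=0.01)
        assert linear_wear(field) == pytest.approx(0.01)

    def test_zero_field(self):
        mesh = build_bearing_mesh(11.1, 2.0)
        field = WearField(mesh, np.zeros(mesh.n_nodes), "small")
        assert volumetric_wear(field) == 0.0
        assert linear_wear(field) == 0.0

    def test_single_node_linear_wear(self):
        mesh = build_bearing_mesh(11.1, 2.0)
        depth = np.zeros(mesh.n_nodes)
        depth[17] = 0.042
        field = WearField(mesh, depth, "small")
        assert linear_wear(field) == pytest.approx(0.042)

    def test_smooth_field_quadrature_vs_refined_mesh(self):
        # same smooth analytic depth field integrated on two resolutions
        def depth_fn(dirs):
            return 1e-3 * (1.0 + dirs[:, 2]) ** 2

        coarse = build_bearing_mesh(11.1, 1.5)
        fine = build_bearing_mesh(11.1, 0.4)
        v_coarse = volumetric_wear(
            WearField(coarse, depth_fn(coarse.node_directions), "small")
        )
        v_fine = volumetric_wear(
            WearField(fine, depth_fn(fine.node_directions), "small")
        )
        assert v_coarse == pytest.approx(v_fine, rel=0.01)

    def test_negative_depth_rejected(self):
        mesh = build_bearing_mesh(11.1, 2.0)
        with pytest.raises(ValueError):
            WearField(mesh, np.full(mesh.n_nodes, -1e-6), "small")
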