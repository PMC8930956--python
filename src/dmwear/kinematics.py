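"""Joint-angle kinematics, dual-mobility motion partition and sliding fields.

Joint angles are converted to head orientations with the intrinsic Euler
sequence flexion (about the pelvis mediolateral axis z) -> abduction (about
the anterior axis x) -> internal rotation (about the superior axis y),
then expressed in the cup frame.  Per-step rotation increments of the head
relative to the shell drive sliding.

For a dual-mobility cup the increment is split between the small (head vs
liner inner surface) and large (liner outer surface vs shell) articulations
by a quasi-static friction-torque rule: the articulation with the lower
resisting torque ``T ~ mu * R_eff * sum(p A)`` moves — in practice the small
one, whose effective radius is smaller at near-equal load integrals.  The
third articulation (femoral neck on the liner chamfer, geometrically absent
here) is a rotation-threshold surrogate: once the head-liner excursion
exceeds ``theta_lim`` the excess rotation is transferred to the liner, i.e.
to the large articulation.  The split composes exactly: liner-relative
rotations recombine to the full head-relative-to-shell increment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .cohort import GaitCycle
from .contact import ContactState
from .implants import ImplantSpec, SurfaceMesh

__all__ = [
    "PartitionParams",
    "LinerState",
    "MotionIncrement",
    "head_orientations",
    "head_rotation_increments",
    "partition_motion",
    "sliding_field",
    "mean_orientation",
]


@dataclass(frozen=True)
class PartitionParams:
    theta_lim_deg: float = 25.0  # third-articulation engagement threshold
    mu: float = 0.01  # friction coefficient, all metal-PE interfaces

    @property
    def theta_lim(self) -> float:
        return np.radians(self.theta_lim_deg)


@dataclass(frozen=True)
class LinerState:
    """Orientation state of the mobile liner.

    ``head_in_liner`` is the head orientation relative to the liner,
    ``liner_in_shell`` the liner orientation relative to the shell (cup
    frame); their composition is the head orientation in the cup frame.
    """

    head_in_liner: Rotation
    liner_in_shell: Rotation

    @property
    def excursion(self) -> float:
        """Head-liner angle in radians (third-articulation engagement metric)."""
        return float(np.linalg.norm(self.head_in_liner.as_rotvec()))


@dataclass(frozen=True)
class MotionIncrement:
    """One time step's rotation split between the two articulations.

    Rotation vectors are space-frame (cup frame) increments in radians;
    conventional cups always carry a zero large-articulation component.
    """

    step_index: int
    small_rotation: np.ndarray  # (3,) rad
    large_rotation: np.ndarray  # (3,) rad
    liner_orientation: Rotation


def head_orientations(gait_cycle: GaitCycle, cup_transform: Rotation) -> Rotation:
    """Head orientation at every sample, expressed in the cup frame.

    Intrinsic Euler sequence z (flexion) -> x (abduction) -> y (rotation) in
    the pelvis frame, conjugated into the cup frame by ``cup_transform``
    (the cup-to-pelvis rotation from :func:`cup_orientation_transform`).
    """
    angles = gait_cycle.angles
    if not np.isfinite(angles).all():
        raise ValueError("joint angles contain NaN or inf")
    r_pelvis = Rotation.from_euler("ZXY", angles, degrees=True)
    return cup_transform.inv() * r_pelvis * cup_transform


def head_rotation_increments(
    gait_cycle: GaitCycle, cup_transform: Rotation
) -> np.ndarray:
    """Space-frame rotation vectors (rad, cup frame) for each time step.

    Step ``i`` rotates the head from sample ``i`` to ``i + 1``; a closed
    (periodic) cycle makes the increments sum to ~0.  A non-periodic cycle
    triggers a warning, not an error.
    """
    if gait_cycle.n_samples < 2:
        raise ValueError("need at least two samples")
    if np.abs(gait_cycle.angles[0] - gait_cycle.angles[-1]).max() > 1e-6:
        warnings.warn("gait cycle is not periodic; increments will not close")
    r = head_orientations(gait_cycle, cup_transform)
    # space-frame increment: R(t+1) = dR * R(t)
    return (r[1:] * r[:-1].inv()).as_rotvec()


def mean_orientation(rotations: Rotation) -> Rotation:
    """Rotation-vector mean; adequate for the modest excursions of gait."""
    return Rotation.from_rotvec(rotations.as_rotvec().mean(axis=0))


def initial_liner_state(
    head_orientation_t0: Rotation,
    head_orientation_mean: Rotation | None = None,
) -> LinerState:
    """Liner state at cycle start.

    By default the liner rests at the cycle-mean head orientation — the
    settled state of the threshold engagement rule, toward which any start
    drifts — so ``head_in_liner`` begins as the head's offset from that mean.
    Passing ``head_orientation_mean=None`` is not allowed here; use
    ``Rotation.identity()`` for a shell-aligned start.
    """
    liner = (
        head_orientation_mean
        if head_orientation_mean is not None
        else Rotation.identity()
    )
    return LinerState(
        head_in_liner=liner.inv() * head_orientation_t0, liner_in_shell=liner
    )


def partition_motion(
    total_increment: np.ndarray,
    small_state: ContactState | None,
    large_state: ContactState | None,
    spec: ImplantSpec,
    partition_params: PartitionParams,
    liner_state: LinerState | None = None,
    step_index: int = 0,
) -> tuple[MotionIncrement, LinerState | None]:
    """Split one head-relative-to-shell increment between the articulations.

    Conventional cups route everything to the single (small) articulation.
    Dual-mobility cups move the lower-friction-torque articulation and apply
    the ``theta_lim`` excursion clamp; the returned liner state carries the
    updated orientations.  Rotations compose exactly:
    ``liner_in_shell' * head_in_liner' == dR * liner_in_shell * head_in_liner``.
    """
    total_increment = np.asarray(total_increment, dtype=float)
    if small_state is None:
        raise ValueError("small-articulation contact state is required")
    if not spec.is_dual_mobility:
        return (
            MotionIncrement(
                step_index=step_index,
                small_rotation=total_increment,
                large_rotation=np.zeros(3),
                liner_orientation=Rotation.identity(),
            ),
            None,
        )
    if large_state is None or liner_state is None:
        raise ValueError("dual mobility needs a large-articulation state and liner state")

    dR = Rotation.from_rotvec(total_increment)
    q_ls, q_hl = liner_state.liner_in_shell, liner_state.head_in_liner
    mu = partition_params.mu
    t_small = mu * spec.small_seat_radius * small_state.load_integral
    t_large = mu * spec.liner_outer_radius * large_state.load_integral

    if t_large < t_small:
        # large articulation is easier to move: liner rotates with the head
        q_ls_new, q_hl_new = dR * q_ls, q_hl
    else:
        # motion at the small articulation, then the excursion clamp
        q_hl_tent = q_ls.inv() * dR * q_ls * q_hl
        rv = q_hl_tent.as_rotvec()
        phi = float(np.linalg.norm(rv))
        if phi > partition_params.theta_lim:
            q_hl_new = Rotation.from_rotvec(rv * (partition_params.theta_lim / phi))
            q_ls_new = q_ls * q_hl_tent * q_hl_new.inv()
        else:
            q_hl_new, q_ls_new = q_hl_tent, q_ls

    # space-frame (cup frame) increments seen by each articulation
    large_rot = (q_ls_new * q_ls.inv()).as_rotvec()
    small_rot = (q_ls_new * (q_hl_new * q_hl.inv()) * q_ls_new.inv()).as_rotvec()
    new_state = LinerState(head_in_liner=q_hl_new, liner_in_shell=q_ls_new)
    return (
        MotionIncrement(
            step_index=step_index,
            small_rotation=small_rot,
            large_rotation=large_rot,
            liner_orientation=q_ls_new,
        ),
        new_state,
    )


def sliding_field(mesh: SurfaceMesh, rotation_vector: np.ndarray) -> np.ndarray:
    """Per-node sliding increment ``|omega x r|`` (mm) for one rotation step."""
    if mesh.radius <= 0:
        raise ValueError("mesh radius must be positive")
    rotation_vector = np.asarray(rotation_vector, dtype=float)
    return np.linalg.norm(
        np.cross(rotation_vector[None, :], mesh.node_positions), axis=1
    )
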