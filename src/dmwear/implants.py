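"""Implant constructs, bearing-surface meshes and cup orientation.

Five acetabular constructs with a 52-mm external shell are modelled:

========  ===========  ========  =============
config    head (mm)    liner     dual mobility
========  ===========  ========  =============
DM22PE    22.2         UHMWPE    yes
SD22PE    22.2         UHMWPE    no
SD32PE    32.0         UHMWPE    no
SD32XL    32.0         XLPE      no
DM22XL    22.2         XLPE      yes
========  ===========  ========  =============

A dual-mobility (DM) cup interposes a mobile polyethylene liner between the
femoral head (small articulation, concave inner surface) and the fixed metal
shell (large articulation, convex outer surface).  Conventional cups (SD)
constrain the liner as an insert, leaving a single head-liner articulation.

Bearing surfaces are discretized as quasi-uniform triangulated hemispheres
with per-node Voronoi-like areas (one third of incident triangle areas);
the wear model only ever consumes surface pressure and sliding, so no solid
mesh is carried.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial import Delaunay
from scipy.spatial.transform import Rotation

__all__ = [
    "MaterialModel",
    "ImplantSpec",
    "SurfaceMesh",
    "UHMWPE",
    "XLPE",
    "COCR_RIGID",
    "CONFIG_IDS",
    "make_implant_spec",
    "build_bearing_mesh",
    "cup_orientation_transform",
    "mesh_convergence_report",
]

# UHMWPE reference wear coefficient, mm^3 N^-1 m^-1
K_W_UHMWPE = 10.656e-7


@dataclass(frozen=True)
class MaterialModel:
    """Bearing material: elastic constants, yield cap and Archard coefficient.

    ``elastic_modulus`` in MPa, ``yield_stress`` in MPa, ``wear_coefficient``
    in mm^3 N^-1 m^-1.  Rigid metals carry ``None`` for the polyethylene-only
    fields.  ``friction_coefficient`` (0.01 for all metal-PE interfaces) is
    used only by the dual-mobility motion-partition torque rule.
    """

    name: str
    elastic_modulus: float | None
    poisson_ratio: float | None
    yield_stress: float | None
    wear_coefficient: float | None
    friction_coefficient: float = 0.01

    @property
    def is_rigid(self) -> bool:
        return self.elastic_modulus is None


UHMWPE = MaterialModel("UHMWPE", 500.0, 0.45, 16.0, K_W_UHMWPE)
XLPE = MaterialModel("XLPE", 1000.0, 0.45, 20.0, 0.2 * K_W_UHMWPE)
COCR_RIGID = MaterialModel("CoCr-rigid", None, None, None, None)


@dataclass(frozen=True)
class ImplantSpec:
    """One acetabular construct: geometry, liner material, cup orientation.

    All lengths in mm, angles in degrees.  ``small_articulation_radial_clearance``
    is the radial gap between femoral head and liner inner surface;
    ``large_articulation_radial_clearance`` (dual mobility only) between liner
    outer surface and shell seat.
    """

    config_id: str
    head_diameter: float
    shell_external_diameter: float
    liner_material: MaterialModel
    is_dual_mobility: bool
    small_articulation_radial_clearance: float
    large_articulation_radial_clearance: float | None
    liner_thickness_small: float
    liner_outer_diameter: float | None
    cup_inclination: float = 40.0
    cup_anteversion: float = 15.0

    def __post_init__(self) -> None:
        if self.small_articulation_radial_clearance <= 0:
            raise ValueError("small-articulation clearance must be > 0")
        if self.is_dual_mobility:
            if self.large_articulation_radial_clearance is None:
                raise ValueError("dual-mobility spec needs a large-articulation clearance")
            if self.large_articulation_radial_clearance <= 0:
                raise ValueError("large-articulation clearance must be > 0")
            if not (
                self.head_diameter
                < self.liner_outer_diameter
                < self.shell_external_diameter
            ):
                raise ValueError("need head OD < liner OD < shell OD")

    @property
    def head_radius(self) -> float:
        return 0.5 * self.head_diameter

    @property
    def small_seat_radius(self) -> float:
        """Radius of the liner's concave inner bearing surface."""
        return self.head_radius + self.small_articulation_radial_clearance

    @property
    def liner_outer_radius(self) -> float | None:
        if self.liner_outer_diameter is None:
            return None
        return 0.5 * self.liner_outer_diameter


# Shell wall 3 mm -> seat (internal) diameter 46 mm for a 52 mm shell.
_SHELL_WALL = 3.0
_SHELL_OD = 52.0
_SHELL_ID = _SHELL_OD - 2.0 * _SHELL_WALL

# Radial clearances by head size: larger metal-on-PE heads are machined more
# conformally (0.1 mm diametral) than 22.2 mm heads (0.3 mm diametral).
_CLEARANCE_SMALL = {22.2: 0.05, 32.0: 0.025}
_CLEARANCE_LARGE = 0.05

_PRESETS: dict[str, tuple[float, MaterialModel, bool]] = {
    "DM22PE": (22.2, UHMWPE, True),
    "SD22PE": (22.2, UHMWPE, False),
    "SD32PE": (32.0, UHMWPE, False),
    "SD32XL": (32.0, XLPE, False),
    "DM22XL": (22.2, XLPE, True),
}
CONFIG_IDS: tuple[str, ...] = tuple(_PRESETS)


def make_implant_spec(config_id: str, **overrides) -> ImplantSpec:
    """Return one of the five preset constructs, optionally overriding fields.

    Parameters
    ----------
    config_id:
        One of ``DM22PE, SD22PE, SD32PE, SD32XL, DM22XL``.
    **overrides:
        Any :class:`ImplantSpec` field, e.g. ``small_articulation_radial_clearance``.
    """
    if config_id not in _PRESETS:
        raise ValueError(
            f"unknown construct {config_id!r}; valid ids: {', '.join(_PRESETS)}"
        )
    head_d, material, is_dm = _PRESETS[config_id]
    if is_dm:
        liner_od = _SHELL_ID  # mobile liner fills the shell seat
        thickness = 0.5 * (liner_od - head_d)
        large_clearance = _CLEARANCE_LARGE
    else:
        liner_od = None
        thickness = 0.5 * (_SHELL_ID - head_d)
        large_clearance = None
    spec = ImplantSpec(
        config_id=config_id,
        head_diameter=head_d,
        shell_external_diameter=_SHELL_OD,
        liner_material=material,
        is_dual_mobility=is_dm,
        small_articulation_radial_clearance=_CLEARANCE_SMALL[head_d],
        large_articulation_radial_clearance=large_clearance,
        liner_thickness_small=thickness,
        liner_outer_diameter=liner_od,
    )
    if overrides:
        spec = replace(spec, **overrides)
    return spec


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated bearing hemisphere in the cup frame.

    ``node_directions`` are unit vectors; the hemisphere pole (+z of the cup
    frame) is the cup axis.  ``node_areas`` assign each node one third of its
    incident triangle areas, so they sum to the hemisphere area.
    """

    node_directions: np.ndarray  # (n, 3) unit vectors
    radius: float  # mm
    node_areas: np.ndarray  # (n,) mm^2
    triangles: np.ndarray  # (m, 3) int
    articulation_tag: str  # "small" | "large"

    @property
    def n_nodes(self) -> int:
        return len(self.node_directions)

    @property
    def node_positions(self) -> np.ndarray:
        return self.radius * self.node_directions

    @property
    def mean_edge_length(self) -> float:
        p = self.node_positions
        t = self.triangles
        e = np.concatenate(
            [
                np.linalg.norm(p[t[:, 0]] - p[t[:, 1]], axis=1),
                np.linalg.norm(p[t[:, 1]] - p[t[:, 2]], axis=1),
                np.linalg.norm(p[t[:, 2]] - p[t[:, 0]], axis=1),
            ]
        )
        return float(e.mean())


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Quasi-uniform unit directions on the z >= 0 hemisphere (pole included)."""
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    i = np.arange(n)
    z = 1.0 - (i + 0.5) / n  # z from ~1 (pole) down to ~0 (rim)
    phi = 2.0 * np.pi * i / golden
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    # mean point spacing s on the unit hemisphere for n cells of 2*pi/n each
    s = np.sqrt(4.0 * np.pi / (np.sqrt(3.0) * n))
    # drop interior points crowding the equator, then close it with a rim ring
    pts = pts[np.arcsin(np.clip(z, 0, 1)) > 0.5 * s]
    n_rim = max(6, int(round(2.0 * np.pi / s)))
    ang = 2.0 * np.pi * np.arange(n_rim) / n_rim
    rim = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(n_rim)])
    return np.vstack([pts, rim])


def build_bearing_mesh(
    radius: float, target_edge_length: float = 0.75, articulation_tag: str = "small"
) -> SurfaceMesh:
    """Triangulate a bearing hemisphere of ``radius`` mm.

    Nodes are a Fibonacci point set plus a closed equatorial rim, connected by
    a Delaunay triangulation in the Lambert azimuthal equal-area projection
    (a homeomorphism of the hemisphere onto a disk, so the planar
    triangulation is a valid surface triangulation).  Mean edge length lands
    within ~20% of ``target_edge_length``; node areas sum to 2*pi*R^2 within 1%
    at the default 0.75 mm resolution.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not (0.1 < target_edge_length < 5.0):
        raise ValueError("target_edge_length must lie in (0.1, 5) mm")
    if articulation_tag not in ("small", "large"):
        raise ValueError("articulation_tag must be 'small' or 'large'")

    # node count so that mean area per node ~ equilateral-triangle lattice cell
    cell = (np.sqrt(3.0) / 2.0) * target_edge_length**2
    n = max(32, int(round(2.0 * np.pi * radius**2 / cell)))
    dirs = _fibonacci_hemisphere(n)

    # Lambert equal-area projection about the pole: rho = 2 sin(theta/2)
    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))
    rho = 2.0 * np.sin(theta / 2.0)
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])
    planar = np.column_stack([rho * np.cos(phi), rho * np.sin(phi)])
    tri = Delaunay(planar).simplices

    pos = radius * dirs
    v1 = pos[tri[:, 1]] - pos[tri[:, 0]]
    v2 = pos[tri[:, 2]] - pos[tri[:, 0]]
    cross = np.cross(v1, v2)
    tri_area = 0.5 * np.linalg.norm(cross, axis=1)
    keep = tri_area > 1e-12 * radius**2
    tri, tri_area = tri[keep], tri_area[keep]

    areas = np.zeros(len(dirs))
    for k in range(3):
        np.add.at(areas, tri[:, k], tri_area / 3.0)

    return SurfaceMesh(
        node_directions=dirs,
        radius=float(radius),
        node_areas=areas,
        triangles=tri,
        articulation_tag=articulation_tag,
    )


def cup_orientation_transform(
    inclination_deg: float, anteversion_deg: float
) -> Rotation:
    """Rotation mapping cup-frame vectors into the pelvis frame.

    Pelvis frame (right hip): x anterior, y superior, z lateral, right-handed.
    The cup frame's +z is the cup pole axis (pointing from the cup opening
    into the bone).  At (0, 0) the pole is the pelvis superior axis (+y).
    Radiographic convention: inclination tilts the pole in the frontal plane
    about the anterior axis (opening turns lateral), then anteversion rotates
    about the superior axis (opening turns anterior).
    """
    for a in (inclination_deg, anteversion_deg):
        if not (0 <= a < 90):
            raise ValueError("cup angles must lie in [0, 90)")
    base = Rotation.from_euler("x", -90, degrees=True)  # cup +z -> pelvis +y
    incl = Rotation.from_euler("x", -inclination_deg, degrees=True)
    antev = Rotation.from_euler("y", anteversion_deg, degrees=True)
    return antev * incl * base


def mesh_convergence_report(
    spec: ImplantSpec,
    edge_lengths: Sequence[float],
    reference_gait,
    tolerance: float = 0.015,
    sim_params=None,
):
    """Volumetric wear of ``spec`` vs mesh refinement.

    Runs the single-cycle wear pipeline on ``reference_gait`` at each edge
    length (must be strictly decreasing) and reports the relative change of
    per-cycle volumetric wear between successive refinements.  Returns a
    pandas DataFrame with columns ``edge_length_mm, volumetric_wear_mm3,
    rel_change, converged``; ``converged`` flags levels whose change from the
    next finer level is below ``tolerance``.
    """
    import pandas as pd

    from .wear import SimulationParams, simulate_cycle, volumetric_wear

    edges = list(edge_lengths)
    if len(edges) < 2:
        raise ValueError("need at least two refinement levels")
    if any(b >= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edge lengths must be strictly decreasing")

    if sim_params is None:
        sim_params = SimulationParams()
    vols = []
    for h in edges:
        params = replace(sim_params, mesh_edge_mm=h)
        fields = simulate_cycle(spec, reference_gait, params)
        vols.append(sum(volumetric_wear(f) for f in fields))
    vols_arr = np.asarray(vols)
    rel = np.full(len(edges), np.nan)
    rel[1:] = np.abs(np.diff(vols_arr)) / np.abs(vols_arr[1:])
    converged = np.zeros(len(edges), dtype=bool)
    converged[1:] = rel[1:] < tolerance
    return pd.DataFrame(
        {
            "edge_length_mm": edges,
            "volumetric_wear_mm3": vols_arr,
            "rel_change": rel,
            "converged": converged,
        }
    )
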