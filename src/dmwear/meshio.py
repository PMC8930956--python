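"""Minimal ASCII mesh export with a per-vertex scalar (wear depth).

Two viewer-friendly formats: legacy VTK PolyData (POINT_DATA scalar) and PLY
with an extra ``wear`` vertex property.  Writers and matching readers are
deliberately tiny — just enough for wear-map export and lossless (1e-9)
round-tripping in tests; they are not general-purpose parsers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_vtk_polydata", "read_vtk_polydata", "write_ply", "read_ply"]

_FMT = "%.12g"


def write_vtk_polydata(
    path: str | Path,
    points: np.ndarray,
    triangles: np.ndarray,
    scalar: np.ndarray,
    scalar_name: str = "wear_depth_mm",
) -> None:
    points = np.asarray(points, float)
    triangles = np.asarray(triangles, int)
    scalar = np.asarray(scalar, float)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nbearing surface wear map\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} double\n")
        for p in points:
            fh.write(" ".join(_FMT % v for v in p) + "\n")
        fh.write(f"POLYGONS {len(triangles)} {4 * len(triangles)}\n")
        for t in triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        fh.write(f"POINT_DATA {len(points)}\n")
        fh.write(f"SCALARS {scalar_name} double 1\nLOOKUP_TABLE default\n")
        for v in scalar:
            fh.write(_FMT % v + "\n")


def read_vtk_polydata(path: str | Path):
    """Read back a file written by :func:`write_vtk_polydata`."""
    lines = Path(path).read_text().splitlines()
    i = lines.index("DATASET POLYDATA") + 1
    n_pts = int(lines[i].split()[1])
    points = np.array([[float(x) for x in lines[i + 1 + k].split()] for k in range(n_pts)])
    i += 1 + n_pts
    n_tri = int(lines[i].split()[1])
    tris = np.array(
        [[int(x) for x in lines[i + 1 + k].split()[1:]] for k in range(n_tri)]
    )
    i += 1 + n_tri
    assert lines[i].startswith("POINT_DATA")
    scalar = np.array([float(lines[i + 3 + k]) for k in range(n_pts)])
    return points, tris, scalar


def write_ply(
    path: str | Path,
    points: np.ndarray,
    triangles: np.ndarray,
    scalar: np.ndarray,
) -> None:
    points = np.asarray(points, float)
    triangles = np.asarray(triangles, int)
    scalar = np.asarray(scalar, float)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(points)}\n")
        for ax in "xyz":
            fh.write(f"property double {ax}\n")
        fh.write("property double wear\n")
        fh.write(f"element face {len(triangles)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for p, w in zip(points, scalar):
            fh.write(" ".join(_FMT % v for v in (*p, w)) + "\n")
        for t in triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def read_ply(path: str | Path):
    """Read back a file written by :func:`write_ply`."""
    lines = Path(path).read_text().splitlines()
    n_vert = n_face = 0
    for i, ln in enumerate(lines):
        if ln.startswith("element vertex"):
            n_vert = int(ln.split()[-1])
        elif ln.startswith("element face"):
            n_face = int(ln.split()[-1])
        elif ln == "end_header":
            body = i + 1
            break
    vert = np.array([[float(x) for x in lines[body + k].split()] for k in range(n_vert)])
    tris = np.array(
        [[int(x) for x in lines[body + n_vert + k].split()[1:]] for k in range(n_face)]
    )
    return vert[:, :3], tris, vert[:, 3]
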