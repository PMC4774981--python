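"""Minimal legacy-ASCII VTK writers for visualization output.

Two writers: vessel networks as polylines with per-segment cell data
(radius, maturity, Strahler order) and lattice scalar fields as
STRUCTURED_POINTS.  Legacy VTK is a plain-text format; files open directly
in ParaView.
"""

from __future__ import annotations

import numpy as np

from .config import LatticeSpec
from .vascular_network import VesselNetwork

_MATURITY_CODE = {"mature": 0, "immature": 1, "collapsed": 2}


def write_network_vtk(net: VesselNetwork, path: str) -> None:
    lat = net.lattice
    points: list[tuple[float, float, float]] = []
    lines: list[list[int]] = []
    radius, maturity, order, is_neo = [], [], [], []
    for seg in net.segments:
        start = len(points)
        for nd in seg.node_path:
            points.append(lat.coords(int(nd)))
        lines.append(list(range(start, start + len(seg.node_path))))
        radius.append(seg.R)
        maturity.append(_MATURITY_CODE[seg.maturity])
        order.append(seg.order)
        is_neo.append(int(seg.is_neo))
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ngliosim vessel network\n"
                 "ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} float\n")
        for p in points:
            fh.write(f"{p[0]:.3f} {p[1]:.3f} {p[2]:.3f}\n")
        size = sum(len(l) + 1 for l in lines)
        fh.write(f"LINES {len(lines)} {size}\n")
        for l in lines:
            fh.write(" ".join(map(str, [len(l)] + l)) + "\n")
        fh.write(f"CELL_DATA {len(lines)}\n")
        for name, vals, typ in (("radius", radius, "float"),
                                ("maturity", maturity, "int"),
                                ("strahler_order", order, "int"),
                                ("is_neo", is_neo, "int")):
            fh.write(f"SCALARS {name} {typ} 1\nLOOKUP_TABLE default\n")
            for v in vals:
                fh.write(f"{v}\n")


def write_field_vtk(field: np.ndarray, lattice: LatticeSpec, path: str,
                    name: str = "field") -> None:
    nx, ny, nz = lattice.shape
    h = lattice.spacing
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ngliosim scalar field\n"
                 "ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {h} {h} {h}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        # VTK structured points vary x fastest
        data = np.asarray(field).reshape(nx, ny, nz).transpose(2, 1, 0).ravel()
        np.savetxt(fh, data, fmt="%.6g")
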