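"""Hexahedral Q2/Q1 meshes for the specimen geometries.

The cylindrical specimen is modelled as a quarter cylinder (two flat symmetry
faces, one curved hull, glued top and bottom).  The quarter disk is meshed
with a butterfly (O-grid) layout: a core square block and two blocks bridging
to the circular arc, extruded along the axis.  With the default resolution
(``n_circum = n_radial = 4``, ``n_axial = 8``) this yields
``4**2 + 2*4*4 = 48`` in-plane cells and 384 hexahedra, the discretisation
used for the r = 4 mm specimens.  Mid-edge nodes on the hull are placed
exactly on the cylinder surface, so the quadratic geometry follows the
curved boundary.

Coordinates are stored in metres; the public interface takes millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from .elements import geometric_factors
from .exceptions import BrainPoroError

MM_TO_M = 1e-3

#: fraction of the radius used for the side length of the core square block
_CORE_FRACTION = 0.45


@dataclass(frozen=True)
class MeshSpec:
    """Geometry and resolution of the quarter-cylinder discretisation.

    ``radius`` and ``height`` in mm; ``n_circum``/``n_radial`` control the
    butterfly block subdivision in-plane, ``n_axial`` the number of element
    layers.  Elements are Q2 (triquadratic displacement) / Q1 (trilinear
    continuous pressure) hexahedra with full 3x3x3 Gauss integration.
    """

    radius: float = 4.0
    height: float = 3.4
    n_circum: int = 4
    n_radial: int = 4
    n_axial: int = 8

    def __post_init__(self):
        if self.radius <= 0 or self.height <= 0:
            raise ValueError("mesh dimensions must be positive")
        if min(self.n_circum, self.n_radial, self.n_axial) < 1:
            raise ValueError("element counts must be >= 1")

    @property
    def n_elements(self) -> int:
        return (self.n_circum ** 2 + 2 * self.n_radial * self.n_circum) * self.n_axial


@dataclass
class Mesh:
    """A Q2/Q1 hexahedral mesh with tagged boundary node sets.

    ``coords`` (m) lists all displacement (Q2) nodes; ``hex27`` their
    element connectivity; ``pnode_unode`` maps each pressure (Q1) node to the
    displacement node it coincides with, and ``hex8`` is the pressure
    connectivity in pressure-node numbering.  ``node_sets``/``pnode_sets``
    hold boundary tags {bottom, top, hull/side tags, symmetry_x, symmetry_y}.
    """

    coords: np.ndarray
    hex27: np.ndarray
    hex8: np.ndarray
    pnode_unode: np.ndarray
    node_sets: Dict[str, np.ndarray]
    pnode_sets: Dict[str, np.ndarray]
    top_faces: np.ndarray            # (nf, 9) u-node ids of top-surface faces
    midheight_hull_nodes: np.ndarray  # u-node ids on the hull ring at z = h/2
    symmetry_factor: float            # full specimen = factor * modelled wedge
    top_area_ref: float               # reference area of the modelled top face (m^2)
    spec: MeshSpec | None = None
    # geometric quadrature data, computed lazily
    _geo: tuple | None = field(default=None, repr=False)

    @property
    def n_unodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_pnodes(self) -> int:
        return self.pnode_unode.shape[0]

    @property
    def n_elements(self) -> int:
        return self.hex27.shape[0]

    def geometry(self):
        """(dNdX_u, dNdX_p, wdetJ) at all quadrature points (cached)."""
        if self._geo is None:
            coords_e = self.coords[self.hex27]
            dNdX_u, dNdX_p, wdetJ, detJ = geometric_factors(coords_e)
            if np.any(detJ <= 0.0):
                raise BrainPoroError("mesh contains non-positive Jacobians")
            self._geo = (dNdX_u, dNdX_p, wdetJ)
        return self._geo

    @property
    def volume(self) -> float:
        """Reference volume of the modelled domain (m^3)."""
        return float(self.geometry()[2].sum())


# ---------------------------------------------------------------------------
# quarter-cylinder butterfly mesh
# ---------------------------------------------------------------------------

def _butterfly_blocks(radius: float, nc: int, nr: int):
    """Fine-grid (half-step) point arrays for the three quarter-disk blocks.

    Returns a list of (nx_fine, ny_fine, xy) arrays, xy of shape
    (nx_fine, ny_fine, 2), where the first index is the "radial" block
    direction and fine steps are half element steps (Q2 nodes).
    """
    a = _CORE_FRACTION * radius
    blocks = []

    # core square: s along x, t along y, nc x nc cells
    s = np.linspace(0.0, 1.0, 2 * nc + 1)
    t = np.linspace(0.0, 1.0, 2 * nc + 1)
    X, Y = np.meshgrid(a * s, a * t, indexing="ij")
    blocks.append(np.stack([X, Y], axis=-1))

    # block B: inner edge x = a (bottom-right of the core), outer arc 0..45 deg
    xi = np.linspace(0.0, 1.0, 2 * nr + 1)[:, None]
    eta = np.linspace(0.0, 1.0, 2 * nc + 1)[None, :]
    inner = np.stack([np.full_like(eta, a), a * eta], axis=-1)
    th = np.deg2rad(45.0) * eta
    outer = np.stack([radius * np.cos(th), radius * np.sin(th)], axis=-1)
    blocks.append((1.0 - xi[..., None]) * inner + xi[..., None] * outer)

    # block C: inner edge y = a (top of the core), outer arc 45..90 deg;
    # eta runs from the diagonal towards the x = 0 plane so that the
    # (xi, eta) frame keeps positive orientation
    inner = np.stack([a * (1.0 - eta), np.full_like(eta, a)], axis=-1)
    th = np.deg2rad(45.0) + np.deg2rad(45.0) * eta
    outer = np.stack([radius * np.cos(th), radius * np.sin(th)], axis=-1)
    blocks.append((1.0 - xi[..., None]) * inner + xi[..., None] * outer)

    return blocks


def build_quarter_cylinder_mesh(spec: MeshSpec) -> Mesh:
    """Butterfly-extruded quarter-cylinder mesh with tagged boundaries.

    Boundary tags: ``bottom`` (z=0), ``top`` (z=h), ``hull`` (curved surface,
    the only drained boundary in the experiments), ``symmetry_x`` (x=0 plane)
    and ``symmetry_y`` (y=0 plane).
    """
    r_m = spec.radius * MM_TO_M
    h_m = spec.height * MM_TO_M
    nc, nr, nz = spec.n_circum, spec.n_radial, spec.n_axial
    blocks = _butterfly_blocks(r_m, nc, nr)

    # merge block fine grids into a global 2D node list
    tol = 1e-9 * r_m
    node_ids: Dict[tuple, int] = {}
    pts2d = []
    block_gid = []
    for xy in blocks:
        gid = np.empty(xy.shape[:2], dtype=int)
        for i in range(xy.shape[0]):
            for j in range(xy.shape[1]):
                key = (round(xy[i, j, 0] / tol), round(xy[i, j, 1] / tol))
                if key not in node_ids:
                    node_ids[key] = len(pts2d)
                    pts2d.append(xy[i, j])
                gid[i, j] = node_ids[key]
        block_gid.append(gid)
    pts2d = np.asarray(pts2d)
    n2d = len(pts2d)

    # 2D quadratic cells (9 fine nodes each, order di + 3*dj)
    cells2d = []
    for xy, gid in zip(blocks, block_gid):
        ncx = (xy.shape[0] - 1) // 2
        ncy = (xy.shape[1] - 1) // 2
        for cj in range(ncy):
            for ci in range(ncx):
                cells2d.append([gid[2 * ci + di, 2 * cj + dj]
                                for dj in range(3) for di in range(3)])
    cells2d = np.asarray(cells2d)

    # extrusion: fine z levels l = 0..2nz, node id = node2d * nlev + l
    nlev = 2 * nz + 1
    zlev = np.linspace(0.0, h_m, nlev)
    coords = np.empty((n2d * nlev, 3))
    coords[:, 0] = np.repeat(pts2d[:, 0], nlev)
    coords[:, 1] = np.repeat(pts2d[:, 1], nlev)
    coords[:, 2] = np.tile(zlev, n2d)

    hex27 = np.empty((cells2d.shape[0] * nz, 27), dtype=int)
    e = 0
    for k in range(nz):
        for c in cells2d:
            hex27[e] = [c[a2d] * nlev + (2 * k + dk)
                        for dk in range(3) for a2d in range(9)]
            e += 1

    mesh = _finalise_mesh(coords, hex27, spec=spec)

    rad = np.hypot(coords[:, 0], coords[:, 1])
    geom_tol = 1e-6 * r_m
    mesh.node_sets = {
        "bottom": np.flatnonzero(np.abs(coords[:, 2]) < geom_tol),
        "top": np.flatnonzero(np.abs(coords[:, 2] - h_m) < geom_tol),
        "hull": np.flatnonzero(np.abs(rad - r_m) < geom_tol),
        "symmetry_x": np.flatnonzero(np.abs(coords[:, 0]) < geom_tol),
        "symmetry_y": np.flatnonzero(np.abs(coords[:, 1]) < geom_tol),
    }
    mesh.pnode_sets = _pnode_sets(mesh)
    mesh.top_faces = _extrude_top_faces(cells2d, nz, nlev)
    on_mid = np.abs(coords[:, 2] - 0.5 * h_m) < geom_tol
    mesh.midheight_hull_nodes = np.flatnonzero(
        on_mid & (np.abs(rad - r_m) < geom_tol))
    mesh.symmetry_factor = 4.0
    mesh.top_area_ref = 0.25 * np.pi * r_m ** 2
    return mesh


def build_box_mesh(lx: float, ly: float, lz: float,
                   nx: int = 1, ny: int = 1, nz: int = 1) -> Mesh:
    """Structured box mesh (dimensions in mm) for benchmark problems.

    Tags: bottom/top (z), xmin/xmax, ymin/ymax.  ``symmetry_x``/``symmetry_y``
    alias xmin/ymin so the same boundary-condition specs apply.
    """
    Lx, Ly, Lz = (v * MM_TO_M for v in (lx, ly, lz))
    fx = np.linspace(0.0, Lx, 2 * nx + 1)
    fy = np.linspace(0.0, Ly, 2 * ny + 1)
    fz = np.linspace(0.0, Lz, 2 * nz + 1)
    X, Y, Z = np.meshgrid(fx, fy, fz, indexing="ij")
    coords = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)

    def nid(i, j, k):
        return (i * len(fy) + j) * len(fz) + k

    hex27 = np.empty((nx * ny * nz, 27), dtype=int)
    e = 0
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                hex27[e] = [nid(2 * i + di, 2 * j + dj, 2 * k + dk)
                            for dk in range(3) for dj in range(3)
                            for di in range(3)]
                e += 1
    mesh = _finalise_mesh(coords, hex27, spec=None)

    tol = 1e-9 * max(Lx, Ly, Lz)
    sets = {
        "bottom": np.flatnonzero(np.abs(coords[:, 2]) < tol),
        "top": np.flatnonzero(np.abs(coords[:, 2] - Lz) < tol),
        "xmin": np.flatnonzero(np.abs(coords[:, 0]) < tol),
        "xmax": np.flatnonzero(np.abs(coords[:, 0] - Lx) < tol),
        "ymin": np.flatnonzero(np.abs(coords[:, 1]) < tol),
        "ymax": np.flatnonzero(np.abs(coords[:, 1] - Ly) < tol),
    }
    sets["symmetry_x"] = sets["xmin"]
    sets["symmetry_y"] = sets["ymin"]
    mesh.node_sets = sets
    mesh.pnode_sets = _pnode_sets(mesh)

    faces = []
    for e in range(nx * ny * nz):
        # element's top face nodes are local a = di + 3*dj + 9*2
        if np.all(np.abs(coords[hex27[e, 18:27], 2] - Lz) < tol):
            faces.append(hex27[e, 18:27])
    mesh.top_faces = np.asarray(faces, dtype=int)
    mesh.midheight_hull_nodes = np.array([], dtype=int)
    mesh.symmetry_factor = 1.0
    mesh.top_area_ref = Lx * Ly
    return mesh


def _finalise_mesh(coords, hex27, spec):
    """Derive the Q1 pressure numbering from the element corner nodes."""
    corner_local = [0, 2, 6, 8, 18, 20, 24, 26]  # (di,dj,dk) in {0,2}^3
    corner_unodes = np.unique(hex27[:, corner_local])
    pid_of_unode = -np.ones(coords.shape[0], dtype=int)
    pid_of_unode[corner_unodes] = np.arange(len(corner_unodes))
    hex8 = pid_of_unode[hex27[:, corner_local]]
    return Mesh(coords=coords, hex27=hex27, hex8=hex8,
                pnode_unode=corner_unodes, node_sets={}, pnode_sets={},
                top_faces=np.empty((0, 9), dtype=int),
                midheight_hull_nodes=np.array([], dtype=int),
                symmetry_factor=1.0, top_area_ref=0.0, spec=spec)


def _pnode_sets(mesh: Mesh) -> Dict[str, np.ndarray]:
    pid_of_unode = -np.ones(mesh.n_unodes, dtype=int)
    pid_of_unode[mesh.pnode_unode] = np.arange(mesh.n_pnodes)
    out = {}
    for tag, nodes in mesh.node_sets.items():
        pids = pid_of_unode[nodes]
        out[tag] = np.unique(pids[pids >= 0])
    return out


def _extrude_top_faces(cells2d, nz, nlev):
    k = nz - 1
    faces = []
    for c in cells2d:
        faces.append([c[a2d] * nlev + (2 * k + 2) for a2d in range(9)])
    return np.asarray(faces, dtype=int)
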