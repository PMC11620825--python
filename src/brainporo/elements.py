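"""Reference-element machinery: triquadratic (Q2) displacement / trilinear (Q1)
pressure hexahedra with 3x3x3 Gauss quadrature (full integration).

Local node ordering is lexicographic in the reference coordinates,
``a = di + 3*dj + 9*dk`` for Q2 and ``a = di + 2*dj + 4*dk`` for Q1, with
reference nodes at -1, 0, 1 (Q2) and -1, 1 (Q1) per direction.  The mesh
builder emits connectivity in exactly this order.
"""

from __future__ import annotations

import numpy as np


def _lag2(x):
    """Quadratic Lagrange basis on nodes (-1, 0, 1) and derivatives."""
    N = np.array([0.5 * x * (x - 1.0), 1.0 - x * x, 0.5 * x * (x + 1.0)])
    dN = np.array([x - 0.5, -2.0 * x, x + 0.5])
    return N, dN


def _lag1(x):
    N = np.array([0.5 * (1.0 - x), 0.5 * (1.0 + x)])
    dN = np.array([-0.5, 0.5])
    return N, dN


def shape_q2(xi):
    """Q2 shape functions and reference gradients at one point xi=(x,y,z)."""
    Nx, dNx = _lag2(xi[0])
    Ny, dNy = _lag2(xi[1])
    Nz, dNz = _lag2(xi[2])
    N = np.einsum("i,j,k->kji", Nx, Ny, Nz).reshape(-1)  # order di+3dj+9dk
    dN = np.empty((27, 3))
    dN[:, 0] = np.einsum("i,j,k->kji", dNx, Ny, Nz).reshape(-1)
    dN[:, 1] = np.einsum("i,j,k->kji", Nx, dNy, Nz).reshape(-1)
    dN[:, 2] = np.einsum("i,j,k->kji", Nx, Ny, dNz).reshape(-1)
    return N, dN


def shape_q1(xi):
    Nx, dNx = _lag1(xi[0])
    Ny, dNy = _lag1(xi[1])
    Nz, dNz = _lag1(xi[2])
    N = np.einsum("i,j,k->kji", Nx, Ny, Nz).reshape(-1)
    dN = np.empty((8, 3))
    dN[:, 0] = np.einsum("i,j,k->kji", dNx, Ny, Nz).reshape(-1)
    dN[:, 1] = np.einsum("i,j,k->kji", Nx, dNy, Nz).reshape(-1)
    dN[:, 2] = np.einsum("i,j,k->kji", Nx, Ny, dNz).reshape(-1)
    return N, dN


# 3-point Gauss rule per direction (exact through degree 5)
_G = np.sqrt(3.0 / 5.0)
GAUSS3_PTS = np.array([-_G, 0.0, _G])
GAUSS3_WTS = np.array([5.0, 8.0, 5.0]) / 9.0

QP_XI = np.array([[x, y, z] for z in GAUSS3_PTS for y in GAUSS3_PTS
                  for x in GAUSS3_PTS])
QP_W = np.array([wx * wy * wz for wz in GAUSS3_WTS for wy in GAUSS3_WTS
                 for wx in GAUSS3_WTS])
NQ = len(QP_W)

# tabulated basis at the quadrature points
N_U = np.empty((NQ, 27))
DN_U = np.empty((NQ, 27, 3))
N_P = np.empty((NQ, 8))
DN_P = np.empty((NQ, 8, 3))
for _q, _xi in enumerate(QP_XI):
    N_U[_q], DN_U[_q] = shape_q2(_xi)
    N_P[_q], DN_P[_q] = shape_q1(_xi)

# 2D 3x3 rule and 9-node quadratic quad basis for face (traction) integrals
QP2_XI = np.array([[x, y] for y in GAUSS3_PTS for x in GAUSS3_PTS])
QP2_W = np.array([wx * wy for wy in GAUSS3_WTS for wx in GAUSS3_WTS])
N_F = np.empty((9, 9))
DN_F = np.empty((9, 9, 2))
for _q, (_x, _y) in enumerate(QP2_XI):
    _Nx, _dNx = _lag2(_x)
    _Ny, _dNy = _lag2(_y)
    N_F[_q] = np.einsum("i,j->ji", _Nx, _Ny).reshape(-1)  # order di + 3*dj
    DN_F[_q, :, 0] = np.einsum("i,j->ji", _dNx, _Ny).reshape(-1)
    DN_F[_q, :, 1] = np.einsum("i,j->ji", _Nx, _dNy).reshape(-1)


def geometric_factors(coords_e: np.ndarray):
    """Isoparametric Jacobians for a batch of Q2 elements.

    Parameters
    ----------
    coords_e : (ne, 27, 3) node coordinates per element.

    Returns
    -------
    dNdX_u : (ne, NQ, 27, 3), dNdX_p : (ne, NQ, 8, 3), wdetJ : (ne, NQ)
    """
    # J[e,q,i,j] = d x_i / d xi_j
    J = np.einsum("eai,qaj->eqij", coords_e, DN_U)
    detJ = np.linalg.det(J)
    Jinv = np.linalg.inv(J)
    dNdX_u = np.einsum("qaj,eqji->eqai", DN_U, Jinv)
    dNdX_p = np.einsum("qaj,eqji->eqai", DN_P, Jinv)
    wdetJ = detJ * QP_W[None, :]
    return dNdX_u, dNdX_p, wdetJ, detJ
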