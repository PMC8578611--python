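"""Axisymmetric finite-volume Laplace solver for spreading resistance.

Independent numerical check on the closed-form access-resistance formulas
in :mod:`mea3d.impedance`.  The conduction problem is solved on the r-z
half-plane of the cylindrical saline bath:

* the exposed electrode metal (bare shaft + end cap) is an equipotential
  at 1 V;
* the insulated electrode body (gold under SU-8, cone, sleeve) is given a
  conductivity ~1e9 times below saline, which makes it an effective
  insulator without special-casing internal boundaries;
* the top and bottom bath faces are no-flux (natural Neumann);
* the circumferential wall is grounded (V = 0), representing a
  semi-infinite medium.

The spreading resistance is V/I with I the total current leaving the
equipotential surface.  Node-centred finite volumes with harmonic-mean
face conductivities give monotone convergence under grid refinement.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse
import scipy.sparse.linalg

from .geometry import UM, ElectrodeGeometry, MaterialSet, _outer_radius_um
from .impedance import BathModel

__all__ = ["fd_spreading_oracle"]

_SIGMA_INSULATOR_RATIO = 1e-9


def fd_spreading_oracle(
    geom: ElectrodeGeometry,
    mats: MaterialSet,
    bath: BathModel | None = None,
    grid_step: float = 5e-6,
) -> float:
    """Spreading resistance (ohm) from a finite-volume Laplace solve.

    ``grid_step`` is the target node spacing in metres and must resolve
    the core radius with at least 4 cells.  The electrode stands on the
    bath floor with its axis on r = 0.
    """
    bath = bath or BathModel()
    a = geom.core_radius_um * UM
    if grid_step > a / 4.0:
        raise ValueError("grid_step must resolve the core radius with >= 4 cells")

    R = bath.bath_diameter / 2.0
    H = bath.bath_height
    z_tip = geom.total_height_um * UM
    if z_tip > H + 1e-12:
        raise ValueError("electrode taller than the bath")
    l_exp = geom.exposed_length_um * UM

    nr = int(np.ceil(R / grid_step)) + 1
    nz = int(np.ceil(H / grid_step)) + 1
    r = np.linspace(0.0, R, nr)
    z = np.linspace(0.0, H, nz)
    hr = r[1] - r[0]
    hz = z[1] - z[0]
    rr, zz = np.meshgrid(r, z, indexing="ij")

    # node classification; an electrode shorter than one cell degenerates to
    # a disc flush with the insulating floor (the Newman configuration)
    z_um = zz / UM
    if z_tip <= hz:
        inside_body = np.zeros_like(rr, dtype=bool)
        exposed = (rr <= a + 1e-15) & (zz <= hz / 2.0)
    else:
        body_r = _outer_radius_um(geom, z_um.ravel()).reshape(zz.shape) * UM
        inside_body = (zz <= z_tip + hz / 2.0) & (rr <= body_r + 1e-15)
        exposed = (
            (rr <= a + 1e-15)
            & (zz <= z_tip + hz / 2.0)
            & (zz >= z_tip - l_exp - hz / 2.0)
        )
    insulator = inside_body & ~exposed
    wall = np.zeros_like(insulator)
    wall[-1, :] = True  # r = R, grounded
    dirichlet = exposed | wall
    v_dirichlet = np.where(exposed, 1.0, 0.0)

    sigma = np.where(insulator, mats.sigma_saline * _SIGMA_INSULATOR_RATIO,
                     mats.sigma_saline)

    n = nr * nz
    idx = np.arange(n).reshape(nr, nz)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    diag = np.zeros(n)

    def add_edges(i_from, i_to, g):
        """Accumulate conductance g between node index arrays."""
        rows.append(i_from)
        cols.append(i_to)
        vals.append(-g)
        np.add.at(diag, i_from, g)

    # radial faces between (i, j) and (i+1, j): area 2*pi*r_{i+1/2}*dz with
    # half-height cells on the top and bottom boundary rows
    sig_face = 2.0 * sigma[:-1, :] * sigma[1:, :] / (sigma[:-1, :] + sigma[1:, :])
    r_face = 0.5 * (rr[:-1, :] + rr[1:, :])
    dz = np.full(nz, hz)
    dz[0] = dz[-1] = hz / 2.0
    g_r = sig_face * 2.0 * np.pi * r_face * dz[np.newaxis, :] / hr
    i_lo = idx[:-1, :].ravel()
    i_hi = idx[1:, :].ravel()
    add_edges(i_lo, i_hi, g_r.ravel())
    add_edges(i_hi, i_lo, g_r.ravel())

    # axial faces between (i, j) and (i, j+1): annular cell cross-sections,
    # pi*(hr/2)^2 on the axis and a half-width annulus at the outer wall
    sig_face = 2.0 * sigma[:, :-1] * sigma[:, 1:] / (sigma[:, :-1] + sigma[:, 1:])
    r_in = np.maximum(r - hr / 2.0, 0.0)
    r_out = np.minimum(r + hr / 2.0, R)
    area = np.pi * (r_out**2 - r_in**2)
    g_z = sig_face * area[:, np.newaxis] / hz
    i_lo = idx[:, :-1].ravel()
    i_hi = idx[:, 1:].ravel()
    add_edges(i_lo, i_hi, g_z.ravel())
    add_edges(i_hi, i_lo, g_z.ravel())

    A = scipy.sparse.coo_matrix(
        (
            np.concatenate(vals + [diag]),
            (np.concatenate(rows + [np.arange(n)]),
             np.concatenate(cols + [np.arange(n)])),
        ),
        shape=(n, n),
    ).tocsr()

    # impose Dirichlet rows as identity
    d_mask = dirichlet.ravel()
    b = np.zeros(n)
    b[d_mask] = v_dirichlet.ravel()[d_mask]
    keep = scipy.sparse.diags((~d_mask).astype(float))
    ident = scipy.sparse.diags(d_mask.astype(float))
    # move known Dirichlet values to the RHS of free rows
    v_known = np.zeros(n)
    v_known[d_mask] = b[d_mask]
    rhs = b - keep @ (A @ v_known)
    rhs[d_mask] = b[d_mask]
    A_free = keep @ A @ keep + ident
    v = scipy.sparse.linalg.spsolve(A_free.tocsr(), rhs)
    v[d_mask] = b[d_mask]

    # total current out of the driven surface: I = sum_e sum_n G_en (V_e - V_n)
    flux = A @ v  # row e of A gives sum_n G_en (V_e - V_n) for interior stencil
    current = flux[exposed.ravel()].sum()
    if not np.isfinite(current) or current <= 0:
        raise RuntimeError("finite-volume solve did not converge to a valid current")
    return float(1.0 / current)
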