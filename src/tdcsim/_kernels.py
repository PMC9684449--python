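"""Numba stencil kernels for the voxel finite-volume operator.

The discrete operator is a 7-point stencil with face conductances Cx/Cy/Cz
(shape (nx-1,ny,nz) etc., face f between cells f and f+1) plus a diagonal
Dirichlet coupling; `diag` is the full diagonal (sum of incident conductances
plus Dirichlet terms, or 1 for cells outside the conductive domain).
"""

import numba as nb
import numpy as np


@nb.njit(cache=True, fastmath=True)
def apply_op(u, cx, cy, cz, diag, out):
    nx, ny, nz = u.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                acc = diag[i, j, k] * u[i, j, k]
                if i > 0:
                    acc -= cx[i - 1, j, k] * u[i - 1, j, k]
                if i < nx - 1:
                    acc -= cx[i, j, k] * u[i + 1, j, k]
                if j > 0:
                    acc -= cy[i, j - 1, k] * u[i, j - 1, k]
                if j < ny - 1:
                    acc -= cy[i, j, k] * u[i, j + 1, k]
                if k > 0:
                    acc -= cz[i, j, k - 1] * u[i, j, k - 1]
                if k < nz - 1:
                    acc -= cz[i, j, k] * u[i, j, k + 1]
                out[i, j, k] = acc


@nb.njit(cache=True, fastmath=True)
def residual(u, b, cx, cy, cz, diag, out):
    nx, ny, nz = u.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                acc = diag[i, j, k] * u[i, j, k]
                if i > 0:
                    acc -= cx[i - 1, j, k] * u[i - 1, j, k]
                if i < nx - 1:
                    acc -= cx[i, j, k] * u[i + 1, j, k]
                if j > 0:
                    acc -= cy[i, j - 1, k] * u[i, j - 1, k]
                if j < ny - 1:
                    acc -= cy[i, j, k] * u[i, j + 1, k]
                if k > 0:
                    acc -= cz[i, j, k - 1] * u[i, j, k - 1]
                if k < nz - 1:
                    acc -= cz[i, j, k] * u[i, j, k + 1]
                out[i, j, k] = b[i, j, k] - acc


@nb.njit(cache=True, fastmath=True)
def rb_sweep(u, b, cx, cy, cz, diag, parity):
    """In-place Gauss-Seidel update of one checkerboard colour.

    Cells of equal parity do not couple in the 7-point stencil, so updating a
    colour in place is an exact red-black Gauss-Seidel half-sweep.
    """
    nx, ny, nz = u.shape
    for i in range(nx):
        for j in range(ny):
            kstart = (parity - (i + j)) % 2
            for k in range(kstart, nz, 2):
                acc = b[i, j, k]
                if i > 0:
                    acc += cx[i - 1, j, k] * u[i - 1, j, k]
                if i < nx - 1:
                    acc += cx[i, j, k] * u[i + 1, j, k]
                if j > 0:
                    acc += cy[i, j - 1, k] * u[i, j - 1, k]
                if j < ny - 1:
                    acc += cy[i, j, k] * u[i, j + 1, k]
                if k > 0:
                    acc += cz[i, j, k - 1] * u[i, j, k - 1]
                if k < nz - 1:
                    acc += cz[i, j, k] * u[i, j, k + 1]
                u[i, j, k] = acc / diag[i, j, k]


@nb.njit(cache=True, fastmath=True, inline="always")
def _norm_radius(px, py, pz, ax, ay, az, pert_scale, hc):
    """Normalised radius s such that s <= R_k means 'inside shell k', for the
    analytic ellipsoid + low-order-harmonic head geometry (centre at 0)."""
    r = np.sqrt(px * px + py * py + pz * pz)
    if r == 0.0:
        return 0.0
    x = px / r
    y = py / r
    z = pz / r
    q = (x / ax) ** 2 + (y / ay) ** 2 + (z / az) ** 2
    fac = 1.0 / np.sqrt(q)
    if pert_scale != 0.0:
        h = (
            hc[0] * 0.5 * (3.0 * z * z - 1.0)
            + hc[1] * x * y
            + hc[2] * x * z
            + hc[3] * y * z
            + hc[4] * (x * x - y * y)
            + hc[5] * 0.5 * z * (5.0 * z * z - 3.0)
            + hc[6] * x * (x * x - 3.0 * y * y)
            + hc[7] * y * (3.0 * x * x - y * y)
        )
        fac *= 1.0 + pert_scale * h
    return r / fac


@nb.njit(cache=True, fastmath=True)
def homogenize_faces(
    faces, axis, face_centers, h, ns,
    shell_radii, sigmas_inward, ax_ratios, pert_scale, hcoeffs, out, ok,
):
    """Series-parallel effective conductance factor for boundary faces.

    For each face, sample an ns^3 block spanning the two adjacent cells
    (column length h along `axis`, face area h x h transverse); at each axial
    station take the arithmetic (parallel) mean of sigma over the transverse
    samples, then combine stations harmonically (series).  Writes sigma_eff
    into `out`; ok=False marks faces whose sample block leaves the head.
    """
    n = faces.shape[0]
    nsh = shell_radii.shape[0]
    ta = 0 if axis != 0 else 1
    tb = 2 if axis != 2 else 1
    for f in range(n):
        inv_sum = 0.0
        valid = True
        for ia in range(ns):
            oa = ((ia + 0.5) / ns - 0.5) * h
            tr_sum = 0.0
            for it in range(ns):
                ot = ((it + 0.5) / ns - 0.5) * h
                for iu in range(ns):
                    ou = ((iu + 0.5) / ns - 0.5) * h
                    px = face_centers[f, 0]
                    py = face_centers[f, 1]
                    pz = face_centers[f, 2]
                    if axis == 0:
                        px += oa
                    elif axis == 1:
                        py += oa
                    else:
                        pz += oa
                    if ta == 0:
                        px += ot
                    elif ta == 1:
                        py += ot
                    else:
                        pz += ot
                    if tb == 1:
                        py += ou
                    else:
                        pz += ou
                    s = _norm_radius(
                        px, py, pz,
                        ax_ratios[0], ax_ratios[1], ax_ratios[2],
                        pert_scale, hcoeffs,
                    )
                    sig = 0.0
                    for k in range(nsh - 1, -1, -1):
                        if s <= shell_radii[k]:
                            sig = sigmas_inward[k]
                            break
                    if sig <= 0.0:
                        valid = False
                    tr_sum += sig
                if not valid:
                    break
            if not valid:
                break
            inv_sum += 1.0 / (tr_sum / (ns * ns))
        if valid:
            out[f] = ns / inv_sum
            ok[f] = True
        else:
            ok[f] = False


@nb.njit(cache=True, fastmath=True)
def gradient_masked(phi, cond, h_m, out):
    """Cell-centred E = -grad(phi) using only conductive neighbours.

    Central difference where both neighbours are conductive, one-sided where
    only one is, zero where none.  `out` has shape (nx,ny,nz,3); h_m is the
    voxel size in metres.
    """
    nx, ny, nz = phi.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not cond[i, j, k]:
                    out[i, j, k, 0] = 0.0
                    out[i, j, k, 1] = 0.0
                    out[i, j, k, 2] = 0.0
                    continue
                for ax in range(3):
                    if ax == 0:
                        has_m = i > 0 and cond[i - 1, j, k]
                        has_p = i < nx - 1 and cond[i + 1, j, k]
                        vm = phi[i - 1, j, k] if has_m else 0.0
                        vp = phi[i + 1, j, k] if has_p else 0.0
                    elif ax == 1:
                        has_m = j > 0 and cond[i, j - 1, k]
                        has_p = j < ny - 1 and cond[i, j + 1, k]
                        vm = phi[i, j - 1, k] if has_m else 0.0
                        vp = phi[i, j + 1, k] if has_p else 0.0
                    else:
                        has_m = k > 0 and cond[i, j, k - 1]
                        has_p = k < nz - 1 and cond[i, j, k + 1]
                        vm = phi[i, j, k - 1] if has_m else 0.0
                        vp = phi[i, j, k + 1] if has_p else 0.0
                    v0 = phi[i, j, k]
                    if has_m and has_p:
                        g = (vp - vm) / (2.0 * h_m)
                    elif has_p:
                        g = (vp - v0) / h_m
                    elif has_m:
                        g = (v0 - vm) / h_m
                    else:
                        g = 0.0
                    out[i, j, k, ax] = -g
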