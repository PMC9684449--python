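"""Geometric multigrid preconditioner for the voxel conduction operator.

Cell-centred V-cycle with piecewise-constant prolongation, summation
restriction and Galerkin-consistent coarse operators: with constant
prolongation P and restriction R = P^T, the Galerkin operator R A P is again a
7-point stencil whose face conductances are the sums of the fine faces on
each coarse interface and whose Dirichlet diagonal is the sum over children.
Red-black Gauss-Seidel smoothing with the colour order reversed between the
pre- and post-smooth keeps the cycle symmetric, so it is a valid (fixed, SPD)
preconditioner for conjugate gradients.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from ._kernels import apply_op, rb_sweep, residual


def _pad_even(a, axes=(0, 1, 2)):
    pads = []
    for ax in range(a.ndim):
        if ax in axes and a.shape[ax] % 2 == 1:
            pads.append((0, 1))
        else:
            pads.append((0, 0))
    if any(p != (0, 0) for p in pads):
        return np.pad(a, pads)
    return a


class _Level:
    def __init__(self, cx, cy, cz, dii):
        self.cx, self.cy, self.cz = cx, cy, cz
        self.dii = dii  # Dirichlet diagonal contribution
        diag = dii.copy()
        diag[:-1] += cx
        diag[1:] += cx
        diag[:, :-1] += cy
        diag[:, 1:] += cy
        diag[:, :, :-1] += cz
        diag[:, :, 1:] += cz
        self.active = diag > 0
        diag[~self.active] = 1.0
        self.diag = diag
        self.shape = dii.shape
        self._lu = None

    def matvec(self, u, out=None):
        if out is None:
            out = np.empty_like(u)
        apply_op(u, self.cx, self.cy, self.cz, self.diag, out)
        return out

    def coarsen(self) -> "_Level":
        dii = _pad_even(self.dii)
        nx, ny, nz = dii.shape

        def _pad_to(a, shape):
            pads = [(0, s - c) for s, c in zip(shape, a.shape)]
            if any(p != (0, 0) for p in pads):
                return np.pad(a, pads)
            return a

        cx = _pad_to(self.cx, (nx - 1, ny, nz))
        cy = _pad_to(self.cy, (nx, ny - 1, nz))
        cz = _pad_to(self.cz, (nx, ny, nz - 1))
        # coarse x-faces: fine faces at odd x-index, summed over 2x2 children
        ccx = (
            cx[1:-1:2]
            .reshape(nx // 2 - 1, 1, ny // 2, 2, nz // 2, 2)
            .sum(axis=(1, 3, 5))
        )
        ccy = (
            cy[:, 1:-1:2]
            .reshape(nx // 2, 2, ny // 2 - 1, 1, nz // 2, 2)
            .sum(axis=(1, 3, 5))
        )
        ccz = (
            cz[:, :, 1:-1:2]
            .reshape(nx // 2, 2, ny // 2, 2, nz // 2 - 1, 1)
            .sum(axis=(1, 3, 5))
        )
        cdii = dii.reshape(nx // 2, 2, ny // 2, 2, nz // 2, 2).sum(axis=(1, 3, 5))
        # children straddling a coarse cell boundary couple only through the
        # coarse faces; interior fine faces vanish from the Galerkin operator
        return _Level(ccx, ccy, ccz, cdii)

    def to_csr(self) -> sparse.csr_matrix:
        nx, ny, nz = self.shape
        n = nx * ny * nz
        idx = np.arange(n).reshape(self.shape)
        rows, cols, vals = [idx.ravel()], [idx.ravel()], [self.diag.ravel()]
        for c, sl_a, sl_b in (
            (self.cx, (slice(None, -1),), (slice(1, None),)),
            (self.cy, (slice(None), slice(None, -1)), (slice(None), slice(1, None))),
            (
                self.cz,
                (slice(None), slice(None), slice(None, -1)),
                (slice(None), slice(None), slice(1, None)),
            ),
        ):
            a, b = idx[sl_a].ravel(), idx[sl_b].ravel()
            v = c.ravel()
            rows += [a, b]
            cols += [b, a]
            vals += [-v, -v]
        m = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
        return m.tocsr()


class MultigridSolver:
    """PCG with a symmetric V-cycle preconditioner."""

    def __init__(self, cx, cy, cz, dii, nu_pre=1, nu_post=1,
                 coarse_max_cells=6000):
        self.levels = [_Level(cx, cy, cz, dii)]
        while np.prod(self.levels[-1].shape) > coarse_max_cells and min(
            self.levels[-1].shape
        ) >= 4:
            self.levels.append(self.levels[-1].coarsen())
        lv = self.levels[-1]
        lv._lu = splu(sparse.csc_matrix(lv.to_csr()))
        self.nu_pre = nu_pre
        self.nu_post = nu_post

    # -- cycle -------------------------------------------------------------

    def _vcycle(self, li, b):
        lv = self.levels[li]
        if lv._lu is not None:
            return lv._lu.solve(b.ravel()).reshape(lv.shape)
        u = np.zeros_like(b)
        tmp = np.empty_like(b)
        for _ in range(self.nu_pre):
            rb_sweep(u, b, lv.cx, lv.cy, lv.cz, lv.diag, 0)
            rb_sweep(u, b, lv.cx, lv.cy, lv.cz, lv.diag, 1)
        residual(u, b, lv.cx, lv.cy, lv.cz, lv.diag, tmp)
        r = _pad_even(tmp)
        nx, ny, nz = r.shape
        rc = r.reshape(nx // 2, 2, ny // 2, 2, nz // 2, 2).sum(axis=(1, 3, 5))
        ec = self._vcycle(li + 1, rc)
        ef = np.repeat(np.repeat(np.repeat(ec, 2, 0), 2, 1), 2, 2)
        sx, sy, sz = lv.shape
        u += ef[:sx, :sy, :sz]
        # reversed colour order keeps the cycle symmetric for PCG
        for _ in range(self.nu_post):
            rb_sweep(u, b, lv.cx, lv.cy, lv.cz, lv.diag, 1)
            rb_sweep(u, b, lv.cx, lv.cy, lv.cz, lv.diag, 0)
        return u

    def precondition(self, r):
        return self._vcycle(0, r)

    # -- PCG ---------------------------------------------------------------

    def solve(self, b, tol=1e-8, maxiter=400, x0=None):
        """Preconditioned CG on the finest level.

        Returns (solution, relative_residual, iterations).
        """
        lv = self.levels[0]
        x = np.zeros_like(b) if x0 is None else x0.copy()
        r = np.empty_like(b)
        residual(x, b, lv.cx, lv.cy, lv.cz, lv.diag, r)
        bnorm = float(np.linalg.norm(b))
        if bnorm == 0.0:
            return x, 0.0, 0
        z = self.precondition(r)
        p = z.copy()
        rz = float((r * z).sum())
        relres = float(np.linalg.norm(r)) / bnorm
        it = 0
        ap = np.empty_like(b)
        while relres > tol and it < maxiter:
            lv.matvec(p, ap)
            alpha = rz / float((p * ap).sum())
            x += alpha * p
            r -= alpha * ap
            relres = float(np.linalg.norm(r)) / bnorm
            if relres <= tol:
                it += 1
                break
            z = self.precondition(r)
            rz_new = float((r * z).sum())
            beta = rz_new / rz
            rz = rz_new
            p = z + beta * p
            it += 1
        return x, relres, it
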