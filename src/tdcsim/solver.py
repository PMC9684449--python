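"""Quasi-static conduction solve: sigma-weighted Laplace on the voxel grid.

The montage's electrode footprints impose Dirichlet values on the scalp faces
they cover (+1 on the anode group, 0 on the cathode group — all cathodes share
one terminal, so current splits freely in multi-cathode montages); every other
boundary face carries a homogeneous Neumann (zero normal current) condition.
The voxel finite-volume discretisation uses harmonic face averaging of the
per-voxel conductivity, giving a symmetric M-matrix system solved by
multigrid-preconditioned conjugate gradients.  Current-controlled stimulation
is realised by scaling the unit-drive solution to the montage's prescribed
total current, which is exact by linearity.

Units are SI internally (m, S/m, V, A); the interface layer speaks mm and mA.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from ._kernels import gradient_masked, homogenize_faces
from ._multigrid import MultigridSolver
from .errors import ConfigurationError, GeometryError, SolverError
from .montage import Montage
from .phantom import ConductivityMap, HeadPhantom

MM = 1e-3  # metres per millimetre


@dataclass
class ConductionSystem:
    """Assembled discrete conduction problem for one phantom x montage."""

    phantom: HeadPhantom
    montage: Montage
    sigma: ConductivityMap
    cx: np.ndarray            # face conductances (S), x-faces (nx-1,ny,nz)
    cy: np.ndarray
    cz: np.ndarray
    dirichlet_diag: np.ndarray   # (nx,ny,nz) sum of Dirichlet couplings (S)
    rhs: np.ndarray              # (nx,ny,nz) Dirichlet coupling * phi_bc
    conductive: np.ndarray       # (nx,ny,nz) bool
    # per Dirichlet face: flat cell index, conductance, boundary value
    bc_cells: np.ndarray
    bc_cond: np.ndarray
    bc_phi: np.ndarray

    def to_csr(self):
        """Sparse matrix view of the operator (for inspection/tests)."""
        from ._multigrid import _Level

        return _Level(self.cx, self.cy, self.cz, self.dirichlet_diag).to_csr()


@dataclass
class FieldSolution:
    """Potential and electric field for one phantom x montage solve."""

    phi: np.ndarray             # volts, (nx,ny,nz); 0 outside the head
    e_vector: np.ndarray        # V/m, (nx,ny,nz,3)
    e_mag: np.ndarray           # V/m, (nx,ny,nz)
    delivered_current_mA: float
    montage_name: str
    solve_residual: float
    system: ConductionSystem
    drive_scale: float = 1.0  # anode terminal potential (V); 1 for unit drive

    @property
    def phantom(self) -> HeadPhantom:
        return self.system.phantom

    def export_nifti(self, path) -> None:
        """Write e_mag (plus potential) as a two-volume NIfTI."""
        import nibabel as nib

        data = np.stack([self.e_mag, self.phi], axis=-1).astype(np.float32)
        img = nib.Nifti1Image(data, self.phantom.affine)
        nib.save(img, str(path))


def _boundary_faces(cond: np.ndarray):
    """Outward boundary faces of the conductive domain.

    Returns (cell_index_array (n,3), outward_axis (n,), outward_sign (n,)).
    """
    cells, axes, signs = [], [], []
    for ax in range(3):
        for sign in (+1, -1):
            inner = np.ones_like(cond)
            shifted = np.roll(cond, -sign, axis=ax)
            # roll wraps; edge cells treated as facing outside
            edge = np.zeros_like(cond)
            idx = [slice(None)] * 3
            idx[ax] = -1 if sign > 0 else 0
            shifted[tuple(idx)] = False
            face = cond & ~shifted & inner.astype(bool)
            w = np.argwhere(face)
            cells.append(w)
            axes.append(np.full(len(w), ax))
            signs.append(np.full(len(w), sign))
    return np.concatenate(cells), np.concatenate(axes), np.concatenate(signs)


def _harmonic_face(a, b):
    out = np.zeros_like(a)
    nz = (a > 0) & (b > 0)
    out[nz] = 2.0 * a[nz] * b[nz] / (a[nz] + b[nz])
    return out


_FACE_CACHE: dict = {}


def face_conductances(
    phantom: HeadPhantom,
    sigma: ConductivityMap,
    homogenize: bool = True,
    ns: int = 4,
) -> tuple:
    """Face conductances (S) of the conduction operator; montage-independent.

    Baseline: harmonic mean of the two adjacent voxel conductivities times
    the voxel size.  With `homogenize` (default), faces adjacent to an
    interior tissue boundary are replaced by a sub-voxel series-parallel
    estimate sampled from the analytic phantom geometry: the arithmetic mean
    of sigma over the face-parallel samples at each axial station, combined
    harmonically along the face normal.  This restores the radial resistance
    of the thin skull and the tangential shunting of the one-to-two-voxel CSF
    layer, both of which the labelled grid staircases.  Faces at the outer
    scalp boundary keep the label-based value (a sub-voxel column crossing
    the scalp would series-block legitimate skin current).

    Results are cached per (phantom spec, conductivities, ns), so the fifteen
    montages of a study subject share one computation.
    """
    spec = phantom.spec
    key = (
        spec.outer_radius_mm,
        tuple(sorted(spec.thickness_mm.items())),
        tuple(spec.ellipsoid_axis_ratios),
        spec.perturbation_amplitude_mm,
        spec.voxel_size_mm,
        spec.seed,
        tuple(sorted(sigma.values.items())),
        homogenize,
        ns,
    )
    if key in _FACE_CACHE:
        return _FACE_CACHE[key]
    labels = phantom.label_grid
    h = phantom.voxel_size_mm
    h_m = h * MM
    sig = sigma.as_array(int(labels.max()) + 1)[labels]
    C = [
        _harmonic_face(sig[:-1], sig[1:]) * h_m,
        _harmonic_face(sig[:, :-1], sig[:, 1:]) * h_m,
        _harmonic_face(sig[:, :, :-1], sig[:, :, 1:]) * h_m,
    ]
    if homogenize:
        shape = phantom.shape_model
        near = np.zeros(labels.shape, dtype=bool)
        for ax in range(3):
            la = labels[tuple([slice(None)] * ax + [slice(None, -1)])]
            lb = labels[tuple([slice(None)] * ax + [slice(1, None)])]
            d = (la != lb) & (la > 0) & (lb > 0)
            sl = [slice(None)] * 3
            sl[ax] = slice(None, -1)
            near[tuple(sl)] |= d
            sl[ax] = slice(1, None)
            near[tuple(sl)] |= d
        radii = np.asarray(shape.shell_radii_mm, dtype=float)
        sigmas_inward = np.array(
            [sigma.values[l] for l in (1, 2, 3, 4, 5)], dtype=float
        )
        center = np.asarray(shape.center_mm, dtype=float)
        for ax in range(3):
            sl_a = [slice(None)] * 3
            sl_a[ax] = slice(None, -1)
            sl_b = [slice(None)] * 3
            sl_b[ax] = slice(1, None)
            la, lb = labels[tuple(sl_a)], labels[tuple(sl_b)]
            sel = (near[tuple(sl_a)] | near[tuple(sl_b)]) & (la > 0) & (lb > 0)
            w = np.argwhere(sel)
            if len(w) == 0:
                continue
            fc = phantom.origin_mm + (w + 0.5) * h - center
            fc[:, ax] += h / 2.0
            out = np.empty(len(w))
            ok = np.zeros(len(w), dtype=np.bool_)
            homogenize_faces(
                w, ax, np.ascontiguousarray(fc), h, ns,
                radii, sigmas_inward,
                np.asarray(shape.axis_ratios, dtype=float),
                float(shape._pert_scale),
                np.asarray(shape.harmonic_coeffs, dtype=float),
                out, ok,
            )
            keep = ok
            C[ax][w[keep, 0], w[keep, 1], w[keep, 2]] = out[keep] * h_m
    result = tuple(C)
    if len(_FACE_CACHE) > 8:
        _FACE_CACHE.pop(next(iter(_FACE_CACHE)))
    _FACE_CACHE[key] = result
    return result


def assemble_system(
    phantom: HeadPhantom,
    sigma: ConductivityMap,
    montage: Montage,
    homogenize_faces_flag: bool = True,
) -> ConductionSystem:
    """Assemble the finite-volume system for a montage on a phantom."""
    labels = phantom.label_grid
    present = np.unique(labels)
    missing = [int(l) for l in present if l != 0 and l not in sigma.values]
    if missing:
        raise ConfigurationError(f"no conductivity for tissue labels {missing}")
    if not montage.anodes or not montage.cathodes:
        raise ConfigurationError("montage must have an anode and a cathode")

    h_m = phantom.voxel_size_mm * MM
    sig = sigma.as_array(int(labels.max()) + 1)[labels]  # S/m per voxel
    cond = labels > 0

    cx, cy, cz = face_conductances(
        phantom, sigma, homogenize=homogenize_faces_flag
    )

    # Dirichlet faces: boundary faces whose centres fall inside a footprint
    cells, axes, signs = _boundary_faces(cond)
    centers = phantom.index_to_world(cells)
    offs = np.zeros_like(centers)
    offs[np.arange(len(cells)), axes] = signs * phantom.voxel_size_mm / 2.0
    face_pts = centers + offs

    ddiag = np.zeros(labels.shape)
    rhs = np.zeros(labels.shape)
    bc_cells, bc_cond, bc_phi = [], [], []
    taken = np.zeros(len(cells), dtype=bool)
    for el in montage.electrodes:
        phi_bc = 1.0 if el.polarity == "anode" else 0.0
        # cheap prefilter by chord distance, then exact footprint membership
        near = (
            np.linalg.norm(face_pts - el.center, axis=1)
            < 1.3 * _patch_radius_mm(el) + 2 * phantom.voxel_size_mm
        )
        sel = np.zeros(len(cells), dtype=bool)
        if np.any(near):
            sel[near] = el.contains(face_pts[near])
        sel &= ~taken
        if not np.any(sel):
            # sub-voxel electrode: fall back to the nearest free boundary face
            order = np.argsort(np.linalg.norm(face_pts - el.center, axis=1))
            for idx_near in order[:8]:
                if not taken[idx_near]:
                    sel[idx_near] = True
                    break
            else:
                raise GeometryError(
                    f"electrode at {np.round(el.center, 1)} covers no scalp "
                    f"face at {phantom.voxel_size_mm} mm resolution"
                )
        taken |= sel
        w = cells[sel]
        sig_cell = sig[w[:, 0], w[:, 1], w[:, 2]]
        c_dir = 2.0 * sig_cell * h_m  # half-cell coupling sigma*A/(h/2)
        flat = np.ravel_multi_index((w[:, 0], w[:, 1], w[:, 2]), labels.shape)
        np.add.at(ddiag.ravel(), flat, c_dir)
        np.add.at(rhs.ravel(), flat, c_dir * phi_bc)
        bc_cells.append(flat)
        bc_cond.append(c_dir)
        bc_phi.append(np.full(len(flat), phi_bc))

    return ConductionSystem(
        phantom=phantom,
        montage=montage,
        sigma=sigma,
        cx=cx,
        cy=cy,
        cz=cz,
        dirichlet_diag=ddiag,
        rhs=rhs,
        conductive=cond,
        bc_cells=np.concatenate(bc_cells),
        bc_cond=np.concatenate(bc_cond),
        bc_phi=np.concatenate(bc_phi),
    )


def _patch_radius_mm(el) -> float:
    s = el.shape
    if s.kind == "rect":
        return float(np.hypot(s.width_cm, s.height_cm)) * 5.0
    return s.diameter_cm * 5.0


def solve_potential(
    system: ConductionSystem,
    tol: float = 1e-8,
    maxiter: int = 400,
    x0: Optional[np.ndarray] = None,
) -> FieldSolution:
    """Solve the unit-Dirichlet drive (anodes at 1 V, cathodes at 0 V)."""
    mg = MultigridSolver(system.cx, system.cy, system.cz, system.dirichlet_diag)
    phi, relres, iters = mg.solve(system.rhs, tol=tol, maxiter=maxiter, x0=x0)
    if relres > tol:
        raise SolverError(
            f"PCG stalled: relative residual {relres:.2e} after {iters} iterations"
        )
    phi[~system.conductive] = 0.0
    h_m = system.phantom.voxel_size_mm * MM
    e_vec = np.empty(phi.shape + (3,))
    gradient_masked(phi, system.conductive, h_m, e_vec)
    e_mag = np.linalg.norm(e_vec, axis=-1)
    delivered_A = anode_current(system, phi)
    if delivered_A <= 0:
        raise SolverError("degenerate geometry: no current delivered")
    return FieldSolution(
        phi=phi,
        e_vector=e_vec,
        e_mag=e_mag,
        delivered_current_mA=delivered_A * 1e3,
        montage_name=system.montage.name,
        solve_residual=relres,
        system=system,
    )


def anode_current(
    system: ConductionSystem, phi: np.ndarray, drive: float = 1.0
) -> float:
    """Net current (A) entering through the anode Dirichlet faces.

    `drive` is the anode terminal potential consistent with `phi` (1 V for a
    unit-drive solve; `FieldSolution.drive_scale` for scaled solutions)."""
    u = phi.ravel()[system.bc_cells]
    inj = system.bc_cond * (system.bc_phi * drive - u)
    return float(inj[system.bc_phi > 0].sum())


def scale_to_current(sol: FieldSolution, target_mA: float) -> FieldSolution:
    """Rescale a unit-drive solution to a prescribed total current (mA)."""
    if sol.delivered_current_mA == 0:
        raise SolverError("cannot scale a zero-current solution")
    k = target_mA / sol.delivered_current_mA
    return replace(
        sol,
        phi=sol.phi * k,
        e_vector=sol.e_vector * k,
        e_mag=sol.e_mag * abs(k),
        delivered_current_mA=target_mA,
        drive_scale=sol.drive_scale * k,
    )


def solve_montage(
    phantom: HeadPhantom,
    montage: Montage,
    sigma: Optional[ConductivityMap] = None,
    tol: float = 1e-8,
) -> FieldSolution:
    """Assemble, solve and scale to the montage's prescribed current."""
    sigma = sigma or ConductivityMap()
    system = assemble_system(phantom, sigma, montage)
    sol = solve_potential(system, tol=tol)
    return scale_to_current(sol, montage.total_current_mA)


def current_through_surface(sol: FieldSolution, surface) -> float:
    """Conduction current (mA) crossing a separating surface.

    `surface` is either ``("plane", axis, coordinate_mm)`` — an axis-aligned
    plane, positive current flowing toward +axis — or a boolean voxel mask,
    in which case the result is the net current leaving the masked region
    through interior faces (electrode faces are domain boundary, not interior,
    so a region containing the anode contact reports +total current).
    """
    sys_ = sol.system
    phi = sol.phi

    if isinstance(surface, tuple) and surface[0] == "plane":
        _, axis, coord = surface
        ax = {"x": 0, "y": 1, "z": 2}[axis] if isinstance(axis, str) else int(axis)
        ph = sys_.phantom
        axes_coords = ph.voxel_centers_axes()[ax]
        i = int(np.searchsorted(axes_coords, coord)) - 1
        if i < 0 or i >= phi.shape[ax] - 1:
            raise GeometryError("plane lies outside the grid")
        c = (sys_.cx, sys_.cy, sys_.cz)[ax]
        sl_lo = [slice(None)] * 3
        sl_lo[ax] = i
        sl_hi = [slice(None)] * 3
        sl_hi[ax] = i + 1
        flux = c[tuple(sl_lo)] * (phi[tuple(sl_lo)] - phi[tuple(sl_hi)])
        return float(flux.sum()) * 1e3

    mask = np.asarray(surface, dtype=bool)
    if mask.shape != phi.shape:
        raise GeometryError("surface mask must match the grid shape")
    total = 0.0
    for ax, c in enumerate((sys_.cx, sys_.cy, sys_.cz)):
        sl_a = [slice(None)] * 3
        sl_a[ax] = slice(None, -1)
        sl_b = [slice(None)] * 3
        sl_b[ax] = slice(1, None)
        in_a, in_b = mask[tuple(sl_a)], mask[tuple(sl_b)]
        dphi = phi[tuple(sl_a)] - phi[tuple(sl_b)]
        # faces where a is inside and b outside: current a->b counts positive
        out_faces = in_a & ~in_b
        total += float((c[out_faces] * dphi[out_faces]).sum())
        in_faces = ~in_a & in_b
        total -= float((c[in_faces] * dphi[in_faces]).sum())
    return total * 1e3
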