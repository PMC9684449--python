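"""Conduction solver: operator structure, closed forms, conservation laws."""

import numpy as np
import pytest
import scipy.sparse as sp

from tdcsim import (
    ConductivityMap,
    Montage,
    build_study_montage,
    current_through_surface,
    disc,
    make_pad,
    scale_to_current,
    solve_montage,
)
from tdcsim.errors import SolverError
from tdcsim.phantom import CSF, GM, SKIN, SKULL, WM
from tdcsim.solver import anode_current, assemble_system, solve_potential
from tdcsim._kernels import gradient_masked
from tdcsim._multigrid import MultigridSolver, _Level


def _polar_discs(phantom, diameter_cm=1.0, current=2.0):
    sh = phantom.shape_model
    an = sh.scalp_point(np.array([0.0, 0.0, 1.0]))
    ca = sh.scalp_point(np.array([0.0, 0.0, -1.0]))
    return Montage(
        "POLES",
        [
            make_pad(an, disc(diameter_cm), "anode", phantom),
            make_pad(ca, disc(diameter_cm), "cathode", phantom),
        ],
        current,
        "test",
    )


def test_operator_is_m_matrix(coarse_phantom, coarse_eeg):
    """Symmetric, off-diagonals <= 0, zero row sums at interior nodes."""
    m = build_study_montage("APPS", coarse_phantom, coarse_eeg)
    system = assemble_system(coarse_phantom, ConductivityMap(), m)
    A = system.to_csr()
    asym = abs(A - A.T)
    assert asym.max() < 1e-12
    off = A - sp.diags(A.diagonal())
    assert off.max() <= 1e-15
    # rows without Dirichlet coupling sum to ~0 (conservation); identity rows
    # (outside) sum to 1
    rowsum = np.asarray(A.sum(axis=1)).ravel().reshape(system.rhs.shape)
    interior = system.conductive & (system.dirichlet_diag == 0)
    assert np.abs(rowsum[interior]).max() < 1e-12


def test_two_cell_chain_closed_form():
    """phi fixed at 1 and 0 on the ends of a 2-cell bar: linear potential,
    |E| = (delta phi)/L exactly."""
    h = 2.0  # mm
    h_m = h * 1e-3
    sigma = 1.0
    cx = np.full((1, 1, 1), sigma * h_m)
    cy = np.zeros((2, 0, 1))
    cz = np.zeros((2, 1, 0))
    dii = np.zeros((2, 1, 1))
    dii[0] = 2 * sigma * h_m  # Dirichlet face at the left end, phi = 1
    dii[1] = 2 * sigma * h_m  # right end, phi = 0
    rhs = np.zeros((2, 1, 1))
    rhs[0] = dii[0] * 1.0
    lv = _Level(cx, cy, cz, dii)
    import scipy.sparse.linalg as spla

    phi = spla.spsolve(lv.to_csr().tocsc(), rhs.ravel()).reshape(2, 1, 1)
    assert phi[0, 0, 0] == pytest.approx(0.75, abs=1e-12)
    assert phi[1, 0, 0] == pytest.approx(0.25, abs=1e-12)
    e = np.empty((2, 1, 1, 3))
    gradient_masked(phi, np.ones((2, 1, 1), dtype=bool), h_m, e)
    L_m = 2 * h_m
    assert abs(e[0, 0, 0, 0]) == pytest.approx(1.0 / L_m, rel=1e-12)


def test_uniform_sigma_scale_invariance(coarse_phantom):
    """Doubling a homogeneous conductivity leaves the unit-drive potential
    unchanged (Laplace scale invariance)."""
    m = _polar_discs(coarse_phantom)
    uniform = {SKIN: 0.2, SKULL: 0.2, CSF: 0.2, GM: 0.2, WM: 0.2}
    s1 = solve_potential(assemble_system(coarse_phantom, ConductivityMap(uniform), m))
    doubled = {k: 2 * v for k, v in uniform.items()}
    s2 = solve_potential(assemble_system(coarse_phantom, ConductivityMap(doubled), m))
    assert np.allclose(s1.phi, s2.phi, atol=1e-6)
    assert s2.delivered_current_mA == pytest.approx(2 * s1.delivered_current_mA, rel=1e-6)


def test_scaling_linearity(apps_solution):
    s4 = scale_to_current(apps_solution, 4.0)
    assert np.allclose(s4.e_mag, 2.0 * apps_solution.e_mag)
    assert s4.delivered_current_mA == pytest.approx(4.0)
    s0 = scale_to_current(apps_solution, 0.0)
    assert not np.any(s0.e_mag)
    assert apps_solution.delivered_current_mA == pytest.approx(2.0, rel=1e-3)


def test_emag_is_vector_norm(apps_solution):
    assert np.allclose(
        apps_solution.e_mag, np.linalg.norm(apps_solution.e_vector, axis=-1)
    )


def test_polarity_swap_antisymmetry(sphere_phantom):
    m = _polar_discs(sphere_phantom)
    swapped = Montage(
        "POLES_SWAPPED",
        [
            make_pad(m.electrodes[0].center, disc(1.0), "cathode", sphere_phantom),
            make_pad(m.electrodes[1].center, disc(1.0), "anode", sphere_phantom),
        ],
        2.0,
        "test",
    )
    s1 = solve_montage(sphere_phantom, m)
    s2 = solve_montage(sphere_phantom, swapped)
    cond = s1.system.conductive
    # potentials are mirror images around the mid-value; fields negate
    inner = cond.copy()
    inner &= sphere_phantom.tissue_mask([GM, WM])
    assert np.allclose(s1.e_vector[inner], -s2.e_vector[inner], atol=2e-4)
    assert np.allclose(s1.e_mag[inner], s2.e_mag[inner], atol=2e-4)


def test_current_conservation(apps_solution):
    """Separating plane carries the full 2 mA; a closed interior box without
    electrodes carries ~0; anode box carries +2 mA."""
    total = current_through_surface(apps_solution, ("plane", "y", 0.0))
    assert abs(total) == pytest.approx(2.0, rel=0.01)
    shape = apps_solution.phi.shape
    box = np.zeros(shape, dtype=bool)
    c = [s // 2 for s in shape]
    box[c[0] - 8: c[0] + 8, c[1] - 8: c[1] + 8, c[2] - 8: c[2] + 8] = True
    assert abs(current_through_surface(apps_solution, box)) < 0.02
    anode_box = np.zeros(shape, dtype=bool)
    anode_box[:, : c[1], :] = True  # posterior half contains the CP3 anode
    assert current_through_surface(apps_solution, anode_box) == pytest.approx(
        2.0, rel=0.01
    )


def test_mirror_symmetric_montage_field(sphere_phantom, eeg_map):
    """The bilateral C3-C4 montage on the symmetric phantom: mirroring across
    the midsagittal plane swaps anode and cathode, so |E| is symmetric."""
    m = build_study_montage("BILAT_M1", sphere_phantom, eeg_map)
    sol = solve_montage(sphere_phantom, m)
    emag = sol.e_mag
    flipped = emag[::-1, :, :]
    mask = sol.system.conductive & sol.system.conductive[::-1, :, :]
    mask &= sphere_phantom.tissue_mask([GM, WM])
    denom = np.abs(emag[mask]).max()
    assert np.abs(emag[mask] - flipped[mask]).max() < 0.02 * denom


def test_anode_current_positive(apps_solution):
    i = anode_current(
        apps_solution.system, apps_solution.phi, apps_solution.drive_scale
    )
    assert i * 1e3 == pytest.approx(2.0, rel=1e-3)


def test_solver_reports_residual(apps_solution):
    assert apps_solution.solve_residual <= 1e-8


def test_nonconvergence_raises(sphere_phantom):
    m = _polar_discs(sphere_phantom)
    system = assemble_system(sphere_phantom, ConductivityMap(), m)
    with pytest.raises(SolverError):
        solve_potential(system, tol=1e-14, maxiter=2)


def test_multigrid_galerkin_consistency(rng):
    """The coarse operator equals R A P for constant prolongation on a random
    conductance field (checked densely on a small grid)."""
    shape = (6, 6, 6)
    cx = rng.uniform(0.1, 2.0, (5, 6, 6))
    cy = rng.uniform(0.1, 2.0, (6, 5, 6))
    cz = rng.uniform(0.1, 2.0, (6, 6, 5))
    dii = np.zeros(shape)
    dii[0, :, :] = rng.uniform(0.0, 1.0, (6, 6))
    fine = _Level(cx, cy, cz, dii)
    coarse = fine.coarsen()
    A = fine.to_csr().toarray()
    Ac = coarse.to_csr().toarray()
    # prolongation matrix for 2x2x2 blocks
    n_f, n_c = 6**3, 3**3
    P = np.zeros((n_f, n_c))
    idx_f = np.arange(n_f).reshape(shape)
    idx_c = np.arange(n_c).reshape(3, 3, 3)
    for i in range(6):
        for j in range(6):
            for k in range(6):
                P[idx_f[i, j, k], idx_c[i // 2, j // 2, k // 2]] = 1.0
    assert np.allclose(P.T @ A @ P, Ac, atol=1e-10)


def test_field_export_roundtrip(tmp_path, apps_solution):
    import nibabel as nib

    path = tmp_path / "field.nii.gz"
    apps_solution.export_nifti(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    assert np.allclose(data[..., 0], apps_solution.e_mag, atol=1e-5)
    assert np.allclose(data[..., 1], apps_solution.phi, atol=1e-5)
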