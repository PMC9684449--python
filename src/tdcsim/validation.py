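"""Solver-versus-oracle validation on the unperturbed spherical phantom."""

from __future__ import annotations

import numpy as np

from .montage import Montage, disc, make_pad
from .oracle import ShellModel, shell_potential
from .phantom import ConductivityMap, PhantomSpec, build_phantom
from .solver import assemble_system, scale_to_current, solve_potential


def oracle_comparison(
    voxel_size_mm: float = 2.0,
    disc_diameter_cm: float = 1.0,
    current_mA: float = 2.0,
    series_order: int = 400,
    tol: float = 1e-8,
) -> dict:
    """Solve two scalp discs at opposite poles of the default 5-shell sphere
    and compare the potential with the analytic Legendre-series solution.

    Returns relative L2 errors over the whole conductive volume and over the
    brain (inside the CSF boundary), with both solutions in the common
    zero-mean gauge.
    """
    spec = PhantomSpec(voxel_size_mm=voxel_size_mm)
    phantom = build_phantom(spec)
    sh = phantom.shape_model
    anode_pt = sh.scalp_point(np.array([0.0, 0.0, 1.0]))
    cathode_pt = sh.scalp_point(np.array([0.0, 0.0, -1.0]))
    montage = Montage(
        "ORACLE_DISCS",
        [
            make_pad(anode_pt, disc(disc_diameter_cm), "anode", phantom),
            make_pad(cathode_pt, disc(disc_diameter_cm), "cathode", phantom),
        ],
        current_mA,
        "validation",
    )
    sigma = ConductivityMap()
    system = assemble_system(phantom, sigma, montage)
    sol = scale_to_current(solve_potential(system, tol=tol), current_mA)

    cap_angle = (disc_diameter_cm * 10.0 / 2.0) / spec.outer_radius_mm
    model = ShellModel(
        radii_mm=spec.shell_radii_mm,
        sigmas=tuple(sigma[l] for l in (1, 2, 3, 4, 5)),
        anode_dir=(0.0, 0.0, 1.0),
        cathode_dir=(0.0, 0.0, -1.0),
        cap_angle_rad=cap_angle,
        series_order=series_order,
    )
    cond = system.conductive
    ax = phantom.voxel_centers_axes()
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([X[cond], Y[cond], Z[cond]], axis=1)
    oracle = shell_potential(model, pts, current_mA)
    solver = sol.phi[cond]
    r = np.linalg.norm(pts, axis=1)
    out = {"n_voxels": int(cond.sum()), "voxel_size_mm": voxel_size_mm,
           "solve_residual": sol.solve_residual}
    for name, mask in (
        ("all", np.ones(len(pts), dtype=bool)),
        ("brain", r < spec.shell_radii_mm[2]),
    ):
        a = solver[mask] - solver[mask].mean()
        b = oracle[mask] - oracle[mask].mean()
        out[f"rel_l2_{name}"] = float(np.linalg.norm(a - b) / np.linalg.norm(b))
    return out
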