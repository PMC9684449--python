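"""Analytic Legendre-series solution for concentric multi-shell spheres.

Ground truth for the voxel solver: a layered sphere (radii strictly
decreasing, one conductivity per layer) driven by a surface current source
and sink, either point electrodes or uniform-current spherical caps.  For
each harmonic degree l the potential in layer j is

    phi_j(r, gamma) = (A_jl x^l + B_jl x^-(l+1)) P_l(cos gamma),   x = r/R

with B = 0 in the core.  Coefficients propagate outward through the
interfaces (continuity of phi and of sigma dphi/dr) and are scaled to match
the Neumann condition sigma dphi/dr = j_l at the outer surface, where j_l is
the Legendre expansion of the injected current density (a delta for point
electrodes, a uniform cap density otherwise).  The l = 0 term vanishes for a
balanced source/sink pair, which also fixes the zero-mean-over-surface gauge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numba as nb
import numpy as np

from .errors import InvalidSpecError

MM = 1e-3


@dataclass(frozen=True)
class ShellModel:
    """Concentric-shell sphere with one surface anode and one cathode."""

    radii_mm: tuple                 # strictly decreasing, outermost first
    sigmas: tuple                   # S/m per layer, same order
    anode_dir: tuple = (0.0, 0.0, 1.0)
    cathode_dir: tuple = (0.0, 0.0, -1.0)
    cap_angle_rad: float = 0.0      # 0 => point electrodes
    series_order: int = 300

    def __post_init__(self):
        r = np.asarray(self.radii_mm, dtype=float)
        if np.any(np.diff(r) >= 0) or np.any(r <= 0):
            raise InvalidSpecError("radii must be positive, strictly decreasing")
        if len(self.sigmas) != len(r):
            raise InvalidSpecError("need one conductivity per layer")
        if any(s <= 0 for s in self.sigmas):
            raise InvalidSpecError("conductivities must be > 0")
        if self.series_order < 1:
            raise InvalidSpecError("series_order must be >= 1")
        if not 0 <= self.cap_angle_rad < np.pi / 2:
            raise InvalidSpecError("cap angle must be in [0, pi/2)")

    @property
    def n_layers(self) -> int:
        return len(self.radii_mm)


def _legendre_at(x: float, lmax: int) -> np.ndarray:
    out = np.empty(lmax + 1)
    out[0] = 1.0
    if lmax >= 1:
        out[1] = x
    for l in range(2, lmax + 1):
        out[l] = ((2 * l - 1) * x * out[l - 1] - (l - 1) * out[l - 2]) / l
    return out


def _source_coeffs(model: ShellModel) -> np.ndarray:
    """j_l for unit current (1 A) injected at the pole, l = 0..L."""
    L = model.series_order
    R = model.radii_mm[0] * MM
    l = np.arange(L + 1, dtype=float)
    if model.cap_angle_rad == 0.0:
        return (2.0 * l + 1.0) / (4.0 * np.pi * R * R)
    ca = float(np.cos(model.cap_angle_rad))
    P = _legendre_at(ca, L + 1)
    j0 = 1.0 / (2.0 * np.pi * R * R * (1.0 - ca))  # uniform cap density
    out = np.empty(L + 1)
    out[0] = j0 * (1.0 - ca) / 2.0
    for ll in range(1, L + 1):
        out[ll] = j0 * (P[ll - 1] - P[ll + 1]) / 2.0
    return out


def _layer_coefficients(model: ShellModel) -> tuple:
    """(A, B) arrays of shape (L+1, n_layers) for unit current at the pole.

    Layers are ordered as in the model (outermost first); radii are
    normalised by the outer radius.  l = 0 row is zero (gauge / balanced
    pair).
    """
    L = model.series_order
    nlay = model.n_layers
    x_if = np.asarray(model.radii_mm[1:], dtype=float) / model.radii_mm[0]
    sig = np.asarray(model.sigmas, dtype=float)
    R = model.radii_mm[0] * MM
    jl = _source_coeffs(model)
    A = np.zeros((L + 1, nlay))
    B = np.zeros((L + 1, nlay))
    for l in range(1, L + 1):
        a = np.zeros(nlay)
        b = np.zeros(nlay)
        a[nlay - 1] = 1.0  # core: regular solution only
        for j in range(nlay - 1, 0, -1):
            # interface at x_if[j-1] between inner layer j and outer j-1
            xi = x_if[j - 1]
            xl = xi**l
            xm = xi ** (-(l + 1))
            phi = a[j] * xl + b[j] * xm
            dphi = sig[j] * (l * a[j] * xl / xi - (l + 1) * b[j] * xm / xi)
            # solve for outer-layer coefficients
            m11, m12 = xl, xm
            m21 = sig[j - 1] * l * xl / xi
            m22 = -sig[j - 1] * (l + 1) * xm / xi
            det = m11 * m22 - m12 * m21
            a[j - 1] = (phi * m22 - m12 * dphi) / det
            b[j - 1] = (m11 * dphi - phi * m21) / det
        # outer Neumann: sigma dphi/dr(R) = jl
        deriv = sig[0] * (l * a[0] - (l + 1) * b[0]) / R
        if deriv == 0.0:
            continue
        c = jl[l] / deriv
        A[l] = a * c
        B[l] = b * c
    return A, B


@nb.njit(cache=True, fastmath=True)
def _series_eval(rnorm, cosg, region, A, B, pot, dpot_dr, dpot_scaled):
    """Accumulate the Legendre series and its derivatives per point.

    pot: sum coef_l(x) P_l(cos g)
    dpot_dr: sum dcoef_l/dx P_l (radial derivative wrt x)
    dpot_scaled: sum coef_l(x) P_l'(cos g)  (for the tangential component)
    """
    n = rnorm.shape[0]
    L = A.shape[0] - 1
    for p in range(n):
        x = rnorm[p]
        cg = cosg[p]
        reg = region[p]
        pl_m1 = 1.0  # P_0
        pl = cg      # P_1
        dp_m1 = 0.0  # P_0'
        dp = 1.0     # P_1'
        xl = x       # x^l at l=1
        xinv = 1.0 / (x * x)  # x^-(l+1) at l=1
        acc = 0.0
        accr = 0.0
        acct = 0.0
        for l in range(1, L + 1):
            if l > 1:
                plp = ((2 * l - 1) * cg * pl - (l - 1) * pl_m1) / l
                dpp = dp_m1 + (2 * l - 1) * pl
                pl_m1 = pl
                pl = plp
                dp_m1 = dp
                dp = dpp
                xl *= x
                xinv /= x
            a = A[l, reg]
            b = B[l, reg]
            coef = a * xl
            dcoef = l * a * xl / x
            if b != 0.0:  # core has B = 0 while x^-(l+1) overflows near 0
                coef += b * xinv
                dcoef -= (l + 1) * b * xinv / x
            acc += coef * pl
            accr += dcoef * pl
            acct += coef * dp
        pot[p] += acc
        dpot_dr[p] += accr
        dpot_scaled[p] += acct


def _regions(model: ShellModel, rnorm: np.ndarray) -> np.ndarray:
    bounds = np.asarray(model.radii_mm[1:], dtype=float) / model.radii_mm[0]
    # region index: 0 outermost layer ... n-1 core
    return np.searchsorted(-bounds, -rnorm, side="right").astype(np.int64)


def _eval_electrode(model, pts_mm, sign, direction, A, B, want_field):
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    R = model.radii_mm[0]
    r = np.linalg.norm(pts_mm, axis=1)
    if np.any(r > R * (1 + 1e-9)):
        raise InvalidSpecError("evaluation points must lie inside the outer radius")
    rnorm = np.clip(r / R, 1e-9, 1.0)
    rhat = np.zeros_like(pts_mm)
    nz = r > 0
    rhat[nz] = pts_mm[nz] / r[nz, None]
    cosg = np.clip(rhat @ d, -1.0, 1.0)
    region = _regions(model, rnorm)
    pot = np.zeros(len(pts_mm))
    dpr = np.zeros(len(pts_mm))
    dps = np.zeros(len(pts_mm))
    _series_eval(rnorm, cosg, region, A, B, pot, dpr, dps)
    pot *= sign
    if not want_field:
        return pot, None
    R_m = R * MM
    # E = -dphi/dr rhat + (1/r) coef P_l' (cos g rhat - d); the second factor
    # absorbs sin(gamma) so the axis is regular
    r_m = np.maximum(rnorm * R_m, 1e-6)
    Er = -(sign * dpr / R_m)[:, None] * rhat
    Et = (sign * dps / r_m)[:, None] * (cosg[:, None] * rhat - d[None, :])
    return pot, Er + Et


class _CoeffCache:
    _store: dict = {}

    @classmethod
    def get(cls, model: ShellModel):
        key = (model.radii_mm, model.sigmas, model.cap_angle_rad, model.series_order)
        if key not in cls._store:
            cls._store[key] = _layer_coefficients(model)
            if len(cls._store) > 16:
                cls._store.pop(next(iter(cls._store)))
        return cls._store[key]


def _check_convergence(model: ShellModel, A: np.ndarray, B: np.ndarray) -> None:
    # tail estimate at the outer surface (x = 1), where decay is slowest
    surf = np.abs(A[:, 0] + B[:, 0])
    total = surf.sum()
    tail = surf[-10:].sum()
    if total > 0 and tail / total > 1e-2:
        warnings.warn(
            "Legendre series may be truncated too early "
            f"(tail fraction {tail / total:.2e}); increase series_order",
            stacklevel=3,
        )


def shell_potential(model: ShellModel, eval_points_mm, current_mA: float) -> np.ndarray:
    """Potential (V) at interior points for +I at the anode, -I at the cathode.

    Gauge: zero mean over the outer surface.
    """
    pts = np.atleast_2d(np.asarray(eval_points_mm, dtype=float))
    A, B = _CoeffCache.get(model)
    _check_convergence(model, A, B)
    I = current_mA * 1e-3
    pa, _ = _eval_electrode(model, pts, +I, model.anode_dir, A, B, False)
    pc, _ = _eval_electrode(model, pts, -I, model.cathode_dir, A, B, False)
    return pa + pc


def shell_efield(model: ShellModel, eval_points_mm, current_mA: float) -> np.ndarray:
    """Electric field vectors (V/m) at interior points."""
    pts = np.atleast_2d(np.asarray(eval_points_mm, dtype=float))
    A, B = _CoeffCache.get(model)
    _check_convergence(model, A, B)
    I = current_mA * 1e-3
    _, ea = _eval_electrode(model, pts, +I, model.anode_dir, A, B, True)
    _, ec = _eval_electrode(model, pts, -I, model.cathode_dir, A, B, True)
    return ea + ec


def homogeneous_point_potential(
    radius_mm: float, sigma: float, anode_dir, cathode_dir,
    eval_points_mm, current_mA: float, order: int = 300,
) -> np.ndarray:
    """Closed-form series for a homogeneous sphere with two point electrodes.

    phi = I/(4 pi sigma R) sum_l (2l+1)/l (r/R)^l P_l(cos gamma), superposed
    for source and sink; independent reduction used as a test oracle.
    """
    pts = np.atleast_2d(np.asarray(eval_points_mm, dtype=float))
    R_m = radius_mm * MM
    I = current_mA * 1e-3
    out = np.zeros(len(pts))
    r = np.linalg.norm(pts, axis=1)
    rnorm = np.clip(r / radius_mm, 0.0, 1.0)
    rhat = np.zeros_like(pts)
    nz = r > 0
    rhat[nz] = pts[nz] / r[nz, None]
    for sign, d in ((+1.0, anode_dir), (-1.0, cathode_dir)):
        d = np.asarray(d, dtype=float)
        d = d / np.linalg.norm(d)
        cosg = np.clip(rhat @ d, -1.0, 1.0)
        acc = np.zeros(len(pts))
        pl_m1 = np.ones(len(pts))
        pl = cosg.copy()
        xl = rnorm.copy()
        for l in range(1, order + 1):
            if l > 1:
                plp = ((2 * l - 1) * cosg * pl - (l - 1) * pl_m1) / l
                pl_m1, pl = pl, plp
                xl = xl * rnorm
            acc += (2 * l + 1) / l * xl * pl
        out += sign * I / (4.0 * np.pi * sigma * R_m) * acc
    return out
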