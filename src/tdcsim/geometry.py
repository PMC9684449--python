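"""Analytic star-shaped head geometry and on-surface arc computations.

The phantom geometry is star-shaped around its centre: every tissue boundary is
a radial surface ``r_k(d) = R_k * a(d) * g(d)`` where ``R_k`` is the nominal
shell radius, ``a(d)`` the ellipsoidal direction factor and ``g(d)`` a smooth
low-order angular perturbation shared by all shells.  Sharing ``a*g`` across
shells makes nesting structural: boundaries can never cross for positive
factors.

Scalp "geodesics" are realised as central-section arcs: the curve obtained by
rotating a direction inside the plane spanned by two directions and radially
projecting onto the surface.  On a sphere these are exact great-circle
geodesics; on mildly ellipsoidal/perturbed heads they are short, near-geodesic
curves, which is the accuracy regime the 10-10 construction and electrode
footprints need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError

# Low-order real harmonic basis used for the surface perturbation, written as
# polynomials in the direction components (l=2 and l=3 sectorial/tesseral
# shapes; l=0,1 are excluded so the perturbation neither rescales nor
# translates the head).
_HARMONICS = (
    lambda x, y, z: 0.5 * (3.0 * z * z - 1.0),
    lambda x, y, z: x * y,
    lambda x, y, z: x * z,
    lambda x, y, z: y * z,
    lambda x, y, z: x * x - y * y,
    lambda x, y, z: 0.5 * z * (5.0 * z * z - 3.0),
    lambda x, y, z: x * (x * x - 3.0 * y * y),
    lambda x, y, z: y * (3.0 * x * x - y * y),
)


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n == 0):
        raise GeometryError("cannot normalise zero vector")
    return v / n


@dataclass(frozen=True)
class RadialHeadModel:
    """Analytic radial geometry of a nested-shell head.

    Parameters
    ----------
    shell_radii_mm:
        Outer radius of each shell, strictly decreasing (skin, skull, csf,
        gm, wm outer boundaries).
    axis_ratios:
        Semi-axis multipliers (right-left, anterior-posterior,
        superior-inferior) applied to all shells.
    perturbation_amplitude_mm:
        Peak radial displacement of the scalp produced by the harmonic
        perturbation, in mm.
    harmonic_coeffs:
        Coefficients of the harmonic basis (len == 8).  All zero means a pure
        ellipsoid.
    center_mm:
        World position of the head centre (RAS, mm).
    """

    shell_radii_mm: tuple
    axis_ratios: tuple = (1.0, 1.0, 1.0)
    perturbation_amplitude_mm: float = 0.0
    harmonic_coeffs: tuple = (0.0,) * len(_HARMONICS)
    center_mm: tuple = (0.0, 0.0, 0.0)
    _pert_scale: float = field(init=False, default=0.0)

    def __post_init__(self):
        radii = np.asarray(self.shell_radii_mm, dtype=float)
        if np.any(np.diff(radii) >= 0) or np.any(radii <= 0):
            raise GeometryError("shell radii must be positive and strictly decreasing")
        if self.perturbation_amplitude_mm < 0:
            raise GeometryError("perturbation amplitude must be >= 0")
        if self.perturbation_amplitude_mm > 0.2 * radii[0]:
            # keeps g(d) well away from zero so per-ray shell thicknesses stay
            # positive and the surface remains star-shaped
            raise GeometryError(
                "perturbation amplitude exceeds 20% of the outer radius; "
                "shell nesting can no longer be guaranteed"
            )
        coeffs = np.asarray(self.harmonic_coeffs, dtype=float)
        scale = 0.0
        if self.perturbation_amplitude_mm > 0 and np.any(coeffs != 0):
            # normalise so that max |h| over the sphere ~ 1, estimated on a
            # dense deterministic direction sample
            dirs = _fibonacci_sphere(2048)
            h = self._raw_harmonic(dirs)
            m = float(np.max(np.abs(h)))
            if m > 0:
                scale = self.perturbation_amplitude_mm / (m * radii[0])
        object.__setattr__(self, "_pert_scale", scale)

    # -- radial functions --------------------------------------------------

    def _raw_harmonic(self, dirs: np.ndarray) -> np.ndarray:
        x, y, z = dirs[..., 0], dirs[..., 1], dirs[..., 2]
        out = np.zeros(dirs.shape[:-1])
        for c, f in zip(self.harmonic_coeffs, _HARMONICS):
            if c != 0.0:
                out += c * f(x, y, z)
        return out

    def ellipsoid_factor(self, dirs: np.ndarray) -> np.ndarray:
        """a(d): radius multiplier of the unit-mean ellipsoid along d."""
        a = np.asarray(self.axis_ratios, dtype=float)
        q = (dirs / a) ** 2
        return 1.0 / np.sqrt(q.sum(axis=-1))

    def perturbation_factor(self, dirs: np.ndarray) -> np.ndarray:
        """g(d) = 1 + amplitude-scaled harmonic perturbation."""
        if self._pert_scale == 0.0:
            return np.ones(dirs.shape[:-1])
        return 1.0 + self._pert_scale * self._raw_harmonic(dirs)

    def angular_factor(self, dirs: np.ndarray) -> np.ndarray:
        return self.ellipsoid_factor(dirs) * self.perturbation_factor(dirs)

    def shell_radius(self, shell: int, dirs: np.ndarray) -> np.ndarray:
        """Radius of shell boundary `shell` (0 = scalp) along directions."""
        return self.shell_radii_mm[shell] * self.angular_factor(dirs)

    def scalp_radius(self, dirs: np.ndarray) -> np.ndarray:
        return self.shell_radius(0, dirs)

    # -- point utilities ---------------------------------------------------

    def directions(self, points: np.ndarray) -> np.ndarray:
        """Unit directions from the head centre to world points."""
        return _unit(np.asarray(points, dtype=float) - np.asarray(self.center_mm))

    def scalp_point(self, dirs: np.ndarray) -> np.ndarray:
        dirs = np.asarray(dirs, dtype=float)
        r = self.scalp_radius(dirs)
        return np.asarray(self.center_mm) + dirs * r[..., None]

    def label_points(self, points: np.ndarray, labels_inward: np.ndarray) -> np.ndarray:
        """Tissue label for world points.

        `labels_inward` maps shell index -> label, e.g. [1,2,3,4,5] for
        skin..wm.  Points outside the scalp get 0.
        """
        pts = np.asarray(points, dtype=float) - np.asarray(self.center_mm)
        rad = np.linalg.norm(pts, axis=-1)
        out = np.zeros(rad.shape, dtype=np.int8)
        nz = rad > 0
        dirs = np.zeros_like(pts)
        dirs[nz] = pts[nz] / rad[nz, None]
        fac = self.angular_factor(dirs)
        # normalised radius: compare against nominal shell radii
        s = np.full(rad.shape, np.inf)
        s[nz] = rad[nz] / fac[nz]
        radii = np.asarray(self.shell_radii_mm)
        # innermost shell first: assign the deepest label whose boundary
        # contains the point
        for shell in range(len(radii)):
            out[s <= radii[shell]] = labels_inward[shell]
        out[~nz] = labels_inward[-1]
        return out

    # -- arcs and geodesics ------------------------------------------------

    def _plane_basis(self, dir_a: np.ndarray, dir_b: np.ndarray):
        e1 = _unit(dir_a)
        b = _unit(dir_b)
        w = b - (b @ e1) * e1
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            raise GeometryError("arc endpoints are collinear with the centre")
        return e1, w / nw

    def arc_points(self, point_a, point_b, n: int = 257, via=None):
        """Sample the central-section arc from A to B on the scalp.

        Returns (points (n,3), cumulative arc length (n,)).  For
        nearly-antipodal endpoints a `via` point must select the hemisphere.
        """
        da = self.directions(point_a)
        db = self.directions(point_b)
        cosang = float(np.clip(da @ db, -1.0, 1.0))
        if via is not None:
            dv = self.directions(via)
            e1, e2 = self._plane_basis(da, dv)
        else:
            if cosang < -0.999:
                raise GeometryError(
                    "arc endpoints are nearly antipodal; pass a 'via' point"
                )
            e1, e2 = self._plane_basis(da, db)
        theta_b = float(np.arctan2(db @ e2, db @ e1)) % (2.0 * np.pi)
        phis = np.linspace(0.0, theta_b, n)
        dirs = np.outer(np.cos(phis), e1) + np.outer(np.sin(phis), e2)
        pts = self.scalp_point(dirs)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        return pts, s

    def arc_length(self, point_a, point_b, n: int = 257, via=None) -> float:
        _, s = self.arc_points(point_a, point_b, n=n, via=via)
        return float(s[-1])

    def arc_fraction_point(self, point_a, point_b, frac: float, n: int = 513, via=None):
        """Point at arc-length fraction `frac` of the arc from A to B."""
        pts, s = self.arc_points(point_a, point_b, n=n, via=via)
        target = frac * s[-1]
        i = int(np.searchsorted(s, target))
        i = min(max(i, 1), len(s) - 1)
        t = (target - s[i - 1]) / max(s[i] - s[i - 1], 1e-300)
        p = pts[i - 1] + t * (pts[i] - pts[i - 1])
        # re-project radially onto the scalp
        return self.scalp_point(self.directions(p))

    def geodesic_distance(self, point_a, points_b, n: int = 129) -> np.ndarray:
        """Arc length from A to each point in `points_b` (vectorised)."""
        pb = np.atleast_2d(np.asarray(points_b, dtype=float))
        da = self.directions(point_a)
        db = self.directions(pb)
        cosang = np.clip(db @ da, -1.0, 1.0)
        w = db - cosang[:, None] * da
        nw = np.linalg.norm(w, axis=1)
        theta = np.arccos(cosang)
        out = np.zeros(len(pb))
        ok = nw > 1e-12
        if np.any(ok):
            e2 = w[ok] / nw[ok, None]
            t = np.linspace(0.0, 1.0, n)
            phis = theta[ok, None] * t[None, :]
            dirs = (
                np.cos(phis)[..., None] * da[None, None, :]
                + np.sin(phis)[..., None] * e2[:, None, :]
            )
            r = self.scalp_radius(dirs)
            pts = dirs * r[..., None]
            seg = np.linalg.norm(np.diff(pts, axis=1), axis=2)
            out[ok] = seg.sum(axis=1)
        return out

    def tangent_basis(self, point) -> tuple:
        """Orthonormal basis of the tangent plane at a scalp point.

        Uses the radial direction as the (approximate) surface normal, which
        is exact on spheres and adequate for mild ellipticity/perturbation.
        """
        d = self.directions(point)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(d @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = _unit(ref - (ref @ d) * d)
        e2 = np.cross(d, e1)
        return e1, e2

    def tangent_toward(self, point_a, point_b) -> np.ndarray:
        """Unit tangent at A of the central-section arc A -> B."""
        da = self.directions(point_a)
        db = self.directions(point_b)
        _, e2 = self._plane_basis(da, db)
        return e2

    def walk(self, point, tangent, distance_mm: float, step_mm: float = 0.25):
        """Walk `distance_mm` along the central-section arc leaving `point`
        with initial tangent `tangent`; returns the end point."""
        if distance_mm == 0.0:
            return self.scalp_point(self.directions(point))
        d0 = self.directions(point)
        t = np.asarray(tangent, dtype=float)
        t = _unit(t - (t @ d0) * d0)
        # march in angle until the cumulative arc length reaches the target
        r0 = float(self.scalp_radius(d0))
        dphi = step_mm / r0
        max_steps = min(int(2.0 * np.pi / dphi) + 2, int(1.8 * distance_mm / step_mm) + 8)
        phis = np.arange(max_steps + 1) * dphi
        dirs = np.outer(np.cos(phis), d0) + np.outer(np.sin(phis), t)
        pts = self.scalp_point(dirs)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        if distance_mm > s[-1]:
            raise GeometryError("walk distance exceeds the closed arc length")
        i = int(np.searchsorted(s, distance_mm))
        i = min(max(i, 1), len(s) - 1)
        frac = (distance_mm - s[i - 1]) / max(s[i] - s[i - 1], 1e-300)
        p = pts[i - 1] + frac * (pts[i] - pts[i - 1])
        return self.scalp_point(self.directions(p))

    def log_map(self, center_point, points) -> np.ndarray:
        """Azimuthal-equidistant coordinates of scalp points around a centre.

        Returns (n, 2) coordinates (u, v) in mm in the basis returned by
        :meth:`tangent_basis` at `center_point`.  Exact on spheres.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        dc = self.directions(center_point)
        e1, e2 = self.tangent_basis(center_point)
        dp = self.directions(pts)
        cosang = np.clip(dp @ dc, -1.0, 1.0)
        w = dp - cosang[:, None] * dc
        nw = np.linalg.norm(w, axis=1)
        dist = self.geodesic_distance(center_point, pts)
        uv = np.zeros((len(pts), 2))
        ok = nw > 1e-12
        tw = np.zeros_like(w)
        tw[ok] = w[ok] / nw[ok, None]
        uv[:, 0] = dist * (tw @ e1)
        uv[:, 1] = dist * (tw @ e2)
        return uv

    def exp_map(self, center_point, uv: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`log_map`: map tangent coordinates to scalp points."""
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        e1, e2 = self.tangent_basis(center_point)
        d0 = self.directions(center_point)
        dist = np.hypot(uv[:, 0], uv[:, 1])
        out = np.tile(self.scalp_point(d0), (len(uv), 1))
        ok = dist > 1e-12
        if not np.any(ok):
            return out
        tan = (uv[ok, 0, None] * e1 + uv[ok, 1, None] * e2) / dist[ok, None]
        # batched angular march: common angle grid, per-point arc-length lookup
        r0 = float(self.scalp_radius(d0))
        dmax = float(dist[ok].max())
        nphi = max(int(1.8 * dmax / 0.25) + 8, 16)
        phis = np.linspace(0.0, min(1.6 * dmax / r0 + 0.05, 2.0 * np.pi), nphi)
        dirs = (
            np.cos(phis)[None, :, None] * d0[None, None, :]
            + np.sin(phis)[None, :, None] * tan[:, None, :]
        )
        pts = self.scalp_point(dirs)
        seg = np.linalg.norm(np.diff(pts, axis=1), axis=2)
        s = np.concatenate([np.zeros((seg.shape[0], 1)), np.cumsum(seg, axis=1)], axis=1)
        if np.any(dist[ok] > s[:, -1]):
            raise GeometryError("exp_map distance exceeds the sampled arc")
        res = np.empty((ok.sum(), 3))
        for j in range(ok.sum()):
            i = int(np.searchsorted(s[j], dist[ok][j]))
            i = min(max(i, 1), s.shape[1] - 1)
            t = (dist[ok][j] - s[j, i - 1]) / max(s[j, i] - s[j, i - 1], 1e-300)
            res[j] = pts[j, i - 1] + t * (pts[j, i] - pts[j, i - 1])
        out[ok] = self.scalp_point(self.directions(res))
        return out


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform direction sample."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
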