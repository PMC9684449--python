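"""Synthetic multi-compartment head phantoms.

A phantom is a voxelised stack of five nested tissue shells — skin, skull,
cerebrospinal fluid (CSF), grey matter and white matter — built from an
analytic star-shaped geometry (:class:`~tdcsim.geometry.RadialHeadModel`).
Default nominal shell radii are 92/86/80/78/70 mm, a typical adult head scale,
giving 6 mm skin, 6 mm skull, 2 mm CSF and 8 mm grey-matter shells.  A
population generator draws per-subject variation in overall size, skull
thickness, CSF depth and global shape (ellipsoidal axis ratios plus a smooth
low-order surface perturbation).

Coordinate conventions: world frame is RAS in mm (+x right, +y anterior,
+z superior), voxel indices are 0-based and voxel centres sit at
``origin + (index + 0.5) * voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Mapping

import numpy as np

from .errors import GeometryError, InvalidSpecError
from .geometry import RadialHeadModel

# Tissue labels, ordered from outside in.
OUTSIDE, SKIN, SKULL, CSF, GM, WM = 0, 1, 2, 3, 4, 5
TISSUE_NAMES = {OUTSIDE: "outside", SKIN: "skin", SKULL: "skull",
                CSF: "csf", GM: "gm", WM: "wm"}
_LABELS_INWARD = np.array([SKIN, SKULL, CSF, GM, WM], dtype=np.int8)

#: Tissue conductivities in S/m.  Skull is the strong insulator (two orders of
#: magnitude below skin) and CSF the strong conductor; this contrast drives
#: the current shunting that tDCS dosimetry has to model.
DEFAULT_CONDUCTIVITIES: Mapping[int, float] = {
    SKIN: 0.465,
    SKULL: 0.01,
    CSF: 1.654,
    GM: 0.275,
    WM: 0.126,
}

LANDMARK_DIRECTIONS = {
    "nasion": np.array([0.0, 1.0, 0.0]),
    "inion": np.array([0.0, -1.0, 0.0]),
    "lpa": np.array([-1.0, 0.0, 0.0]),
    "rpa": np.array([1.0, 0.0, 0.0]),
    "vertex": np.array([0.0, 0.0, 1.0]),
}


@dataclass(frozen=True)
class ConductivityMap:
    """Tissue label -> conductivity (S/m)."""

    values: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDUCTIVITIES)
    )

    def __post_init__(self):
        for label, sigma in self.values.items():
            if sigma <= 0:
                raise InvalidSpecError(
                    f"conductivity for tissue {label} must be > 0, got {sigma}"
                )

    def __getitem__(self, label: int) -> float:
        return self.values[label]

    def as_array(self, n_labels: int = 6) -> np.ndarray:
        """Dense lookup array indexed by tissue label (0 for outside)."""
        out = np.zeros(n_labels)
        for label, sigma in self.values.items():
            out[label] = sigma
        return out


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic head.

    ``thickness_mm`` holds shell thicknesses for skin, skull, csf and gm;
    white matter fills the remainder of the head.
    """

    outer_radius_mm: float = 92.0
    thickness_mm: Mapping[str, float] = field(
        default_factory=lambda: {"skin": 6.0, "skull": 6.0, "csf": 2.0, "gm": 8.0}
    )
    ellipsoid_axis_ratios: tuple = (1.0, 1.0, 1.0)
    perturbation_amplitude_mm: float = 0.0
    voxel_size_mm: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.voxel_size_mm <= 0:
            raise InvalidSpecError("voxel_size_mm must be > 0")
        if self.outer_radius_mm <= 0:
            raise InvalidSpecError("outer_radius_mm must be > 0")
        missing = {"skin", "skull", "csf", "gm"} - set(self.thickness_mm)
        if missing:
            raise InvalidSpecError(f"missing shell thicknesses: {sorted(missing)}")
        for name, t in self.thickness_mm.items():
            if t <= 0:
                raise InvalidSpecError(f"{name} thickness must be > 0, got {t}")
        if sum(self.thickness_mm.values()) >= self.outer_radius_mm:
            raise InvalidSpecError("shell thicknesses exceed the outer radius")
        if any(a <= 0 for a in self.ellipsoid_axis_ratios):
            raise InvalidSpecError("axis ratios must be > 0")
        if self.perturbation_amplitude_mm < 0:
            raise InvalidSpecError("perturbation amplitude must be >= 0")

    @property
    def shell_radii_mm(self) -> tuple:
        t = self.thickness_mm
        r0 = self.outer_radius_mm
        r1 = r0 - t["skin"]
        r2 = r1 - t["skull"]
        r3 = r2 - t["csf"]
        r4 = r3 - t["gm"]
        return (r0, r1, r2, r3, r4)


@dataclass(frozen=True)
class HeadPhantom:
    """One voxelised synthetic participant."""

    label_grid: np.ndarray          # (nx, ny, nz) int8 tissue labels
    voxel_size_mm: float
    origin_mm: np.ndarray           # world position of the grid corner
    landmarks: Mapping[str, np.ndarray]
    shape_model: RadialHeadModel    # analytic geometry behind the voxels
    spec: PhantomSpec

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[:3, :3] *= self.voxel_size_mm
        a[:3, 3] = self.origin_mm
        return a

    def voxel_centers_axes(self):
        """Per-axis world coordinates of voxel centres."""
        return tuple(
            self.origin_mm[k] + (np.arange(self.label_grid.shape[k]) + 0.5)
            * self.voxel_size_mm
            for k in range(3)
        )

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.floor((pts - self.origin_mm) / self.voxel_size_mm).astype(int)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return self.origin_mm + (idx + 0.5) * self.voxel_size_mm

    def tissue_mask(self, labels) -> np.ndarray:
        labels = np.atleast_1d(labels)
        return np.isin(self.label_grid, labels)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size_mm**3)

    def head_volume_mm3(self) -> float:
        return float(np.count_nonzero(self.label_grid)) * self.voxel_volume_mm3

    @cached_property
    def scalp_surface(self):
        """Triangulated scalp surface (vertices_mm, faces) via marching cubes."""
        from skimage.measure import marching_cubes

        vol = (self.label_grid > 0).astype(np.float32)
        verts, faces, _, _ = marching_cubes(vol, level=0.5)
        verts = self.origin_mm + (verts + 0.5) * self.voxel_size_mm
        return verts, faces

    def translated(self, shift_mm) -> "HeadPhantom":
        """Rigidly translate the phantom (grid origin, landmarks, shape)."""
        shift = np.asarray(shift_mm, dtype=float)
        from dataclasses import replace as _replace

        shape = _replace(
            self.shape_model,
            center_mm=tuple(np.asarray(self.shape_model.center_mm) + shift),
        )
        return HeadPhantom(
            label_grid=self.label_grid,
            voxel_size_mm=self.voxel_size_mm,
            origin_mm=self.origin_mm + shift,
            landmarks={k: v + shift for k, v in self.landmarks.items()},
            shape_model=shape,
            spec=self.spec,
        )

    def export_nifti(self, path) -> None:
        import nibabel as nib

        img = nib.Nifti1Image(self.label_grid.astype(np.uint8), self.affine)
        nib.save(img, str(path))


def load_nifti_labels(path):
    """Read back a label volume written by :meth:`HeadPhantom.export_nifti`.

    Returns (label_grid, voxel_size_mm, origin_mm); the analytic shape model
    is not recoverable from the file.
    """
    import nibabel as nib

    img = nib.load(str(path))
    grid = np.asarray(img.dataobj).astype(np.int8)
    aff = img.affine
    voxel = float(aff[0, 0])
    origin = np.asarray(aff[:3, 3], dtype=float)
    return grid, voxel, origin


def _harmonic_coeffs(seed: int) -> tuple:
    rng = np.random.default_rng(seed)
    return tuple(rng.standard_normal(8))


def build_phantom(spec: PhantomSpec) -> HeadPhantom:
    """Voxelise a phantom spec into a labelled head volume.

    Deterministic: the same spec (including seed) always yields a
    byte-identical label grid.
    """
    if not isinstance(spec, PhantomSpec):
        raise InvalidSpecError("build_phantom expects a PhantomSpec")
    coeffs = (
        _harmonic_coeffs(spec.seed)
        if spec.perturbation_amplitude_mm > 0
        else (0.0,) * 8
    )
    try:
        shape = RadialHeadModel(
            shell_radii_mm=spec.shell_radii_mm,
            axis_ratios=tuple(spec.ellipsoid_axis_ratios),
            perturbation_amplitude_mm=spec.perturbation_amplitude_mm,
            harmonic_coeffs=coeffs,
        )
    except GeometryError:
        raise
    # bounding box with one voxel of outside padding on each side
    h = spec.voxel_size_mm
    semi = spec.outer_radius_mm * np.asarray(spec.ellipsoid_axis_ratios)
    semi = semi * (1.0 + 1.2 * spec.perturbation_amplitude_mm / spec.outer_radius_mm)
    n = np.ceil(semi / h).astype(int) + 2
    dims = 2 * n
    origin = -n * h
    ax = [origin[k] + (np.arange(dims[k]) + 0.5) * h for k in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    labels = shape.label_points(pts, _LABELS_INWARD).reshape(tuple(dims))
    landmarks = {
        name: shape.scalp_point(d) for name, d in LANDMARK_DIRECTIONS.items()
    }
    return HeadPhantom(
        label_grid=labels,
        voxel_size_mm=h,
        origin_mm=origin.astype(float),
        landmarks=landmarks,
        shape_model=shape,
        spec=spec,
    )


#: Population variability used for study cohorts: ranges for uniform draws.
#: Chosen to bracket adult head-size and tissue-depth variation around the
#: default phantom (overall scale +-5%, skull 4-9 mm, CSF 1-3 mm, mild
#: anterior-posterior elongation as in real heads).
DEFAULT_VARIABILITY: Mapping[str, tuple] = {
    "outer_radius_mm": (87.0, 97.0),
    "skin": (5.0, 7.0),
    "skull": (4.0, 9.0),
    "csf": (1.0, 3.0),
    "gm": (7.0, 9.0),
    "axis_rl": (0.94, 1.02),
    "axis_ap": (1.00, 1.12),
    "axis_si": (0.96, 1.06),
    "perturbation_amplitude_mm": (0.0, 2.5),
}


def sample_population(
    n: int,
    variability: Mapping[str, tuple] | None = None,
    seed: int = 0,
    voxel_size_mm: float = 2.0,
) -> list:
    """Draw `n` independent phantom specs from uniform parameter ranges."""
    if n < 0:
        raise InvalidSpecError("population size must be >= 0")
    ranges = dict(DEFAULT_VARIABILITY)
    if variability:
        ranges.update(variability)
    for key, (lo, hi) in ranges.items():
        if hi < lo:
            raise InvalidSpecError(f"invalid range for {key}: ({lo}, {hi})")
    # reject ranges that could produce non-nesting shells
    max_thick = sum(ranges[k][1] for k in ("skin", "skull", "csf", "gm"))
    if max_thick >= ranges["outer_radius_mm"][0]:
        raise InvalidSpecError(
            "thickness ranges permit shells thicker than the smallest head"
        )
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n):
        u = {k: rng.uniform(lo, hi) for k, (lo, hi) in ranges.items()}
        specs.append(
            PhantomSpec(
                outer_radius_mm=u["outer_radius_mm"],
                thickness_mm={
                    "skin": u["skin"],
                    "skull": u["skull"],
                    "csf": u["csf"],
                    "gm": u["gm"],
                },
                ellipsoid_axis_ratios=(u["axis_rl"], u["axis_ap"], u["axis_si"]),
                perturbation_amplitude_mm=u["perturbation_amplitude_mm"],
                voxel_size_mm=voxel_size_mm,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def with_voxel_size(spec: PhantomSpec, voxel_size_mm: float) -> PhantomSpec:
    """Same anatomy at a different grid resolution."""
    return replace(spec, voxel_size_mm=voxel_size_mm)
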