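"""Electrode montages on a phantom scalp.

Electrodes are ideal surface patches: a rectangle or disc projected onto the
scalp with the exponential map (geodesic rectangle/disc), carrying a polarity
and no thickness, sponge or gel model.  The montage registry reproduces the
fifteen study configurations used in the four modelling rounds:

* Round 1 — electrode position: conventional bilateral M1 (C3-C4) and M1-SO
  (C3-Fp2) 7x5 cm pads, 4x1 HD with 0.5 cm discs (C3 centre, FC3/C1/CP3/C5
  ring), and the two surround montages LRPS (C1-C5) and APPS (CP3-FC3).
* Round 2 — electrode size: 1x1, 3x3, 5x5 and 7x5 cm APPS pads recentred on
  the CP3-FC3 axis so all four share the edge-to-edge distance of the 1x1
  pads at CP3-FC3.
* Round 3 — inter-electrode distance: 7x5 cm APPS pads moved apart along the
  CP3-FC3 scalp geodesic in +2 cm edge-distance steps up to +8 cm.
* Round 4 — optimised APPS: 1x1 cm pads on the CP3-FC3 axis moved 2 cm closer
  together than the CP3-FC3 baseline.

Orientation convention (the study never states pad orientation): bilateral and
M1-SO pads have their long axis along the scalp's left-right direction; the
surround montages (APPS/LRPS and all their variants) have the long axis
perpendicular to the surround axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import GeometryError, InvalidSpecError
from .phantom import HeadPhantom
from .tenten import EEGMap

CM = 10.0  # mm per cm


@dataclass(frozen=True)
class PadShape:
    """Rectangle (width x height, cm) or disc (diameter, cm)."""

    kind: str                       # "rect" | "disc"
    width_cm: float = 0.0           # rect: extent along the long axis
    height_cm: float = 0.0          # rect: extent along the short axis
    diameter_cm: float = 0.0

    def __post_init__(self):
        if self.kind == "rect":
            if self.width_cm <= 0 or self.height_cm <= 0:
                raise InvalidSpecError("rectangle dimensions must be > 0")
        elif self.kind == "disc":
            if self.diameter_cm <= 0:
                raise InvalidSpecError("disc diameter must be > 0")
        else:
            raise InvalidSpecError(f"unknown electrode shape kind {self.kind!r}")

    @property
    def nominal_area_cm2(self) -> float:
        if self.kind == "rect":
            return self.width_cm * self.height_cm
        return np.pi * (self.diameter_cm / 2.0) ** 2

    @property
    def half_extent_along_axis_cm(self) -> float:
        """Half-size along the montage axis (short axis for rectangles)."""
        if self.kind == "rect":
            return self.height_cm / 2.0
        return self.diameter_cm / 2.0


def rect(width_cm: float, height_cm: float) -> PadShape:
    return PadShape(kind="rect", width_cm=width_cm, height_cm=height_cm)


def disc(diameter_cm: float) -> PadShape:
    return PadShape(kind="disc", diameter_cm=diameter_cm)


@dataclass(frozen=True)
class Footprint:
    """Discretised scalp patch: quadrature samples, their areas, boundary."""

    points: np.ndarray      # (n, 3) sample points on the scalp
    areas_mm2: np.ndarray   # (n,) quadrature areas
    boundary: np.ndarray    # (m, 3) perimeter points on the scalp

    @property
    def area_cm2(self) -> float:
        return float(self.areas_mm2.sum()) / CM**2


@dataclass(frozen=True)
class Electrode:
    center: np.ndarray
    shape: PadShape
    polarity: str           # "anode" | "cathode"
    long_axis: np.ndarray   # tangent unit vector of the rectangle long axis
    footprint: Footprint
    _phantom_shape: object = field(repr=False, default=None)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Membership of scalp points in the pad's geodesic footprint."""
        sh = self._phantom_shape
        uv = sh.log_map(self.center, points)
        e1, e2 = sh.tangent_basis(self.center)
        ca, sa = float(self.long_axis @ e1), float(self.long_axis @ e2)
        u = uv[:, 0] * ca + uv[:, 1] * sa
        v = -uv[:, 0] * sa + uv[:, 1] * ca
        if self.shape.kind == "rect":
            return (np.abs(u) <= self.shape.width_cm * CM / 2.0) & (
                np.abs(v) <= self.shape.height_cm * CM / 2.0
            )
        return np.hypot(u, v) <= self.shape.diameter_cm * CM / 2.0


@dataclass(frozen=True)
class Montage:
    name: str
    electrodes: Sequence[Electrode]
    total_current_mA: float = 2.0
    round_tag: str = "custom"

    def __post_init__(self):
        pols = [e.polarity for e in self.electrodes]
        if "anode" not in pols or "cathode" not in pols:
            raise InvalidSpecError("montage needs at least one anode and one cathode")
        if self.total_current_mA <= 0:
            raise InvalidSpecError("total current must be > 0")

    @property
    def anodes(self):
        return [e for e in self.electrodes if e.polarity == "anode"]

    @property
    def cathodes(self):
        return [e for e in self.electrodes if e.polarity == "cathode"]


# ---------------------------------------------------------------------------
# pad construction
# ---------------------------------------------------------------------------

def make_pad(
    center,
    shape: PadShape,
    polarity: str,
    phantom: HeadPhantom,
    long_axis_hint=None,
    samples_per_cm: float = 4.0,
) -> Electrode:
    """Project an electrode shape onto the scalp, centred at a scalp point.

    The footprint is the image of the flat shape under the scalp's exponential
    map at `center`; its area therefore tracks the nominal area up to metric
    distortion (a few percent for pads up to 7 cm on head-sized curvature).
    """
    if polarity not in ("anode", "cathode"):
        raise InvalidSpecError(f"polarity must be anode/cathode, got {polarity!r}")
    sh = phantom.shape_model
    center = sh.scalp_point(sh.directions(center))
    scalp_scale = float(sh.scalp_radius(sh.directions(center)))
    if shape.kind == "rect":
        half_diag = np.hypot(shape.width_cm, shape.height_cm) * CM / 2.0
    else:
        half_diag = shape.diameter_cm * CM / 2.0
    if half_diag > 0.6 * np.pi * scalp_scale / 2.0:
        raise GeometryError("electrode larger than the available scalp cap")

    e1, e2 = sh.tangent_basis(center)
    if long_axis_hint is None:
        long_axis_hint = np.array([1.0, 0.0, 0.0])
    d = sh.directions(center)
    t = np.asarray(long_axis_hint, dtype=float)
    t = t - (t @ d) * d
    if np.linalg.norm(t) < 1e-9:
        raise GeometryError("long-axis hint is normal to the scalp here")
    t /= np.linalg.norm(t)

    if shape.kind == "rect":
        w, h = shape.width_cm * CM, shape.height_cm * CM
        nu = max(int(np.ceil(shape.width_cm * samples_per_cm)), 2)
        nv = max(int(np.ceil(shape.height_cm * samples_per_cm)), 2)
        us = np.linspace(-w / 2.0, w / 2.0, nu + 1)
        vs = np.linspace(-h / 2.0, h / 2.0, nv + 1)
        U, V = np.meshgrid(us, vs, indexing="ij")
        corners_flat = np.column_stack([U.ravel(), V.ravel()])
        # boundary: perimeter at fine sampling
        per = []
        nb = max(int(2 * (shape.width_cm + shape.height_cm)) * 2, 16)
        for s in np.linspace(0, 1, nb, endpoint=False):
            p = s * 2 * (w + h)
            if p < w:
                per.append((-w / 2 + p, -h / 2))
            elif p < w + h:
                per.append((w / 2, -h / 2 + (p - w)))
            elif p < 2 * w + h:
                per.append((w / 2 - (p - w - h), h / 2))
            else:
                per.append((-w / 2, h / 2 - (p - 2 * w - h)))
        bnd_flat = np.asarray(per)
    else:
        r = shape.diameter_cm * CM / 2.0
        nr = max(int(np.ceil(shape.diameter_cm * samples_per_cm)), 4)
        rs = np.linspace(0.0, r, nr + 1)
        na = max(8 * nr, 32)
        angs = np.linspace(0, 2 * np.pi, na, endpoint=False)
        # polar quadrature grid (rings of quads)
        U = np.outer(rs, np.cos(angs))
        V = np.outer(rs, np.sin(angs))
        corners_flat = np.column_stack([U.ravel(), V.ravel()])
        bnd_flat = np.column_stack([r * np.cos(angs), r * np.sin(angs)])
        nu, nv = nr, na

    # rotate flat coords into the (t, t_perp) frame expressed in (e1, e2)
    ca, sa = float(t @ e1), float(t @ e2)
    rot = np.array([[ca, -sa], [sa, ca]])
    mapped = sh.exp_map(center, corners_flat @ rot.T)
    bnd = sh.exp_map(center, bnd_flat @ rot.T)

    if shape.kind == "rect":
        corners = mapped.reshape(nu + 1, nv + 1, 3)
        quad_centers = 0.25 * (
            corners[:-1, :-1] + corners[1:, :-1] + corners[:-1, 1:] + corners[1:, 1:]
        )
        d1 = corners[1:, 1:] - corners[:-1, :-1]
        d2 = corners[1:, :-1] - corners[:-1, 1:]
        areas = 0.5 * np.linalg.norm(np.cross(d1, d2), axis=-1)
        pts = quad_centers.reshape(-1, 3)
        areas = areas.reshape(-1)
    else:
        corners = mapped.reshape(nu + 1, nv, 3)
        nxt = np.roll(np.arange(nv), -1)
        quad_centers = 0.25 * (
            corners[:-1] + corners[1:] + corners[:-1, nxt] + corners[1:, nxt]
        )
        d1 = corners[1:, nxt] - corners[:-1]
        d2 = corners[1:] - corners[:-1, nxt]
        areas = 0.5 * np.linalg.norm(np.cross(d1, d2), axis=-1)
        pts = quad_centers.reshape(-1, 3)
        areas = areas.reshape(-1)

    foot = Footprint(points=pts, areas_mm2=areas, boundary=bnd)
    return Electrode(
        center=center,
        shape=shape,
        polarity=polarity,
        long_axis=t,
        footprint=foot,
        _phantom_shape=sh,
    )


# ---------------------------------------------------------------------------
# distances and overlap
# ---------------------------------------------------------------------------

def _pair_edge_distance(a: Electrode, b: Electrode, phantom: HeadPhantom) -> float:
    sh = phantom.shape_model
    if np.any(a.contains(b.footprint.boundary)) or np.any(
        b.contains(a.footprint.boundary)
    ):
        raise GeometryError(f"electrode footprints overlap ({a.polarity}/{b.polarity})")
    best = np.inf
    for pa in a.footprint.boundary:
        d = sh.geodesic_distance(pa, b.footprint.boundary)
        best = min(best, float(d.min()))
    return best


def edge_to_edge_distance(m: Montage, phantom: HeadPhantom) -> float:
    """Minimal geodesic scalp distance between footprint boundaries, in cm.

    For multi-cathode (4x1 HD) montages, returns the mean over
    anode-to-cathode pairs.
    """
    if len(m.electrodes) == 2:
        return _pair_edge_distance(m.electrodes[0], m.electrodes[1], phantom) / CM
    anodes, cathodes = m.anodes, m.cathodes
    if len(anodes) == 1 and len(cathodes) >= 2:
        vals = [_pair_edge_distance(anodes[0], c, phantom) for c in cathodes]
        return float(np.mean(vals)) / CM
    raise InvalidSpecError(
        "edge_to_edge_distance needs 2 electrodes or a single-anode ring montage"
    )


def check_no_overlap(m: Montage) -> bool:
    """True iff all pairwise footprints are disjoint with positive clearance."""
    els = list(m.electrodes)
    for i in range(len(els)):
        for j in range(i + 1, len(els)):
            a, b = els[i], els[j]
            if np.any(a.contains(b.footprint.boundary)):
                return False
            if np.any(b.contains(a.footprint.boundary)):
                return False
            if np.any(a.contains(np.atleast_2d(b.center))):
                return False
            if np.any(b.contains(np.atleast_2d(a.center))):
                return False
    return True


def offset_along_ap(m: Montage, delta_cm: float, phantom: HeadPhantom) -> Montage:
    """Move a two-electrode montage's pads apart (or together) along their
    connecting scalp geodesic, |delta|/2 each, keeping sizes.

    Positive delta increases the centre separation by delta of arc length;
    the minimal boundary-to-boundary distance grows by delta in the planar
    limit and slightly less on a curved scalp (the closest boundary points
    drift off-axis)."""
    if len(m.electrodes) != 2:
        raise InvalidSpecError("offset_along_ap needs exactly a 2-electrode montage")
    if delta_cm == 0.0:
        return m
    sh = phantom.shape_model
    a, b = m.electrodes
    half = abs(delta_cm) * CM / 2.0
    new_els = []
    for e, other in ((a, b), (b, a)):
        t_toward = sh.tangent_toward(e.center, other.center)
        t = -t_toward if delta_cm > 0 else t_toward
        try:
            new_center = sh.walk(e.center, t, half)
        except GeometryError as err:
            raise GeometryError(f"offset moves electrode off the scalp: {err}")
        axis_dir = sh.tangent_toward(new_center, other.center)
        perp = np.cross(sh.directions(new_center), axis_dir)
        new_els.append(
            make_pad(new_center, e.shape, e.polarity, phantom, long_axis_hint=perp)
        )
    out = Montage(
        name=m.name,
        electrodes=new_els,
        total_current_mA=m.total_current_mA,
        round_tag=m.round_tag,
    )
    if not check_no_overlap(out):
        raise GeometryError("offset causes electrode overlap")
    return out


# ---------------------------------------------------------------------------
# the fifteen study montages
# ---------------------------------------------------------------------------

ROUND1 = ("BILAT_M1", "M1_SO", "HD", "LRPS", "APPS")
ROUND2 = ("APPS_1X1", "APPS_3X3", "APPS_5X5", "APPS_7X5")
ROUND3 = ("APPS_P0", "APPS_P2", "APPS_P4", "APPS_P6", "APPS_P8")
ROUND4 = ("OPT_APPS",)
MONTAGE_NAMES = ROUND1 + ROUND2 + ROUND3 + ROUND4

_ROUND_OF = {}
for _names, _tag in ((ROUND1, "round1"), (ROUND2, "round2"),
                     (ROUND3, "round3"), (ROUND4, "round4")):
    for _n in _names:
        _ROUND_OF[_n] = _tag

_R2_SIZES = {"APPS_1X1": (1.0, 1.0), "APPS_3X3": (3.0, 3.0),
             "APPS_5X5": (5.0, 5.0), "APPS_7X5": (7.0, 5.0)}


def _surround_pair(
    phantom, anode_pt, cathode_pt, shape_a, shape_c, current, name, tag
) -> Montage:
    """Two pads at given scalp points, long axes perpendicular to the
    connecting geodesic."""
    sh = phantom.shape_model
    els = []
    for pt, other, shp, pol in (
        (anode_pt, cathode_pt, shape_a, "anode"),
        (cathode_pt, anode_pt, shape_c, "cathode"),
    ):
        axis_dir = sh.tangent_toward(pt, other)
        perp = np.cross(sh.directions(pt), axis_dir)
        els.append(make_pad(pt, shp, pol, phantom, long_axis_hint=perp))
    return Montage(name=name, electrodes=els, total_current_mA=current, round_tag=tag)


def _axis_pair_at_separation(
    phantom, eeg, shape, sep_mm, current, name, tag
) -> Montage:
    """Pads on the CP3-FC3 axis, symmetric about its midpoint, centres
    `sep_mm` apart along the axis geodesic (anode posterior at the CP3 end)."""
    sh = phantom.shape_model
    mid = sh.arc_fraction_point(eeg["CP3"], eeg["FC3"], 0.5)
    t_to_fc3 = sh.tangent_toward(mid, eeg["FC3"])
    anode_pt = sh.walk(mid, -t_to_fc3, sep_mm / 2.0)
    cathode_pt = sh.walk(mid, t_to_fc3, sep_mm / 2.0)
    return _surround_pair(
        phantom, anode_pt, cathode_pt, shape, shape, current, name, tag
    )


def _matched_distance_montage(
    phantom, eeg, shape, target_edge_mm, current, name, tag
) -> Montage:
    """Solve for the centre separation achieving a given edge distance."""
    sep = target_edge_mm + 2.0 * shape.half_extent_along_axis_cm * CM
    m = _axis_pair_at_separation(phantom, eeg, shape, sep, current, name, tag)
    for _ in range(4):  # secant refinement against scalp curvature
        err = target_edge_mm - edge_to_edge_distance(m, phantom) * CM
        if abs(err) < 0.1:
            break
        sep += err
        m = _axis_pair_at_separation(phantom, eeg, shape, sep, current, name, tag)
    return m


def round3_edge_distance_cm(baseline_cm: float, offset_cm: float) -> float:
    """Design arithmetic of the distance round: each step adds its offset to
    the baseline edge-to-edge distance (e.g. a 2.12 cm baseline + 8 -> 10.12)."""
    return baseline_cm + offset_cm


def opt_apps_edge_distance_cm(baseline_1x1_cm: float) -> float:
    """Design arithmetic of the optimised montage: 1x1 cm pads moved 2 cm
    closer than their CP3-FC3 baseline (e.g. 6.12 cm -> 4.12 cm)."""
    return baseline_1x1_cm - 2.0


def baseline_1x1_edge_distance_cm(phantom: HeadPhantom, eeg: EEGMap) -> float:
    """Edge-to-edge distance of 1x1 cm pads at CP3-FC3 on this phantom."""
    m = _surround_pair(
        phantom, eeg["CP3"], eeg["FC3"], rect(1, 1), rect(1, 1), 2.0, "tmp", "round2"
    )
    return edge_to_edge_distance(m, phantom)


def build_study_montage(
    name: str, phantom: HeadPhantom, eeg: EEGMap, total_current_mA: float = 2.0
) -> Montage:
    """Construct one of the fifteen study montage configurations."""
    if name not in MONTAGE_NAMES:
        raise KeyError(
            f"unknown montage {name!r}; valid names: {', '.join(MONTAGE_NAMES)}"
        )
    tag = _ROUND_OF[name]
    needed = {"C3", "C4", "Fp2", "FC3", "C1", "CP3", "C5"}
    missing = [k for k in needed if k not in eeg]
    if missing:
        raise KeyError(f"EEG map lacks labels {missing}")

    pad75 = rect(7, 5)
    if name == "BILAT_M1":
        els = [
            make_pad(eeg["C3"], pad75, "anode", phantom),
            make_pad(eeg["C4"], pad75, "cathode", phantom),
        ]
        m = Montage(name, els, total_current_mA, tag)
    elif name == "M1_SO":
        els = [
            make_pad(eeg["C3"], pad75, "anode", phantom),
            make_pad(eeg["Fp2"], pad75, "cathode", phantom),
        ]
        m = Montage(name, els, total_current_mA, tag)
    elif name == "HD":
        d05 = disc(0.5)
        els = [make_pad(eeg["C3"], d05, "anode", phantom)]
        for lab in ("FC3", "C1", "CP3", "C5"):
            els.append(make_pad(eeg[lab], d05, "cathode", phantom))
        m = Montage(name, els, total_current_mA, tag)
    elif name == "LRPS":
        m = _surround_pair(
            phantom, eeg["C1"], eeg["C5"], pad75, pad75, total_current_mA, name, tag
        )
    elif name in ("APPS", "APPS_P0"):
        m = _surround_pair(
            phantom, eeg["CP3"], eeg["FC3"], pad75, pad75, total_current_mA, name, tag
        )
    elif name in _R2_SIZES:
        target = baseline_1x1_edge_distance_cm(phantom, eeg) * CM
        w, h = _R2_SIZES[name]
        m = _matched_distance_montage(
            phantom, eeg, rect(w, h), target, total_current_mA, name, tag
        )
    elif name.startswith("APPS_P"):
        # Round 3: same 7x5 pads, edge-to-edge distance = APPS baseline + k cm,
        # centres moved symmetrically along the CP3-FC3 scalp geodesic
        base = _surround_pair(
            phantom, eeg["CP3"], eeg["FC3"], pad75, pad75, total_current_mA, name, tag
        )
        target = edge_to_edge_distance(base, phantom) * CM + float(name[6:]) * CM
        m = _matched_distance_montage(
            phantom, eeg, pad75, target, total_current_mA, name, tag
        )
    elif name == "OPT_APPS":
        target = opt_apps_edge_distance_cm(
            baseline_1x1_edge_distance_cm(phantom, eeg)
        ) * CM
        if target <= 0:
            raise GeometryError("optimised-APPS edge distance would be negative")
        m = _matched_distance_montage(
            phantom, eeg, rect(1, 1), target, total_current_mA, name, tag
        )
    else:  # pragma: no cover
        raise KeyError(name)

    if not check_no_overlap(m):
        raise GeometryError(f"montage {name} has overlapping electrodes on this phantom")
    return m


# ---------------------------------------------------------------------------
# montage definition files
# ---------------------------------------------------------------------------

def montage_to_dict(m: Montage) -> dict:
    out = {
        "name": m.name,
        "total_current_mA": m.total_current_mA,
        "round_tag": m.round_tag,
        "electrodes": [],
    }
    for e in m.electrodes:
        shp = {"kind": e.shape.kind}
        if e.shape.kind == "rect":
            shp.update(width_cm=e.shape.width_cm, height_cm=e.shape.height_cm)
        else:
            shp.update(diameter_cm=e.shape.diameter_cm)
        out["electrodes"].append(
            {
                "center_mm": [float(v) for v in e.center],
                "long_axis": [float(v) for v in e.long_axis],
                "polarity": e.polarity,
                "shape": shp,
            }
        )
    return out


def montage_from_dict(d: dict, phantom: HeadPhantom) -> Montage:
    els = []
    for ed in d["electrodes"]:
        shp = PadShape(**ed["shape"])
        els.append(
            make_pad(
                np.asarray(ed["center_mm"], dtype=float),
                shp,
                ed["polarity"],
                phantom,
                long_axis_hint=np.asarray(ed["long_axis"], dtype=float),
            )
        )
    return Montage(
        name=d["name"],
        electrodes=els,
        total_current_mA=float(d["total_current_mA"]),
        round_tag=d.get("round_tag", "custom"),
    )


def save_montage_yaml(m: Montage, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(montage_to_dict(m), fh, sort_keys=False)


def load_montage_yaml(path, phantom: HeadPhantom) -> Montage:
    import yaml

    with open(path) as fh:
        return montage_from_dict(yaml.safe_load(fh), phantom)
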