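"""Proportional 10-10 EEG electrode positions on a phantom scalp.

The construction is the classic nested-arc procedure:

1. Cz is fixed iteratively as the joint midpoint of the nasion-inion and
   left-right preauricular scalp arcs.
2. Midline positions subdivide the nasion-inion arc in 10% steps (Fpz at 10%,
   Fz 30%, FCz 40%, Cz 50%, CPz 60%, Pz 70%, Oz 90%).
3. The central coronal row subdivides the LPA-RPA arc through Cz (T7 at 10%,
   C5 20%, C3 30%, C1 40%, Cz 50%, mirrored on the right).
4. The 10% circumferential ring passes through Fpz, T7/T8 and Oz; each ring
   point lies at 80% of the Cz-to-base arc along its meridian, and named ring
   positions (Fp1/Fp2 at 10%, F7/F8 20%, FT7/FT8 40%, TP7/TP8 60%, P7/P8 70%,
   O1/O2 90% of the half-ring from Fpz) are located by arc length along the
   ring itself.
5. Intermediate rows interpolate between ring and midline: FC3 sits at 50% of
   the FT7-FCz arc (FC5 at 25%, FC1 at 75%), and likewise for the CP row.

On an unperturbed sphere every step reduces to closed-form angles, which the
tests use as oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import LandmarkError
from .phantom import HeadPhantom

_REQUIRED_LANDMARKS = ("nasion", "inion", "lpa", "rpa", "vertex")

# half-ring arc fractions (from Fpz, per side)
_RING_FRACTIONS = {0.1: "Fp", 0.2: "F", 0.4: "FT", 0.6: "TP", 0.7: "P", 0.9: "O"}
_RING_NUMBERS = {"Fp": ("1", "2"), "F": ("7", "8"), "FT": ("7", "8"),
                 "TP": ("7", "8"), "P": ("7", "8"), "O": ("1", "2")}


@dataclass(frozen=True)
class EEGMap:
    """10-10 label -> scalp point (RAS mm)."""

    positions: Mapping[str, np.ndarray]

    def __getitem__(self, label: str) -> np.ndarray:
        return self.positions[label]

    def __contains__(self, label: str) -> bool:
        return label in self.positions

    def labels(self):
        return sorted(self.positions)

    def export_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["label", "x_mm", "y_mm", "z_mm"])
            for label in self.labels():
                p = self.positions[label]
                w.writerow([label, f"{p[0]:.6f}", f"{p[1]:.6f}", f"{p[2]:.6f}"])

    @classmethod
    def load_csv(cls, path) -> "EEGMap":
        import csv

        pos = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                pos[row["label"]] = np.array(
                    [float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"])]
                )
        return cls(positions=pos)


def locate_1010(phantom: HeadPhantom, ring_samples: int = 121) -> EEGMap:
    """Compute 10-10 positions on a phantom's scalp by nested arcs."""
    lm = phantom.landmarks
    missing = [k for k in _REQUIRED_LANDMARKS if k not in lm]
    if missing:
        raise LandmarkError(f"missing landmarks: {missing}")
    pts = np.array([lm[k] for k in _REQUIRED_LANDMARKS])
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    if np.any(d[np.triu_indices(len(pts), 1)] < 1e-6):
        raise LandmarkError("coincident landmarks")

    shape = phantom.shape_model
    nasion, inion, lpa, rpa = lm["nasion"], lm["inion"], lm["lpa"], lm["rpa"]

    # --- Cz: joint midpoint of the two principal arcs --------------------
    cz = lm["vertex"]
    for _ in range(4):
        mid_s = shape.arc_fraction_point(nasion, inion, 0.5, via=cz)
        cz = shape.arc_fraction_point(lpa, rpa, 0.5, via=mid_s)

    pos: dict[str, np.ndarray] = {"Cz": cz}

    # --- midline (nasion -> inion) ----------------------------------------
    midline = {"Fpz": 0.1, "AFz": 0.2, "Fz": 0.3, "FCz": 0.4, "CPz": 0.6,
               "Pz": 0.7, "POz": 0.8, "Oz": 0.9}
    for label, frac in midline.items():
        pos[label] = shape.arc_fraction_point(nasion, inion, frac, via=cz)

    # --- central coronal row (LPA -> RPA through Cz) ----------------------
    coronal = {"T7": 0.1, "C5": 0.2, "C3": 0.3, "C1": 0.4,
               "C2": 0.6, "C4": 0.7, "C6": 0.8, "T8": 0.9}
    for label, frac in coronal.items():
        pos[label] = shape.arc_fraction_point(lpa, rpa, frac, via=cz)

    # --- 10% circumferential ring -----------------------------------------
    d_nas = shape.directions(nasion)
    d_rpa = shape.directions(rpa)
    d_lpa = shape.directions(lpa)
    for side, d_side in (("right", d_rpa), ("left", d_lpa)):
        psis = np.linspace(0.0, np.pi, ring_samples)
        ring = np.empty((ring_samples, 3))
        for i, psi in enumerate(psis):
            base_dir = np.cos(psi) * d_nas + np.sin(psi) * d_side
            base_pt = shape.scalp_point(base_dir / np.linalg.norm(base_dir))
            ring[i] = shape.arc_fraction_point(cz, base_pt, 0.8)
        seg = np.linalg.norm(np.diff(ring, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        for frac, prefix in _RING_FRACTIONS.items():
            target = frac * s[-1]
            i = int(np.clip(np.searchsorted(s, target), 1, len(s) - 1))
            t = (target - s[i - 1]) / max(s[i] - s[i - 1], 1e-300)
            p = ring[i - 1] + t * (ring[i] - ring[i - 1])
            p = shape.scalp_point(shape.directions(p))
            num = _RING_NUMBERS[prefix][1 if side == "right" else 0]
            pos[f"{prefix}{num}"] = p

    # --- FC and CP rows ----------------------------------------------------
    for row, edge_prefix, mid_label in (("FC", "FT", "FCz"), ("CP", "TP", "CPz")):
        for side, lateral in (("7", "left"), ("8", "right")):
            edge = pos[f"{edge_prefix}{side}"]  # FT7/FT8 or TP7/TP8
            nums = ("5", "3", "1") if lateral == "left" else ("6", "4", "2")
            for num, frac in zip(nums, (0.25, 0.5, 0.75)):
                pos[f"{row}{num}"] = shape.arc_fraction_point(
                    edge, pos[mid_label], frac
                )

    return EEGMap(positions=pos)
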