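"""Outcome measures for one field solution.

Three study endpoints plus the peak-location analysis:

* ``roi_mean`` — mean E-field magnitude in a 10 mm-radius grey-matter sphere
  centred on the first grey-matter voxel under the C3 scalp position (the
  "on-target" dose at the motor hand knob).
* ``p99_mean`` — mean E-field magnitude over the top 1% of brain voxels by
  volume, irrespective of location (the "wherever it lands" peak dose).
* ``focality_volume`` — brain volume with E-field at or above half of the
  robust peak (99.9th percentile) value; smaller is more focal.  The robust
  peak, rather than the literal maximum, avoids dependence on single-voxel
  outliers next to electrode edges.
* ``peak_offset`` — distance from the centroid of the supra-99.9th-percentile
  region to the montage midpoint projected onto grey matter, quantifying the
  "maximal field midway between the electrodes" effect.

All metrics are volume-weighted; on the uniform grids used here that reduces
to voxel counting with fractional weighting at percentile boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyMaskError, GeometryError, InvalidSpecError
from .phantom import GM, WM, HeadPhantom
from .solver import FieldSolution
from .tenten import EEGMap

BRAIN_LABELS = (GM, WM)


@dataclass(frozen=True)
class ROISpec:
    """Spherical tissue-masked region of interest."""

    center_mm: np.ndarray
    radius_mm: float = 10.0
    tissue_labels: tuple = (GM,)

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise InvalidSpecError("ROI radius must be > 0")


@dataclass(frozen=True)
class MetricSet:
    roi_mean_Vpm: float
    p99_mean_Vpm: float
    focality_mm3: float
    peak_point_mm: np.ndarray
    peak_midpoint_offset_mm: float


def locate_roi(
    phantom: HeadPhantom,
    eeg: EEGMap,
    label: str = "C3",
    radius_mm: float = 10.0,
) -> ROISpec:
    """ROI centred on the first grey-matter voxel under an EEG position.

    A ray is cast from the scalp point toward the head centre; the first
    voxel centre carrying the grey-matter label fixes the ROI centre, which
    then stays identical across all montages of that phantom.
    """
    if label not in eeg:
        raise InvalidSpecError(f"EEG label {label!r} not in map")
    if radius_mm <= 0:
        raise InvalidSpecError("ROI radius must be > 0")
    start = np.asarray(eeg[label], dtype=float)
    center = np.asarray(phantom.shape_model.center_mm, dtype=float)
    direction = center - start
    dist = np.linalg.norm(direction)
    direction = direction / dist
    step = phantom.voxel_size_mm / 4.0
    ts = np.arange(0.0, dist, step)
    pts = start[None, :] + ts[:, None] * direction[None, :]
    idx = phantom.world_to_index(pts)
    shp = phantom.label_grid.shape
    ok = np.all((idx >= 0) & (idx < shp), axis=1)
    labs = np.full(len(idx), -1)
    labs[ok] = phantom.label_grid[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
    hits = np.flatnonzero(labs == GM)
    if len(hits) == 0:
        raise GeometryError(f"ray from {label} hits no grey matter")
    roi_center = phantom.index_to_world(idx[hits[0]])[0]
    return ROISpec(center_mm=roi_center, radius_mm=radius_mm)


def _roi_mask(sol: FieldSolution, roi: ROISpec) -> np.ndarray:
    ph = sol.phantom
    ax = ph.voxel_centers_axes()
    dx = ax[0] - roi.center_mm[0]
    dy = ax[1] - roi.center_mm[1]
    dz = ax[2] - roi.center_mm[2]
    d2 = (
        dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
    )
    mask = d2 <= roi.radius_mm**2
    mask &= ph.tissue_mask(list(roi.tissue_labels))
    return mask


def roi_mean(sol: FieldSolution, roi: ROISpec) -> float:
    """Mean |E| (V/m) over the grey-matter voxels inside the ROI sphere."""
    mask = _roi_mask(sol, roi)
    if not np.any(mask):
        raise EmptyMaskError("ROI contains no voxels of the requested tissue")
    return float(sol.e_mag[mask].mean())


def _weighted_top_fraction_mean(values: np.ndarray, frac: float) -> float:
    """Mean of the top `frac` of equal-volume elements, fractional at the cut."""
    v = np.sort(values)[::-1]
    n_exact = frac * len(v)
    n_full = int(np.floor(n_exact))
    rem = n_exact - n_full
    total = v[:n_full].sum()
    weight = float(n_full)
    if rem > 0 and n_full < len(v):
        total += rem * v[n_full]
        weight += rem
    if weight == 0:
        # fewer than one element: the single largest value
        return float(v[0])
    return float(total / weight)


def p99_mean(sol: FieldSolution, mask_labels=BRAIN_LABELS) -> float:
    """Mean |E| of the top 1% (by volume) of masked voxels."""
    mask = sol.phantom.tissue_mask(list(mask_labels))
    if not np.any(mask):
        raise EmptyMaskError("empty tissue mask")
    return _weighted_top_fraction_mean(sol.e_mag[mask], 0.01)


def robust_peak(
    sol: FieldSolution, mask_labels=BRAIN_LABELS, peak_percentile: float = 99.9
) -> float:
    """Volume-weighted percentile of |E| used as the robust peak value."""
    mask = sol.phantom.tissue_mask(list(mask_labels))
    if not np.any(mask):
        raise EmptyMaskError("empty tissue mask")
    return float(np.percentile(sol.e_mag[mask], peak_percentile))


def focality_volume(
    sol: FieldSolution,
    mask_labels=BRAIN_LABELS,
    level_fraction: float = 0.5,
    peak_percentile: float = 99.9,
) -> float:
    """Masked volume (mm^3) with |E| >= level_fraction x robust peak.

    Scale-invariant: depends only on the shape of the field.  Smaller volume
    means more focal stimulation.
    """
    if not 0 < level_fraction <= 1:
        raise InvalidSpecError("level_fraction must be in (0, 1]")
    mask = sol.phantom.tissue_mask(list(mask_labels))
    if not np.any(mask):
        raise EmptyMaskError("empty tissue mask")
    thresh = level_fraction * robust_peak(sol, mask_labels, peak_percentile)
    n = int(np.count_nonzero(sol.e_mag[mask] >= thresh))
    return n * sol.phantom.voxel_volume_mm3


def montage_midpoint_on_gm(sol: FieldSolution) -> np.ndarray:
    """Scalp midpoint between the two electrode centres, projected to GM."""
    m = sol.system.montage
    ph = sol.phantom
    sh = ph.shape_model
    if len(m.electrodes) == 2:
        a, b = m.electrodes
        scalp_mid = sh.arc_fraction_point(a.center, b.center, 0.5)
    else:
        # ring montages: the central electrode is the reference
        anodes = m.anodes
        if len(anodes) != 1:
            raise GeometryError("ambiguous midpoint for multi-anode montage")
        scalp_mid = anodes[0].center
    center = np.asarray(sh.center_mm, dtype=float)
    direction = center - scalp_mid
    direction /= np.linalg.norm(direction)
    step = ph.voxel_size_mm / 4.0
    ts = np.arange(0.0, np.linalg.norm(center - scalp_mid), step)
    pts = scalp_mid[None, :] + ts[:, None] * direction[None, :]
    idx = ph.world_to_index(pts)
    shp = ph.label_grid.shape
    ok = np.all((idx >= 0) & (idx < shp), axis=1)
    labs = np.full(len(idx), -1)
    labs[ok] = ph.label_grid[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
    hits = np.flatnonzero(labs == GM)
    if len(hits) == 0:
        raise GeometryError("midpoint ray hits no grey matter")
    return ph.index_to_world(idx[hits[0]])[0]


def peak_location(
    sol: FieldSolution, mask_labels=BRAIN_LABELS, peak_percentile: float = 99.9
) -> np.ndarray:
    """Volume-weighted centroid of the supra-percentile region (mm)."""
    ph = sol.phantom
    mask = ph.tissue_mask(list(mask_labels))
    if not np.any(mask):
        raise EmptyMaskError("empty tissue mask")
    thresh = robust_peak(sol, mask_labels, peak_percentile)
    hot = mask & (sol.e_mag >= thresh)
    if not np.any(hot):  # ties/uniform fields: fall back to the mask
        hot = mask
    idx = np.argwhere(hot)
    return ph.index_to_world(idx).mean(axis=0)


def peak_offset(
    sol: FieldSolution, mask_labels=BRAIN_LABELS, peak_percentile: float = 99.9
) -> tuple:
    """(offset_mm, peak_point_mm): distance from the hot-spot centroid to the
    montage midpoint's grey-matter projection."""
    peak = peak_location(sol, mask_labels, peak_percentile)
    target = montage_midpoint_on_gm(sol)
    return float(np.linalg.norm(peak - target)), peak


def compute_metrics(
    sol: FieldSolution,
    roi: ROISpec,
    mask_labels=BRAIN_LABELS,
    level_fraction: float = 0.5,
    peak_percentile: float = 99.9,
) -> MetricSet:
    off, peak = peak_offset(sol, mask_labels, peak_percentile)
    return MetricSet(
        roi_mean_Vpm=roi_mean(sol, roi),
        p99_mean_Vpm=p99_mean(sol, mask_labels),
        focality_mm3=focality_volume(sol, mask_labels, level_fraction, peak_percentile),
        peak_point_mm=peak,
        peak_midpoint_offset_mm=off,
    )
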