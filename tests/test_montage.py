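"""Montage construction: footprints, distances, the fifteen study configs."""

import numpy as np
import pytest

from tdcsim import (
    Montage,
    build_study_montage,
    check_no_overlap,
    disc,
    edge_to_edge_distance,
    make_pad,
    offset_along_ap,
    rect,
)
from tdcsim.errors import GeometryError, InvalidSpecError
from tdcsim.montage import (
    MONTAGE_NAMES,
    baseline_1x1_edge_distance_cm,
    load_montage_yaml,
    save_montage_yaml,
)


def test_pad_area_tracks_nominal(sphere_phantom, eeg_map):
    for shape, nominal in ((rect(7, 5), 35.0), (rect(1, 1), 1.0),
                           (disc(0.5), np.pi * 0.25**2)):
        el = make_pad(eeg_map["C3"], shape, "anode", sphere_phantom)
        assert el.footprint.area_cm2 == pytest.approx(nominal, rel=0.05)


def test_invalid_shapes_rejected(sphere_phantom, eeg_map):
    with pytest.raises(InvalidSpecError):
        rect(0.0, 5.0)
    with pytest.raises(InvalidSpecError):
        disc(-1.0)
    with pytest.raises(InvalidSpecError):
        make_pad(eeg_map["C3"], rect(7, 5), "source", sphere_phantom)
    with pytest.raises(GeometryError):
        make_pad(eeg_map["C3"], rect(40, 40), "anode", sphere_phantom)


def test_unknown_montage_name(sphere_phantom, eeg_map):
    with pytest.raises(KeyError):
        build_study_montage("NOT_A_MONTAGE", sphere_phantom, eeg_map)


def test_apps_configuration(sphere_phantom, eeg_map):
    m = build_study_montage("APPS", sphere_phantom, eeg_map)
    assert m.total_current_mA == 2.0
    anode, cathode = m.anodes[0], m.cathodes[0]
    assert np.linalg.norm(anode.center - eeg_map["CP3"]) < 0.5
    assert np.linalg.norm(cathode.center - eeg_map["FC3"]) < 0.5
    assert anode.shape.width_cm == 7 and anode.shape.height_cm == 5


def test_hd_configuration(sphere_phantom, eeg_map):
    m = build_study_montage("HD", sphere_phantom, eeg_map)
    assert len(m.anodes) == 1 and len(m.cathodes) == 4
    for el in m.electrodes:
        assert el.shape.kind == "disc" and el.shape.diameter_cm == 0.5
    assert np.linalg.norm(m.anodes[0].center - eeg_map["C3"]) < 0.5
    assert check_no_overlap(m)
    # mean anode-cathode clearance is positive and close to the 10-10 ring
    d = edge_to_edge_distance(m, sphere_phantom)
    assert 1.5 < d < 4.0


def test_all_fifteen_build_without_overlap(sphere_phantom, eeg_map):
    assert len(MONTAGE_NAMES) == 15
    for name in MONTAGE_NAMES:
        m = build_study_montage(name, sphere_phantom, eeg_map)
        assert check_no_overlap(m), name
        assert m.anodes and m.cathodes


def test_round2_matched_distances(sphere_phantom, eeg_map):
    """All four size variants share the 1x1-at-CP3-FC3 edge distance (1 mm)."""
    target = baseline_1x1_edge_distance_cm(sphere_phantom, eeg_map)
    for name in ("APPS_1X1", "APPS_3X3", "APPS_5X5", "APPS_7X5"):
        m = build_study_montage(name, sphere_phantom, eeg_map)
        d = edge_to_edge_distance(m, sphere_phantom)
        assert d == pytest.approx(target, abs=0.1), name


def test_round3_distance_ladder(sphere_phantom, eeg_map):
    """Edge distances step by exactly +2 cm from baseline (2 mm tolerance)."""
    base = edge_to_edge_distance(
        build_study_montage("APPS", sphere_phantom, eeg_map), sphere_phantom
    )
    for k in (2, 4, 6, 8):
        m = build_study_montage(f"APPS_P{k}", sphere_phantom, eeg_map)
        d = edge_to_edge_distance(m, sphere_phantom)
        assert d == pytest.approx(base + k, abs=0.2), k


def test_opt_apps_is_two_cm_closer(sphere_phantom, eeg_map):
    base = baseline_1x1_edge_distance_cm(sphere_phantom, eeg_map)
    m = build_study_montage("OPT_APPS", sphere_phantom, eeg_map)
    assert m.electrodes[0].shape.width_cm == 1.0
    d = edge_to_edge_distance(m, sphere_phantom)
    assert d == pytest.approx(base - 2.0, abs=0.1)


def test_edge_distance_matches_bruteforce(sphere_phantom, eeg_map):
    """Library edge distance equals a brute-force scan over dense boundary
    samples with independent pairwise arc integration."""
    m = build_study_montage("APPS_1X1", sphere_phantom, eeg_map)
    a, b = m.electrodes
    sh = sphere_phantom.shape_model
    best = np.inf
    for pa in a.footprint.boundary:
        for pb in b.footprint.boundary:
            da, db = sh.directions(pa), sh.directions(pb)
            ang = np.arccos(np.clip(da @ db, -1, 1))
            # independent dense integration of the central-section arc
            ts = np.linspace(0, 1, 400)
            e2 = db - (db @ da) * da
            e2 /= np.linalg.norm(e2)
            dirs = np.cos(ang * ts)[:, None] * da + np.sin(ang * ts)[:, None] * e2
            pts = sh.scalp_point(dirs)
            best = min(best, np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    lib = edge_to_edge_distance(m, sphere_phantom) * 10.0
    assert lib == pytest.approx(best, rel=0.01)


def test_overlapping_pads_detected(sphere_phantom, eeg_map):
    a = make_pad(eeg_map["C3"], rect(7, 5), "anode", sphere_phantom)
    b = make_pad(eeg_map["C3"], rect(7, 5), "cathode", sphere_phantom)
    m = Montage("BAD", [a, b], 2.0, "test")
    assert not check_no_overlap(m)
    with pytest.raises(GeometryError):
        edge_to_edge_distance(m, sphere_phantom)


def test_offset_identity_and_area_preservation(sphere_phantom, eeg_map):
    m = build_study_montage("APPS", sphere_phantom, eeg_map)
    assert offset_along_ap(m, 0.0, sphere_phantom) is m
    moved = offset_along_ap(m, 4.0, sphere_phantom)
    for e0, e1 in zip(m.electrodes, moved.electrodes):
        assert e1.footprint.area_cm2 == pytest.approx(e0.footprint.area_cm2, rel=0.01)
    # centre separation grows by the full delta of arc length
    sh = sphere_phantom.shape_model
    d0 = float(sh.geodesic_distance(m.electrodes[0].center, m.electrodes[1].center)[0])
    d1 = float(
        sh.geodesic_distance(moved.electrodes[0].center, moved.electrodes[1].center)[0]
    )
    assert d1 - d0 == pytest.approx(40.0, abs=1.0)
    # moving far off the scalp cap must fail
    with pytest.raises(GeometryError):
        offset_along_ap(m, -8.0, sphere_phantom)


def test_montage_polarity_invariants():
    with pytest.raises(InvalidSpecError):
        Montage("X", [], 2.0, "t")


def test_yaml_roundtrip(tmp_path, sphere_phantom, eeg_map):
    m = build_study_montage("APPS_3X3", sphere_phantom, eeg_map)
    path = tmp_path / "m.yaml"
    save_montage_yaml(m, path)
    back = load_montage_yaml(path, sphere_phantom)
    assert back.name == m.name
    assert back.total_current_mA == m.total_current_mA
    for e0, e1 in zip(m.electrodes, back.electrodes):
        assert np.allclose(e0.center, e1.center, atol=1e-6)
        assert e0.polarity == e1.polarity
        assert e0.shape == e1.shape


def test_montage_construction_deterministic(sphere_phantom, eeg_map):
    m1 = build_study_montage("APPS_5X5", sphere_phantom, eeg_map)
    m2 = build_study_montage("APPS_5X5", sphere_phantom, eeg_map)
    for a, b in zip(m1.electrodes, m2.electrodes):
        assert np.array_equal(a.center, b.center)
        assert np.array_equal(a.footprint.points, b.footprint.points)
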