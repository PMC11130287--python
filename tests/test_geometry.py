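"""Membrane-frame observables: plane, depths, distances, angles,
state classification, frame averaging, rigid-motion invariance."""

import numpy as np
import pandas as pd
import pytest

from ldhairpin import geometry as geo, synthetic as syn


def _frame(ca_z=None, ca_points=None, cyto_z=0.0, lumenal_z=-38.0):
    """Minimal frame: a few Calpha atoms plus two phosphate layers."""
    rows = []
    if ca_points is None:
        ca_points = [(0.0, 0.0, z) for z in (ca_z if ca_z is not None else [])]
    for i, (x, y, z) in enumerate(ca_points):
        rows.append({"residue_index": i + 1, "residue_name": "ALA",
                     "atom_name": "CA", "x": x, "y": y, "z": z})
    for j, (x, y) in enumerate([(-10, -10), (10, -10), (0, 10), (5, 5)]):
        rows.append({"residue_index": 500 + j, "residue_name": "POP",
                     "atom_name": "P", "x": x, "y": y, "z": cyto_z})
        rows.append({"residue_index": 600 + j, "residue_name": "POP",
                     "atom_name": "P", "x": x, "y": y, "z": lumenal_z})
    return geo.MembraneFrame(pd.DataFrame(rows))


# --------------------------------------------------------------- plane

def test_phosphate_plane_is_the_mean_p_level():
    assert geo.phosphate_plane(_frame(ca_z=[0.0])) == pytest.approx(0.0)
    frame = _frame(ca_z=[0.0], cyto_z=20.0)
    assert geo.phosphate_plane(frame) == pytest.approx(2.0)


def test_plane_requires_three_p_atoms():
    rows = [{"residue_index": 1, "residue_name": "ALA", "atom_name": "CA",
             "x": 0.0, "y": 0.0, "z": 0.0}]
    with pytest.raises(ValueError, match="P atoms"):
        geo.phosphate_plane(geo.MembraneFrame(pd.DataFrame(rows)))


# --------------------------------------------------------------- depth

def test_depth_sign_convention():
    frame = _frame(ca_z=[0.0, -5.0, 5.0])
    assert geo.residue_depth(frame, 1) == pytest.approx(0.0)
    assert geo.residue_depth(frame, 2) == pytest.approx(0.5)   # inserted
    assert geo.residue_depth(frame, 3) == pytest.approx(-0.5)  # solvent side

def test_depth_flips_when_the_membrane_interior_is_above():
    # annotate leaflets explicitly: cytoplasmic plane at z=0 with the
    # second leaflet above it, so insertion points along +z
    rows = [{"residue_index": 1, "residue_name": "ALA", "atom_name": "CA",
             "x": 0.0, "y": 0.0, "z": 5.0}]
    for j, z in enumerate([0.0] * 3 + [38.0] * 3):
        rows.append({"residue_index": 500 + j, "residue_name": "POP",
                     "atom_name": "P", "x": float(j), "y": -float(j), "z": z})
    atoms = pd.DataFrame(rows)
    leaflet = pd.Series(["cytoplasmic"] * 3 + ["lumenal"] * 3,
                        index=atoms.index[atoms["atom_name"] == "P"])
    frame = geo.MembraneFrame(atoms, leaflet_of_p=leaflet)
    assert geo.residue_depth(frame, 1) == pytest.approx(0.5)


def test_missing_calpha_is_named():
    with pytest.raises(ValueError, match="99"):
        geo.residue_depth(_frame(ca_z=[0.0]), 99)


def test_deep_v_fixture_kink_depth_two_nanometers(deep_v_frame):
    assert geo.residue_depth(deep_v_frame, 102) == pytest.approx(2.0, abs=0.04)


# ------------------------------------------------------------ distance

def test_pair_distance_pythagoras():
    frame = _frame(ca_points=[(0, 0, 0), (3, 4, 0), (0, 0, 0)])
    assert geo.pair_distance(frame, 1, 2) == pytest.approx(5.0)
    assert geo.pair_distance(frame, 1, 3) == pytest.approx(0.0)
    assert geo.pair_distance(frame, 2, 1) == geo.pair_distance(frame, 1, 2)


def test_distance_triangle_inequality():
    frame = _frame(ca_points=[(0, 0, 0), (3, 4, 0), (-2, 7, 5)])
    d12 = geo.pair_distance(frame, 1, 2)
    d23 = geo.pair_distance(frame, 2, 3)
    d13 = geo.pair_distance(frame, 1, 3)
    assert d13 <= d12 + d23 + 1e-12


def test_open_shallow_fixture_tip_distance(open_shallow_frame):
    assert geo.pair_distance(open_shallow_frame, 91, 118) == pytest.approx(36.0, abs=0.7)


# -------------------------------------------------------------- angles

@pytest.mark.parametrize("direction,expected", [
    ((0, 0, 1), 90.0),
    ((1, 0, 0), 0.0),
    ((1, 0, 1), 45.0),
])
def test_tilt_angle_of_a_straight_trace(direction, expected):
    d = np.asarray(direction, dtype=float)
    pts = [tuple(t * d) for t in range(5)]
    frame = _frame(ca_points=pts)
    assert geo.tilt_angle(frame, (1, 5)) == pytest.approx(expected, abs=1e-9)


def test_tilt_needs_three_distinct_points():
    frame = _frame(ca_points=[(0, 0, 0), (0, 0, 0), (0, 0, 0)])
    with pytest.raises(ValueError, match="distinct"):
        geo.tilt_angle(frame, (1, 3))


@pytest.mark.parametrize("d1,d2,expected", [
    ((1, 0, 0), (-1, 0, 0), 180.0),
    ((1, 0, 1), (-1, 0, 1), 90.0),
])
def test_opening_angle_of_straight_arms(d1, d2, expected):
    d1, d2 = np.asarray(d1, float), np.asarray(d2, float)
    pts = ([tuple(t * d1 / np.linalg.norm(d1)) for t in (3, 2, 1)]
           + [(0.0, 0.0, 0.0)]
           + [tuple(t * d2 / np.linalg.norm(d2)) for t in (1, 2, 3)])
    frame = _frame(ca_points=pts)
    assert geo.opening_angle(frame, (1, 3), (5, 7), 4) == pytest.approx(expected, abs=1e-6)


def test_deep_v_opens_less_than_open_shallow(deep_v_frame, open_shallow_frame):
    args = ((80, 101), (103, 128), 102)
    assert geo.opening_angle(deep_v_frame, *args) < geo.opening_angle(open_shallow_frame, *args)


# ------------------------------------------------------ classification

def test_classify_conformation_thresholds():
    assert geo.classify_conformation(2.0, 80.0) == "deep_V"
    assert geo.classify_conformation(0.1, 30.0) == "open_shallow"
    assert geo.classify_conformation(0.7, 50.0) == "ambiguous"


def test_fixture_states_are_recovered(deep_v_frame, open_shallow_frame):
    assert geo.measure_structure(deep_v_frame).conformation == "deep_V"
    assert geo.measure_structure(open_shallow_frame).conformation == "open_shallow"


# ----------------------------------------------------- frame averaging

def test_frame_average_of_identical_frames(deep_v_frame):
    mean, sem = geo.frame_average([deep_v_frame] * 4,
                                  lambda f: geo.residue_depth(f, 102), window=1.0)
    assert mean == pytest.approx(2.0, abs=0.04)
    assert sem == 0.0


def test_frame_average_window_selects_trailing_frames():
    frames = [_frame(ca_z=[-10.0 * d]) for d in (9.0, 9.0, 1.0, 2.0)]
    mean, _ = geo.frame_average(frames, lambda f: geo.residue_depth(f, 1), window=0.5)
    assert mean == pytest.approx(1.5)
    mean_all, _ = geo.frame_average(frames[-2:], lambda f: geo.residue_depth(f, 1),
                                    window=1.0)
    assert mean_all == pytest.approx(1.5)


def test_frame_average_requires_frames():
    with pytest.raises(ValueError):
        geo.frame_average([], lambda f: 0.0)


# --------------------------------------------- rigid-motion invariance

def _rigid_xy(frame, angle_deg, dx, dy):
    a = np.radians(angle_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    atoms = frame.atoms.copy()
    xy = atoms[["x", "y"]].to_numpy() @ rot.T + np.array([dx, dy])
    atoms[["x", "y"]] = xy
    return geo.MembraneFrame(atoms)


@pytest.mark.parametrize("angle,dx,dy", [(37.0, 12.0, -8.0), (180.0, 0.0, 5.0)])
def test_observables_invariant_under_rotation_about_the_normal(deep_v_frame, angle, dx, dy):
    moved = _rigid_xy(deep_v_frame, angle, dx, dy)
    assert geo.residue_depth(moved, 102) == pytest.approx(
        geo.residue_depth(deep_v_frame, 102), abs=1e-9)
    assert geo.tilt_angle(moved, (80, 128)) == pytest.approx(
        geo.tilt_angle(deep_v_frame, (80, 128)), abs=1e-9)
    assert geo.pair_distance(moved, 91, 118) == pytest.approx(
        geo.pair_distance(deep_v_frame, 91, 118), abs=1e-9)


# ----------------------------------------------------------------- IO

def test_pdb_round_trip_preserves_observables(tmp_path, deep_v_frame):
    path = tmp_path / "deep.pdb"
    deep_v_frame.to_pdb(path)
    back = geo.MembraneFrame.from_pdb(path)
    assert geo.residue_depth(back, 102) == pytest.approx(
        geo.residue_depth(deep_v_frame, 102), abs=1e-3)
    assert geo.pair_distance(back, 91, 118) == pytest.approx(
        geo.pair_distance(deep_v_frame, 91, 118), abs=1e-2)


def test_csv_round_trip(tmp_path, open_shallow_frame):
    path = tmp_path / "frame.csv"
    open_shallow_frame.to_csv(path)
    back = geo.MembraneFrame.from_csv(path)
    assert geo.measure_structure(back).conformation == "open_shallow"
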