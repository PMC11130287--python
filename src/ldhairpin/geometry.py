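"""Structure-derived membrane observables for hairpin peptides.

A :class:`MembraneFrame` holds per-atom coordinates (Angstrom, membrane
normal along z) together with phosphate (P) reference atoms that define
the membrane surface. The observables distinguishing a deep, closed-V
insertion from an open, shallow interfacial state are:

* per-residue insertion depth of the Calpha below the mean z-level of the
  cytoplasmic-leaflet phosphates (nm, positive = inserted),
* the tilt of the peptide's first principal axis against the membrane
  plane (degrees, 90 = perpendicular),
* Calpha-Calpha distances between the two helix arms (Angstrom),
* the opening angle of the V at the kink residue.

Coordinates are read from PDB, GRO or a plain per-atom CSV table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

ATOM_COLUMNS = ("residue_index", "residue_name", "atom_name", "x", "y", "z")


class MembraneFrame:
    """Per-atom coordinate table with phosphate leaflet assignment.

    Parameters
    ----------
    atoms:
        DataFrame with columns ``residue_index, residue_name, atom_name,
        x, y, z`` (coordinates in Angstrom).
    leaflet_of_p:
        Optional explicit assignment for P atoms (index-aligned with the
        P rows), values ``cytoplasmic``/``lumenal``. When absent, P atoms
        above the global P midplane are called cytoplasmic.
    """

    def __init__(self, atoms: pd.DataFrame, leaflet_of_p: pd.Series | None = None):
        missing = [c for c in ATOM_COLUMNS if c not in atoms.columns]
        if missing:
            raise ValueError(f"atom table is missing columns {missing}")
        self.atoms = atoms.reset_index(drop=True)
        p_mask = self.atoms["atom_name"] == "P"
        if leaflet_of_p is not None:
            self._leaflet = leaflet_of_p
        elif p_mask.any():
            z = self.atoms.loc[p_mask, "z"]
            mid = z.mean()
            self._leaflet = pd.Series(
                np.where(z.to_numpy() >= mid, "cytoplasmic", "lumenal"),
                index=z.index,
            )
        else:
            self._leaflet = pd.Series(dtype=object)

    # ---------------------------------------------------------------- access
    def p_atoms(self, leaflet: str = "cytoplasmic") -> pd.DataFrame:
        p = self.atoms[self.atoms["atom_name"] == "P"]
        if self._leaflet.empty:
            return p.iloc[0:0]
        keep = self._leaflet[self._leaflet == leaflet].index
        return p.loc[p.index.intersection(keep)]

    @property
    def n_leaflets(self) -> int:
        return int(self._leaflet.nunique()) if not self._leaflet.empty else 0

    def ca(self, residue_index: int) -> np.ndarray:
        sel = self.atoms[
            (self.atoms["residue_index"] == residue_index)
            & (self.atoms["atom_name"] == "CA")
        ]
        if len(sel) == 0:
            raise ValueError(f"residue {residue_index} has no Calpha atom")
        if len(sel) > 1:
            raise ValueError(f"residue {residue_index} has multiple Calpha atoms")
        return sel[["x", "y", "z"]].to_numpy()[0]

    def ca_coords(self, residue_range: tuple[int, int] | None = None) -> np.ndarray:
        sel = self.atoms[self.atoms["atom_name"] == "CA"]
        if residue_range is not None:
            lo, hi = residue_range
            sel = sel[(sel["residue_index"] >= lo) & (sel["residue_index"] <= hi)]
        sel = sel.sort_values("residue_index")
        return sel[["x", "y", "z"]].to_numpy()

    def peptide_residues(self) -> list[int]:
        sel = self.atoms[self.atoms["atom_name"] == "CA"]
        return sorted(sel["residue_index"].unique().tolist())

    # ------------------------------------------------------------------- IO
    @classmethod
    def from_csv(cls, path) -> "MembraneFrame":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.atoms.to_csv(path, index=False)

    @classmethod
    def from_pdb(cls, path, model: int = 1) -> "MembraneFrame":
        frames = frames_from_pdb(path)
        return frames[model - 1]

    @classmethod
    def from_gro(cls, path) -> "MembraneFrame":
        from biotite.structure.io.gro import GROFile

        arr = GROFile.read(str(path)).get_structure(model=1)
        return cls(_atomarray_to_table(arr))

    def to_pdb(self, path) -> None:
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        n = len(self.atoms)
        arr = struc.AtomArray(n)
        arr.coord = self.atoms[["x", "y", "z"]].to_numpy(dtype=float)
        arr.res_id = self.atoms["residue_index"].to_numpy(dtype=int)
        arr.res_name = np.array(self.atoms["residue_name"].tolist(), dtype="U5")
        arr.atom_name = np.array(self.atoms["atom_name"].tolist(), dtype="U6")
        arr.chain_id = np.full(n, "A", dtype="U4")
        arr.element = np.array(
            ["P" if a == "P" else "C" for a in self.atoms["atom_name"]], dtype="U2"
        )
        arr.hetero = np.array([a == "P" for a in self.atoms["atom_name"]], dtype=bool)
        f = PDBFile()
        f.set_structure(arr)
        f.write(str(path))


def _atomarray_to_table(arr) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "residue_index": np.asarray(arr.res_id, dtype=int),
            "residue_name": np.asarray(arr.res_name, dtype=str),
            "atom_name": np.asarray(arr.atom_name, dtype=str),
            "x": arr.coord[:, 0],
            "y": arr.coord[:, 1],
            "z": arr.coord[:, 2],
        }
    )


def frames_from_pdb(path) -> list[MembraneFrame]:
    """Read a (possibly multi-model) PDB file into a list of frames."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    if stack.stack_depth() == 0:
        raise ValueError(f"{path}: no models found")
    frames = []
    for i in range(stack.stack_depth()):
        frames.append(MembraneFrame(_atomarray_to_table(stack[i])))
    return frames


# ------------------------------------------------------------- observables

def phosphate_plane(frame: MembraneFrame, leaflet: str = "cytoplasmic") -> float:
    """Mean z-level of the leaflet's P atoms, in nm."""
    p = frame.p_atoms(leaflet)
    if len(p) < 3:
        raise ValueError(f"need >=3 {leaflet} P atoms to define a plane, found {len(p)}")
    return float(p["z"].mean()) / 10.0


def _insertion_sign(frame: MembraneFrame, plane_z_ang: float) -> float:
    """+1 when insertion points along -z from the cytoplasmic plane.

    With two phosphate leaflets the membrane interior lies toward the
    opposite leaflet; for single-leaflet frames fall back to the side on
    which the peptide's mean Calpha sits.
    """
    other = frame.p_atoms("lumenal")
    if len(other) >= 3:
        return 1.0 if other["z"].mean() < plane_z_ang else -1.0
    ca = frame.ca_coords()
    if ca.size == 0:
        return 1.0
    return 1.0 if ca[:, 2].mean() <= plane_z_ang else -1.0


def residue_depth(frame: MembraneFrame, residue_index: int) -> float:
    """Signed insertion depth (nm) of the residue's Calpha below the
    cytoplasmic phosphate plane; negative values are on the solvent side."""
    plane_nm = phosphate_plane(frame)
    plane_ang = plane_nm * 10.0
    ca = frame.ca(residue_index)
    sign = _insertion_sign(frame, plane_ang)
    return float(sign * (plane_ang - ca[2]) / 10.0)


def depth_profile(frame: MembraneFrame, residue_range: tuple[int, int] | None = None) -> pd.DataFrame:
    """Per-residue insertion depth table (residue, depth_nm)."""
    residues = frame.peptide_residues()
    if residue_range is not None:
        lo, hi = residue_range
        residues = [r for r in residues if lo <= r <= hi]
    return pd.DataFrame(
        {"residue": residues, "depth_nm": [residue_depth(frame, r) for r in residues]}
    )


def pair_distance(frame: MembraneFrame, residue_a: int, residue_b: int,
                  atom_name: str = "CA") -> float:
    """Euclidean distance (Angstrom) between the named atoms of two residues."""
    def atom(res):
        sel = frame.atoms[
            (frame.atoms["residue_index"] == res) & (frame.atoms["atom_name"] == atom_name)
        ]
        if len(sel) == 0:
            raise ValueError(f"residue {res} has no atom {atom_name}")
        return sel[["x", "y", "z"]].to_numpy()[0]

    return float(np.linalg.norm(atom(residue_a) - atom(residue_b)))


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise ValueError("degenerate coordinates: all points coincide")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def tilt_angle(frame: MembraneFrame, residue_range: tuple[int, int]) -> float:
    """Angle (degrees, [0, 90]) between the first principal axis of the
    Calpha trace and the membrane plane; 90 = perpendicular to the plane."""
    coords = frame.ca_coords(residue_range)
    if len(coords) < 3:
        raise ValueError("need >=3 Calpha atoms for a tilt axis")
    if len(np.unique(coords.round(9), axis=0)) < 3:
        raise ValueError("need >=3 distinct Calpha positions for a tilt axis")
    axis = _principal_axis(coords)
    axis = axis / np.linalg.norm(axis)
    return float(np.degrees(np.arcsin(min(1.0, abs(axis[2])))))


def opening_angle(frame: MembraneFrame, arm1_range: tuple[int, int],
                  arm2_range: tuple[int, int], kink_residue: int) -> float:
    """Angle (degrees, [0, 180]) at the kink between the two arm principal
    axes, each oriented away from the kink."""
    kink = frame.ca(kink_residue)
    axes = []
    for rng in (arm1_range, arm2_range):
        coords = frame.ca_coords(rng)
        if len(coords) < 3:
            raise ValueError(f"arm {rng} needs >=3 Calpha atoms")
        axis = _principal_axis(coords)
        away = coords.mean(axis=0) - kink
        if np.dot(axis, away) < 0:
            axis = -axis
        axes.append(axis / np.linalg.norm(axis))
    cosang = float(np.clip(np.dot(axes[0], axes[1]), -1.0, 1.0))
    return float(np.degrees(math.acos(cosang)))


def classify_conformation(kink_depth_nm: float, tilt_deg: float,
                          deep_depth_min: float = 1.0, shallow_depth_max: float = 0.5,
                          deep_tilt_min: float = 55.0, shallow_tilt_max: float = 45.0) -> str:
    """Label a hairpin state from its kink depth and tilt.

    ``deep_V`` needs a deep kink and a near-perpendicular tilt,
    ``open_shallow`` a surface-proximal kink and a flat tilt; anything in
    between is ``ambiguous``.
    """
    if not (np.isfinite(kink_depth_nm) and np.isfinite(tilt_deg)):
        raise ValueError("kink depth and tilt must be finite")
    if kink_depth_nm >= deep_depth_min and tilt_deg >= deep_tilt_min:
        return "deep_V"
    if kink_depth_nm <= shallow_depth_max and tilt_deg <= shallow_tilt_max:
        return "open_shallow"
    return "ambiguous"


@dataclass
class StructureObservables:
    kink_depth_nm: float
    tilt_deg: float
    tip_distance_ang: float
    opening_angle_deg: float
    conformation: str

    def to_dict(self) -> dict:
        return {
            "kink_depth_nm": self.kink_depth_nm,
            "tilt_deg": self.tilt_deg,
            "tip_distance_ang": self.tip_distance_ang,
            "opening_angle_deg": self.opening_angle_deg,
            "conformation": self.conformation,
        }


def measure_structure(frame: MembraneFrame, kink_residue: int = 102,
                      tip_residues: tuple[int, int] = (91, 118),
                      residue_range: tuple[int, int] = (80, 128),
                      arm1_range: tuple[int, int] | None = None,
                      arm2_range: tuple[int, int] | None = None) -> StructureObservables:
    """All scalar observables of one hairpin frame, plus its state call."""
    if arm1_range is None:
        arm1_range = (residue_range[0], kink_residue - 1)
    if arm2_range is None:
        arm2_range = (kink_residue + 1, residue_range[1])
    depth = residue_depth(frame, kink_residue)
    tilt = tilt_angle(frame, residue_range)
    return StructureObservables(
        kink_depth_nm=depth,
        tilt_deg=tilt,
        tip_distance_ang=pair_distance(frame, *tip_residues),
        opening_angle_deg=opening_angle(frame, arm1_range, arm2_range, kink_residue),
        conformation=classify_conformation(depth, tilt),
    )


def frame_average(frames: list[MembraneFrame], observable, window: float = 0.25) -> tuple[float, float]:
    """Average an observable over the trailing ``window`` fraction of frames.

    Returns (mean, SEM across the used frames; 0 for a single frame).
    """
    if not frames:
        raise ValueError("no frames given")
    if not (0 < window <= 1):
        raise ValueError("window must lie in (0, 1]")
    n_used = max(1, int(math.ceil(window * len(frames))))
    vals = np.array([observable(f) for f in frames[-n_used:]], dtype=float)
    mean = float(vals.mean())
    sem = 0.0 if len(vals) < 2 else float(vals.std(ddof=1) / math.sqrt(len(vals)))
    return mean, sem
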