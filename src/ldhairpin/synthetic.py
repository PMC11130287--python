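"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here,
emulating the statistical structure of the corresponding wet-lab or
simulation measurement:

* per-residue PEGylation gel-band tables for a deep-V (bilayer) or
  open-shallow (LD monolayer) hairpin state,
* cwEPR power-saturation curves on the standard 2-30 dB grid,
* toy hairpin-in-membrane Calpha structures with prescribed kink depth,
  tilt and arm-tip distance,
* Boltzmann-distributed umbrella-window samples from an analytic free
  energy profile,
* crosslinking/PEGylation lane tables.

All generators are pure functions of their spec plus a seed; independent
sub-streams are derived per residue/window so that adding one element
never reshuffles the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import epr, geometry, wham
from .sequence import SCAN_START, SCAN_END, wt_aa, wt_aa3

CONFORMATIONS = ("deep_V", "open_shallow")

#: Segment plan of the hairpin scan: fully exposed termini, short
#: interfacial stretches, and the 29-residue membrane-embedded core
#: W94-R122 flanked by them.
DEFAULT_SEGMENTS: dict[str, tuple[int, int]] = {
    "exposed_N": (80, 89),
    "interface_N": (90, 93),
    "embedded": (94, 122),
    "interface_C": (123, 123),
    "exposed_C": (124, 128),
}

#: Canonical alpha-helix periodicity (residues/turn) used for the partial
#: solvent exposure of the interfacial helix in the open-shallow state.
HELIX_PERIOD = 3.6

#: True relative accessibility (percent) per segment class.
ACC_EXPOSED = 100.0
ACC_INTERFACE = 50.0
ACC_EMBEDDED_DEEP = 5.0
ACC_EMBEDDED_SHALLOW_BASE = 30.0
ACC_EMBEDDED_SHALLOW_AMP = 15.0

#: Detergent-lane PEGylation efficiency of the positive control, and the
#: (failing) efficiency at residues whose positive control is unreliable.
DETERGENT_EFFICIENCY = 0.9
LOW_CONTROL_EFFICIENCY = 0.05

#: Thermal energy at 310 K in kJ/mol.
KT_310 = wham.kT_from_temperature(310.0)

# The cysteine scan covers S80-R128 = 49 positions even though the source
# mutant library was reported as 48 clones; the generator covers all 49
# and records the discrepancy in the ground-truth sidecar.
SCAN_COVERAGE_NOTE = (
    "49 positions generated for the 80-128 scan; the source library was "
    "reported with 48 clones without naming the absent position"
)


def _rng(*key) -> np.random.Generator:
    return np.random.default_rng(tuple(int(k) for k in key))


def _lognormal_noise(rng: np.random.Generator, sd_fraction: float, size=None):
    """Multiplicative log-normal factor with unit median; for small
    sd_fraction the coefficient of variation is ~sd_fraction."""
    if sd_fraction == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = float(np.sqrt(np.log1p(sd_fraction ** 2)))
    return np.exp(rng.normal(0.0, sigma, size=size))


# =================================================================
# accessibility (PEGylation) profiles
# =================================================================

@dataclass(frozen=True)
class GroundTruthSpec:
    """Ground truth for one membrane context of the accessibility scan."""

    conformation: str = "deep_V"
    residue_range: tuple[int, int] = (SCAN_START, SCAN_END)
    segment_boundaries: dict = field(default_factory=lambda: dict(DEFAULT_SEGMENTS))
    noise_sd_fraction: float = 0.0
    seed: int = 0
    n_replicates: int = 2
    low_control_residues: tuple[int, ...] = (102, 113, 114)

    def __post_init__(self):
        if self.conformation not in CONFORMATIONS:
            raise ValueError(
                f"unknown conformation {self.conformation!r}; expected one of {CONFORMATIONS}"
            )
        if self.noise_sd_fraction < 0:
            raise ValueError("noise_sd_fraction must be >= 0")
        lo, hi = self.residue_range
        if hi < lo:
            raise ValueError("empty residue range")
        covered = sorted(
            r for (a, b) in self.segment_boundaries.values() for r in range(a, b + 1)
        )
        if covered != list(range(lo, hi + 1)):
            raise ValueError("segments must be disjoint and jointly cover residue_range")

    def segment_of(self, residue: int) -> str:
        for label, (a, b) in self.segment_boundaries.items():
            if a <= residue <= b:
                return label
        raise ValueError(f"residue {residue} outside residue_range")


def true_accessibility(spec: GroundTruthSpec, residue: int) -> float:
    """Noise-free relative accessibility (percent) at one residue."""
    label = spec.segment_of(residue)
    if label.startswith("exposed"):
        return ACC_EXPOSED
    if label.startswith("interface"):
        return ACC_INTERFACE
    if spec.conformation == "deep_V":
        return ACC_EMBEDDED_DEEP
    start = spec.segment_boundaries[label][0]
    phase = 2.0 * np.pi * (residue - start) / HELIX_PERIOD
    return ACC_EMBEDDED_SHALLOW_BASE + ACC_EMBEDDED_SHALLOW_AMP * np.sin(phase)


def gen_accessibility_profile(spec: GroundTruthSpec) -> pd.DataFrame:
    """Gel-band intensity table for the single-cysteine scan.

    Columns: residue, wt_aa, lane, band, intensity, replicate. Per
    residue and replicate there are three lanes (no_mPEG, mPEG,
    detergent_mPEG), each with 0-PEG and 1-PEG bands; band intensities
    carry multiplicative log-normal noise of the spec's sd fraction.
    """
    lo, hi = spec.residue_range
    total = 100.0
    rows = []
    for residue in range(lo, hi + 1):
        acc = true_accessibility(spec, residue) / 100.0
        d_eff = (LOW_CONTROL_EFFICIENCY if residue in spec.low_control_residues
                 else DETERGENT_EFFICIENCY)
        native_frac = d_eff * acc
        for rep in range(1, spec.n_replicates + 1):
            rng = _rng(spec.seed, residue, rep)
            lanes = {
                "no_mPEG": {"PEG0": total, "PEG1": 0.0},
                "mPEG": {"PEG0": total * (1 - native_frac), "PEG1": total * native_frac},
                "detergent_mPEG": {"PEG0": total * (1 - d_eff), "PEG1": total * d_eff},
            }
            for lane, bands in lanes.items():
                for band, intensity in bands.items():
                    noisy = intensity * _lognormal_noise(rng, spec.noise_sd_fraction)
                    rows.append({
                        "residue": residue, "wt_aa": wt_aa(residue), "lane": lane,
                        "band": band, "intensity": float(noisy), "replicate": rep,
                    })
    return pd.DataFrame(rows)


def ground_truth_sidecar(spec: GroundTruthSpec) -> dict:
    """JSON-serializable record of what the generator encoded."""
    lo, hi = spec.residue_range
    return {
        "spec": {**asdict(spec), "segment_boundaries": {
            k: list(v) for k, v in spec.segment_boundaries.items()}},
        "true_accessibility_pct": {
            str(r): float(true_accessibility(spec, r)) for r in range(lo, hi + 1)
        },
        "coverage_note": SCAN_COVERAGE_NOTE,
    }


# =================================================================
# cwEPR saturation curves
# =================================================================

def gen_saturation_curve(I: float, P_half: float, epsilon: float,
                         powers=None, noise_sd: float = 0.0, seed: int = 0,
                         site: str = "", condition: str = "N2") -> epr.SaturationCurve:
    """Saturation curve A(P) with additive Gaussian noise.

    Defaults to the standard 0.2-126.2 mW grid (2-30 dB from a 200 mW
    source).
    """
    if P_half <= 0:
        raise ValueError("P_half must be positive")
    if not (epr.EPSILON_BOUNDS[0] <= epsilon <= epr.EPSILON_BOUNDS[1]):
        raise ValueError(f"epsilon must lie in {epr.EPSILON_BOUNDS}")
    powers = epr.default_power_grid() if powers is None else np.asarray(powers, dtype=float)
    if np.any(powers <= 0):
        raise ValueError("powers must be strictly positive")
    amplitudes = epr.saturation_model(powers, I, P_half, epsilon)
    if noise_sd > 0:
        amplitudes = amplitudes + _rng(seed).normal(0.0, noise_sd, size=powers.size)
    return epr.SaturationCurve(site, condition, powers, amplitudes)


#: Spin-labeled positions of the purified-peptide EPR series.
DEFAULT_EPR_SITES = (81, 93, 96, 101, 107, 113, 115, 118, 119, 127)

#: Intrinsic (N2) half-saturation power and the geometric-mean collision
#: increment used to realize a target depth parameter.
EPR_P_HALF_N2 = 2.0
EPR_DELTA_SCALE = 3.0


def phi_ground_truth(spec: GroundTruthSpec, residue: int,
                     exposed_min: float = 75.0, embedded_max: float = 25.0) -> float:
    """Target depth parameter implied by the shared accessibility plan:
    embedded positions get +1.5, exposed -1.5, interfacial 0."""
    acc = true_accessibility(spec, residue)
    if acc >= exposed_min:
        return -1.5
    if acc <= embedded_max:
        return 1.5
    return 0.0


def gen_epr_sites(spec: GroundTruthSpec, sites=DEFAULT_EPR_SITES,
                  noise_sd: float = 0.0, seed: int | None = None,
                  ) -> tuple[pd.DataFrame, dict]:
    """Per-site saturation-curve triples (N2, O2, NiEDDA) whose half-
    saturation powers encode the depth parameter implied by the spec's
    segment plan.

    Returns (tidy table: site, condition, power_mW, amplitude; ground
    truth {site: phi}).
    """
    seed = spec.seed if seed is None else seed
    rows = []
    truth = {}
    for j, residue in enumerate(sites):
        phi = phi_ground_truth(spec, residue)
        truth[residue] = phi
        p_half = {
            "N2": EPR_P_HALF_N2,
            "O2": EPR_P_HALF_N2 + EPR_DELTA_SCALE * float(np.exp(phi / 2.0)),
            "NiEDDA": EPR_P_HALF_N2 + EPR_DELTA_SCALE * float(np.exp(-phi / 2.0)),
        }
        site = f"{wt_aa(residue)}{residue}C"
        for ci, cond in enumerate(epr.CONDITIONS):
            curve = gen_saturation_curve(
                I=1.0, P_half=p_half[cond], epsilon=1.5,
                noise_sd=noise_sd, seed=(seed * 1000 + j * 10 + ci),
                site=site, condition=cond,
            )
            for p, a in zip(curve.powers, curve.amplitudes):
                rows.append({"site": site, "condition": cond,
                             "power_mW": float(p), "amplitude": float(a)})
    return pd.DataFrame(rows), truth


# =================================================================
# hairpin structures
# =================================================================

@dataclass(frozen=True)
class HairpinGeometrySpec:
    """Build parameters for a toy helix-kink-helix hairpin in a membrane.

    kink_depth is in nm below the cytoplasmic phosphate plane; tilt_deg
    is the angle of the peptide's first principal axis against the
    membrane plane; arm_tip_distance is the Calpha 91-118 distance in
    Angstrom; helix_rise is the per-residue rise along each arm.
    """

    kink_depth: float = 2.0  # nm
    tilt_deg: float = 80.0
    arm_tip_distance: float = 20.0  # Angstrom
    helix_rise: float = 1.5  # Angstrom / residue
    seed: int = 0
    residue_range: tuple[int, int] = (SCAN_START, SCAN_END)
    kink_residue: int = 102
    tip_residues: tuple[int, int] = (91, 118)
    lumenal_offset: float = 3.8  # nm below the cytoplasmic plane
    n_p_per_leaflet: int = 120
    p_jitter_sd: float = 0.5  # Angstrom

    @classmethod
    def deep_v(cls, seed: int = 0) -> "HairpinGeometrySpec":
        return cls(kink_depth=2.0, tilt_deg=80.0, arm_tip_distance=20.0, seed=seed)

    @classmethod
    def open_shallow(cls, seed: int = 0) -> "HairpinGeometrySpec":
        return cls(kink_depth=0.1, tilt_deg=30.0, arm_tip_distance=36.0, seed=seed)


def _v_half_angle(spec: HairpinGeometrySpec) -> float:
    """Half-opening angle (radians) that realizes the requested tip
    distance given the arm lengths to the tip residues."""
    s1 = (spec.kink_residue - spec.tip_residues[0]) * spec.helix_rise
    s2 = (spec.tip_residues[1] - spec.kink_residue) * spec.helix_rise
    d2 = spec.arm_tip_distance ** 2
    lo, hi = (s1 - s2) ** 2, (s1 + s2) ** 2
    if not (lo <= d2 <= hi):
        raise ValueError(
            "infeasible geometry: arm_tip_distance "
            f"{spec.arm_tip_distance:g} A outside the reachable range "
            f"[{np.sqrt(lo):.2f}, {np.sqrt(hi):.2f}] A for these arm lengths"
        )
    sin2 = (d2 - lo) / (hi - lo)
    return float(np.arcsin(np.sqrt(sin2)))


def gen_hairpin_structure(spec: HairpinGeometrySpec) -> geometry.MembraneFrame:
    """Build a Calpha-trace hairpin plus phosphate reference layers.

    The trace is a planar helix-kink-helix V: two straight arms meeting
    at the kink residue, opened to match the requested tip distance, then
    rigidly rotated so the principal axis makes ``tilt_deg`` with the
    membrane plane and translated so the kink sits ``kink_depth`` nm
    below the cytoplasmic phosphate plane (mean z = 0). A lower P layer
    at ``-lumenal_offset`` marks the opposite membrane surface.
    """
    lo, hi = spec.residue_range
    if not (lo < spec.kink_residue < hi):
        raise ValueError("kink residue must lie inside the residue range")
    gamma = _v_half_angle(spec)

    a1 = np.array([np.sin(gamma), 0.0, np.cos(gamma)])   # N-arm direction
    a2 = np.array([-np.sin(gamma), 0.0, np.cos(gamma)])  # C-arm direction
    residues = np.arange(lo, hi + 1)
    coords = np.zeros((residues.size, 3))
    for i, res in enumerate(residues):
        if res <= spec.kink_residue:
            coords[i] = (spec.kink_residue - res) * spec.helix_rise * a1
        else:
            coords[i] = (res - spec.kink_residue) * spec.helix_rise * a2

    # Rotate rigidly (about y) so the principal axis hits the target tilt.
    axis = _first_axis(coords)
    phi = np.degrees(np.arctan2(axis[2], axis[0]))  # axis orientation in xz
    target = spec.tilt_deg if phi <= 90.0 else 180.0 - spec.tilt_deg
    beta = np.radians(target - phi)
    rot = np.array([
        [np.cos(beta), 0.0, -np.sin(beta)],
        [0.0, 1.0, 0.0],
        [np.sin(beta), 0.0, np.cos(beta)],
    ])
    coords = coords @ rot.T

    kink_idx = int(np.nonzero(residues == spec.kink_residue)[0][0])
    coords = coords + (np.array([0.0, 0.0, -10.0 * spec.kink_depth]) - coords[kink_idx])

    rows = [
        {
            "residue_index": int(res), "residue_name": wt_aa3(int(res)),
            "atom_name": "CA", "x": float(c[0]), "y": float(c[1]), "z": float(c[2]),
        }
        for res, c in zip(residues, coords)
    ]

    rng = _rng(spec.seed, 7)
    for leaflet_i, z0 in enumerate((0.0, -10.0 * spec.lumenal_offset)):
        xy = rng.uniform(-35.0, 35.0, size=(spec.n_p_per_leaflet, 2))
        z = rng.normal(0.0, spec.p_jitter_sd, size=spec.n_p_per_leaflet)
        z -= z.mean()  # the leaflet's mean plane is exactly z0
        for i in range(spec.n_p_per_leaflet):
            rows.append({
                "residue_index": 1000 + leaflet_i * 1000 + i, "residue_name": "POP",
                "atom_name": "P", "x": float(xy[i, 0]), "y": float(xy[i, 1]),
                "z": float(z0 + z[i]),
            })
    return geometry.MembraneFrame(pd.DataFrame(rows))


def _first_axis(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if axis[2] < 0 or (axis[2] == 0 and axis[0] < 0):
        axis = -axis
    return axis / np.linalg.norm(axis)


# =================================================================
# umbrella sampling
# =================================================================

@dataclass(frozen=True)
class AnalyticPMF:
    """Closed-form free-energy profile used as the WHAM validation oracle.

    Forms: ``harmonic`` (params: kappa [kJ/mol/nm^2]), ``double_well``
    (params: height [kJ/mol], half_separation [nm]) and ``tabulated``
    (params: grid, values; linear interpolation).
    """

    form: str = "harmonic"
    params: dict = field(default_factory=lambda: {"kappa": 50.0})
    domain: tuple[float, float] = (-2.0, 2.0)

    def __post_init__(self):
        if self.form not in ("harmonic", "double_well", "tabulated"):
            raise ValueError(f"unknown PMF form {self.form!r}")
        if not self.domain[0] < self.domain[1]:
            raise ValueError("empty domain")

    def __call__(self, xi):
        xi = np.asarray(xi, dtype=float)
        if self.form == "harmonic":
            g = 0.5 * self.params["kappa"] * xi ** 2
        elif self.form == "double_well":
            h, a = self.params["height"], self.params["half_separation"]
            g = h * ((xi / a) ** 2 - 1.0) ** 2
        else:
            g = np.interp(xi, np.asarray(self.params["grid"]), np.asarray(self.params["values"]))
        if not np.all(np.isfinite(g)):
            raise ValueError("PMF must be finite on its domain")
        return g


def gen_umbrella_samples(pmf: AnalyticPMF, centers, k: float = 1000.0,
                         n_per_window: int = 1000, kT: float = KT_310,
                         seed: int = 0, grid_step: float = 1e-4,
                         ) -> list[wham.UmbrellaWindow]:
    """Draw i.i.d. samples from each window's biased Boltzmann density.

    Sampling is by inverse CDF on a fine grid (default 1e-4 nm) of
    p_i(xi) proportional to exp(-[G(xi) + k/2 (xi - xi_i)^2]/kT), which is
    exact in the grid-resolution limit and autocorrelation-free.
    """
    centers = np.asarray(centers, dtype=float)
    lo, hi = pmf.domain
    if np.any(centers < lo) or np.any(centers > hi):
        raise ValueError("window center outside the PMF domain")
    if n_per_window < 1:
        raise ValueError("n_per_window must be >= 1")
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    G = pmf(grid)
    windows = []
    for i, c in enumerate(centers):
        logp = -(G + 0.5 * k * (grid - c) ** 2) / kT
        p = np.exp(logp - logp.max()) + 1e-300
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * grid_step)])
        cdf /= cdf[-1]
        u = _rng(seed, i).uniform(size=n_per_window)
        samples = np.interp(u, cdf, grid)
        windows.append(wham.UmbrellaWindow(window_id=i, center=float(c),
                                           force_constant=float(k), samples=samples))
    return windows


# =================================================================
# crosslinking lanes
# =================================================================

def gen_crosslink_lanes(true_crosslinked_fraction: dict[str, float],
                        peg_efficiency: float = 0.7,
                        noise_sd_fraction: float = 0.0, seed: int = 0,
                        total: float = 100.0) -> pd.DataFrame:
    """DMSO/BMH lane band intensities for a double-cysteine mutant.

    Per context, a fraction of molecules is intramolecularly crosslinked
    by BMH and thereby rendered non-PEGylatable (0-PEG); the remainder
    PEGylates per-site with ``peg_efficiency`` (binomial over the two
    cysteines). Band intensities carry multiplicative log-normal noise.
    """
    p = peg_efficiency
    if not (0 <= p <= 1):
        raise ValueError("peg_efficiency must lie in [0, 1]")
    rows = []
    for ctx_i, (context, f) in enumerate(sorted(true_crosslinked_fraction.items())):
        if not (0 <= f <= 1):
            raise ValueError(f"crosslinked fraction for {context!r} must lie in [0, 1]")
        base = {"PEG0": (1 - p) ** 2, "PEG1": 2 * p * (1 - p), "PEG2": p ** 2}
        lanes = {
            "DMSO": base,
            "BMH": {
                "PEG0": f + (1 - f) * base["PEG0"],
                "PEG1": (1 - f) * base["PEG1"],
                "PEG2": (1 - f) * base["PEG2"],
            },
        }
        rng = _rng(seed, ctx_i)
        for lane, bands in lanes.items():
            for band, frac in bands.items():
                rows.append({
                    "context": context, "lane": lane, "band": band,
                    "intensity": float(total * frac * _lognormal_noise(rng, noise_sd_fraction)),
                })
    return pd.DataFrame(rows)


# =================================================================
# writers
# =================================================================

def write_ground_truth_json(spec: GroundTruthSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(ground_truth_sidecar(spec), fh, indent=2, sort_keys=True)
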