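"""Weighted histogram analysis method (WHAM) for 1-D umbrella sampling.

Umbrella windows restrain a reaction coordinate xi with harmonic biases
U_i(xi) = k_i/2 (xi - xi_i)^2. WHAM merges the biased histograms into the
unbiased probability per bin b by self-consistent iteration of

    P(b) = sum_i n_i(b) / sum_i N_i exp[(f_i - U_i(b)) / kT]
    f_i  = -kT ln sum_b P(b) exp[-U_i(b) / kT]

and reports the potential of mean force G(b) = -kT ln P(b), anchored so
its minimum over occupied bins is zero. Errors are estimated by
bootstrapping over whole windows (resampling the window set with
replacement and re-solving).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Boltzmann constant times Avogadro in kJ/(mol K).
KB_KJ_PER_MOL_K = 0.008314462618


def kT_from_temperature(temperature_K: float = 310.0) -> float:
    """Thermal energy kT in kJ/mol at the given temperature (default 310 K)."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    return KB_KJ_PER_MOL_K * temperature_K


@dataclass
class UmbrellaWindow:
    """Biased reaction-coordinate samples from one umbrella window."""

    window_id: int
    center: float  # nm
    force_constant: float  # kJ mol^-1 nm^-2
    samples: np.ndarray  # nm
    burn_in_fraction: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.force_constant < 0:
            raise ValueError("force constant must be non-negative")
        if not (0 <= self.burn_in_fraction < 1):
            raise ValueError("burn_in_fraction must lie in [0, 1)")
        if self.retained.size == 0:
            raise ValueError(f"window {self.window_id}: no samples left after burn-in")

    @property
    def retained(self) -> np.ndarray:
        """Samples after burn-in removal."""
        start = int(self.burn_in_fraction * self.samples.size)
        return self.samples[start:]


@dataclass
class PMFProfile:
    """Free-energy profile on a bin grid, anchored to zero at its minimum."""

    bin_centers: np.ndarray
    free_energy: np.ndarray  # kJ/mol; NaN on unoccupied bins
    kT: float
    converged: bool
    iterations: int
    sem: np.ndarray | None = None
    message: str = ""
    window_free_energies: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def occupied(self) -> np.ndarray:
        return np.isfinite(self.free_energy)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"bin_center_nm": self.bin_centers, "G_kJmol": self.free_energy})
        if self.sem is not None:
            out["sem_kJmol"] = self.sem
        return out


def plan_windows(pull_rate: float, duration: float, spacing: float,
                 start: float = 0.0) -> np.ndarray:
    """Equally spaced umbrella centers covering the pulled span.

    The span is ``pull_rate * duration`` and both endpoints are included:
    count = floor(span / spacing) + 1. A spacing larger than the span
    degenerates to a single window at ``start``.
    """
    if pull_rate <= 0 or duration <= 0 or spacing <= 0:
        raise ValueError("pull_rate, duration and spacing must be positive")
    span = pull_rate * duration
    n = int(math.floor(span / spacing + 1e-9)) + 1
    return start + spacing * np.arange(max(n, 1))


def build_histograms(windows: list[UmbrellaWindow], bin_width: float = 0.02,
                     xi_range: tuple[float, float] | None = None,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram every window's retained samples on a shared grid.

    Returns (counts with shape [n_windows, n_bins], bin edges). The range
    must already cover all samples; out-of-range samples are an error so
    that truncation can never silently bias the profile.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not windows:
        raise ValueError("no windows given")
    if xi_range is None:
        lo = min(w.retained.min() for w in windows)
        hi = max(w.retained.max() for w in windows)
        lo -= bin_width
        hi += bin_width
    else:
        lo, hi = xi_range
    n_bins = max(1, int(math.ceil((hi - lo) / bin_width - 1e-9)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts = np.zeros((len(windows), n_bins))
    for i, w in enumerate(windows):
        s = w.retained
        if s.min() < edges[0] or s.max() > edges[-1]:
            raise ValueError(
                f"window {w.window_id}: samples outside histogram range "
                f"[{edges[0]:g}, {edges[-1]:g}]; widen the range"
            )
        counts[i], _ = np.histogram(s, bins=edges)
    return counts, edges


def _overlap_gaps(counts: np.ndarray, centers_order: np.ndarray) -> list[tuple[int, int]]:
    """Adjacent window pairs (by center) sharing no occupied bin."""
    gaps = []
    occ = counts > 0
    for a, b in zip(centers_order[:-1], centers_order[1:]):
        if not np.any(occ[a] & occ[b]):
            gaps.append((int(a), int(b)))
    return gaps


def wham_solve(counts: np.ndarray, windows: list[UmbrellaWindow], kT: float,
               tolerance_kT: float = 1e-7, max_iterations: int = 100_000,
               edges: np.ndarray | None = None, bin_centers: np.ndarray | None = None,
               f_init: np.ndarray | None = None) -> PMFProfile:
    """Self-consistent WHAM solution of the coupled equations.

    ``counts`` is the [n_windows, n_bins] histogram matrix on the grid
    described by ``edges`` (or ``bin_centers``). Iteration stops when
    max_i |delta f_i| < tolerance_kT * kT. Non-overlapping adjacent
    windows yield ``converged=False`` with the gap named and the profile
    withheld (all-NaN).
    """
    counts = np.asarray(counts, dtype=float)
    if bin_centers is None:
        if edges is None:
            raise ValueError("provide edges or bin_centers")
        bin_centers = 0.5 * (edges[:-1] + edges[1:])
    bin_centers = np.asarray(bin_centers, dtype=float)
    if counts.shape != (len(windows), bin_centers.size):
        raise ValueError("counts shape does not match windows x bins")

    centers = np.array([w.center for w in windows])
    ks = np.array([w.force_constant for w in windows])
    order = np.argsort(centers)
    gaps = _overlap_gaps(counts, order)
    nan = np.full(bin_centers.size, np.nan)
    if gaps:
        ids = ", ".join(f"({windows[a].window_id}, {windows[b].window_id})" for a, b in gaps)
        return PMFProfile(bin_centers, nan, kT, False, 0,
                          message=f"no histogram overlap between adjacent windows: {ids}")

    U = 0.5 * ks[:, None] * (bin_centers[None, :] - centers[:, None]) ** 2
    A = np.exp(-U / kT)  # bias Boltzmann factors; underflow to 0 is benign
    N = counts.sum(axis=1)
    ntot = counts.sum(axis=0)
    occ = ntot > 0

    f = np.zeros(len(windows)) if f_init is None else np.array(f_init, dtype=float)
    f = f - f[0]
    tol = tolerance_kT * kT
    iterations = 0
    converged = False
    P = np.zeros(bin_centers.size)
    for iterations in range(1, max_iterations + 1):
        g = np.exp(f / kT)
        denom = (N * g) @ A  # per-bin normalization
        with np.errstate(divide="ignore", invalid="ignore"):
            P = np.where(occ & (denom > 0), ntot / np.where(denom > 0, denom, 1.0), 0.0)
        Z = A @ P
        f_new = -kT * np.log(Z)
        f_new -= f_new[0]
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tol:
            converged = True
            break

    with np.errstate(divide="ignore"):
        G = np.where(P > 0, -kT * np.log(np.where(P > 0, P, 1.0)), np.nan)
    if np.any(np.isfinite(G)):
        G = G - np.nanmin(G)
    return PMFProfile(bin_centers, G, kT, converged, iterations,
                      window_free_energies=f)


def bootstrap_sem(counts: np.ndarray, windows: list[UmbrellaWindow], kT: float,
                  n_boot: int = 50, seed: int = 0, **solve_kwargs) -> np.ndarray:
    """Bootstrap SEM of the profile, resampling whole windows.

    The resampling unit is the window histogram: each replicate draws
    ``n_windows`` windows with replacement, re-solves WHAM, and the SEM
    per bin is the standard deviation of the anchored profiles across
    replicates (bins missing in a replicate are skipped for it).
    """
    if n_boot < 2:
        raise ValueError("need n_boot >= 2")
    counts = np.asarray(counts, dtype=float)
    base = wham_solve(counts, windows, kT, **solve_kwargs)
    rng = np.random.default_rng(seed)
    n_w = len(windows)
    profiles = np.full((n_boot, counts.shape[1]), np.nan)
    for r in range(n_boot):
        idx = rng.integers(0, n_w, size=n_w)
        sub = [windows[i] for i in idx]
        warm = base.window_free_energies[idx] if base.window_free_energies.size else None
        prof = wham_solve(counts[idx], sub, kT, bin_centers=base.bin_centers,
                          f_init=warm, **{k: v for k, v in solve_kwargs.items()
                                          if k not in ("edges", "bin_centers", "f_init")})
        # replicates whose window draw disconnects or fails to converge
        # carry no estimate and are skipped
        if prof.converged:
            profiles[r] = prof.free_energy
    n_ok = np.sum(np.isfinite(profiles), axis=0)
    sem = np.full(profiles.shape[1], np.nan)
    ok = n_ok >= 2
    if np.any(ok):
        cols = np.where(np.isfinite(profiles[:, ok]), profiles[:, ok], np.nan)
        with np.errstate(invalid="ignore"):
            mean = np.nansum(cols, axis=0) / n_ok[ok]
            var = np.nansum((cols - mean) ** 2, axis=0) / (n_ok[ok] - 1)
        sem[ok] = np.sqrt(var)
    return sem


def estimate_pmf(windows: list[UmbrellaWindow], temperature_K: float = 310.0,
                 bin_width: float = 0.02, xi_range: tuple[float, float] | None = None,
                 n_boot: int = 0, seed: int = 0,
                 tolerance_kT: float = 1e-7, max_iterations: int = 100_000) -> PMFProfile:
    """Histogram the windows, solve WHAM and (optionally) bootstrap errors."""
    kT = kT_from_temperature(temperature_K)
    counts, edges = build_histograms(windows, bin_width, xi_range)
    profile = wham_solve(counts, windows, kT, tolerance_kT=tolerance_kT,
                         max_iterations=max_iterations, edges=edges)
    if n_boot >= 2 and profile.converged:
        profile.sem = bootstrap_sem(counts, windows, kT, n_boot=n_boot, seed=seed,
                                    tolerance_kT=tolerance_kT,
                                    max_iterations=max_iterations,
                                    bin_centers=profile.bin_centers)
    return profile


def recovery_rmse(profile: PMFProfile, reference, counts: np.ndarray | None = None,
                  min_counts: int = 25) -> float:
    """RMSE (kJ/mol) between the anchored profile and an analytic reference.

    Both profiles are anchored at their minimum over the compared bins.
    ``min_counts`` restricts the comparison to bins holding at least that
    many total samples: a bin with n counts carries a free-energy sampling
    error of roughly kT/sqrt(n), so near-empty tail bins (whose individual
    error is several kT) would otherwise swamp the estimator comparison.
    The default of 25 keeps per-bin sampling error below about kT/5.
    """
    mask = profile.occupied.copy()
    if counts is not None:
        mask &= np.asarray(counts).sum(axis=0) >= min_counts
    if not np.any(mask):
        raise ValueError("no bins satisfy the comparison criteria")
    g = profile.free_energy[mask]
    ref = np.asarray(reference(profile.bin_centers[mask]), dtype=float)
    err = (g - g.min()) - (ref - ref.min())
    return float(np.sqrt(np.mean(err ** 2)))


# ------------------------------------------------------------------- IO

def windows_to_frame(windows: list[UmbrellaWindow]) -> pd.DataFrame:
    rows = []
    for w in windows:
        rows.append(pd.DataFrame({
            "window_id": w.window_id, "center_nm": w.center,
            "k": w.force_constant, "xi_nm": w.samples,
        }))
    return pd.concat(rows, ignore_index=True)


def windows_from_frame(df: pd.DataFrame, burn_in_fraction: float = 0.0) -> list[UmbrellaWindow]:
    windows = []
    for wid, grp in df.groupby("window_id", sort=True):
        windows.append(UmbrellaWindow(
            window_id=int(wid),
            center=float(grp["center_nm"].iloc[0]),
            force_constant=float(grp["k"].iloc[0]),
            samples=grp["xi_nm"].to_numpy(),
            burn_in_fraction=burn_in_fraction,
        ))
    return windows


def read_umbrella_csv(path, burn_in_fraction: float = 0.0) -> list[UmbrellaWindow]:
    return windows_from_frame(pd.read_csv(path), burn_in_fraction)


def write_umbrella_csv(windows: list[UmbrellaWindow], path) -> None:
    windows_to_frame(windows).to_csv(path, index=False)
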