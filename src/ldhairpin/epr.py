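"""cwEPR power-saturation analysis and membrane depth parameters.

Site-directed spin labels saturate differently depending on collisions with
paramagnetic relaxants: lipid-soluble O2 is enriched in the membrane core,
water-soluble NiEDDA is excluded from it, and non-paramagnetic N2 provides
the intrinsic relaxation baseline. The peak-to-peak amplitude ``A`` of the
central EPR line as a function of incident microwave power ``P`` follows

    A = I * sqrt(P) * [1 + (2**(1/eps) - 1) * P / P_half]**(-eps)

where ``P_half`` is the power at which the amplitude falls to half its
unsaturated extrapolation and ``eps`` is the saturation-homogeneity
exponent (1.5 for homogeneous, 0.5 for inhomogeneous saturation). The
membrane depth parameter compares the relaxant-induced increments of
``P_half`` over the N2 baseline:

    phi = ln[ dP_half(O2) / dP_half(NiEDDA) ]

Positive phi means membrane-embedded, negative means solvent-exposed, and
values near zero place the label at the membrane-solvent interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

CONDITIONS = ("N2", "O2", "NiEDDA")

#: Default klystron source power (mW); with the 2-30 dB attenuation grid it
#: yields incident powers from 126.19 down to 0.2 mW.
DEFAULT_SOURCE_POWER_MW = 200.0

EPSILON_BOUNDS = (0.5, 1.5)


def attenuation_to_power(db: float | np.ndarray, source_power_mw: float = DEFAULT_SOURCE_POWER_MW):
    """Convert attenuator setting (dB) to incident microwave power (mW)."""
    db = np.asarray(db, dtype=float)
    if np.any(db < 0):
        raise ValueError("attenuation must be >= 0 dB")
    if source_power_mw <= 0:
        raise ValueError("source power must be positive")
    out = source_power_mw * 10.0 ** (-db / 10.0)
    return float(out) if out.ndim == 0 else out


def default_power_grid(source_power_mw: float = DEFAULT_SOURCE_POWER_MW) -> np.ndarray:
    """Incident powers for the standard 2-30 dB (2 dB step) attenuation sweep,
    sorted ascending (0.2 ... 126.19 mW for a 200 mW source)."""
    db = np.arange(2.0, 30.0 + 1e-9, 2.0)
    return np.sort(attenuation_to_power(db, source_power_mw))


def saturation_model(P, I, P_half, epsilon):
    """Peak-to-peak amplitude of the central EPR line at power ``P`` (mW)."""
    P = np.asarray(P, dtype=float)
    if P_half <= 0:
        raise ValueError("P_half must be positive")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    bracket = 1.0 + (2.0 ** (1.0 / epsilon) - 1.0) * P / P_half
    return I * np.sqrt(P) * bracket ** (-epsilon)


@dataclass
class SaturationCurve:
    """Power-saturation data for one labeled site under one relaxant condition."""

    site: str
    condition: str
    powers: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self):
        self.powers = np.asarray(self.powers, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")
        if self.powers.shape != self.amplitudes.shape or self.powers.ndim != 1:
            raise ValueError("powers and amplitudes must be 1-D arrays of equal length")
        if np.any(self.powers <= 0):
            raise ValueError("powers must be strictly positive")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes must be finite")

    @property
    def fittable(self) -> bool:
        """At least 5 points spanning at least one decade of power."""
        return self.powers.size >= 5 and self.powers.max() / self.powers.min() >= 10.0


@dataclass
class SaturationFit:
    """Least-squares fit of the saturation model to one curve."""

    site: str
    condition: str
    I: float
    P_half: float
    epsilon: float
    I_se: float
    P_half_se: float
    epsilon_se: float
    residual_norm: float
    converged: bool
    epsilon_mode: str = "free"


@dataclass
class DepthResult:
    """Depth parameter for one site from its three condition fits."""

    site: str
    dP_oxygen: float
    dP_niedda: float
    phi: float
    call: str
    reason: str | None = None


def _initial_guesses(powers: np.ndarray, amplitudes: np.ndarray) -> tuple[float, float]:
    order = np.argsort(powers)
    P, A = powers[order], amplitudes[order]
    ratio = A / np.sqrt(P)
    I0 = float(np.median(ratio[:3]))
    # P_half guess: first power where A/sqrt(P) drops below half its
    # low-power value; fall back to the geometric mean of the power range.
    below = np.nonzero(ratio < 0.5 * I0)[0]
    if below.size:
        P0 = float(P[below[0]])
    else:
        P0 = float(np.sqrt(P.min() * P.max()))
    return max(I0, 1e-12), max(P0, 1e-9)


def fit_saturation(curve: SaturationCurve, epsilon_mode: str | float = "free") -> SaturationFit:
    """Fit (I, P_half[, epsilon]) to one saturation curve.

    ``epsilon_mode`` is ``"free"`` (bounded to [0.5, 1.5]) or a fixed value.
    Standard errors come from the Gauss-Newton curvature of the residual
    surface. Optimizer failure yields ``converged=False``, never an
    exception.
    """
    if not curve.fittable:
        raise ValueError(
            f"curve for site {curve.site!r}/{curve.condition}: need >=5 points "
            "spanning >=1 decade of power"
        )
    n_params = 3 if epsilon_mode == "free" else 2
    if curve.powers.size < n_params:
        raise ValueError("fewer points than fit parameters")

    I0, P0 = _initial_guesses(curve.powers, curve.amplitudes)
    mode = "free" if epsilon_mode == "free" else f"fixed({float(epsilon_mode)})"
    try:
        if epsilon_mode == "free":
            popt, pcov = curve_fit(
                saturation_model, curve.powers, curve.amplitudes,
                p0=[I0, P0, 1.0],
                bounds=([0.0, 1e-12, EPSILON_BOUNDS[0]], [np.inf, np.inf, EPSILON_BOUNDS[1]]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=20000,
            )
            I, P_half, eps = popt
            se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
            I_se, P_se, e_se = se
        else:
            eps = float(epsilon_mode)
            if not (EPSILON_BOUNDS[0] <= eps <= EPSILON_BOUNDS[1]):
                raise ValueError(f"fixed epsilon must lie in {EPSILON_BOUNDS}")

            def model2(P, I, P_half):
                return saturation_model(P, I, P_half, eps)

            popt, pcov = curve_fit(
                model2, curve.powers, curve.amplitudes,
                p0=[I0, P0], bounds=([0.0, 1e-12], [np.inf, np.inf]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=20000,
            )
            I, P_half = popt
            se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
            I_se, P_se, e_se = se[0], se[1], 0.0
        resid = curve.amplitudes - saturation_model(curve.powers, I, P_half, eps)
        return SaturationFit(curve.site, curve.condition, float(I), float(P_half), float(eps),
                             float(I_se), float(P_se), float(e_se),
                             float(np.linalg.norm(resid)), True, mode)
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "epsilon" in str(exc):
            raise
        return SaturationFit(curve.site, curve.condition, np.nan, np.nan, np.nan,
                             np.nan, np.nan, np.nan, np.nan, False, mode)


def depth_parameter(fit_o2: SaturationFit, fit_niedda: SaturationFit,
                    fit_n2: SaturationFit, tol: float = 0.3) -> DepthResult:
    """Depth parameter phi = ln(dP_half(O2)/dP_half(NiEDDA)) and its call.

    ``tol`` is the half-width of the interface band on phi: labels are
    ``embedded`` (phi > tol), ``exposed`` (phi < -tol), ``interface``
    otherwise; non-positive increments or non-converged fits yield
    ``indeterminate``.
    """
    site = fit_o2.site
    for f in (fit_o2, fit_niedda, fit_n2):
        if not f.converged:
            return DepthResult(site, np.nan, np.nan, np.nan, "indeterminate",
                               f"{f.condition} fit did not converge")
    dP_o2 = fit_o2.P_half - fit_n2.P_half
    dP_ni = fit_niedda.P_half - fit_n2.P_half
    if dP_o2 <= 0 or dP_ni <= 0:
        return DepthResult(site, dP_o2, dP_ni, np.nan, "indeterminate",
                           "non-positive collision increment")
    phi = float(np.log(dP_o2 / dP_ni))
    if phi > tol:
        call = "embedded"
    elif phi < -tol:
        call = "exposed"
    else:
        call = "interface"
    return DepthResult(site, float(dP_o2), float(dP_ni), phi, call)


def _residue_of(site: str) -> int:
    digits = "".join(ch for ch in str(site) if ch.isdigit())
    return int(digits) if digits else -1


def hairpin_signature(phis: np.ndarray) -> bool:
    """True when negative-phi flanks bracket a positive-phi core along the
    sequence (the monotopic hairpin pattern)."""
    phis = np.asarray(phis, dtype=float)
    neg = np.nonzero(phis < 0)[0]
    pos = np.nonzero(phis > 0)[0]
    if neg.size < 2 or pos.size < 1:
        return False
    return bool(np.any((pos > neg.min()) & (pos < neg.max())))


def depth_profile(results: list[DepthResult]) -> tuple[pd.DataFrame, bool]:
    """Order per-site depth results by residue index and flag the hairpin
    signature (negative-phi flanks around a positive-phi core)."""
    if not results:
        raise ValueError("need at least one site")
    rows = sorted(results, key=lambda r: _residue_of(r.site))
    table = pd.DataFrame(
        {
            "site": [r.site for r in rows],
            "residue": [_residue_of(r.site) for r in rows],
            "dP_oxygen_mW": [r.dP_oxygen for r in rows],
            "dP_niedda_mW": [r.dP_niedda for r in rows],
            "phi": [r.phi for r in rows],
            "call": [r.call for r in rows],
        }
    )
    phis = table["phi"].to_numpy()
    return table, hairpin_signature(phis[np.isfinite(phis)])


def curves_from_table(df: pd.DataFrame,
                      source_power_mw: float = DEFAULT_SOURCE_POWER_MW) -> list[SaturationCurve]:
    """Build SaturationCurves from a tidy table.

    Expected columns: ``site``, ``condition``, ``amplitude`` and either
    ``power_mW`` or ``attenuation_dB`` (converted using ``source_power_mw``).
    """
    df = df.copy()
    if "power_mW" not in df.columns:
        if "attenuation_dB" not in df.columns:
            raise ValueError("need a power_mW or attenuation_dB column")
        df["power_mW"] = attenuation_to_power(df["attenuation_dB"].to_numpy(), source_power_mw)
    curves = []
    for (site, cond), grp in df.groupby(["site", "condition"], sort=True):
        curves.append(SaturationCurve(str(site), str(cond),
                                      grp["power_mW"].to_numpy(),
                                      grp["amplitude"].to_numpy()))
    return curves


def analyze_sites(df: pd.DataFrame, epsilon_mode: str | float = "free",
                  phi_tol: float = 0.3,
                  source_power_mw: float = DEFAULT_SOURCE_POWER_MW,
                  ) -> tuple[pd.DataFrame, pd.DataFrame, bool]:
    """Fit every site/condition curve in a saturation table and derive the
    per-site depth profile.

    Returns (fit table, depth table, hairpin signature flag).
    """
    curves = curves_from_table(df, source_power_mw)
    fits: dict[tuple[str, str], SaturationFit] = {}
    for c in curves:
        fits[(c.site, c.condition)] = fit_saturation(c, epsilon_mode)
    fit_table = pd.DataFrame(
        [
            {
                "site": f.site, "condition": f.condition, "I": f.I,
                "P_half_mW": f.P_half, "epsilon": f.epsilon,
                "P_half_se": f.P_half_se, "converged": f.converged,
            }
            for f in fits.values()
        ]
    ).sort_values(["site", "condition"], ignore_index=True)

    results = []
    for site in sorted({s for s, _ in fits}, key=_residue_of):
        triple = [fits.get((site, cond)) for cond in ("O2", "NiEDDA", "N2")]
        if any(t is None for t in triple):
            continue
        results.append(depth_parameter(*triple, tol=phi_tol))
    depth_table, signature = depth_profile(results)
    return fit_table, depth_table, signature
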