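"""Topology mapping from cysteine-accessibility (PEGylation) gel data.

A single-cysteine mutant is PEGylated only where the cysteine is solvent
exposed; membrane-buried positions are protected. Each mutant is run in
three lanes: a no-mPEG control, a native +mPEG lane, and a detergent-
solubilized +mPEG lane that defines the maximum attainable PEGylation
(set to 100%). The relative PEGylation per residue is the native
PEGylated fraction over the detergent fraction, in percent; the
per-residue profile is then classified into exposed / interface /
embedded bands and the longest contiguous embedded run is the hairpin
segment call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LANES = ("no_mPEG", "mPEG", "detergent_mPEG")
BANDS = ("PEG0", "PEG1", "PEG2")

DEFAULT_EXPOSED_MIN = 75.0
DEFAULT_EMBEDDED_MAX = 25.0
#: Detergent-lane PEGylated fraction below which the positive control is
#: considered to have failed and the residue's value is withheld.
DEFAULT_CONTROL_FLOOR = 0.2


def pegylated_fraction(peg0: float, peg1: float = 0.0, peg2: float = 0.0,
                       lane: str = "") -> float:
    """Fraction of the lane's intensity in shifted (PEGylated) bands."""
    bands = np.array([peg0, peg1, peg2], dtype=float)
    if np.any(bands < 0):
        raise ValueError(f"negative band intensity in lane {lane!r}")
    total = bands.sum()
    if total <= 0:
        raise ValueError(f"all-zero band intensities in lane {lane!r}")
    return float((bands[1] + bands[2]) / total)


def relative_pegylation(native_fraction: float, detergent_fraction: float,
                        control_floor: float = DEFAULT_CONTROL_FLOOR,
                        ) -> tuple[float, str]:
    """Relative PEGylation in percent, detergent lane = 100%.

    Returns (value, flag). When the detergent positive control is at or
    below ``control_floor`` the value is withheld (NaN) and the flag is
    ``low_positive_control``; otherwise the ratio is clipped to [0, 100].
    """
    if detergent_fraction <= control_floor:
        return float("nan"), "low_positive_control"
    pct = 100.0 * native_fraction / detergent_fraction
    return float(np.clip(pct, 0.0, 100.0)), "ok"


def aggregate_replicates(values) -> tuple[float, float, int]:
    """Mean, sample SD and n of replicate percentages.

    The SD is undefined (NaN) for a single replicate.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("no replicate values")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
    return mean, sd, int(vals.size)


@dataclass
class TopologyMap:
    """Per-residue relative accessibility with segment calls."""

    table: pd.DataFrame  # residue, wt_aa, mean_pct, sd_pct, n, flag, label
    embedded_segment: tuple[int, int] | None
    bridge: bool = True

    @property
    def embedded_length(self) -> int:
        if self.embedded_segment is None:
            return 0
        return self.embedded_segment[1] - self.embedded_segment[0] + 1

    def to_dict(self) -> dict:
        return {
            "embedded_segment": list(self.embedded_segment) if self.embedded_segment else None,
            "embedded_length": self.embedded_length,
            "labels": dict(zip(self.table["residue"].astype(int).tolist(),
                               self.table["label"].tolist())),
        }


def _lane_fraction(grp: pd.DataFrame, lane: str) -> float:
    sel = grp[grp["lane"] == lane]
    if sel.empty:
        raise ValueError(f"missing lane {lane!r}")
    bands = {b: 0.0 for b in BANDS}
    for _, row in sel.iterrows():
        bands[row["band"]] = float(row["intensity"])
    return pegylated_fraction(bands["PEG0"], bands["PEG1"], bands["PEG2"], lane=lane)


def relative_pegylation_table(records: pd.DataFrame,
                              control_floor: float = DEFAULT_CONTROL_FLOOR) -> pd.DataFrame:
    """Reduce the raw band table to per-residue mean/SD relative PEGylation.

    ``records`` follows the accessibility CSV schema
    (residue, wt_aa, lane, band, intensity, replicate).
    """
    rows = []
    for residue, res_grp in records.groupby("residue", sort=True):
        wt = res_grp["wt_aa"].iloc[0] if "wt_aa" in res_grp else "X"
        values, flags = [], []
        for _, rep_grp in res_grp.groupby("replicate", sort=True):
            native = _lane_fraction(rep_grp, "mPEG")
            detergent = _lane_fraction(rep_grp, "detergent_mPEG")
            pct, flag = relative_pegylation(native, detergent, control_floor)
            flags.append(flag)
            if flag == "ok":
                values.append(pct)
        if values:
            mean, sd, n = aggregate_replicates(values)
            flag = "ok"
        else:
            mean, sd, n = float("nan"), float("nan"), 0
            flag = "low_positive_control"
        rows.append({"residue": int(residue), "wt_aa": wt, "mean_pct": mean,
                     "sd_pct": sd, "n": n, "flag": flag})
    if not rows:
        raise ValueError("empty accessibility table")
    return pd.DataFrame(rows).sort_values("residue", ignore_index=True)


def _base_label(mean_pct: float, exposed_min: float, embedded_max: float) -> str:
    if mean_pct >= exposed_min:
        return "exposed"
    if mean_pct <= embedded_max:
        return "embedded"
    return "interface"


def classify_topology(table: pd.DataFrame,
                      exposed_min: float = DEFAULT_EXPOSED_MIN,
                      embedded_max: float = DEFAULT_EMBEDDED_MAX,
                      bridge: bool = True) -> TopologyMap:
    """Label residues exposed/interface/embedded and call the hairpin segment.

    ``table`` needs columns ``residue``, ``mean_pct`` and (optionally)
    ``flag``; residues flagged unreliable inherit the label of their
    flanking reliable residues when both flanks agree (else interface).
    With ``bridge`` enabled (default) inherited-embedded residues count as
    embedded when extracting the longest contiguous embedded run; without
    it they break runs.
    """
    if not (0 <= embedded_max < exposed_min <= 100):
        raise ValueError("thresholds must satisfy 0 <= embedded_max < exposed_min <= 100")
    if table.empty:
        raise ValueError("empty topology table")
    tab = table.sort_values("residue").reset_index(drop=True).copy()
    if "flag" not in tab.columns:
        tab["flag"] = "ok"
    reliable = (tab["flag"] == "ok") & np.isfinite(tab["mean_pct"].astype(float))

    labels = np.empty(len(tab), dtype=object)
    for i in range(len(tab)):
        if reliable[i]:
            labels[i] = _base_label(float(tab["mean_pct"].iloc[i]), exposed_min, embedded_max)
    rel_idx = np.nonzero(reliable.to_numpy())[0]
    for i in np.nonzero(~reliable.to_numpy())[0]:
        left = rel_idx[rel_idx < i]
        right = rel_idx[rel_idx > i]
        if left.size and right.size and labels[left[-1]] == labels[right[0]]:
            labels[i] = labels[left[-1]]
        else:
            labels[i] = "interface"
    tab["label"] = labels

    counts_as_embedded = (labels == "embedded") & (reliable.to_numpy() | bridge)
    segment = _longest_run(tab["residue"].to_numpy(int), counts_as_embedded)
    return TopologyMap(tab, segment, bridge=bridge)


def _longest_run(residues: np.ndarray, mask: np.ndarray) -> tuple[int, int] | None:
    best = None
    start = None
    for i, flag in enumerate(mask):
        contiguous = i > 0 and residues[i] == residues[i - 1] + 1
        if flag and start is not None and not contiguous:
            # numbering gap inside an embedded stretch ends the run
            start = i
        elif flag and start is None:
            start = i
        elif not flag:
            start = None
            continue
        if start is not None:
            length = residues[i] - residues[start] + 1
            if best is None or length > (best[1] - best[0] + 1):
                best = (int(residues[start]), int(residues[i]))
    return best


def build_topology_map(records: pd.DataFrame,
                       exposed_min: float = DEFAULT_EXPOSED_MIN,
                       embedded_max: float = DEFAULT_EMBEDDED_MAX,
                       bridge: bool = True,
                       control_floor: float = DEFAULT_CONTROL_FLOOR) -> TopologyMap:
    """Raw band table -> classified topology map (one call)."""
    table = relative_pegylation_table(records, control_floor)
    return classify_topology(table, exposed_min, embedded_max, bridge)


def periodicity_score(values) -> dict:
    """Dominant period (residues) of a profile segment by discrete Fourier
    transform, with the peak's share of total non-DC spectral power.

    Periods are searched in [2, n/2]. A constant segment has no non-DC
    power: relative_power is 0 and the period undefined (NaN).
    """
    vals = np.asarray(list(values), dtype=float)
    n = vals.size
    if n < 8:
        raise ValueError("segment too short for periodicity analysis (need >= 8)")
    centered = vals - vals.mean()
    power = np.abs(np.fft.rfft(centered)) ** 2
    total = power[1:].sum()
    if total <= 0:
        return {"dominant_period": float("nan"), "relative_power": 0.0}
    k = np.arange(power.size)
    allowed = (k >= 2) & (k <= n // 2)
    k_peak = int(k[allowed][np.argmax(power[allowed])])
    return {
        "dominant_period": float(n / k_peak),
        "relative_power": float(power[k_peak] / total),
    }


def crosslink_efficiency(lanes: pd.DataFrame) -> pd.DataFrame:
    """Quantify intramolecular crosslinking from 0-PEG band enrichment.

    ``lanes`` has columns context, lane (DMSO | BMH), band, intensity.
    Per context: relative 0-PEG level = 100 * PEG0(BMH)/PEG0(DMSO), the
    increase over the DMSO control (floored at 0), and across contexts
    the increases normalized so the maximum is 100%.
    """
    rows = []
    for context, grp in lanes.groupby("context", sort=True):
        def band(lane):
            sel = grp[(grp["lane"] == lane) & (grp["band"] == "PEG0")]
            if sel.empty:
                raise ValueError(f"context {context!r}: missing {lane} PEG0 band")
            return float(sel["intensity"].sum())

        dmso, bmh = band("DMSO"), band("BMH")
        if dmso <= 0:
            raise ValueError(f"context {context!r}: zero DMSO PEG0 band")
        rel = 100.0 * bmh / dmso
        rows.append({"context": context, "rel_peg0_pct": rel,
                     "increase_pct": max(rel - 100.0, 0.0)})
    out = pd.DataFrame(rows)
    top = out["increase_pct"].max()
    out["normalized_pct"] = 0.0 if top <= 0 else 100.0 * out["increase_pct"] / top
    return out
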