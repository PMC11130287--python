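"""End-to-end orchestration: fixtures -> per-assay analysis -> report.

A run generates, for two membrane contexts (bilayer = deep-V hairpin,
monolayer = open-shallow hairpin), the four assay inputs with shared
ground truth, analyzes each assay, and combines the calls into a
topology report with a cross-assay concordance summary. Every output is
a CSV/JSON file under the run directory, listed with checksums in a
manifest so a rerun with the same config reproduces every byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import accessibility, epr, geometry, synthetic, wham

STAGES = ("simulate", "pegmap", "xlink", "epr", "geometry", "wham", "report")

#: Membrane context -> hairpin conformation encoded in its fixtures.
CONTEXTS = {"bilayer": "deep_V", "monolayer": "open_shallow"}

#: Ground-truth intramolecular crosslinked fractions (BMH, L91C/L118C):
#: efficient in the closed bilayer state, roughly halved on the LD.
DEFAULT_CROSSLINK_FRACTIONS = {"bilayer": 0.8, "monolayer": 0.4}


@dataclass
class RunConfig:
    """Declarative run configuration; unknown keys are rejected."""

    seed: int = 1
    outdir: str = "results/run"
    stages: tuple[str, ...] = STAGES
    # fixture generation
    noise_sd_fraction: float = 0.0
    n_replicates: int = 2
    crosslink_fractions: dict = field(default_factory=lambda: dict(DEFAULT_CROSSLINK_FRACTIONS))
    # accessibility mapping
    exposed_min: float = 75.0
    embedded_max: float = 25.0
    bridge: bool = True
    control_floor: float = 0.2
    # EPR
    epsilon_mode: str | float = "free"
    phi_tol: float = 0.3
    # umbrella sampling / WHAM demo landscape
    temperature_K: float = 310.0
    wham_kappa: float = 50.0
    wham_force_constant: float = 1000.0
    wham_span_start: float = -1.6
    wham_pull_rate: float = 0.032
    wham_pull_duration: float = 100.0
    wham_spacing: float = 0.1
    wham_n_per_window: int = 2000
    wham_bin_width: float = 0.02
    wham_n_boot: int = 20

    def __post_init__(self):
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid stages are {STAGES}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - valid)
        if unknown:
            raise ValueError(f"unknown config keys {unknown}; valid keys are {sorted(valid)}")
        data = dict(data)
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["stages"] = list(self.stages)
        return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


class PipelineError(RuntimeError):
    pass


def _require(path: Path, stage: str, upstream: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"stage {stage!r}: missing upstream output {path.name} "
            f"(run the {upstream!r} stage first)"
        )
    return path


def _geometry_spec(conformation: str, seed: int) -> synthetic.HairpinGeometrySpec:
    if conformation == "deep_V":
        return synthetic.HairpinGeometrySpec.deep_v(seed=seed)
    return synthetic.HairpinGeometrySpec.open_shallow(seed=seed)


def run_pipeline(config: RunConfig) -> tuple[dict, dict]:
    """Execute the requested stages in dependency order.

    Returns (report, manifest); both are also written as JSON under
    ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.stages)
    files: list[Path] = []
    report: dict = {"contexts": {ctx: {} for ctx in CONTEXTS}}

    # ---------------------------------------------------------- simulate
    if "simulate" in stages:
        for i, (ctx, conf) in enumerate(CONTEXTS.items()):
            spec = synthetic.GroundTruthSpec(
                conformation=conf, noise_sd_fraction=config.noise_sd_fraction,
                seed=config.seed + 100 + i, n_replicates=config.n_replicates,
            )
            acc = synthetic.gen_accessibility_profile(spec)
            acc.to_csv(out / f"accessibility_{ctx}.csv", index=False)
            synthetic.write_ground_truth_json(spec, out / f"ground_truth_{ctx}.json")
            sat, phi_truth = synthetic.gen_epr_sites(
                spec, noise_sd=config.noise_sd_fraction, seed=config.seed + 200 + i)
            sat.to_csv(out / f"saturation_{ctx}.csv", index=False)
            _dump_json({str(k): v for k, v in phi_truth.items()},
                       out / f"phi_truth_{ctx}.json")
            frame = synthetic.gen_hairpin_structure(
                _geometry_spec(conf, seed=config.seed + 300 + i))
            frame.to_pdb(out / f"structure_{ctx}.pdb")
            files += [out / f"accessibility_{ctx}.csv", out / f"ground_truth_{ctx}.json",
                      out / f"saturation_{ctx}.csv", out / f"phi_truth_{ctx}.json",
                      out / f"structure_{ctx}.pdb"]
        lanes = synthetic.gen_crosslink_lanes(
            config.crosslink_fractions, noise_sd_fraction=config.noise_sd_fraction,
            seed=config.seed + 400)
        lanes.to_csv(out / "crosslink_lanes.csv", index=False)
        files.append(out / "crosslink_lanes.csv")

        pmf = synthetic.AnalyticPMF("harmonic", {"kappa": config.wham_kappa})
        centers = wham.plan_windows(config.wham_pull_rate, config.wham_pull_duration,
                                    config.wham_spacing, start=config.wham_span_start)
        windows = synthetic.gen_umbrella_samples(
            pmf, centers, k=config.wham_force_constant,
            n_per_window=config.wham_n_per_window,
            kT=wham.kT_from_temperature(config.temperature_K),
            seed=config.seed + 500)
        wham.write_umbrella_csv(windows, out / "umbrella.csv")
        files.append(out / "umbrella.csv")

    # ------------------------------------------------------------ pegmap
    if "pegmap" in stages:
        for ctx in CONTEXTS:
            path = _require(out / f"accessibility_{ctx}.csv", "pegmap", "simulate")
            records = pd.read_csv(path)
            tmap = accessibility.build_topology_map(
                records, exposed_min=config.exposed_min,
                embedded_max=config.embedded_max, bridge=config.bridge,
                control_floor=config.control_floor)
            tmap.table.to_csv(out / f"topology_{ctx}.csv", index=False)
            summary = tmap.to_dict()
            # Periodicity is scored over the membrane-proximal span (first
            # to last non-exposed residue): in the open state the helical
            # exposure pattern interrupts the embedded run itself.
            tab = tmap.table.set_index("residue")
            proximal = tab.index[tab["label"] != "exposed"]
            if len(proximal) and proximal.max() - proximal.min() + 1 >= 8:
                vals = tab.loc[proximal.min():proximal.max(), "mean_pct"]
                summary["periodicity"] = accessibility.periodicity_score(
                    vals.fillna(vals.mean()))
            _dump_json(summary, out / f"topology_{ctx}.json")
            files += [out / f"topology_{ctx}.csv", out / f"topology_{ctx}.json"]
            report["contexts"][ctx]["pegmap"] = summary
    else:
        for ctx in CONTEXTS:
            report["contexts"][ctx]["pegmap"] = None

    # ------------------------------------------------------------- xlink
    if "xlink" in stages:
        path = _require(out / "crosslink_lanes.csv", "xlink", "simulate")
        quant = accessibility.crosslink_efficiency(pd.read_csv(path))
        quant.to_csv(out / "crosslink_quantification.csv", index=False)
        files.append(out / "crosslink_quantification.csv")
        report["crosslink"] = {
            row["context"]: {"increase_pct": row["increase_pct"],
                             "normalized_pct": row["normalized_pct"]}
            for _, row in quant.iterrows()
        }
    else:
        report["crosslink"] = None

    # --------------------------------------------------------------- epr
    if "epr" in stages:
        for ctx in CONTEXTS:
            path = _require(out / f"saturation_{ctx}.csv", "epr", "simulate")
            fit_table, depth_table, signature = epr.analyze_sites(
                pd.read_csv(path), epsilon_mode=config.epsilon_mode,
                phi_tol=config.phi_tol)
            fit_table.to_csv(out / f"saturation_fits_{ctx}.csv", index=False)
            depth_table.to_csv(out / f"depth_parameters_{ctx}.csv", index=False)
            files += [out / f"saturation_fits_{ctx}.csv", out / f"depth_parameters_{ctx}.csv"]
            report["contexts"][ctx]["epr"] = {
                "phi": {int(r): float(p) for r, p in
                        zip(depth_table["residue"], depth_table["phi"])},
                "calls": {int(r): c for r, c in
                          zip(depth_table["residue"], depth_table["call"])},
                "hairpin_signature": bool(signature),
            }

    # ---------------------------------------------------------- geometry
    if "geometry" in stages:
        for ctx in CONTEXTS:
            path = _require(out / f"structure_{ctx}.pdb", "geometry", "simulate")
            frame = geometry.MembraneFrame.from_pdb(path)
            obs = geometry.measure_structure(frame)
            _dump_json(obs.to_dict(), out / f"geometry_{ctx}.json")
            files.append(out / f"geometry_{ctx}.json")
            report["contexts"][ctx]["geometry"] = obs.to_dict()

    # -------------------------------------------------------------- wham
    if "wham" in stages:
        path = _require(out / "umbrella.csv", "wham", "simulate")
        windows = wham.read_umbrella_csv(path)
        profile = wham.estimate_pmf(
            windows, temperature_K=config.temperature_K,
            bin_width=config.wham_bin_width, n_boot=config.wham_n_boot,
            seed=config.seed + 600)
        profile.to_frame().to_csv(out / "pmf.csv", index=False)
        truth = synthetic.AnalyticPMF("harmonic", {"kappa": config.wham_kappa})
        counts, _ = wham.build_histograms(windows, config.wham_bin_width)
        conv = {"converged": bool(profile.converged),
                "iterations": int(profile.iterations),
                "rmse_vs_analytic_kJmol": wham.recovery_rmse(profile, truth, counts),
                "occupied_bins": int(profile.occupied.sum())}
        _dump_json(conv, out / "pmf_convergence.json")
        files += [out / "pmf.csv", out / "pmf_convergence.json"]
        report["pmf"] = conv

    # ------------------------------------------------------------ report
    if "report" in stages:
        report["concordance"] = concordance_check(report)
        _dump_json(report, out / "report.json")
        files.append(out / "report.json")

    manifest = {
        "config": config.to_dict(),
        "stages_run": stages,
        "outputs": {p.name: _sha256(p) for p in sorted(set(files))},
    }
    _dump_json(manifest, out / "manifest.json")
    return report, manifest


def concordance_check(report: dict) -> dict:
    """Per-context agreement between assay calls on shared residues.

    For each context with both a PEGylation map and EPR depth calls, the
    fraction of shared residues on which the exposed/interface/embedded
    labels agree, alongside the geometric classifier's state label.
    """
    out = {}
    for ctx, entry in report.get("contexts", {}).items():
        peg = entry.get("pegmap") or {}
        epr_entry = entry.get("epr") or {}
        labels = {int(k): v for k, v in (peg.get("labels") or {}).items()}
        calls = {int(k): v for k, v in (epr_entry.get("calls") or {}).items()}
        shared = sorted(set(labels) & set(calls))
        ctx_out = {}
        if len(shared) >= 1 and labels and calls:
            agree = sum(labels[r] == calls[r] for r in shared)
            ctx_out["n_shared_sites"] = len(shared)
            ctx_out["fraction_agree"] = agree / len(shared)
        geom = entry.get("geometry") or {}
        if geom:
            ctx_out["geometry_call"] = geom.get("conformation")
        if ctx_out:
            out[ctx] = ctx_out
    return out
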