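#!/usr/bin/env python
"""WHAM free-energy profile from the umbrella-sampling fixture.

The fixture draws Boltzmann samples from a known harmonic landscape
(kappa = 50 kJ/mol/nm^2) in 33 windows spaced 0.1 nm with k = 1000
kJ/mol/nm^2 at 310 K. The self-consistent WHAM solution is compared
against the analytic profile and errors are bootstrapped over windows.
Expected outcome: recovery RMSE well below 0.5 kJ/mol over well-sampled
bins.
"""

from pathlib import Path

from ldhairpin import synthetic as syn, wham

FIXTURES = Path("results/fixtures")
OUT = Path("results/wham")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    windows = wham.read_umbrella_csv(FIXTURES / "umbrella.csv")
    profile = wham.estimate_pmf(windows, temperature_K=310.0, bin_width=0.02,
                                n_boot=20, seed=1)
    profile.to_frame().to_csv(OUT / "pmf.csv", index=False)
    truth = syn.AnalyticPMF("harmonic", {"kappa": 50.0})
    counts, _ = wham.build_histograms(windows, 0.02)
    rmse = wham.recovery_rmse(profile, truth, counts)
    print(f"windows: {len(windows)}; converged: {profile.converged} "
          f"after {profile.iterations} iterations")
    print(f"recovery RMSE vs analytic landscape: {rmse:.3f} kJ/mol "
          f"(well-sampled bins)")


if __name__ == "__main__":
    main()
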