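"""WHAM estimator: window planning, histograms, self-consistent solve,
analytic-profile recovery, bootstrap errors."""

import numpy as np
import pytest

from ldhairpin import synthetic as syn, wham

KT = wham.kT_from_temperature(310.0)


# ------------------------------------------------------------ planning

@pytest.mark.parametrize("rate,duration,spacing,expected", [
    (0.032, 100.0, 0.1, 33),
    (0.01, 100.0, 0.25, 5),
    (0.1, 1.0, 0.1, 2),     # span of exactly one spacing
    (0.01, 1.0, 0.5, 1),    # spacing larger than span
])
def test_plan_windows_counts(rate, duration, spacing, expected):
    centers = wham.plan_windows(rate, duration, spacing)
    assert centers.size == expected
    if centers.size > 1:
        assert np.allclose(np.diff(centers), spacing)


def test_plan_windows_rejects_nonpositive_inputs():
    with pytest.raises(ValueError):
        wham.plan_windows(0.0, 100.0, 0.1)


# ---------------------------------------------------------- histograms

def test_histogram_concentrates_in_one_bin():
    w = wham.UmbrellaWindow(0, 0.0, 1000.0, np.full(50, 0.101))
    counts, edges = wham.build_histograms([w], bin_width=0.02, xi_range=(0.0, 0.2))
    assert counts.sum() == 50
    assert counts.max() == 50


def test_burn_in_removes_leading_samples():
    w = wham.UmbrellaWindow(0, 0.0, 1000.0, np.linspace(0, 1, 100),
                            burn_in_fraction=0.5)
    assert w.retained.size == 50
    counts, _ = wham.build_histograms([w], bin_width=0.1, xi_range=(-0.05, 1.05))
    assert counts.sum() == 50


def test_identical_windows_histogram_identically():
    samples = np.linspace(-0.2, 0.2, 200)
    ws = [wham.UmbrellaWindow(i, 0.0, 1000.0, samples) for i in range(2)]
    counts, _ = wham.build_histograms(ws, bin_width=0.02)
    np.testing.assert_array_equal(counts[0], counts[1])


def test_out_of_range_samples_are_an_error():
    w = wham.UmbrellaWindow(0, 0.0, 1000.0, np.array([0.0, 2.0]))
    with pytest.raises(ValueError, match="range"):
        wham.build_histograms([w], bin_width=0.1, xi_range=(-0.5, 0.5))


# --------------------------------------------------------------- solve

def _tabulated(grid, values, domain=(-1.0, 1.0)):
    return syn.AnalyticPMF("tabulated", {"grid": list(grid), "values": list(values)},
                           domain=domain)


def test_single_unbiased_window_equals_boltzmann_inversion():
    pmf = _tabulated([-1.0, 0.0, 1.0], [0.0, 5.0, 0.0])
    (w,) = syn.gen_umbrella_samples(pmf, [0.0], k=0.0, n_per_window=20000,
                                    kT=KT, seed=3)
    counts, edges = wham.build_histograms([w], bin_width=0.05)
    prof = wham.wham_solve(counts, [w], KT, edges=edges)
    occ = prof.occupied
    hist = counts[0][occ]
    direct = -KT * np.log(hist / hist.sum())
    direct -= direct.min()
    np.testing.assert_allclose(prof.free_energy[occ], direct, atol=1e-9)


def test_flat_density_recovery_within_binomial_noise():
    pmf = _tabulated([-1.0, 1.0], [0.0, 0.0])
    (w,) = syn.gen_umbrella_samples(pmf, [0.0], k=0.0, n_per_window=50000,
                                    kT=KT, seed=8)
    counts, edges = wham.build_histograms([w], bin_width=0.1, xi_range=(-1.0, 1.0))
    prof = wham.wham_solve(counts, [w], KT, edges=edges)
    occ = prof.occupied
    n = counts.sum()
    p = counts[0][occ] / n
    # free-energy deviation allowed: 3x the binomial SEM propagated through -kT ln p
    sem_G = KT * 3.0 * np.sqrt((1 - p) / (n * p))
    dev = np.abs(prof.free_energy[occ] - np.mean(prof.free_energy[occ]))
    assert np.all(dev <= sem_G + 3.0 * KT / np.sqrt(n))


def test_harmonic_profile_recovery():
    pmf = syn.AnalyticPMF("harmonic", {"kappa": 50.0})
    centers = wham.plan_windows(0.032, 100.0, 0.1, start=-1.6)
    windows = syn.gen_umbrella_samples(pmf, centers, k=1000.0, n_per_window=5000,
                                       kT=KT, seed=13)
    counts, edges = wham.build_histograms(windows, 0.02)
    prof = wham.wham_solve(counts, windows, KT, edges=edges)
    assert prof.converged
    assert wham.recovery_rmse(prof, pmf, counts) <= 0.5


def test_double_well_barrier_height_bias():
    pmf = syn.AnalyticPMF("double_well", {"height": 10.0, "half_separation": 0.8})
    centers = wham.plan_windows(0.032, 100.0, 0.1, start=-1.6)
    windows = syn.gen_umbrella_samples(pmf, centers, k=1000.0, n_per_window=5000,
                                       kT=KT, seed=14)
    counts, edges = wham.build_histograms(windows, 0.02)
    prof = wham.wham_solve(counts, windows, KT, edges=edges)
    assert prof.converged
    x = prof.bin_centers
    occ = prof.occupied
    top = np.nanargmin(np.where(occ, np.abs(x), np.inf))
    analytic = pmf(x[top]) - pmf(0.8)  # barrier over the well minima
    assert prof.free_energy[top] == pytest.approx(analytic, abs=1.0)


def test_doubling_counts_leaves_the_profile_unchanged():
    pmf = syn.AnalyticPMF("harmonic", {"kappa": 50.0})
    wins = syn.gen_umbrella_samples(pmf, [-0.3, 0.0, 0.3], k=500.0,
                                    n_per_window=2000, kT=KT, seed=6)
    counts, edges = wham.build_histograms(wins, 0.02)
    a = wham.wham_solve(counts, wins, KT, edges=edges)
    b = wham.wham_solve(2.0 * counts, wins, KT, edges=edges)
    np.testing.assert_allclose(a.free_energy, b.free_energy, atol=1e-6, equal_nan=True)


def test_gauge_invariance_of_initial_window_offsets():
    pmf = syn.AnalyticPMF("harmonic", {"kappa": 50.0})
    wins = syn.gen_umbrella_samples(pmf, [-0.3, 0.0, 0.3], k=500.0,
                                    n_per_window=2000, kT=KT, seed=6)
    counts, edges = wham.build_histograms(wins, 0.02)
    a = wham.wham_solve(counts, wins, KT, edges=edges)
    b = wham.wham_solve(counts, wins, KT, edges=edges,
                        f_init=np.full(3, 7.5))
    np.testing.assert_allclose(a.free_energy, b.free_energy, atol=1e-6, equal_nan=True)


def test_disjoint_windows_report_the_gap():
    w1 = wham.UmbrellaWindow(0, -1.0, 1000.0, np.full(100, -1.0))
    w2 = wham.UmbrellaWindow(1, 1.0, 1000.0, np.full(100, 1.0))
    counts, edges = wham.build_histograms([w1, w2], bin_width=0.1)
    prof = wham.wham_solve(counts, [w1, w2], KT, edges=edges)
    assert not prof.converged
    assert "overlap" in prof.message
    assert np.all(np.isnan(prof.free_energy))


def test_anchoring_minimum_is_exactly_zero():
    pmf = syn.AnalyticPMF("harmonic", {"kappa": 50.0})
    wins = syn.gen_umbrella_samples(pmf, [-0.2, 0.0, 0.2], k=500.0,
                                    n_per_window=1000, kT=KT, seed=2)
    prof = wham.estimate_pmf(wins)
    assert np.nanmin(prof.free_energy) == 0.0


# ----------------------------------------------------------- bootstrap

def test_bootstrap_of_identical_windows_is_zero():
    samples = np.concatenate([np.linspace(-0.1, 0.1, 200)] * 1)
    wins = [wham.UmbrellaWindow(i, 0.0, 500.0, samples) for i in range(5)]
    counts, edges = wham.build_histograms(wins, 0.02)
    sem = wham.bootstrap_sem(counts, wins, KT, n_boot=10, seed=1, edges=edges)
    occupied = counts.sum(axis=0) > 0
    assert np.allclose(sem[occupied], 0.0)


def test_bootstrap_is_deterministic_under_a_seed():
    pmf = syn.AnalyticPMF("harmonic", {"kappa": 50.0})
    wins = syn.gen_umbrella_samples(pmf, [-0.3, 0.0, 0.3], k=500.0,
                                    n_per_window=1000, kT=KT, seed=6)
    counts, edges = wham.build_histograms(wins, 0.02)
    a = wham.bootstrap_sem(counts, wins, KT, n_boot=8, seed=42, edges=edges)
    b = wham.bootstrap_sem(counts, wins, KT, n_boot=8, seed=42, edges=edges)
    np.testing.assert_array_equal(a, b)


def test_bootstrap_needs_two_replicates():
    wins = [wham.UmbrellaWindow(0, 0.0, 500.0, np.zeros(10) + 0.01)]
    counts, edges = wham.build_histograms(wins, 0.02)
    with pytest.raises(ValueError):
        wham.bootstrap_sem(counts, wins, KT, n_boot=1, edges=edges)


def test_bootstrap_sem_shrinks_with_more_samples_per_window():
    # densely overlapping windows (bias sigma > spacing), so replicate
    # composition never disconnects the profile and the error is
    # dominated by per-window sampling noise
    pmf = syn.AnalyticPMF("harmonic", {"kappa": 50.0})
    med = {}
    for n in (200, 5000):
        wins = syn.gen_umbrella_samples(pmf, np.linspace(-0.5, 0.5, 11), k=100.0,
                                        n_per_window=n, kT=KT, seed=31)
        counts, edges = wham.build_histograms(wins, 0.02)
        sem = wham.bootstrap_sem(counts, wins, KT, n_boot=15, seed=5, edges=edges)
        med[n] = np.nanmedian(sem)
    assert med[5000] < med[200]


# ------------------------------------------------------------ validity

def test_window_validation():
    with pytest.raises(ValueError):
        wham.UmbrellaWindow(0, 0.0, -1.0, np.array([0.0]))
    with pytest.raises(ValueError):
        wham.UmbrellaWindow(0, 0.0, 1.0, np.array([]))
    with pytest.raises(ValueError):
        wham.UmbrellaWindow(0, 0.0, 1.0, np.array([0.0]), burn_in_fraction=1.0)


def test_umbrella_csv_round_trip(tmp_path):
    pmf = syn.AnalyticPMF("harmonic", {"kappa": 50.0})
    wins = syn.gen_umbrella_samples(pmf, [0.0, 0.2], n_per_window=50, seed=1)
    path = tmp_path / "umbrella.csv"
    wham.write_umbrella_csv(wins, path)
    back = wham.read_umbrella_csv(path)
    assert len(back) == 2
    np.testing.assert_allclose(back[0].samples, wins[0].samples)
    assert back[1].center == wins[1].center
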