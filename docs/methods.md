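# Methods

This note documents the models implemented in `ldhairpin`, the defaults
and units that matter, the numerical choices, and what the synthetic
fixtures do and do not emulate. Nothing here states an empirical result
that the tests or `scripts/acceptance.py` do not themselves compute.

## Residue frame of reference

All residue numbering is full-length UBXD8 (FAF2), 1-based, with
inclusive intervals. The accessibility scan covers S80–R128. That
interval contains 49 positions; the source mutant library was described
with 48 clones without naming the absent position, so the generator
covers all 49 and records the discrepancy in each dataset's
ground-truth sidecar rather than guessing.

## PEGylation topology mapping

**Model.** A lane's PEGylated fraction is
`(PEG1 + PEG2) / (PEG0 + PEG1 + PEG2)` of the band densitometry
intensities. Relative PEGylation per residue is
`100 × fraction(native lane) / fraction(detergent lane)`, clipped to
[0, 100]: the detergent (Triton X-100) lane defines the maximum
attainable labeling and noise can push the native lane above it.
Replicates are combined as arithmetic mean with sample SD (SD undefined
for n = 1).

**Reliability.** When the detergent lane's PEGylated fraction is at or
below the positive-control floor (default 0.2), the residue's value is
withheld and flagged `low_positive_control`. This operationalizes the
observed failure of the positive control at P102C/I113C/F114C, where
the local secondary structure restricts maleimide access even after
solubilization; the exact cutoff is our choice since none is published.

**Classification.** exposed if mean ≥ `exposed_min` (default 75%),
embedded if ≤ `embedded_max` (default 25%), else interface. The
symmetric-quartile defaults separate the two regimes of the profiles
cleanly; no published thresholds exist. Unreliable residues inherit the
label of their flanking reliable residues when both flanks agree (else
interface). The hairpin segment is the longest contiguous embedded run;
by default (`bridge=True`) inherited-embedded residues extend runs,
because the three unreliable positions sit inside the embedded core and
breaking the run there would be an artifact of the failed control, not
of topology. Whether measured percentages may exceed 100 is not
settled; we clip and flag the choice here.

**Periodicity.** The mean-subtracted discrete Fourier transform of a
profile segment; the dominant period is taken over periods in
[2, n/2] residues and reported with its share of non-DC power. At
segment length 29 the DFT bins nearest the canonical α-helix period
(3.6 residues/turn) lie at 29/8 = 3.625, hence the acceptance band of
3.2–4.0.

**Crosslinking.** Per membrane context, the relative 0-PEG level is
`100 × PEG0(BMH) / PEG0(DMSO)` and the *increase* over the DMSO control
(floored at 0) is normalized across contexts so the maximum is 100%.
The difference-from-100 reading (rather than a pure ratio) is chosen so
that an unchanged band scores exactly zero.

## cwEPR power saturation and depth parameter

**Model.** `A = I·√P·[1 + (2^{1/ε} − 1)·P/P_{1/2}]^{−ε}` with `P` the
incident microwave power (mW), `I` a scaling factor, `P_{1/2}` the
half-saturation power and ε the homogeneity exponent (1.5 homogeneous,
0.5 inhomogeneous). At `P = P_{1/2}` the bracket equals `2^{1/ε}`, so
the amplitude is exactly half the unsaturated extrapolation `I·√P` —
for every ε.

**Power grid.** Attenuation converts as `P = P_src·10^{−dB/10}`. The
source power defaults to 200 mW, the unique value for which the
standard 2–30 dB sweep (2 dB steps) spans exactly 126.19…0.2 mW.

**Fitting.** Trust-region least squares over (I, P_{1/2}[, ε]); ε free
within [0.5, 1.5] by default or fixed. Initial guesses: I from the
median of `A/√P` over the three lowest powers; `P_{1/2}` from the first
power where `A/√P` falls below half its low-power value (fallback:
geometric mean of the power range); ε starts at 1.0. Standard errors
come from the Gauss–Newton curvature; they are reported but not used
for calls. Optimizer failure sets `converged=False` rather than
raising. A fit requires ≥5 points spanning ≥1 decade of power. Fits
operate on amplitude versus power; the conventional √P plotting axis is
presentation only. `P_{1/2}` is taken as the fitted parameter; an
alternative reading extrapolates the linear low-power part of the curve
explicitly, which we do not implement.

**Depth parameter.**
`Φ = ln[(P_{1/2}(O₂) − P_{1/2}(N₂)) / (P_{1/2}(NiEDDA) − P_{1/2}(N₂))]`.
Calls: embedded (Φ > tol), exposed (Φ < −tol), interface otherwise,
with tol = 0.3 (configurable; published guidance is only "close to 0").
Non-positive collision increments or non-converged fits yield
`indeterminate`. A per-site profile shows the monotopic hairpin
signature when negative-Φ sites bracket at least one positive-Φ site
along the sequence. Spectral line-shape simulation and rotational-
correlation-time analysis are out of scope.

## Membrane geometry

Coordinates are read from PDB, GRO or a per-atom CSV (Ångström
internally; depths reported in nm, distances in Å as is conventional
for the respective observables). The cytoplasmic phosphate plane is the
arithmetic mean z of that leaflet's P atoms, which makes every
observable invariant under xy-translation and rotation about the
membrane normal. Leaflets are assigned by z relative to the global
P-atom midplane when not annotated (upper = cytoplasmic).

Signed depth of a residue is the Cα offset from the plane along the
insertion direction. The insertion direction points from the
cytoplasmic plane toward the opposite phosphate layer when one exists
(both the bilayer and the trilayer LD-mimetic have one); for
single-leaflet frames it falls back to the side on which the peptide's
mean Cα sits. Depth is per-residue Cα rather than a residue center of
mass: the per-amino-acid profile is defined on Cα positions and the
plane reference keeps it translation-invariant.

Tilt is the angle between the first principal axis of the Cα trace and
the membrane *plane* (90° = perpendicular). Measuring against the plane
rather than the normal is the only convention under which a
near-vertical deep hairpin reads ~80° and the flat open state ~30°.
The opening angle is measured at the kink between the two arm principal
axes, each oriented away from the kink. The state classifier calls
deep_V at kink depth ≥ 1.0 nm and tilt ≥ 55°, open_shallow at depth
≤ 0.5 nm and tilt ≤ 45°, else ambiguous. Multi-frame input (multi-model
PDB) is averaged over a trailing window (default last 25% of frames)
with SEM across frames, mirroring the practice of analyzing only the
equilibrated tail of a trajectory.

## Umbrella sampling and WHAM

Windows carry harmonic biases `U_i(ξ) = k_i/2 (ξ − ξ_i)²`. The window
planner covers the pulled span `rate × duration` inclusively at fixed
spacing (`floor(span/spacing) + 1` centers); the motivating protocol
(0.032 nm/ns × 100 ns, 0.1 nm spacing, k = 1000 kJ mol⁻¹ nm⁻², 100 ns
per window) yields 33 windows. Burn-in is expressed as a fraction of
each window's samples (the protocol removed 20/50 or 40/100 ns,
hence 0.4 as the configurable default for real data; synthetic samples
are independent and need none).

The solver iterates the standard coupled equations

    P(b) = Σ_i n_i(b) / Σ_i N_i exp[(f_i − U_i(b))/kT]
    f_i  = −kT ln Σ_b P(b) exp[−U_i(b)/kT]

to self-consistency: bin width 0.02 nm (five bins per 0.1 nm window
spacing — a resolution/occupancy trade-off), tolerance 10⁻⁷ kT on
max|Δf_i|, at most 10⁵ iterations, f initialized to 0 (the converged
profile is gauge-invariant to a common offset in f). kT defaults to
310 K (2.577 kJ/mol). Empty bins are reported missing (NaN), never as
zero; the profile is anchored so its minimum over occupied bins is
exactly 0. Adjacent windows (by center) must share at least one
occupied bin; otherwise the solve reports the gap and withholds the
profile.

**Errors.** The bootstrap resamples whole windows with replacement
(matching error estimation "from the set of umbrella histograms"),
re-solves WHAM per replicate (warm-started from the full solution) and
takes the per-bin SD across replicates. Replicates whose window draw
disconnects the histogram chain, or fails to converge, carry no
estimate and are skipped. With marginal overlap this composition
variance — not per-sample noise — can dominate the SEM; the SEM shrinks
with per-window sample size only in the densely overlapping regime.
Sample autocorrelation is not corrected: synthetic samples are
independent by construction, and users feeding real MD samples should
subsample to the correlation time first.

**Recovery metric.** Estimator validation compares the anchored profile
against the analytic landscape by RMSE over bins holding at least 25
total samples (`wham.recovery_rmse`). A bin with n counts carries a
free-energy sampling error of roughly kT/√n, so near-empty tail bins —
individually uncertain by several kT — would otherwise dominate a
comparison whose scale is a fraction of kT; 25 counts keeps the per-bin
sampling error near kT/5 ≈ 0.5 kJ/mol, the comparison scale itself.
This is consistent with the per-bin binomial-SEM allowance used for the
unbiased-window check.

## Synthetic fixtures: what they emulate, and what they do not

**Accessibility.** The segment plan encodes exposed termini (80–89,
124–128, true accessibility 100%), interfacial stretches (90–93 and
123, 50%), and the embedded core 94–122 (5% in the deep-V state). In
the open-shallow state the core instead carries
`30 + 15·sin(2π(r − 94)/3.6)` percent — a partial exposure of one
helical face at exactly the canonical 3.6 residues/turn (the
observation being emulated is only "every third to fourth residue").
Gel noise is multiplicative log-normal (densitometry noise scales with
band intensity) with the sd given as a fraction of intensity; the
detergent-lane efficiency is 0.9, and 0.05 at the three
failed-positive-control residues (102, 113, 114). Sub-streams are keyed
per (seed, residue, replicate) so adding a residue never reshuffles
others.

**EPR.** Site ground truth derives from the same segment plan:
Φ = +1.5 embedded, −1.5 exposed, 0 interfacial, realized as
`P_{1/2}` triples with N₂ baseline 2 mW and increments `3·e^{±Φ/2}` mW,
ε = 1.5. This makes PEGylation and EPR consistent by construction —
which is the point of the concordance check, but also means the
fixtures do not emulate the real-data anomaly where C-terminal
arginines drag water into the membrane and give negative Φ at an
embedded position (R115).

**Structures.** Cα-only helix–kink–helix traces: two straight arms
(1.5 Å/residue rise) meeting at the kink (P102), opened to match the
requested 91–118 tip distance, rigidly rotated to the requested
principal-axis tilt and translated to the requested kink depth below a
synthetic phosphate layer (jittered P pseudo-atoms whose mean plane is
exactly z = 0, plus an opposite layer 3.8 nm below). Build targets:
deep-V 2.0 nm / 80° / 20 Å; open-shallow 0.1 nm / 30° / 36 Å (the
"~0" published for the shallow kink depth is realized as 0.1 nm, just
below the surface). Construction is exact to machine precision, well
inside the 2% build tolerance; geometry measured on any generated
structure returns the build parameters (closure tested). These are
calibration targets taken from microsecond-MD averages, not MD itself:
no side chains, no lipids, no dynamics.

**Umbrella samples.** Inverse-CDF draws on a 10⁻⁴ nm grid of the biased
Boltzmann density — exact in the grid limit and autocorrelation-free,
so WHAM validation is clean; real umbrella trajectories are correlated
and messier. The demo landscape is harmonic (κ = 50 kJ mol⁻¹ nm⁻²)
over [−1.6, 1.6] nm. The ~100 kJ/mol conformational-transition profiles
of the real system require microsecond atomistic MD and are explicitly
out of scope; they enter this package only through the protocol
parameters above.

**Crosslink lanes.** Two cysteines PEGylate independently with
efficiency 0.7; a crosslinked fraction is rendered non-PEGylatable
(0-PEG). Defaults 0.8 (bilayer) and 0.4 (monolayer) encode the observed
~50% reduction of intramolecular crosslinking on LDs.

**What passing tests show.** That every quantification rule, estimator
and classifier behaves correctly on data with the stated statistical
structure and known truth — not that real gels, spectra or trajectories
satisfy that structure. Real data add baseline drift, band overlap,
spectral artifacts, correlated samples and partial-occupancy effects
that these fixtures deliberately omit.

## Problem sizes

Default study sizes were chosen to resolve every effect the tests
assert while keeping any single analysis in seconds: 49 scan positions
× 2 replicates, 10 EPR sites × 3 conditions × 15 powers, 33 umbrella
windows × 2000–5000 samples, 10–20 bootstrap replicates. All
generators accept larger sizes unchanged.
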