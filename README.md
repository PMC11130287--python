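# ldhairpin

Quantitative analysis machinery for determining the intramembrane
positioning of monotopic hairpin proteins — proteins whose hydrophobic
segment enters and exits the membrane on the same side — in an
ER-type phospholipid **bilayer** versus a lipid-droplet (LD)
**monolayer** membrane. The motivating system is the ER/LD protein
UBXD8, whose membrane-proximal region (residues 80–128) adopts a deeply
inserted, closed "deep-V" hairpin in the bilayer and an open, shallow,
interfacial conformation on the LD monolayer.

The package is written for structural biochemists and modellers who
combine four independent readouts of intramembrane positioning and want
each quantification step to be tested, scriptable and reproducible:

1. **Cysteine-accessibility (PEGylation) topology mapping** —
   `ldhairpin.accessibility`. Per residue, the relative PEGylation is
   the PEGylated fraction in the native membrane over the fraction after
   detergent solubilization (set to 100%). Residues are classified
   exposed / interface / embedded and the longest contiguous embedded
   run is the hairpin-segment call; a discrete Fourier transform scores
   the ~3.6-residue helical periodicity of partial exposure.
2. **cwEPR power-saturation depth profiling** — `ldhairpin.epr`. The
   peak-to-peak amplitude of the central EPR line follows
   `A = I·√P·[1 + (2^{1/ε} − 1)·P/P_{1/2}]^{−ε}`; per-site fits under
   N₂, O₂ and NiEDDA give the membrane depth parameter
   `Φ = ln[ΔP_{1/2}(O₂)/ΔP_{1/2}(NiEDDA)]` (positive: embedded,
   negative: exposed, ~0: interface).
3. **Membrane-geometry analytics** — `ldhairpin.geometry`. Per-residue
   Cα insertion depth relative to the cytoplasmic phosphate plane,
   peptide tilt against the membrane plane, arm-tip Cα distances,
   V-opening angle, and a deep-V / open-shallow classifier.
4. **Umbrella-sampling free energies (WHAM)** — `ldhairpin.wham`. A
   from-scratch self-consistent weighted-histogram estimator of the
   potential of mean force with window-level bootstrap errors.

`ldhairpin.synthetic` generates every input with known ground truth
(gel-band tables, saturation curves, toy hairpin structures, Boltzmann
umbrella samples, crosslink lanes), so the whole stack is exercisable
end to end without wet-lab or MD data.

## Worked example

The numbered drivers under `analysis/` run the full study on the
calibrated fixtures; `analysis/07_report.py` performs every stage in one
reproducible pass:

```sh
python analysis/01_simulate.py   # fixtures for both membrane contexts
python analysis/07_report.py    # all stages + combined report
```

which prints

```
bilayer: geometry=deep_V, embedded segment=[94, 122], EPR hairpin signature=True, PEG/EPR agreement=100% on 10 sites
monolayer: geometry=open_shallow, embedded segment=[96, 97], EPR hairpin signature=True, PEG/EPR agreement=100% on 10 sites
crosslink (normalized): bilayer=100%, monolayer=50%
PMF recovery RMSE: 0.280 kJ/mol
```

Reading: in the bilayer the topology map calls one contiguous
29-residue embedded segment (W94–R122) and the geometric observables
(kink 2 nm deep, ~80° tilt, 20 Å arm tips) classify the state deep-V.
On the monolayer the same residues are interspersed with partially
exposed positions every 3–4 residues (helical face at the interface),
the structure is flat and open (~30°, 36 Å), and intramolecular
crosslinking of the arm tips drops to half of the bilayer value. The
PEGylation and EPR depth calls agree on all shared spin-label sites,
and the WHAM estimator reproduces the known sampling landscape to
0.28 kJ/mol.

Individual stages are also available as a CLI
(`ldhairpin simulate|pegmap|xlink|epr-fit|depth|wham|report`), each a
thin wrapper over the library.

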