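# flashmap

Analysis tools for time-resolved serial crystallography (TR-SX) of
photoactivated proteins — the computational stages that turn per-delay
reflection datasets from a pump–probe experiment (such as an XFEL study of
a photolyase, where blue light triggers electron transfer from a tryptophan
chain to the FAD chromophore) into difference electron-density maps,
occupancy estimates and kinetic traces — together with global analysis of
the accompanying femtosecond transient-absorption (TA) spectroscopy.

Intended for structural biologists and spectroscopists working with
light-triggered pump–probe data who want a scriptable, fully seeded and
testable implementation of this analysis chain, including a synthetic-data
generator that provides ground truth for every stage.

## What it computes

**Weighted difference maps.** For each pump–probe delay, observed light and
dark amplitudes are put on a common scale (k·exp(−Bs²/4), fit on log
amplitudes) and combined into weighted difference structure factors

    ΔF_o = w · (F_o(light) − F_o(dark)),      phases from the dark model,

with per-reflection weights

    w = (1 + ΔF² / ⟨ΔF²⟩ + σ²_ΔF / ⟨σ²_ΔF⟩)⁻¹

that suppress outlier differences and noisy measurements. Fourier synthesis
between low- and high-resolution cutoffs (16 Å / 1.9 Å by default) gives
the difference electron density (DED) map whose positive and negative
features mark atoms that moved upon photoexcitation.

**Extrapolated structure factors and activation level.** Only a fraction
*r* of the molecules in the crystal are photoactivated, so the DED map
shows the structural change at reduced contrast. Extrapolated amplitudes

    F_e = F_c(dark) + N_e · ΔF_o,      N_e ≈ 2/r,

approximate the pure excited-state structure factor (the factor 2
compensates the half-height signal of difference Fourier maps computed
with dark phases). `flashmap` estimates N_e by scanning it and integrating
the negative density that appears around the active site once the
extrapolation overshoots; the knee of that curve (located by the maximum
discrete second difference) sits at N_e ≈ 2/r. 2F_e−F_c map coefficients
for excited-state model building are also provided.

**DED kinetics.** Region-integrated time courses (|ρ|/σ above a σ
threshold within a radius of the region atoms, 1 Å / 3.1σ by default),
randomized noise floors (the same integral averaged over thousands of
random six-residue windows), single-feature traces (mean one-signed
density in a 2.5 Å sphere above 2σ), series normalization, and voxel-wise
real-space Pearson correlation between maps.

**TA global analysis.** A sequential kinetic scheme 1→2→…→n with lifetimes
τᵢ (the last possibly non-decaying), convolved analytically with a
Gaussian instrument-response function, is fitted to delay × wavelength
ΔA matrices by variable projection: spectra are solved linearly at each
step while the lifetimes are optimized, yielding the evolution-associated
decay spectra (EADS).

**Synthetic data.** Toy crystals in P1, site displacements driven by
compartment populations of a kinetic scheme, occupancy mixtures formed
exactly in structure-factor space, amplitude noise, and simulated TA
matrices — every generated dataset comes with its ground-truth table.

## Worked example

Generate the standard synthetic crystal (24 atoms, one four-atom residue
displaced by 2.5 Å, activation level r = 2/14 ≈ 0.143, 1% amplitude
noise), then recover the activation level from the negative-density scan:

```python
import numpy as np
from flashmap import (compute_fc, difference_coefficients,
                      negative_density_curve, estimate_ne, activation_from_ne)
from flashmap.synthetic import standard_scenario

dark, light, site, fo_dark, fo_light = standard_scenario(seed=2)
fc = compute_fc(dark, 1.9, 16.0)
diff = difference_coefficients(fo_light, fo_dark, fc, weighting="none")
scan = negative_density_curve(fc, diff, np.arange(2, 41, 2), dark, mask_atoms=site)
ne = estimate_ne(scan)
print(f"estimated Ne = {ne:g}  ->  activation level r = {activation_from_ne(ne):.3f}")
```

prints

```
estimated Ne = 14  ->  activation level r = 0.143
```

i.e. the scan recovers the programmed extrapolation factor 2/r = 14: the
integrated negative density near the displaced site stays flat until the
extrapolation factor passes 2/r and the overshoot starts carving negative
density into the vacated atomic positions.

Fitting a synthetic TA matrix simulated from a four-compartment sequential
scheme (0.52, 12 and 450 ps plus a long-lived terminal state, 150 fs IRF,
signal-to-noise ≈ 50):

```python
fit = fit_global(data, 4, [0.3, 8.0, 300.0, np.inf], irf_fwhm=0.15, seed=0)
```

prints, via the snippet in `docs/methods.md`,

```
fitted lifetimes (ps): 0.526, 12.1, 450 (+ non-decaying terminal); residual rms = 0.102 mOD
```

— the intermediate lifetimes are recovered to ~1%.

A command-line interface mirrors the library: `flashmap simulate`, `ded`,
`extrapolate`, `kinetics`, `tafit`, `report` and `run-all` (driven by a
YAML config; see `flashmap run-all --help`). Reflection files are MTZ or a
plain-text dialect (`cell a b c α β γ` header line, then
`h k l F sigF [phase_deg]` records, `#` comments); maps are CCP4 mode 2;
models are PDB/mmCIF.

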