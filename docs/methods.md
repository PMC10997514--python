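# Methods

This note documents the models, numerical choices and validation strategy
behind `flashmap`, and what the synthetic tests do and do not demonstrate
about real data.

## Crystallographic model

All structure-factor and map arithmetic is carried out in space group P1:
reflection sets store one member of each Friedel pair, maps cover the full
unit cell. Files carrying symmetry are used as-is for geometry; map work
treats the asymmetric content as the full cell. This avoids a symmetry
engine entirely while remaining exact for the P1 synthetic crystals on
which the pipeline is validated.

Calculated structure factors use the kinematic direct sum

    F(h) = Σ_j occ_j · f_j(s) · exp(−B_j s²/4) · exp(+2πi h·x_j),  s = 1/d,

with 4-Gaussian International-Tables form factors taken from gemmi's
tables (H, C, N, O, P, S and everything else gemmi tabulates; hydrogens
contribute only when present in the model). No anisotropic displacement,
anomalous scattering or bulk-solvent model. Synthesis uses the conjugate
convention ρ(x) = (1/V) Σ_h F(h) exp(−2πi h·x) with Friedel completion, on
an FFT grid with default voxel pitch d_min/3 rounded up to even dimensions;
a grid too coarse for the index range is rejected rather than aliased.
F(000) is excluded from all difference and extrapolated syntheses, so those
maps are mean-zero by construction. Phases are degrees in files, and a
signed coefficient on a stored phase is treated as a 180° flip, which keeps
difference and extrapolated coefficients linear operations.

Correctness anchors: the direct sum is tested against an independently
coded double loop and against gemmi's own structure-factor calculator; the
FFT synthesis against a per-voxel complex sum; and the pair against
Parseval's identity (relative error ≤ 1e-6) and against peak positions of
the synthesized atom density.

## Scaling

Light-to-dark (and dark-to-Fc) scaling fits F_ref ≈ k·exp(−B s²/4)·F_target
by amplitude-weighted linear least squares on log amplitudes — the standard
relative Wilson-type scale — and applies the per-reflection factor to
amplitudes and sigmas. On noise-free data the inverse transform is
recovered to well under 1%.

A caveat that matters for simulation work: fitting a scale between datasets
that genuinely differ (a partially photoactivated mixture has a slightly
lower mean amplitude than the dark state) absorbs part of that real
difference into k and B. With the toy crystals used here, where the
perturbed site is a large fraction of the structure, this shifts the
apparent extrapolation-factor knee noticeably (measured: from ~14 to ~22 at
r = 1/7). Synthetic observations are generated on a common absolute scale,
so the recovery studies pass them to the differencing step directly; the
scaling stage remains in the pipeline (and on by default) for data that
actually need it, where the perturbed fraction of a real protein is orders
of magnitude smaller and the absorption is negligible.

## Weighting and difference maps

Weights w = (1 + ΔF²/⟨ΔF²⟩ + σ²/⟨σ²⟩)⁻¹ use plain arithmetic means over the
working reflection set (no resolution binning; a binned variant would be a
straightforward extension but is not implemented). Zero-denominator ratio
terms are defined as 0, so degenerate noise-free sets get w = 1
identically. Applied weights are divided by their mean ("relative"
q-weighting): the weighting then suppresses outliers without shrinking the
overall difference-amplitude scale. The raw w ∈ (0, 1] is what the weights
output column reports.

For **extrapolation**, the differences are used unweighted by default
(`weighting="none"`). The reason is quantitative: the weights are a
function of |ΔF|, and whenever the per-reflection differences are
signal-dominated (as in low-noise synthetic data) the largest — most
informative — differences are shrunk hardest. Measured on the standard
synthetic crystal, the signal-power-weighted mean applied weight is ≈ 0.36,
which attenuates the difference signal in map space by ≈ 2× and inflates
the apparent knee of the negative-density curve to ≈ 2/(0.4·r). On
noise-dominated experimental differences the weights largely decouple from
the signal and this bias shrinks; users who want weighted extrapolation can
pass `weighting="q"`.

## Extrapolation-factor estimation

The negative-density diagnostic synthesizes the extrapolated map for each
N_e on a scan grid and integrates |ρ|/σ_map · V_voxel over voxels within
2.0 Å of the mask atoms whose density lies below −k·σ_map. Two numerical
choices differ from the obvious defaults, both fixed by bias analysis on
ground-truth recovery sweeps (r ∈ {0.05, 0.1, 0.2, 0.5}, 2% noise):

- **Threshold −1σ rather than a deep −3σ.** Negative density at a vacated
  site first appears just past N_e = 2/r and deepens linearly; a threshold
  at −kσ does not register it until the overshoot has grown by the further
  factor 1 + kσ/ρ_peak. At −3σ this delayed the measured knee by 25–30%;
  at −1σ the residual bias is within the scan-grid resolution.
- **Raw (unsmoothed) second differences for the knee.** The maximum
  discrete second difference of a hockey-stick curve falls exactly at the
  kink; a 3-point pre-smoothing spreads the curvature one grid step
  backward and biased the estimate low by one scan step. Smoothing remains
  available (`smooth=True`) for very noisy curves.

A strictly linear or flat curve raises an error advising a wider scan
rather than returning an arbitrary point. The activation level follows as
r = 2/N_e.

The estimator's premise is that the excited-state conformer *vacates* its
dark-state position. The standard synthetic scenario therefore displaces
its site by 2.5 Å — beyond the 1.9 Å resolution length. Sub-resolution
displacements leave a fraction α of the dark density in place and provably
shift the knee to 2/(r(1−α)); that regime limitation applies equally to
real data and is inherent to the method, not to this implementation.

Conversely, the factor-2 relation underlying F_e (and the half-height DED
signal) is a small-perturbation, ensemble result: tests verify the peak
ratio as a median over seeded structures (median ≈ 0.48 at a 0.4 Å
single-atom displacement) and verify CC > 0.95 between the extrapolated
map at N_e = 2/r and the true excited-state map in the modest-displacement
regime (1 Å) where the linearization is accurate.

## DED kinetics

Region integrals sum |ρ|/σ_map · V_voxel over voxels whose centres lie
within the region radius (periodic minimum-image distances, voxel-centre
membership) and pass the σ threshold; both-signed integration is the
default since the time courses track total signal strength, with one-sided
modes available. Defaults: 1 Å radius at 3.1σ for residue regions, 2.5 Å
at 2σ for single-feature traces (a 2 Å variant is used where a single side
chain is tracked). All quantities are in map-σ units and thus invariant
under uniform map rescaling. Noise floors average the same integral over
seeded random windows of six consecutive residues drawn outside the
regions of interest (5000 windows by default; per-window masks are cached,
so the cost is bounded by the number of distinct windows). Normalization
divides a series and its noise floor by the series maximum, preserving
their ratio. The real-space CC is the plain voxel-wise Pearson coefficient
over the grid or an optional mask.

## TA global analysis

Sequential compartments 1→2→…→n with distinct lifetimes; the Bateman
partial-fraction solution is used with each exponential replaced by its
closed-form convolution with a normalized Gaussian IRF,

    E(t; k) = ½ exp(k²σ²/2 − k(t−t₀)) · erfc((kσ − (t−t₀)/σ)/√2),

evaluated through erfcx on one branch and erfc on the other to avoid
overflow at large |t|. σ = FWHM/2.355. A terminal lifetime of ∞ (rate 0)
models a state that does not decay within the window; populations then
conserve total concentration to 1e-9. Exactly degenerate lifetimes are
rejected (the partial fractions are singular); the fitter nudges
transiently degenerate iterates apart by one part in 10⁹.

The fit is a variable projection: for trial lifetimes (optionally t₀ and
IRF width), the EADS are the linear least-squares solution and the
nonlinear parameters minimize the projected residual (Levenberg–Marquardt
on log-lifetimes, which enforces positivity and equalizes scales across
three decades). Three jittered starts (seeded, 0.2 in log-space) guard
against local minima. Lifetime standard errors come from the Jacobian
covariance via the delta method. Noise-free self-simulations are recovered
to <0.1% with residuals at machine precision; at signal-to-noise 50 the
intermediate lifetimes of the four-compartment reference scheme
(0.52 / 12 / 450 ps + terminal, 150 fs IRF) are recovered with median
errors well under 10%.

## Synthetic data: what it does and does not emulate

Toy crystals place 24 (default) C/N/O/S atoms in a 20×24×28 Å P1 cell,
grouped into four-atom pseudo-residues, minimum separation 1.2 Å, B ∈
[10, 30] Å². Photoactivation is an occupancy mixture formed exactly in
structure-factor space, F_mix = (1−r)F_dark + rF_light (complex sums;
additive per site for multi-site series), with Gaussian amplitude noise of
sd = noise_frac·⟨|F|⟩ floored at zero and σ set to that sd. Time series
scale each site's occupancy by its kinetic compartment's population, and
every dataset ships a ground-truth occupancy table.

Emulated: partial-occupancy difference signals, amplitude noise,
resolution truncation, multi-site kinetics, the scale relation between
light/dark/calculated sets. Not emulated: measurement in intensity space
and French–Wilson conversion, space-group symmetry, partiality and
per-image scaling, radiation damage, solvent, model-phase error (phases
come from the exact dark model). Passing recovery tests therefore
demonstrates the correctness and internal consistency of the analysis
chain under the stated noise model — not robustness to the full error
budget of an XFEL experiment.

Default study conditions for the recovery studies: activation level
r = 2/14 (ten replicates, 1% amplitude noise, N_e scan 2–40 step 2,
median reported) and the four-compartment TA scheme above (twenty
replicates, 64 delays from −1 to 3000 ps — linear through the IRF, then
log-spaced — 96 wavelengths, SNR 50, median lifetimes reported). These
sizes keep each full study in the seconds-to-minutes range on one CPU.

## Degenerate inputs and tie-breaks

Zero-variance maps are rejected by the CC; all-zero series cannot be
normalized; empty masks, empty resolution windows, unresolvable selectors,
duplicate Miller indices and negative sigmas raise informative errors.
Knee ties resolve to the smaller N_e (first maximum). The mean-density
(0,0,0) term has no d-spacing and is rejected wherever a spacing is
required.

## Known limitations

- P1 only; symmetry-expanded inputs are not merged back.
- Global (unbinned) weighting means; no outlier rejection beyond the
  weights themselves.
- The negative-density knee needs the scan to bracket 2/r and the
  displaced site to clear its dark position; sub-resolution motions bias
  the estimate high.
- Sequential kinetic schemes only (no branching); dispersion/chirp
  correction of TA data is assumed done upstream, and synthetic TA data
  are generated chirp-free.
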