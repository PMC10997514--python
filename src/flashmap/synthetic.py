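"""Ground-truth-known synthetic data: toy crystals, photoactivated mixtures,
delay series driven by a kinetic scheme, and TA matrices.

A photoactivated crystal with activation level r is an occupancy mixture of
dark and displaced (light) conformers; observed amplitudes are formed in
structure-factor space as |(1-r) F_dark + r F_light| plus Gaussian
amplitude noise, which is exact for kinematic scattering and keeps the
test algebra transparent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import AtomicModel, ReflectionSet, UnitCell
from .sf import structure_factors, unique_hkl
from .ta import KineticScheme, concentration_profiles

__all__ = [
    "PerturbationSpec",
    "make_toy_crystal",
    "perturb_model",
    "simulate_observations",
    "make_timeseries_dataset",
    "standard_scenario",
]

_ELEMENTS = np.array(["C", "C", "C", "N", "O", "S"])  # carbon-rich, protein-like mix


@dataclass
class PerturbationSpec:
    """A displaced site: which atoms move, by how much, and which kinetic
    compartment's population scales its light-state occupancy."""

    site: Sequence  # residue ids (chain, resnum) or atom selectors
    displacement: np.ndarray | float = 0.8
    compartment: int = 0

    def __post_init__(self) -> None:
        disp = np.asarray(self.displacement, dtype=float)
        mag = float(np.linalg.norm(disp)) if disp.ndim else float(disp)
        if not 0.0 < mag <= 3.0:
            raise ValueError("displacement magnitude must lie in (0, 3] Angstrom")
        if self.compartment < 0:
            raise ValueError("compartment index must be non-negative")


def make_toy_crystal(
    seed: int = 0,
    n_atoms: int = 24,
    cell: UnitCell | None = None,
    min_distance: float = 1.2,
    max_tries: int = 20000,
) -> AtomicModel:
    """Seeded random toy crystal in P1.

    Atoms are grouped into pseudo-residues of four (sequential residue
    numbers, chain A) with a minimum pairwise distance (periodic) of
    ``min_distance`` and B-factors uniform in [10, 30] A^2.
    """
    if n_atoms < 2:
        raise ValueError("need at least two atoms")
    if cell is None:
        cell = UnitCell(20.0, 24.0, 28.0, 90.0, 90.0, 90.0)
    rng = np.random.default_rng(seed)
    orth = cell.orth_matrix
    frac_inv = cell.frac_matrix
    placed_frac: list[np.ndarray] = []
    tries = 0
    while len(placed_frac) < n_atoms:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not pack {n_atoms} atoms at {min_distance} A separation"
            )
        cand = rng.random(3)
        ok = True
        for other in placed_frac:
            d = cand - other
            d -= np.round(d)
            if np.linalg.norm(orth @ d) < min_distance:
                ok = False
                break
        if ok:
            placed_frac.append(cand)
    frac = np.array(placed_frac)
    xyz = frac @ orth.T
    elements = rng.choice(_ELEMENTS, size=n_atoms)
    rows = []
    for i in range(n_atoms):
        resnum = i // 4 + 1
        rows.append(
            {
                "element": elements[i],
                "name": f"{elements[i]}{i % 4 + 1}",
                "resname": "TOY",
                "resnum": resnum,
                "chain": "A",
                "x": xyz[i, 0],
                "y": xyz[i, 1],
                "z": xyz[i, 2],
                "occ": 1.0,
                "b": float(rng.uniform(10.0, 30.0)),
            }
        )
    return AtomicModel(cell=cell, atoms=pd.DataFrame(rows), label=f"toy(seed={seed})")


def perturb_model(dark: AtomicModel, spec: PerturbationSpec, seed: int = 0) -> AtomicModel:
    """Light model: the site atoms displaced, all other atoms untouched.

    A vector displacement is applied as-is; a scalar magnitude is applied
    along a seeded random direction (one direction for the whole site).
    """
    light = dark.copy()
    idx = _site_atoms(dark, spec.site)
    if len(idx) == 0:
        raise ValueError("perturbation site resolves to no atoms")
    disp = np.asarray(spec.displacement, dtype=float)
    if disp.ndim == 0:
        rng = np.random.default_rng(seed)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        disp = float(disp) * direction
    for col, dv in zip(("x", "y", "z"), disp):
        light.atoms.loc[idx, col] = light.atoms.loc[idx, col] + dv
    light.label = dark.label + "+light"
    return light


def _site_atoms(model: AtomicModel, site: Sequence) -> np.ndarray:
    entries = list(site)
    if entries and isinstance(entries[0], (tuple, list)) and len(entries[0]) == 3:
        return np.asarray([model.select_atom(tuple(s)) for s in entries])
    return model.select_residue_atoms(entries)


def simulate_observations(
    dark: AtomicModel,
    light: AtomicModel,
    r: float,
    noise_frac: float = 0.0,
    d_min: float = 1.9,
    d_max: float = 16.0,
    seed: int = 0,
) -> tuple[ReflectionSet, ReflectionSet]:
    """Observed dark and photoactivated amplitudes for a mixture crystal.

    F_mix(h) = (1-r) F_dark(h) + r F_light(h) as complex sums; observed
    amplitudes get Gaussian noise of sd = noise_frac * <|F_dark|>, floored
    at zero, and sigmas equal to that sd.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("activation level r must lie in [0, 1]")
    if noise_frac < 0:
        raise ValueError("noise_frac must be non-negative")
    hkl = unique_hkl(dark.cell, d_min, d_max)
    f_dark = structure_factors(dark, hkl)
    f_light = structure_factors(light, hkl)
    f_mix = (1.0 - r) * f_dark + r * f_light
    amp_dark = np.abs(f_dark)
    amp_mix = np.abs(f_mix)
    sd = noise_frac * float(amp_dark.mean())
    rng = np.random.default_rng(seed)
    if sd > 0:
        amp_dark = np.clip(amp_dark + rng.normal(0.0, sd, len(hkl)), 0.0, None)
        amp_mix = np.clip(amp_mix + rng.normal(0.0, sd, len(hkl)), 0.0, None)
    sigmas = np.full(len(hkl), sd)
    fo_dark = ReflectionSet(dark.cell, hkl, amp_dark, sigmas.copy(), label="Fo(dark)")
    fo_light = ReflectionSet(dark.cell, hkl, amp_mix, sigmas.copy(), label="Fo(light)")
    return fo_dark, fo_light


def make_timeseries_dataset(
    dark: AtomicModel,
    specs: Sequence[PerturbationSpec],
    scheme: KineticScheme,
    delays: Sequence[float],
    r_max: float = 0.25,
    noise_frac: float = 0.01,
    d_min: float = 1.9,
    d_max: float = 16.0,
    seed: int = 0,
) -> tuple[ReflectionSet, list[ReflectionSet], pd.DataFrame, list[AtomicModel]]:
    """Per-delay observed amplitudes for several displaced sites whose
    occupancies follow compartment populations.

    At each delay, site s carries occupancy r_max * c_{spec.compartment}(t).
    Site contributions add in structure-factor space (exact for independent
    sites).  Returns (Fo_dark, [Fo_light per delay], truth table, light
    models per site).
    """
    delays = np.asarray(delays, dtype=float)
    profiles = concentration_profiles(scheme, delays)  # (n_comp, n_delays)
    hkl = unique_hkl(dark.cell, d_min, d_max)
    f_dark = structure_factors(dark, hkl)
    lights = []
    site_delta_f = []
    for s, spec in enumerate(specs):
        if spec.compartment >= scheme.n:
            raise ValueError(f"site {s}: compartment {spec.compartment} out of range")
        light = perturb_model(dark, spec, seed=seed + s)
        lights.append(light)
        site_delta_f.append(structure_factors(light, hkl) - f_dark)
    amp_dark_true = np.abs(f_dark)
    sd = noise_frac * float(amp_dark_true.mean())
    rng = np.random.default_rng(seed)
    amp_dark = amp_dark_true.copy()
    if sd > 0:
        amp_dark = np.clip(amp_dark + rng.normal(0.0, sd, len(hkl)), 0.0, None)
    sigmas = np.full(len(hkl), sd)
    fo_dark = ReflectionSet(dark.cell, hkl, amp_dark, sigmas.copy(), label="Fo(dark)")
    fo_per_delay = []
    truth_rows = []
    for it, t in enumerate(delays):
        f_mix = f_dark.copy()
        row = {"delay_ps": float(t)}
        for s, spec in enumerate(specs):
            occ = r_max * float(profiles[spec.compartment, it])
            f_mix = f_mix + occ * site_delta_f[s]
            row[f"site{s + 1}_occupancy"] = occ
        amp = np.abs(f_mix)
        if sd > 0:
            amp = np.clip(amp + rng.normal(0.0, sd, len(hkl)), 0.0, None)
        fo_per_delay.append(
            ReflectionSet(dark.cell, hkl, amp, sigmas.copy(), label=f"Fo(light,{t:g}ps)")
        )
        truth_rows.append(row)
    return fo_dark, fo_per_delay, pd.DataFrame(truth_rows), lights


def standard_scenario(
    seed: int = 0,
    r: float = 2.0 / 14.0,
    noise_frac: float = 0.01,
    displacement: float = 2.5,
    n_atoms: int = 24,
    d_min: float = 1.9,
    d_max: float = 16.0,
):
    """The standard single-site test crystal: a 24-atom toy model whose
    first pseudo-residue is displaced, observed at activation level r.

    Returns (dark model, light model, site atom indices, Fo_dark, Fo_light).
    """
    dark = make_toy_crystal(seed=seed, n_atoms=n_atoms)
    spec = PerturbationSpec(site=[("A", 1)], displacement=displacement, compartment=0)
    light = perturb_model(dark, spec, seed=seed + 1)
    fo_dark, fo_light = simulate_observations(
        dark, light, r=r, noise_frac=noise_frac, d_min=d_min, d_max=d_max, seed=seed + 2
    )
    site = dark.select_residue_atoms([("A", 1)])
    return dark, light, site, fo_dark, fo_light
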