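"""Extrapolated structure factors and estimation of the extrapolation factor.

The extrapolated amplitude F_e = F_c(dark) + N_e * dF_o approximates the
structure factor of the pure photoexcited species when the extrapolation
factor N_e matches 2/r, where r is the fraction of photoactivated molecules
(the factor 2 compensating the half-height signal of difference Fourier
maps computed with dark phases).  Overshooting N_e carves spurious negative
density into the extrapolated map at the positions of displaced atoms, so
scanning N_e and watching the integrated negative density around the active
site locates 2/r as the knee of the curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import AtomicModel, DifferenceSet, RealSpaceMap, ReflectionSet
from .sf import default_grid, synthesize_map

__all__ = [
    "NeScan",
    "extrapolated_coefficients",
    "negative_density_curve",
    "estimate_ne",
    "activation_from_ne",
    "ne_from_activation",
    "refinement_map_coefficients",
]


@dataclass
class NeScan:
    """Negative-density diagnostic as a function of the extrapolation factor."""

    ne_values: np.ndarray
    neg_density: np.ndarray
    chosen_ne: float | None = None
    method: str = "max-second-difference"

    def __post_init__(self) -> None:
        self.ne_values = np.asarray(self.ne_values, dtype=float)
        self.neg_density = np.asarray(self.neg_density, dtype=float)
        if self.ne_values.shape != self.neg_density.shape or len(self.ne_values) < 3:
            raise ValueError("scan needs >= 3 matching ne/neg-density values")
        if np.any(np.diff(self.ne_values) <= 0):
            raise ValueError("ne values must be strictly ascending")


def _aligned_delta(fc_dark: ReflectionSet, diff: DifferenceSet) -> tuple[np.ndarray, np.ndarray]:
    """Delta values aligned to fc_dark's index order (zero where absent)."""
    fc_map = fc_dark.index_map()
    delta = np.zeros(len(fc_dark))
    seen = np.zeros(len(diff), dtype=bool)
    for j, h in enumerate(map(tuple, diff.hkl.tolist())):
        i = fc_map.get(h)
        if i is None:
            if diff.delta[j] != 0.0:
                raise ValueError(f"difference set has nonzero delta at {h} but no Fc")
            continue
        delta[i] = diff.delta[j]
        seen[j] = True
    return delta, seen


def extrapolated_coefficients(
    fc_dark: ReflectionSet, diff: DifferenceSet, ne: float
) -> ReflectionSet:
    """Extrapolated amplitudes |Fe| = |Fc| + ne * delta on dark phases.

    Coefficients are kept signed (a negative value synthesizes as a
    180-degree phase flip) so the operation stays linear in ne; the number
    of negative coefficients is recorded as ``n_negative`` on the result.
    """
    if ne < 0:
        raise ValueError("extrapolation factor must be non-negative")
    if fc_dark.phase is None:
        raise ValueError("fc_dark must carry phases")
    delta, _ = _aligned_delta(fc_dark, diff)
    fe = fc_dark.amplitude + ne * delta
    out = ReflectionSet(
        cell=fc_dark.cell,
        hkl=fc_dark.hkl.copy(),
        amplitude=fe,
        sigma=np.abs(ne) * _aligned_sigma(fc_dark, diff),
        phase=fc_dark.phase.copy(),
        label=f"Fe(ne={ne:g})",
    )
    out.n_negative = int(np.sum(fe < 0))  # type: ignore[attr-defined]
    return out


def _aligned_sigma(fc_dark: ReflectionSet, diff: DifferenceSet) -> np.ndarray:
    fc_map = fc_dark.index_map()
    sigma = np.zeros(len(fc_dark))
    for j, h in enumerate(map(tuple, diff.hkl.tolist())):
        i = fc_map.get(h)
        if i is not None:
            sigma[i] = diff.sigma[j]
    return sigma


def negative_density_curve(
    fc_dark: ReflectionSet,
    diff: DifferenceSet,
    ne_values: Sequence[float],
    mask_model: AtomicModel,
    mask_atoms: np.ndarray | None = None,
    mask_radius: float = 2.0,
    threshold_sigma: float = 1.0,
    grid: Sequence[int] | None = None,
) -> NeScan:
    """Integrated negative density near mask atoms versus the scan of ne.

    For each ne the extrapolated map is synthesized and |rho| is integrated
    (in map-sigma * A^3 units) over voxels below -threshold_sigma * sigma_map
    lying within ``mask_radius`` of the mask atoms (all atoms of
    ``mask_model`` when ``mask_atoms`` is None).

    The default threshold of -1 sigma keeps the onset of the curve close to
    the true overshoot point: negative density at a vacated site first
    appears just past ne = 2/r, and a deep threshold would not register it
    until the overshoot has grown by a further factor 1 + k*sigma/peak.
    """
    ne_values = np.asarray(ne_values, dtype=float)
    if len(ne_values) < 3 or np.any(np.diff(ne_values) <= 0):
        raise ValueError("need >= 3 strictly ascending ne values")
    idx = np.arange(len(mask_model)) if mask_atoms is None else np.asarray(mask_atoms)
    if len(idx) == 0:
        raise ValueError("empty mask: no atoms selected for the negative-density region")
    if grid is None:
        grid = default_grid(fc_dark.cell, float(fc_dark.d_spacings().min()))
    near = _voxels_near_atoms(fc_dark.cell, grid, mask_model.coords()[idx], mask_radius)
    curve = []
    for ne in ne_values:
        fe = extrapolated_coefficients(fc_dark, diff, float(ne))
        density_map = synthesize_map(fe, grid=grid)
        sig = density_map.sigma
        vals = density_map.values.ravel()[near]
        neg = vals < -threshold_sigma * sig
        curve.append(float(np.sum(np.abs(vals[neg]) / sig) * density_map.voxel_volume))
    return NeScan(ne_values=ne_values, neg_density=np.asarray(curve))


def _voxels_near_atoms(cell, grid, coords: np.ndarray, radius: float) -> np.ndarray:
    """Flat voxel indices whose centres lie within radius of any atom
    (periodic minimum image)."""
    nx, ny, nz = grid
    fx = np.arange(nx) / nx
    fy = np.arange(ny) / ny
    fz = np.arange(nz) / nz
    gx, gy, gz = np.meshgrid(fx, fy, fz, indexing="ij")
    vox_frac = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    frac_atoms = coords @ cell.frac_matrix.T
    orth = cell.orth_matrix
    near = np.zeros(len(vox_frac), dtype=bool)
    for fa in frac_atoms:
        dfrac = vox_frac - fa
        dfrac -= np.round(dfrac)
        dxyz = dfrac @ orth.T
        near |= np.einsum("ij,ij->i", dxyz, dxyz) <= radius * radius
    return np.flatnonzero(near)


def estimate_ne(
    scan: NeScan, min_points: int = 5, flatness_tol: float = 1e-6, smooth: bool = False
) -> float:
    """Knee of the negative-density curve: the ne at the maximum discrete
    second difference.

    The raw second difference of a hockey-stick curve peaks exactly at the
    kink, so no pre-smoothing is applied by default; ``smooth=True`` runs a
    3-point moving average first, which helps on very noisy curves at the
    cost of a half-step bias toward smaller ne.  Raises if the curve is too
    short or has no detectable curvature (e.g. a strictly linear scan), in
    which case a wider ne range should be scanned.
    """
    if len(scan.ne_values) < min_points:
        raise ValueError(f"scan has {len(scan.ne_values)} points; need >= {min_points}")
    y = scan.neg_density.astype(float)
    sm = y.copy()
    if smooth:
        sm[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
    d2 = sm[:-2] - 2.0 * sm[1:-1] + sm[2:]
    scale = float(np.max(np.abs(y)) - np.min(np.abs(y)))
    if scale <= 0 or float(np.max(d2)) <= flatness_tol * scale:
        raise ValueError(
            "no knee detected: the negative-density curve has no resolvable "
            "curvature; scan a wider or finer ne range"
        )
    knee = int(np.argmax(d2)) + 1
    chosen = float(scan.ne_values[knee])
    scan.chosen_ne = chosen
    return chosen


def activation_from_ne(ne: float) -> float:
    """Photoactivation level r from the extrapolation factor: r = 2/ne."""
    if ne <= 0:
        raise ValueError("extrapolation factor must be positive")
    r = 2.0 / ne
    if r > 1.0:
        warnings.warn(
            f"ne={ne:g} < 2 implies an activation level {r:.3g} > 1", stacklevel=2
        )
    return r


def ne_from_activation(r: float) -> float:
    """Extrapolation factor from the activation level: ne = 2/r."""
    if not 0.0 < r <= 1.0:
        raise ValueError("activation level must lie in (0, 1]")
    return 2.0 / r


def refinement_map_coefficients(
    fe: ReflectionSet, fc_dark: ReflectionSet
) -> ReflectionSet:
    """2Fe - Fc coefficients on dark phases, for refinement-style maps."""
    ife, ifc = fe.common_indices(fc_dark)
    if len(ife) != len(fe) or len(ife) != len(fc_dark):
        raise ValueError("Fe and Fc index sets do not match")
    if fc_dark.phase is None:
        raise ValueError("fc_dark must carry phases")
    coeff = 2.0 * fe.amplitude[ife] - fc_dark.amplitude[ifc]
    return ReflectionSet(
        cell=fe.cell,
        hkl=fe.hkl[ife],
        amplitude=coeff,
        sigma=np.zeros(len(ife)),
        phase=fc_dark.phase[ifc],
        label="2Fe-Fc",
    )
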