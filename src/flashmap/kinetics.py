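"""Sigma-thresholded integration of difference density and its time courses.

Region kinetics integrate |rho|/sigma_map * voxel volume over voxels within
a radius of the region's atoms that exceed a sigma threshold, per delay.
The noise floor of a map is the same integral averaged over many randomly
drawn six-residue windows far from the regions of interest.  Feature
kinetics average the one-signed density within a small sphere around a
single site.  All quantities are in map-sigma units, so they are invariant
under uniform rescaling of a map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import AtomicModel, RealSpaceMap

__all__ = [
    "RegionSpec",
    "KineticsSeries",
    "integrate_region",
    "noise_floor",
    "feature_series",
    "normalize_series",
    "real_space_cc",
]


@dataclass
class RegionSpec:
    """A named group of residues/ligands with an integration radius and
    sigma threshold.

    ``residues`` entries are (chain, resnum) pairs or residue/ligand names.
    ``sign_mode`` selects which density enters the integral: "both" uses
    |rho| > k sigma, "positive" rho > k sigma, "negative" rho < -k sigma.
    """

    name: str
    residues: Sequence
    radius: float = 1.0
    sigma_threshold: float = 3.1
    sign_mode: str = "both"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.sigma_threshold <= 0:
            raise ValueError("sigma threshold must be positive")
        if self.sign_mode not in ("both", "positive", "negative"):
            raise ValueError("sign_mode must be both/positive/negative")


@dataclass
class KineticsSeries:
    """Integrated DED versus pump-probe delay (delays in ps)."""

    name: str
    delays: np.ndarray
    values: np.ndarray
    noise_floor: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.delays.shape != self.values.shape:
            raise ValueError("delays and values must have matching shape")
        if np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be strictly increasing")
        if self.noise_floor is not None:
            self.noise_floor = np.asarray(self.noise_floor, dtype=float)
            if self.noise_floor.shape != self.values.shape:
                raise ValueError("noise_floor must match values")
            if np.any(self.noise_floor < 0):
                raise ValueError("noise_floor must be non-negative")


def _voxel_mask_near(
    density_map: RealSpaceMap, coords: np.ndarray, radius: float
) -> np.ndarray:
    """Boolean voxel mask: centre within radius of any coordinate (periodic)."""
    cell = density_map.cell
    nx, ny, nz = density_map.shape
    gx, gy, gz = density_map.voxel_fractional_coords()
    vox_frac = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    frac_atoms = np.atleast_2d(coords) @ cell.frac_matrix.T
    orth = cell.orth_matrix
    mask = np.zeros(len(vox_frac), dtype=bool)
    r2 = radius * radius
    for fa in frac_atoms:
        dfrac = vox_frac - fa
        dfrac -= np.round(dfrac)
        dxyz = dfrac @ orth.T
        mask |= np.einsum("ij,ij->i", dxyz, dxyz) <= r2
    return mask.reshape(density_map.shape)


def _thresholded_integral(
    density_map: RealSpaceMap, mask: np.ndarray, spec_threshold: float, sign_mode: str
) -> float:
    sig = density_map.sigma
    if sig == 0:
        return 0.0
    vals = density_map.values[mask]
    cut = spec_threshold * sig
    if sign_mode == "both":
        passing = np.abs(vals) > cut
    elif sign_mode == "positive":
        passing = vals > cut
    else:
        passing = vals < -cut
    return float(np.sum(np.abs(vals[passing]) / sig) * density_map.voxel_volume)


def integrate_region(
    density_map: RealSpaceMap, model: AtomicModel, spec: RegionSpec
) -> float:
    """Integrated DED (map-sigma * A^3) in a region of the model.

    Sums |rho|/sigma_map * voxel volume over voxels whose centres lie within
    ``spec.radius`` of any region atom and whose value passes the sigma
    threshold.
    """
    idx = model.select_residue_atoms(spec.residues)
    if len(idx) == 0:
        raise ValueError(f"region {spec.name!r} resolves to no atoms")
    mask = _voxel_mask_near(density_map, model.coords()[idx], spec.radius)
    return _thresholded_integral(density_map, mask, spec.sigma_threshold, spec.sign_mode)


def noise_floor(
    density_map: RealSpaceMap,
    model: AtomicModel,
    spec: RegionSpec,
    n: int = 5000,
    region_size: int = 6,
    exclude: Sequence[tuple[str, int]] = (),
    seed: int = 0,
) -> float:
    """Noise floor: mean integrated DED over random six-residue windows.

    Windows are contiguous-in-sequence runs of ``region_size`` residues
    drawn (seeded) from residues outside ``exclude``, integrated with the
    same radius/threshold as ``spec``.
    """
    excluded = {(str(c), int(r)) for c, r in exclude}
    residues = [rid for rid in model.residue_ids() if rid not in excluded]
    if len(residues) <= region_size:
        raise ValueError(
            f"model has only {len(residues)} usable residues; need more than {region_size}"
        )
    # valid windows: consecutive positions in the (chain-ordered) residue list
    # that stay within one chain
    starts = [
        i
        for i in range(len(residues) - region_size + 1)
        if all(residues[i + j][0] == residues[i][0] for j in range(region_size))
    ]
    if not starts:
        raise ValueError("no contiguous residue window fits outside the excluded set")
    rng = np.random.default_rng(seed)
    xyz = model.coords()
    # precompute voxel masks per residue, then union per window
    res_masks = {}
    for rid in residues:
        idx = model.select_residue_atoms([rid])
        res_masks[rid] = _voxel_mask_near(density_map, xyz[idx], spec.radius)
    total = 0.0
    draws = rng.choice(len(starts), size=n, replace=True)
    cache: dict[int, float] = {}
    for start_pos in draws:
        start = starts[start_pos]
        if start in cache:
            total += cache[start]
            continue
        mask = np.zeros(density_map.shape, dtype=bool)
        for j in range(region_size):
            mask |= res_masks[residues[start + j]]
        val = _thresholded_integral(density_map, mask, spec.sigma_threshold, spec.sign_mode)
        cache[start] = val
        total += val
    return total / n


def feature_series(
    maps: Sequence[RealSpaceMap],
    delays: Sequence[float],
    center: np.ndarray,
    radius: float = 2.5,
    sign: str = "positive",
    sigma_threshold: float = 2.0,
    name: str = "feature",
) -> KineticsSeries:
    """Mean one-signed density (in map-sigma units) around a point, per delay.

    For each map, averages rho/sigma_map over voxels within ``radius`` of
    ``center`` that pass the one-sided threshold; an empty selection gives 0.
    """
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    if len(maps) == 0:
        raise ValueError("need at least one map")
    if len(maps) != len(delays):
        raise ValueError("maps and delays must align")
    center = np.asarray(center, dtype=float)
    values = []
    for density_map in maps:
        mask = _voxel_mask_near(density_map, center[None, :], radius)
        sig = density_map.sigma
        if sig == 0:
            values.append(0.0)
            continue
        vals = density_map.values[mask] / sig
        passing = vals > sigma_threshold if sign == "positive" else vals < -sigma_threshold
        values.append(float(np.mean(vals[passing])) if passing.any() else 0.0)
    return KineticsSeries(name=name, delays=np.asarray(delays, dtype=float), values=np.asarray(values))


def normalize_series(series: KineticsSeries) -> KineticsSeries:
    """Divide a series (and its noise floor) by the series maximum."""
    peak = float(np.max(series.values))
    if peak <= 0 or np.max(np.abs(series.values)) == 0:
        raise ValueError("cannot normalize an all-zero (or non-positive) series")
    return KineticsSeries(
        name=series.name,
        delays=series.delays.copy(),
        values=series.values / peak,
        noise_floor=None if series.noise_floor is None else series.noise_floor / peak,
        normalized=True,
    )


def real_space_cc(
    map1: RealSpaceMap, map2: RealSpaceMap, mask: np.ndarray | None = None
) -> float:
    """Voxel-wise Pearson correlation coefficient between two maps."""
    if map1.shape != map2.shape:
        raise ValueError(f"grid mismatch: {map1.shape} vs {map2.shape}")
    a = map1.values.ravel()
    b = map2.values.ravel()
    if mask is not None:
        flat = np.asarray(mask, dtype=bool).ravel()
        a, b = a[flat], b[flat]
    a = a - a.mean()
    b = b - b.mean()
    va, vb = float(a @ a), float(b @ b)
    if va == 0 or vb == 0:
        raise ValueError("cannot correlate a zero-variance map")
    return float((a @ b) / np.sqrt(va * vb))
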