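"""Core crystallographic containers.

The package works in space group P1 throughout: reflection sets store one
member of each Friedel pair, maps cover the full unit cell, and models carry
orthogonal coordinates in Angstrom.  Phases are stored in degrees, following
the usual reflection-file conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "UnitCell",
    "ReflectionSet",
    "DifferenceSet",
    "RealSpaceMap",
    "AtomicModel",
    "d_spacing",
    "map_stats",
    "atom_distance",
    "mean_ca_distance",
]


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell; lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell edges must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if self.volume <= 0:
            raise ValueError("cell volume must be positive")

    @property
    def gemmi_cell(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def volume(self) -> float:
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        return float(self.a * self.b * self.c * np.sqrt(max(arg, 0.0)))

    @property
    def orth_matrix(self) -> np.ndarray:
        """Fractional -> orthogonal matrix (a along x convention)."""
        return np.array(self.gemmi_cell.orth.mat.tolist())

    @property
    def frac_matrix(self) -> np.ndarray:
        """Orthogonal -> fractional matrix."""
        return np.array(self.gemmi_cell.frac.mat.tolist())

    def d(self, hkl: Sequence[int]) -> float:
        return d_spacing(self, hkl)

    def d_array(self, hkl: np.ndarray) -> np.ndarray:
        """d-spacings for an (N, 3) integer array of Miller indices."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        # reciprocal metric tensor: G* = (M^-T M^-1) with M the orth matrix
        frac = self.frac_matrix
        gstar = frac @ frac.T
        q2 = np.einsum("ni,ij,nj->n", hkl, gstar, hkl)
        with np.errstate(divide="ignore"):
            return 1.0 / np.sqrt(q2)


def d_spacing(cell: UnitCell, hkl: Sequence[int]) -> float:
    """Resolution of a reflection in Angstrom.

    The (0,0,0) term is the mean-density (F000) term and has no spacing.
    """
    h, k, l = (int(v) for v in hkl)
    if h == 0 and k == 0 and l == 0:
        raise ValueError("(0,0,0) is the mean-density term and has no d-spacing")
    return float(cell.gemmi_cell.calculate_d([h, k, l]))


def _as_hkl_array(hkl: Iterable) -> np.ndarray:
    arr = np.asarray(list(hkl) if not isinstance(hkl, np.ndarray) else hkl)
    arr = np.atleast_2d(arr).astype(np.int64)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("Miller indices must form an (N, 3) integer array")
    return arr


def _check_unique(hkl: np.ndarray, context: str) -> None:
    uniq = np.unique(hkl, axis=0)
    if len(uniq) != len(hkl):
        raise ValueError(f"duplicate Miller indices in {context}")


@dataclass
class ReflectionSet:
    """Amplitudes, sigmas and optional phases on a set of Miller indices.

    Houses observed amplitudes (light or dark), calculated structure factors
    Fc, and extrapolated coefficients Fe.  Amplitudes are non-negative unless
    a phase is present (a signed coefficient on a fixed phase is equivalent
    to a phase flip and is permitted for map coefficients).
    """

    cell: UnitCell
    hkl: np.ndarray
    amplitude: np.ndarray
    sigma: np.ndarray | None = None
    phase: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.hkl = _as_hkl_array(self.hkl)
        n = len(self.hkl)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.amplitude.shape != (n,):
            raise ValueError("amplitude array does not match index count")
        if self.sigma is None:
            self.sigma = np.zeros(n)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.shape != (n,):
            raise ValueError("sigma array does not match index count")
        if np.any(self.sigma < 0):
            raise ValueError("negative sigma")
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=float)
            if self.phase.shape != (n,):
                raise ValueError("phase array does not match index count")
        elif np.any(self.amplitude < 0):
            raise ValueError("negative amplitude without phase")
        _check_unique(self.hkl, f"ReflectionSet {self.label!r}")

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def has_phases(self) -> bool:
        return self.phase is not None

    def d_spacings(self) -> np.ndarray:
        return self.cell.d_array(self.hkl)

    def index_map(self) -> dict[tuple[int, int, int], int]:
        return {tuple(h): i for i, h in enumerate(map(tuple, self.hkl.tolist()))}

    def complex_coefficients(self) -> np.ndarray:
        if self.phase is None:
            raise ValueError("reflection set has no phases")
        return self.amplitude * np.exp(1j * np.radians(self.phase))

    def select(self, mask: np.ndarray, label: str | None = None) -> "ReflectionSet":
        return ReflectionSet(
            cell=self.cell,
            hkl=self.hkl[mask],
            amplitude=self.amplitude[mask],
            sigma=self.sigma[mask],
            phase=None if self.phase is None else self.phase[mask],
            label=self.label if label is None else label,
        )

    def common_indices(self, other: "ReflectionSet | DifferenceSet") -> tuple[np.ndarray, np.ndarray]:
        """Positional indices into self and other for shared Miller indices."""
        omap = other.index_map()
        mine, theirs = [], []
        for i, h in enumerate(map(tuple, self.hkl.tolist())):
            j = omap.get(h)
            if j is not None:
                mine.append(i)
                theirs.append(j)
        return np.asarray(mine, dtype=int), np.asarray(theirs, dtype=int)


@dataclass
class DifferenceSet:
    """Weighted difference amplitudes DeltaFo with dark-model phases.

    ``delta`` is the signed, weighted light-minus-dark amplitude difference;
    ``sigma`` its propagated uncertainty; ``weight`` the per-reflection
    weighting factor; ``phase`` (degrees) is copied from the dark model, so a
    negative delta acts as a 180-degree phase flip during synthesis.
    """

    cell: UnitCell
    hkl: np.ndarray
    delta: np.ndarray
    sigma: np.ndarray
    weight: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        self.hkl = _as_hkl_array(self.hkl)
        n = len(self.hkl)
        for name in ("delta", "sigma", "weight", "phase"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} array does not match index count")
            setattr(self, name, arr)
        if np.any(self.weight <= 0) or np.any(self.weight > 1):
            raise ValueError("weights must lie in (0, 1]")
        if np.any(self.sigma < 0):
            raise ValueError("negative sigma")
        _check_unique(self.hkl, "DifferenceSet")

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def has_phases(self) -> bool:
        return True

    def d_spacings(self) -> np.ndarray:
        return self.cell.d_array(self.hkl)

    def index_map(self) -> dict[tuple[int, int, int], int]:
        return {tuple(h): i for i, h in enumerate(map(tuple, self.hkl.tolist()))}

    def complex_coefficients(self) -> np.ndarray:
        return self.delta * np.exp(1j * np.radians(self.phase))

    def select(self, mask: np.ndarray) -> "DifferenceSet":
        return DifferenceSet(
            cell=self.cell,
            hkl=self.hkl[mask],
            delta=self.delta[mask],
            sigma=self.sigma[mask],
            weight=self.weight[mask],
            phase=self.phase[mask],
        )


@dataclass
class RealSpaceMap:
    """Periodic density grid over the full unit cell.

    Voxel (i, j, k) is centred at fractional coordinate (i/nx, j/ny, k/nz);
    indexing wraps periodically.  ``sigma`` is the root-mean-square deviation
    about the mean, the quantity that density thresholds quoted in "map
    sigma" units refer to.
    """

    cell: UnitCell
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("map values must be a 3-D array")
        if min(self.values.shape) < 4:
            raise ValueError("map grid must be at least 4 voxels along each axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.size)

    @property
    def voxel_volume(self) -> float:
        return self.cell.volume / self.n_voxels

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sigma(self) -> float:
        return float(np.sqrt(np.mean((self.values - self.mean) ** 2)))

    def voxel_fractional_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nx, ny, nz = self.shape
        fx = np.arange(nx) / nx
        fy = np.arange(ny) / ny
        fz = np.arange(nz) / nz
        return np.meshgrid(fx, fy, fz, indexing="ij")


def map_stats(density_map: RealSpaceMap) -> tuple[float, float]:
    """Mean and RMS-about-mean (the map sigma) over all voxels."""
    return density_map.mean, density_map.sigma


_MODEL_COLUMNS = ["element", "name", "resname", "resnum", "chain", "x", "y", "z", "occ", "b"]


@dataclass
class AtomicModel:
    """Atoms in a unit cell, stored as a pandas DataFrame.

    Columns: element, name, resname, resnum, chain, x, y, z (orthogonal
    Angstrom), occ (occupancy in [0,1]) and b (isotropic B in Angstrom^2).
    """

    cell: UnitCell
    atoms: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in _MODEL_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"atom table missing columns: {missing}")
        self.atoms = self.atoms.reset_index(drop=True)
        occ = self.atoms["occ"].to_numpy(dtype=float)
        if np.any((occ < 0) | (occ > 1)):
            raise ValueError("occupancies must lie in [0, 1]")
        if np.any(self.atoms["b"].to_numpy(dtype=float) < 0):
            raise ValueError("B-factors must be non-negative")
        trip = self.atoms[["chain", "resnum", "name"]]
        if trip.duplicated().any():
            dup = trip[trip.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate atom identifier {tuple(dup)}")

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(dtype=float)

    def fractional_coords(self) -> np.ndarray:
        return self.coords() @ self.cell.frac_matrix.T

    def copy(self) -> "AtomicModel":
        return AtomicModel(self.cell, self.atoms.copy(), self.label)

    def residue_ids(self) -> list[tuple[str, int]]:
        """Unique (chain, resnum) pairs in file order."""
        seen: dict[tuple[str, int], None] = {}
        for chain, resnum in zip(self.atoms["chain"], self.atoms["resnum"]):
            seen.setdefault((str(chain), int(resnum)), None)
        return list(seen)

    def select_atom(self, selector: tuple[str, int, str]) -> int:
        """Row index of the single atom matching (chain, resnum, atom name)."""
        chain, resnum, name = selector
        mask = (
            (self.atoms["chain"] == chain)
            & (self.atoms["resnum"] == int(resnum))
            & (self.atoms["name"] == name)
        )
        idx = np.flatnonzero(mask.to_numpy())
        if len(idx) != 1:
            cands = self.atoms.loc[
                (self.atoms["chain"] == chain) & (self.atoms["resnum"] == int(resnum)),
                ["chain", "resnum", "name"],
            ]
            raise ValueError(
                f"selector {selector} matched {len(idx)} atoms; "
                f"candidates in that residue: {cands.to_dict('records')}"
            )
        return int(idx[0])

    def select_residue_atoms(self, residues: Sequence) -> np.ndarray:
        """Row indices for residues given as (chain, resnum) pairs or residue names."""
        mask = np.zeros(len(self.atoms), dtype=bool)
        for res in residues:
            if isinstance(res, str):
                sub = (self.atoms["resname"] == res).to_numpy()
            else:
                chain, resnum = res
                sub = (
                    (self.atoms["chain"] == chain) & (self.atoms["resnum"] == int(resnum))
                ).to_numpy()
            mask |= sub
        return np.flatnonzero(mask)


def atom_distance(
    model: AtomicModel,
    selector_a: tuple[str, int, str],
    selector_b: tuple[str, int, str],
) -> float:
    """Euclidean distance in Angstrom between two uniquely selected atoms."""
    ia = model.select_atom(selector_a)
    ib = model.select_atom(selector_b)
    xyz = model.coords()
    return float(np.linalg.norm(xyz[ia] - xyz[ib]))


def mean_ca_distance(
    model: AtomicModel,
    residues: Sequence[tuple[str, int]],
    target: tuple[str, int, str],
) -> float:
    """Mean of per-residue CA -> target-atom distances in Angstrom."""
    it = model.select_atom(target)
    xyz = model.coords()
    dists = []
    for chain, resnum in residues:
        try:
            ica = model.select_atom((chain, int(resnum), "CA"))
        except ValueError as exc:
            raise ValueError(f"residue {chain}{resnum} lacks a unique CA atom") from exc
        dists.append(np.linalg.norm(xyz[ica] - xyz[it]))
    return float(np.mean(dists))
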