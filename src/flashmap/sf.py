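"""Structure factors and Fourier map synthesis in P1.

Structure factors follow F(h) = sum_j occ_j f_j(s) exp(-B_j s^2 / 4)
exp(+2 pi i h.x_j) with s = 1/d, using the International Tables 4-Gaussian
form factors shipped with gemmi.  Synthesis uses the conjugate convention
rho(x) = (1/V) sum_h F(h) exp(-2 pi i h.x) with Friedel completion so maps
are real.  F(000) is excluded unless explicitly supplied, so synthesized
difference maps are mean-zero.
"""

from __future__ import annotations

from typing import Sequence

import gemmi
import numpy as np

from .core import AtomicModel, DifferenceSet, RealSpaceMap, ReflectionSet, UnitCell

__all__ = [
    "form_factor",
    "unique_hkl",
    "compute_fc",
    "synthesize_map",
    "default_grid",
]

# elements with form factors the synthesis guarantees (others resolve through
# gemmi's table and fail loudly if absent)
_GUARANTEED = {"H", "C", "N", "O", "P", "S"}


def form_factor(element: str, s: np.ndarray | float) -> np.ndarray:
    """X-ray scattering factor f(s), s = 1/d in 1/Angstrom, at rest (B = 0)."""
    el = gemmi.Element(element)
    if el.name == "X" or el.atomic_number == 0:
        raise ValueError(f"unknown element {element!r}")
    coeffs = el.it92
    if coeffs is None:
        raise ValueError(f"no tabulated form factor for element {element!r}")
    s = np.asarray(s, dtype=float)
    stol2 = (s / 2.0) ** 2  # (sin theta / lambda)^2
    a = np.asarray(coeffs.a)
    b = np.asarray(coeffs.b)
    return np.einsum("i,...i->...", a, np.exp(-np.multiply.outer(stol2, b))) + coeffs.c


def unique_hkl(cell: UnitCell, d_min: float, d_max: float) -> np.ndarray:
    """One member of each Friedel pair with d_min <= d <= d_max.

    The retained hemisphere is h > 0, or h = 0 and k > 0, or h = k = 0 and
    l > 0; (0,0,0) is never included.
    """
    if d_min >= d_max:
        raise ValueError("d_min must be smaller than d_max")
    gc = cell.gemmi_cell
    hmax = int(np.floor(gc.a / d_min)) + 1
    kmax = int(np.floor(gc.b / d_min)) + 1
    lmax = int(np.floor(gc.c / d_min)) + 1
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    hemi = (
        (hkl[:, 0] > 0)
        | ((hkl[:, 0] == 0) & (hkl[:, 1] > 0))
        | ((hkl[:, 0] == 0) & (hkl[:, 1] == 0) & (hkl[:, 2] > 0))
    )
    hkl = hkl[hemi]
    d = cell.d_array(hkl)
    keep = (d >= d_min) & (d <= d_max)
    hkl = hkl[keep]
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    return hkl[order]


def compute_fc(
    model: AtomicModel,
    d_min: float,
    d_max: float,
    hkl: np.ndarray | None = None,
    label: str = "Fc",
) -> ReflectionSet:
    """Calculated structure factors for all unique reflections in a d range.

    Returns amplitudes and phases (degrees).  Hydrogens contribute only if
    present in the model.  Anisotropic displacement and bulk solvent are not
    modelled.
    """
    if hkl is None:
        hkl = unique_hkl(model.cell, d_min, d_max)
    else:
        hkl = np.asarray(hkl, dtype=np.int64)
    if len(hkl) == 0:
        raise ValueError("no reflections in the requested resolution range")
    f_complex = structure_factors(model, hkl)
    amp = np.abs(f_complex)
    phase = np.degrees(np.angle(f_complex))
    return ReflectionSet(
        cell=model.cell, hkl=hkl, amplitude=amp, sigma=np.zeros(len(hkl)),
        phase=phase, label=label,
    )


def structure_factors(model: AtomicModel, hkl: np.ndarray) -> np.ndarray:
    """Complex structure factors at the given Miller indices."""
    hkl = np.asarray(hkl, dtype=np.int64)
    s = 1.0 / model.cell.d_array(hkl)
    frac = model.fractional_coords()
    occ = model.atoms["occ"].to_numpy(dtype=float)
    biso = model.atoms["b"].to_numpy(dtype=float)
    elements = model.atoms["element"].to_numpy()
    f = np.zeros(len(hkl), dtype=complex)
    s2_over_4 = (s * s) / 4.0
    for element in np.unique(elements):
        sel = elements == element
        f0 = form_factor(str(element), s)  # (n_hkl,)
        # per-atom Debye-Waller and phase terms for this element
        dw = np.exp(-np.outer(s2_over_4, biso[sel]))  # (n_hkl, n_atoms)
        phase = np.exp(2j * np.pi * (hkl.astype(float) @ frac[sel].T))
        f += f0 * np.einsum("ha,ha->h", dw * occ[sel], phase)
    return f


def default_grid(cell: UnitCell, d_min: float, oversample: float = 3.0) -> tuple[int, int, int]:
    """Even grid dimensions giving a voxel pitch of about d_min/oversample."""
    dims = []
    for edge in (cell.a, cell.b, cell.c):
        n = int(np.ceil(edge * oversample / d_min))
        if n % 2:
            n += 1
        dims.append(max(n, 4))
    return tuple(dims)


def synthesize_map(
    refl: ReflectionSet | DifferenceSet,
    grid: Sequence[int] | None = None,
    d_min_hint: float | None = None,
) -> RealSpaceMap:
    """Fourier synthesis of a phased reflection set onto a unit-cell grid.

    Friedel mates are generated internally (F(-h) = conj F(h)) so the result
    is real.  The map mean equals F(000)/V, i.e. zero whenever the (0,0,0)
    term is absent from the input.
    """
    if not refl.has_phases:
        raise ValueError("cannot synthesize a map: reflection set has no phases")
    hkl = refl.hkl
    coeffs = refl.complex_coefficients()
    cell = refl.cell
    if grid is None:
        if d_min_hint is None:
            d = cell.d_array(hkl)
            d_min_hint = float(d.min())
        grid = default_grid(cell, d_min_hint)
    nx, ny, nz = (int(n) for n in grid)
    max_h = np.abs(hkl).max(axis=0) if len(hkl) else np.zeros(3, dtype=int)
    required = tuple(int(2 * m + 2) for m in max_h)
    if max_h[0] * 2 >= nx or max_h[1] * 2 >= ny or max_h[2] * 2 >= nz:
        raise ValueError(
            f"grid {grid} too coarse for the index range; need at least {required}"
        )
    f_grid = np.zeros((nx, ny, nz), dtype=complex)
    idx = np.mod(hkl, [nx, ny, nz])
    neg = np.mod(-hkl, [nx, ny, nz])
    zero = np.all(hkl == 0, axis=1)
    np.add.at(f_grid, (idx[:, 0], idx[:, 1], idx[:, 2]), coeffs)
    np.add.at(
        f_grid,
        (neg[~zero, 0], neg[~zero, 1], neg[~zero, 2]),
        np.conj(coeffs[~zero]),
    )
    # fftn over a grid holding F(h) at index h mod N evaluates
    # sum_h F(h) exp(-2 pi i h.n/N) at voxel n, which is V * rho(n/N)
    density = np.fft.fftn(f_grid)
    rho = np.real(density) / cell.volume
    return RealSpaceMap(cell=cell, values=rho)
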