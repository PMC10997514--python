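"""File I/O: coordinate models (PDB/mmCIF), reflections (MTZ/text), maps (CCP4).

All formats are handled through gemmi; this module only converts between
gemmi's objects and the package's containers.

The plain-text reflection dialect is whitespace-separated columns
``h k l F sigF [phase_deg]`` with ``#`` comments, one reflection per line.
"""

from __future__ import annotations

import logging
import os
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd

from .core import AtomicModel, RealSpaceMap, ReflectionSet, UnitCell

__all__ = [
    "read_model",
    "write_model",
    "read_reflections",
    "write_reflections",
    "read_map",
    "write_map",
    "read_ta_matrix",
    "write_ta_matrix",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- models

def _structure_to_model(st: gemmi.Structure, label: str) -> AtomicModel:
    cell = UnitCell(st.cell.a, st.cell.b, st.cell.c, st.cell.alpha, st.cell.beta, st.cell.gamma)
    rows = []
    for chain in st[0]:
        for res in chain:
            for atom in res:
                rows.append(
                    {
                        "element": atom.element.name,
                        "name": atom.name,
                        "resname": res.name,
                        "resnum": res.seqid.num,
                        "chain": chain.name,
                        "x": atom.pos.x,
                        "y": atom.pos.y,
                        "z": atom.pos.z,
                        "occ": atom.occ,
                        "b": atom.b_iso,
                    }
                )
    if not rows:
        raise ValueError(f"{label}: file contains no atoms")
    return AtomicModel(cell=cell, atoms=pd.DataFrame(rows), label=label)


def read_model(path: str | os.PathLike) -> AtomicModel:
    """Read a PDB or mmCIF coordinate file (first model, all chains)."""
    path = os.fspath(path)
    try:
        st = gemmi.read_structure(path)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse coordinate file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: file contains no atoms")
    st.setup_entities()
    return _structure_to_model(st, label=os.path.basename(path))


def model_to_structure(model: AtomicModel, name: str = "flashmap") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    st.cell = model.cell.gemmi_cell
    st.spacegroup_hm = "P 1"
    gmodel = gemmi.Model("1")
    for chain_name, chain_df in model.atoms.groupby("chain", sort=False):
        chain = gemmi.Chain(str(chain_name))
        for (resnum, resname), res_df in chain_df.groupby(["resnum", "resname"], sort=False):
            res = gemmi.Residue()
            res.name = str(resname)
            res.seqid = gemmi.SeqId(int(resnum), " ")
            for _, row in res_df.iterrows():
                atom = gemmi.Atom()
                atom.name = str(row["name"])
                atom.element = gemmi.Element(str(row["element"]))
                atom.pos = gemmi.Position(row["x"], row["y"], row["z"])
                atom.occ = float(row["occ"])
                atom.b_iso = float(row["b"])
                res.add_atom(atom)
            chain.add_residue(res)
        gmodel.add_chain(chain)
    st.add_model(gmodel)
    return st


def write_model(model: AtomicModel, path: str | os.PathLike) -> None:
    """Write a model as PDB (default) or mmCIF depending on extension."""
    if len(model) == 0:
        raise ValueError("refusing to write a model with zero atoms")
    path = os.fspath(path)
    st = model_to_structure(model)
    if path.endswith(".cif") or path.endswith(".mmcif"):
        st.make_mmcif_document().write_file(path)
    else:
        st.write_pdb(path)


# ---------------------------------------------------------------- reflections

def read_reflections(path: str | os.PathLike, dialect: str | None = None) -> ReflectionSet:
    """Read reflections from MTZ or the text dialect.

    ``dialect`` may be "mtz" or "text"; when None it is inferred from the
    extension.
    """
    path = os.fspath(path)
    if dialect is None:
        dialect = "mtz" if path.endswith(".mtz") else "text"
    if dialect == "mtz":
        return _read_mtz(path)
    if dialect == "text":
        return _read_text(path)
    raise ValueError(f"unknown reflection dialect {dialect!r}")


def write_reflections(
    refl: ReflectionSet, path: str | os.PathLike, dialect: str | None = None
) -> None:
    path = os.fspath(path)
    if dialect is None:
        dialect = "mtz" if path.endswith(".mtz") else "text"
    if dialect == "mtz":
        _write_mtz(refl, path)
    elif dialect == "text":
        _write_text(refl, path)
    else:
        raise ValueError(f"unknown reflection dialect {dialect!r}")


def _read_mtz(path: str) -> ReflectionSet:
    try:
        mtz = gemmi.read_mtz_file(path)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse MTZ file {path}: {exc}") from exc
    cols = {c.label: i for i, c in enumerate(mtz.columns)}
    for required in ("H", "K", "L", "F", "SIGF"):
        if required not in cols:
            raise ValueError(f"MTZ {path} lacks required column {required}")
    data = np.asarray(mtz.array)
    hkl = data[:, [cols["H"], cols["K"], cols["L"]]].astype(np.int64)
    amplitude = data[:, cols["F"]].astype(float)
    sigma = data[:, cols["SIGF"]].astype(float)
    phase = data[:, cols["PHI"]].astype(float) if "PHI" in cols else None
    if np.any(sigma < 0):
        raise ValueError(f"MTZ {path} contains negative sigma values")
    cell = UnitCell(mtz.cell.a, mtz.cell.b, mtz.cell.c, mtz.cell.alpha, mtz.cell.beta, mtz.cell.gamma)
    if len(np.unique(hkl, axis=0)) != len(hkl):
        raise ValueError(f"MTZ {path} contains duplicate Miller indices")
    return ReflectionSet(
        cell=cell, hkl=hkl, amplitude=amplitude, sigma=sigma, phase=phase,
        label=os.path.basename(path),
    )


def _write_mtz(refl: ReflectionSet, path: str) -> None:
    mtz = gemmi.Mtz(with_base=True)
    mtz.spacegroup = gemmi.SpaceGroup("P 1")
    mtz.set_cell_for_all(refl.cell.gemmi_cell)
    mtz.add_dataset("flashmap")
    mtz.add_column("F", "F")
    mtz.add_column("SIGF", "Q")
    columns = [refl.hkl.astype(float), refl.amplitude[:, None], refl.sigma[:, None]]
    if refl.phase is not None:
        mtz.add_column("PHI", "P")
        columns.append(refl.phase[:, None])
    mtz.set_data(np.hstack(columns))
    mtz.write_to_file(path)


def _read_text(path: str) -> ReflectionSet:
    header = None
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if header is None:
                if parts[0].lower() == "cell":
                    if len(parts) != 7:
                        raise ValueError(f"{path}:{lineno}: cell line needs 6 numbers")
                    header = [float(v) for v in parts[1:]]
                    continue
                raise ValueError(f"{path}:{lineno}: expected a 'cell a b c al be ga' header line")
            if len(parts) not in (5, 6):
                raise ValueError(
                    f"{path}:{lineno}: expected 'h k l F sigF [phase_deg]', got {len(parts)} fields"
                )
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable number: {exc}") from exc
    if header is None or not rows:
        raise ValueError(f"{path}: no reflection records found")
    has_phase = len(rows[0]) == 6
    if any((len(r) == 6) != has_phase for r in rows):
        raise ValueError(f"{path}: mixed phased and unphased records")
    arr = np.asarray(rows, dtype=float)
    hkl = arr[:, :3].astype(np.int64)
    if len(np.unique(hkl, axis=0)) != len(hkl):
        raise ValueError(f"{path}: duplicate Miller indices")
    if np.any(arr[:, 4] < 0):
        raise ValueError(f"{path}: negative sigma values")
    return ReflectionSet(
        cell=UnitCell(*header),
        hkl=hkl,
        amplitude=arr[:, 3],
        sigma=arr[:, 4],
        phase=arr[:, 5] if has_phase else None,
        label=os.path.basename(path),
    )


def _write_text(refl: ReflectionSet, path: str) -> None:
    c = refl.cell
    with open(path, "w") as fh:
        fh.write("# flashmap reflection file: h k l F sigF" + (" phase_deg" if refl.phase is not None else "") + "\n")
        fh.write(f"cell {c.a:.6g} {c.b:.6g} {c.c:.6g} {c.alpha:.6g} {c.beta:.6g} {c.gamma:.6g}\n")
        for i in range(len(refl)):
            h, k, l = refl.hkl[i]
            line = f"{h:d} {k:d} {l:d} {refl.amplitude[i]:.8g} {refl.sigma[i]:.8g}"
            if refl.phase is not None:
                line += f" {refl.phase[i]:.6f}"
            fh.write(line + "\n")


# ---------------------------------------------------------------- maps

def write_map(density_map: RealSpaceMap, path: str | os.PathLike) -> None:
    """Write a CCP4/MRC map (mode 2, full unit cell)."""
    grid = gemmi.FloatGrid(*density_map.shape)
    grid.set_unit_cell(density_map.cell.gemmi_cell)
    grid.spacegroup = gemmi.SpaceGroup("P 1")
    np.asarray(grid.array)[...] = density_map.values.astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header(2, True)
    ccp4.write_ccp4_map(os.fspath(path))


def read_map(path: str | os.PathLike) -> RealSpaceMap:
    path = os.fspath(path)
    try:
        ccp4 = gemmi.read_ccp4_map(path)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse CCP4 map {path}: {exc}") from exc
    ccp4.setup(float("nan"))
    grid = ccp4.grid
    values = np.array(grid.array, dtype=float)
    if np.any(~np.isfinite(values)):
        raise ValueError(f"map {path} does not cover the full unit cell")
    gc = grid.unit_cell
    cell = UnitCell(gc.a, gc.b, gc.c, gc.alpha, gc.beta, gc.gamma)
    return RealSpaceMap(cell=cell, values=values)


# ---------------------------------------------------------------- TA matrices

def read_ta_matrix(path: str | os.PathLike):
    """Read a delay x wavelength matrix: first row wavelengths (nm), first
    column delays (ps), body dA in mOD.  Returns (delays, wavelengths, dA)."""
    arr = np.loadtxt(os.fspath(path), delimiter=",")
    wavelengths = arr[0, 1:]
    delays = arr[1:, 0]
    da = arr[1:, 1:]
    return delays, wavelengths, da


def write_ta_matrix(path: str | os.PathLike, delays, wavelengths, da) -> None:
    delays = np.asarray(delays, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    da = np.asarray(da, dtype=float)
    top = np.concatenate([[np.nan], wavelengths])
    body = np.column_stack([delays, da])
    out = np.vstack([top, body])
    np.savetxt(os.fspath(path), out, delimiter=",", fmt="%.8g")
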