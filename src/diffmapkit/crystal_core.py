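"""Unit cells, space-group symmetry, atomic models and reflection data.

This module defines the two in-memory containers everything else operates
on -- :class:`Structure` (a flat atomic model) and :class:`ReflectionSet`
(a table of Miller indices with amplitudes and optional sigmas/phases) --
together with coordinate conversions, Miller-index geometry, symmetry
expansion of reflections to P1, and readers/writers for the standard
crystallographic file formats (PDB/mmCIF models, MTZ and structure-factor
CIF reflection files).  Cells and space groups are represented by
``gemmi.UnitCell`` and ``gemmi.SpaceGroup`` throughout.

Conventions
-----------
* Orthogonalization follows the PDB convention: *a* along *x*, *b* in the
  *x*-*y* plane (gemmi's default orthogonalization matrix).
* Atomic coordinates are stored fractionally; helpers convert on demand.
* Reflections are reduced to the gemmi reciprocal-space asymmetric unit at
  read time; duplicates after reduction are averaged with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Structure",
    "ReflectionSet",
    "spacegroup",
    "orth_matrix",
    "frac_to_orth",
    "orth_to_frac",
    "resolution_of",
    "reciprocal_metric",
    "read_model",
    "write_model",
    "read_reflections",
    "write_reflections",
    "expand_to_p1",
    "map_to_asu",
]


def spacegroup(symbol: str | gemmi.SpaceGroup) -> gemmi.SpaceGroup:
    """Look up a space group by Hermann-Mauguin (or short) symbol.

    Unsupported/unknown symbols raise ``ValueError`` rather than being
    silently treated as P1.
    """
    if isinstance(symbol, gemmi.SpaceGroup):
        return symbol
    sg = gemmi.find_spacegroup_by_name(symbol)
    if sg is None:
        raise ValueError(f"unknown space-group symbol: {symbol!r}")
    return sg


def _check_cell(cell: gemmi.UnitCell) -> None:
    if min(cell.a, cell.b, cell.c) <= 0 or \
            cell.volume <= 1e-6 * cell.a * cell.b * cell.c:
        raise ValueError(f"degenerate unit cell (vanishing volume): {cell}")
    for ang in (cell.alpha, cell.beta, cell.gamma):
        if not 0.0 < ang < 180.0:
            raise ValueError(f"unit-cell angle outside (0, 180): {ang}")


def orth_matrix(cell: gemmi.UnitCell) -> np.ndarray:
    """3x3 fractional->orthogonal matrix (PDB a-along-x convention)."""
    _check_cell(cell)
    return np.array(cell.orth.mat.tolist(), dtype=float)


def frac_to_orth(cell: gemmi.UnitCell, frac) -> np.ndarray:
    """Convert fractional coordinates to orthogonal angstroms."""
    a = orth_matrix(cell)
    return np.asarray(frac, dtype=float) @ a.T


def orth_to_frac(cell: gemmi.UnitCell, orth) -> np.ndarray:
    """Exact inverse of :func:`frac_to_orth`."""
    b = np.linalg.inv(orth_matrix(cell))
    return np.asarray(orth, dtype=float) @ b.T


def reciprocal_metric(cell: gemmi.UnitCell) -> np.ndarray:
    """Reciprocal metric tensor G* such that 1/d^2 = h . G* . h."""
    ainv = np.linalg.inv(orth_matrix(cell))
    return ainv @ ainv.T


def resolution_of(cell: gemmi.UnitCell, hkl) -> np.ndarray | float:
    """Resolution d = 1/|s| in angstroms of one index or an (n, 3) array."""
    h = np.asarray(hkl, dtype=float)
    single = h.ndim == 1
    h = np.atleast_2d(h)
    if np.any(np.all(h == 0, axis=1)):
        raise ValueError("(0,0,0) has no resolution")
    gstar = reciprocal_metric(cell)
    inv_d2 = np.einsum("ij,jk,ik->i", h, gstar, h)
    d = 1.0 / np.sqrt(inv_d2)
    return float(d[0]) if single else d


# ---------------------------------------------------------------------------
# Atomic model


@dataclass
class Structure:
    """Flat atomic model tied to a unit cell and space group.

    Coordinates are fractional; B-factors are isotropic (A^2); residue
    numbering is 1-based as in the input file.
    """

    elements: list[str]
    xyz_frac: np.ndarray  # (n, 3)
    b_iso: np.ndarray
    occ: np.ndarray
    chain_ids: list[str]
    res_seq: np.ndarray
    cell: gemmi.UnitCell
    sg: gemmi.SpaceGroup

    def __post_init__(self):
        self.xyz_frac = np.atleast_2d(np.asarray(self.xyz_frac, dtype=float))
        self.b_iso = np.asarray(self.b_iso, dtype=float)
        self.occ = np.asarray(self.occ, dtype=float)
        self.res_seq = np.asarray(self.res_seq, dtype=int)
        if len(self.elements) == 0:
            raise ValueError("empty structure")
        _check_cell(self.cell)
        if np.any(self.b_iso < 0):
            raise ValueError("negative B-factor")
        if np.any((self.occ < 0) | (self.occ > 1)):
            raise ValueError("occupancy outside [0, 1]")

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def xyz_orth(self) -> np.ndarray:
        return frac_to_orth(self.cell, self.xyz_frac)

    def with_cell(self, cell: gemmi.UnitCell, sg: gemmi.SpaceGroup | None = None) -> "Structure":
        """Replace cell metadata keeping *orthogonal* coordinates fixed.

        This preserves the molecule's true geometry when the lattice
        changes, which is the physical assumption behind rigid-body
        phasing of non-isomorphous data.
        """
        orth = self.xyz_orth
        new = replace(self, cell=cell, sg=sg if sg is not None else self.sg)
        new.xyz_frac = orth_to_frac(cell, orth)
        return new

    def with_orth_coords(self, orth: np.ndarray) -> "Structure":
        new = replace(self)
        new.xyz_frac = orth_to_frac(self.cell, np.asarray(orth, dtype=float))
        return new

    def select(self, mask) -> "Structure":
        """Subset by boolean mask or integer index array."""
        arr = np.asarray(mask)
        idx = np.where(arr)[0] if arr.dtype == bool else arr.astype(int)
        if len(idx) == 0:
            raise ValueError("selection is empty")
        return Structure(
            elements=[self.elements[i] for i in idx],
            xyz_frac=self.xyz_frac[idx],
            b_iso=self.b_iso[idx],
            occ=self.occ[idx],
            chain_ids=[self.chain_ids[i] for i in idx],
            res_seq=self.res_seq[idx],
            cell=self.cell,
            sg=self.sg,
        )

    def chain_mask(self, chain_id: str) -> np.ndarray:
        return np.array([c == chain_id for c in self.chain_ids])


def _to_gemmi(model: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.cell = model.cell
    st.spacegroup_hm = model.sg.hm
    mdl = gemmi.Model("1")
    orth = model.xyz_orth
    for chain_id in dict.fromkeys(model.chain_ids):
        chain = gemmi.Chain(chain_id)
        for i in range(len(model)):
            if model.chain_ids[i] != chain_id:
                continue
            res = gemmi.Residue()
            res.name = "UNK"
            res.seqid = gemmi.SeqId(int(model.res_seq[i]), " ")
            atom = gemmi.Atom()
            atom.name = f"{model.elements[i]}{i + 1}"
            atom.element = gemmi.Element(model.elements[i])
            atom.pos = gemmi.Position(*orth[i])
            atom.occ = float(model.occ[i])
            atom.b_iso = float(model.b_iso[i])
            res.add_atom(atom)
            chain.add_residue(res)
        mdl.add_chain(chain)
    st.add_model(mdl)
    st.setup_entities()
    return st


def write_model(model: Structure, path: str | Path) -> None:
    """Write a model as PDB or mmCIF (by file extension)."""
    st = _to_gemmi(model)
    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


def read_model(path: str | Path) -> Structure:
    """Read a PDB or mmCIF model.

    The cell record (CRYST1 / _cell) is required: every downstream step
    needs it.
    """
    st = gemmi.read_structure(str(path))
    cell = st.cell
    if cell.volume <= 0 or (cell.a == 1 and cell.b == 1 and cell.c == 1):
        raise ValueError(
            f"{path}: missing or degenerate cell record (CRYST1/_cell); "
            "a unit cell is required"
        )
    sg = spacegroup(st.spacegroup_hm or "P 1")
    elements, frac, b, occ, chains, seq = [], [], [], [], [], []
    for mdl in st:
        for chain in mdl:
            for res in chain:
                for atom in res:
                    elements.append(atom.element.name)
                    frac.append(list(cell.fractionalize(atom.pos)))
                    b.append(atom.b_iso)
                    occ.append(atom.occ)
                    chains.append(chain.name)
                    seq.append(res.seqid.num)
        break
    return Structure(elements, np.array(frac), np.array(b), np.array(occ),
                     chains, np.array(seq), cell, sg)


# ---------------------------------------------------------------------------
# Reflection data


@dataclass
class ReflectionSet:
    """Merged reflection table with cell/symmetry metadata.

    ``df`` has integer columns H, K, L plus F (amplitude, >= 0) and
    optionally SIGF (> 0) and PHI (degrees, in (-180, 180]).  Indices are
    unique and reduced to the reciprocal-space asymmetric unit; (0,0,0) is
    excluded.
    """

    df: pd.DataFrame
    cell: gemmi.UnitCell
    sg: gemmi.SpaceGroup

    def __post_init__(self):
        _check_cell(self.cell)
        for col in ("H", "K", "L", "F"):
            if col not in self.df.columns:
                raise ValueError(f"reflection table lacks column {col!r}")
        if np.any(self.df["F"].to_numpy() < 0):
            raise ValueError("negative amplitude")
        hkl = self.hkl
        if np.any(np.all(hkl == 0, axis=1)):
            raise ValueError("(0,0,0) present in reflection table")
        if "SIGF" in self.df and np.any(self.df["SIGF"].to_numpy() <= 0):
            raise ValueError("non-positive sigma(F)")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def hkl(self) -> np.ndarray:
        return self.df[["H", "K", "L"]].to_numpy(dtype=int)

    @property
    def d(self) -> np.ndarray:
        return np.asarray(resolution_of(self.cell, self.hkl))

    @property
    def d_min(self) -> float:
        return float(self.d.min())

    @property
    def d_max(self) -> float:
        return float(self.d.max())

    def copy(self) -> "ReflectionSet":
        return ReflectionSet(self.df.copy(), self.cell, self.sg)

    def common_with(self, other: "ReflectionSet") -> pd.DataFrame:
        """Inner join on (H,K,L); columns suffixed _1 / _2."""
        return self.df.merge(other.df, on=["H", "K", "L"], suffixes=("_1", "_2"))


def map_to_asu(refl: ReflectionSet) -> ReflectionSet:
    """Reduce indices to the gemmi reciprocal ASU, transforming phases.

    For an operator with rotation R and translation t the phase moves as
    phi(hR) = phi(h) - 360 h.t; a Friedel flip conjugates.  Duplicate
    indices after reduction are averaged with a warning.
    """
    ops = list(refl.sg.operations())
    asu = gemmi.ReciprocalAsu(refl.sg)
    hkl = refl.hkl
    has_phi = "PHI" in refl.df
    new_hkl = np.empty_like(hkl)
    new_phi = refl.df["PHI"].to_numpy(dtype=float).copy() if has_phi else None
    for i, h in enumerate(hkl):
        h_asu, isym = asu.to_asu([int(h[0]), int(h[1]), int(h[2])], refl.sg.operations())
        new_hkl[i] = h_asu
        if has_phi:
            iop = (isym - 1) // 2
            op = ops[iop]
            shift = -360.0 * (h @ np.array(op.tran)) / gemmi.Op.DEN
            phi = new_phi[i] + shift
            if isym % 2 == 0:  # Friedel mate
                phi = -phi
            new_phi[i] = phi
    df = refl.df.copy()
    df[["H", "K", "L"]] = new_hkl
    if has_phi:
        df["PHI"] = (new_phi + 180.0) % 360.0 - 180.0
    dup = df.duplicated(subset=["H", "K", "L"]).any()
    if dup:
        warnings.warn("duplicate reflections after ASU reduction; averaging")
        agg = {c: "mean" for c in df.columns if c not in ("H", "K", "L")}
        df = df.groupby(["H", "K", "L"], as_index=False).agg(agg)
    return ReflectionSet(df.reset_index(drop=True), refl.cell, refl.sg)


def expand_to_p1(refl: ReflectionSet, friedel: bool = True) -> ReflectionSet:
    """Generate all symmetry-equivalent reflections (optionally + Friedel).

    Phases follow phi(hR) = phi(h) - 360 h.t; amplitudes are invariant;
    Friedel mates carry conjugated phases.  The output set is labelled P1.
    """
    hkl = refl.hkl
    f = refl.df["F"].to_numpy(dtype=float)
    sig = refl.df["SIGF"].to_numpy(dtype=float) if "SIGF" in refl.df else None
    phi = refl.df["PHI"].to_numpy(dtype=float) if "PHI" in refl.df else None
    rows_h, rows_f, rows_s, rows_p = [], [], [], []
    for op in refl.sg.operations():
        rot = np.array(op.rot, dtype=float) / gemmi.Op.DEN
        tran = np.array(op.tran, dtype=float) / gemmi.Op.DEN
        h_new = np.rint(hkl @ rot).astype(int)
        rows_h.append(h_new)
        rows_f.append(f)
        rows_s.append(sig)
        if phi is not None:
            rows_p.append(phi - 360.0 * (hkl @ tran))
    h_all = np.vstack(rows_h)
    f_all = np.concatenate(rows_f)
    s_all = np.concatenate(rows_s) if sig is not None else None
    p_all = np.concatenate(rows_p) if phi is not None else None
    if friedel:
        h_all = np.vstack([h_all, -h_all])
        f_all = np.concatenate([f_all, f_all])
        if s_all is not None:
            s_all = np.concatenate([s_all, s_all])
        if p_all is not None:
            p_all = np.concatenate([p_all, -p_all])
    df = pd.DataFrame({"H": h_all[:, 0], "K": h_all[:, 1], "L": h_all[:, 2], "F": f_all})
    if s_all is not None:
        df["SIGF"] = s_all
    if p_all is not None:
        df["PHI"] = (p_all + 180.0) % 360.0 - 180.0
    df = df.drop_duplicates(subset=["H", "K", "L"]).reset_index(drop=True)
    return ReflectionSet(df, refl.cell, spacegroup("P 1"))


# ---------------------------------------------------------------------------
# Reflection file I/O

_MTZ_TYPES = {"F": "F", "SIGF": "Q", "PHI": "P"}


def write_reflections(refl: ReflectionSet, path: str | Path) -> None:
    """Write reflections as MTZ (default) or structure-factor CIF (.cif)."""
    path = Path(path)
    if path.suffix.lower() in (".cif", ".ent"):
        _write_sf_cif(refl, path)
        return
    mtz = gemmi.Mtz(with_base=True)
    mtz.spacegroup = refl.sg
    mtz.cell = refl.cell
    mtz.add_dataset("data")
    cols = [c for c in ("F", "SIGF", "PHI") if c in refl.df.columns]
    for c in cols:
        mtz.add_column(c, _MTZ_TYPES[c])
    data = np.column_stack([refl.hkl.astype(np.float32)] +
                           [refl.df[c].to_numpy(np.float32) for c in cols])
    mtz.set_data(data.astype(np.float32))
    mtz.write_to_file(str(path))


_CIF_TAGS = {
    "F": "_refln.F_meas_au",
    "SIGF": "_refln.F_meas_sigma_au",
    "PHI": "_refln.phase_calc",
}


def _write_sf_cif(refl: ReflectionSet, path: Path) -> None:
    doc = gemmi.cif.Document()
    block = doc.add_new_block("reflections")
    c = refl.cell
    for tag, val in [("_cell.length_a", c.a), ("_cell.length_b", c.b),
                     ("_cell.length_c", c.c), ("_cell.angle_alpha", c.alpha),
                     ("_cell.angle_beta", c.beta), ("_cell.angle_gamma", c.gamma)]:
        block.set_pair(tag, f"{val:.6f}")
    block.set_pair("_symmetry.space_group_name_H-M", gemmi.cif.quote(refl.sg.hm))
    cols = [col for col in ("F", "SIGF", "PHI") if col in refl.df.columns]
    tags = ["_refln.index_h", "_refln.index_k", "_refln.index_l"] + [_CIF_TAGS[c] for c in cols]
    loop = block.init_loop("", tags)
    for _, row in refl.df.iterrows():
        loop.add_row([str(int(row["H"])), str(int(row["K"])), str(int(row["L"]))]
                     + [f"{row[c]:.6f}" for c in cols])
    doc.write_file(str(path))


def read_reflections(path: str | Path, columns: dict[str, str] | None = None,
                     reduce_to_asu: bool = True) -> ReflectionSet:
    """Read an MTZ or structure-factor CIF file into a ReflectionSet.

    Parameters
    ----------
    columns
        Mapping from canonical names (``F``, ``SIGF``, ``PHI``) to the
        labels used in the file, e.g. ``{"F": "FOBS", "PHI": "PHIC"}``.
        Defaults try common labels.
    reduce_to_asu
        Map indices to the reciprocal ASU after reading (default).
    """
    path = Path(path)
    if path.suffix.lower() in (".cif", ".ent"):
        rs = _read_sf_cif(path, columns)
    else:
        rs = _read_mtz(path, columns)
    return map_to_asu(rs) if reduce_to_asu else rs


_DEFAULT_LABELS = {
    "F": ("F", "FOBS", "FP", "F_meas_au", "F-obs", "F-obs-filtered"),
    "SIGF": ("SIGF", "SIGFOBS", "SIGFP", "F_meas_sigma_au", "SIGF-obs"),
    "PHI": ("PHI", "PHIC", "PHIFC", "phase_calc", "PHIF-model"),
}


def _pick_label(available: list[str], canonical: str,
                columns: dict[str, str] | None) -> str | None:
    if columns and canonical in columns:
        label = columns[canonical]
        if label not in available:
            raise KeyError(
                f"column {label!r} not found; available columns: {available}")
        return label
    for cand in _DEFAULT_LABELS[canonical]:
        if cand in available:
            return cand
    if canonical == "F":
        raise KeyError(
            f"no amplitude column found; available columns: {available}")
    return None


def _read_mtz(path: Path, columns: dict[str, str] | None) -> ReflectionSet:
    mtz = gemmi.read_mtz_file(str(path))
    labels = [c.label for c in mtz.columns]
    arr = np.array(mtz, copy=True)
    tab = {lab: arr[:, i] for i, lab in enumerate(labels)}
    df = pd.DataFrame({
        "H": tab["H"].astype(int), "K": tab["K"].astype(int), "L": tab["L"].astype(int),
    })
    for canonical in ("F", "SIGF", "PHI"):
        lab = _pick_label(labels, canonical, columns)
        if lab is not None:
            df[canonical] = tab[lab].astype(float)
    df = df.dropna(subset=["F"]).reset_index(drop=True)
    df = df[~np.all(df[["H", "K", "L"]].to_numpy() == 0, axis=1)].reset_index(drop=True)
    return ReflectionSet(df, mtz.cell, mtz.spacegroup)


def _read_sf_cif(path: Path, columns: dict[str, str] | None) -> ReflectionSet:
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    cell = gemmi.UnitCell(
        *[float(block.find_value(f"_cell.{k}"))
          for k in ("length_a", "length_b", "length_c",
                    "angle_alpha", "angle_beta", "angle_gamma")])
    sg_name = block.find_value("_symmetry.space_group_name_H-M")
    sg = spacegroup(gemmi.cif.as_string(sg_name)) if sg_name else spacegroup("P 1")
    prefix = "_refln."
    table = block.find_mmcif_category("_refln.")
    tags = [t[len(prefix):] for t in table.tags]
    data = {t: [table[i][j] for i in range(len(table))] for j, t in enumerate(tags)}
    df = pd.DataFrame({
        "H": np.array(data["index_h"], dtype=int),
        "K": np.array(data["index_k"], dtype=int),
        "L": np.array(data["index_l"], dtype=int),
    })
    cif_defaults = {"F": "F_meas_au", "SIGF": "F_meas_sigma_au", "PHI": "phase_calc"}
    for canonical in ("F", "SIGF", "PHI"):
        lab = (columns or {}).get(canonical, cif_defaults[canonical])
        if (columns or {}).get(canonical) and lab not in tags:
            raise KeyError(f"column {lab!r} not found; available columns: {tags}")
        if lab in tags:
            df[canonical] = np.array(data[lab], dtype=float)
    if "F" not in df:
        raise KeyError(f"no amplitude column found; available columns: {tags}")
    df = df[~np.all(df[["H", "K", "L"]].to_numpy() == 0, axis=1)].reset_index(drop=True)
    return ReflectionSet(df, cell, sg)
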