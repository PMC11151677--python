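"""Real-space maps: Fourier synthesis, rigid resampling, voxel arithmetic.

A :class:`DensityMap` is a scalar field sampled on a regular grid covering
one full unit cell.  Synthesis evaluates rho(x) = (1/V) sum_h F(h)
exp(-2 pi i h.x) by FFT from a P1-complete, Friedel-consistent coefficient
set.  Resampling applies a rigid pose with periodic tricubic-spline
interpolation (trilinear optional).  Solvent masking zeroes voxels far
from the model; sigma scaling divides by the standard deviation so contour
levels read in sigma units.  Maps are written/read in MRC2014/CCP4 format
via gemmi.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy import ndimage

from .crystal_core import ReflectionSet, Structure, orth_matrix, spacegroup
from .rigid_body import Pose
from .structure_factors import _grid_shape, _sym_ops

__all__ = ["DensityMap", "synthesize_map", "resample_map", "subtract_maps",
           "solvent_mask_map", "sigma_scale", "write_mrc", "read_mrc"]


@dataclass
class DensityMap:
    """Scalar density on an (na, nb, nc) grid over one unit cell."""

    values: np.ndarray
    cell: gemmi.UnitCell
    sg: gemmi.SpaceGroup
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("map grid must be 3-D with >= 2 points per axis")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def sigma(self) -> float:
        return float(self.values.std())

    def copy(self, **kw) -> "DensityMap":
        return DensityMap(self.values.copy(), self.cell, self.sg,
                          kw.get("label", self.label))

    def voxel_frac_coords(self) -> np.ndarray:
        """(N, 3) fractional coordinates of voxel centers, C order."""
        n = self.shape
        grids = np.meshgrid(*[np.arange(nn) / nn for nn in n], indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=-1)


def _coeff_grid(hkl: np.ndarray, f: np.ndarray, shape) -> np.ndarray:
    n = np.array(shape)
    if len(hkl) == 0:  # e.g. an all-zero difference: empty spectrum
        return np.zeros(tuple(shape), dtype=complex)
    if np.any(np.max(np.abs(hkl), axis=0) * 2 >= n):
        raise ValueError("grid too coarse for the coefficient resolution")
    grid = np.zeros(tuple(shape), dtype=complex)
    idx = tuple((hkl % n).T)
    grid[idx] = f
    return grid


def synthesize_map(coeffs: ReflectionSet | tuple[np.ndarray, np.ndarray],
                   grid_spacing: float | None = None,
                   shape: tuple[int, int, int] | None = None,
                   cell: gemmi.UnitCell | None = None,
                   label: str = "") -> DensityMap:
    """Fourier synthesis of a density map from complex coefficients.

    Accepts either a :class:`ReflectionSet` with F and PHI columns (must
    already be expanded to P1) or a ``(hkl, complex_f)`` pair plus
    ``cell``.  Friedel mates are completed automatically; coefficients
    that are present for both +h and -h must be conjugate-consistent
    (checked via the imaginary residue of the synthesized map).
    """
    if isinstance(coeffs, ReflectionSet):
        if "PHI" not in coeffs.df:
            raise ValueError("coefficients need a PHI column for synthesis")
        hkl = coeffs.hkl
        f = coeffs.df["F"].to_numpy() * np.exp(
            1j * np.radians(coeffs.df["PHI"].to_numpy()))
        cell = coeffs.cell
    else:
        hkl, f = coeffs
        hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
        f = np.asarray(f, dtype=complex)
        if cell is None:
            raise ValueError("cell required with raw (hkl, F) coefficients")
    if shape is None:
        if grid_spacing is None:
            raise ValueError("give either grid_spacing or shape")
        shape = _grid_shape(cell, grid_spacing)
    # complete Friedel mates not explicitly present
    have = {tuple(h) for h in hkl}
    extra_h, extra_f = [], []
    for h, fv in zip(hkl, f):
        mh = (-h[0], -h[1], -h[2])
        if mh not in have:
            extra_h.append(mh)
            extra_f.append(np.conj(fv))
    if extra_h:
        hkl = np.vstack([hkl, np.array(extra_h, dtype=int)])
        f = np.concatenate([f, np.array(extra_f)])
    grid = _coeff_grid(hkl, f, shape)
    rho = np.fft.fftn(grid) / cell.volume
    imag_level = np.abs(rho.imag).max()
    scale = max(rho.real.std(), 1e-30)
    if imag_level > 1e-6 * max(scale, np.abs(rho.real).max(), 1e-30):
        raise ValueError(
            f"coefficients are not Friedel-consistent "
            f"(imaginary residue {imag_level:.3g} vs map sigma {scale:.3g})")
    return DensityMap(rho.real, cell, spacegroup("P 1"), label=label)


def resample_map(source: DensityMap, pose: Pose,
                 target_shape: tuple[int, int, int] | None = None,
                 target_cell: gemmi.UnitCell | None = None,
                 order: int = 3) -> DensityMap:
    """Pull a map through a rigid pose: output(x) = source(pose^-1(x)).

    The output grid lives on ``target_cell`` (default: the source cell);
    interpolation is periodic tricubic spline (``order=3``; use 1 for
    trilinear).  ``pose`` maps source-frame orthogonal coordinates onto
    target-frame ones.
    """
    target_cell = target_cell or source.cell
    target_shape = target_shape or source.shape
    out = DensityMap(np.zeros(target_shape), target_cell, source.sg,
                     label=source.label)
    x_frac = out.voxel_frac_coords()
    r_target = x_frac @ orth_matrix(target_cell).T
    r_source = pose.inverse().apply(r_target)
    f_source = r_source @ np.linalg.inv(orth_matrix(source.cell)).T
    coords = (f_source * np.array(source.shape)).T  # (3, N) in voxel units
    vals = ndimage.map_coordinates(source.values, coords, order=order,
                                   mode="grid-wrap")
    out.values = vals.reshape(target_shape)
    return out


def subtract_maps(on: DensityMap, off: DensityMap) -> DensityMap:
    """Voxel-wise difference on - off; grids and cells must match."""
    if on.shape != off.shape:
        raise ValueError(f"grid mismatch: {on.shape} vs {off.shape}")
    if not np.allclose([on.cell.a, on.cell.b, on.cell.c,
                        on.cell.alpha, on.cell.beta, on.cell.gamma],
                       [off.cell.a, off.cell.b, off.cell.c,
                        off.cell.alpha, off.cell.beta, off.cell.gamma]):
        raise ValueError("cell mismatch between maps")
    return DensityMap(on.values - off.values, off.cell, off.sg,
                      label="difference")


def solvent_mask_map(dmap: DensityMap, model: Structure,
                     radius: float | None = None, margin: float = 1.5,
                     include_symmetry: bool = True
                     ) -> tuple[DensityMap, float]:
    """Zero voxels far from every atom of the model.

    A voxel survives if it lies within ``radius`` of some atom (absolute
    cutoff), or -- when ``radius`` is None (default) -- within that atom's
    van der Waals radius plus ``margin`` (1.5 A by default).  Symmetry
    mates of the model and periodic images are included; returns the
    masked map and the fraction of voxels zeroed.
    """
    from scipy.spatial import cKDTree
    a_mat = orth_matrix(dmap.cell)
    ops = _sym_ops(model.sg) if include_symmetry else [(np.eye(3), np.zeros(3))]
    frac_all = np.vstack([(model.xyz_frac @ rot.T + tran) % 1.0
                          for rot, tran in ops])
    elems = np.array(list(model.elements) * len(ops))
    shifts = np.array(np.meshgrid([-1, 0, 1], [-1, 0, 1], [-1, 0, 1])).T.reshape(-1, 3)
    vox = dmap.voxel_frac_coords() @ a_mat.T
    keep_flat = np.zeros(len(vox), dtype=bool)
    for elem in np.unique(elems):
        cutoff = radius if radius is not None else gemmi.Element(elem).vdw_r + margin
        if cutoff <= 0:
            continue
        sel = frac_all[elems == elem]
        pts = np.vstack([(sel + s) @ a_mat.T for s in shifts])
        tree = cKDTree(pts)
        d, _ = tree.query(vox, k=1, distance_upper_bound=cutoff)
        keep_flat |= np.isfinite(d)
    keep = keep_flat.reshape(dmap.shape)
    out = dmap.copy(label=dmap.label + "+masked")
    out.values = np.where(keep, out.values, 0.0)
    return out, float(1.0 - keep.mean())


def sigma_scale(dmap: DensityMap, region: np.ndarray | None = None
                ) -> tuple[DensityMap, float]:
    """Divide a map by its standard deviation over ``region`` (default all).

    Returns the scaled map and the sigma used; zero variance is rejected.
    """
    vals = dmap.values if region is None else dmap.values[region]
    sigma = float(vals.std())
    if sigma <= 0:
        raise ValueError("cannot sigma-scale a constant map")
    out = dmap.copy(label=dmap.label + "+sigma_scaled")
    out.values = out.values / sigma
    return out, sigma


def write_mrc(dmap: DensityMap, path: str | Path) -> None:
    """Write MRC2014/CCP4 format (axis order fast-to-slow = X, Y, Z)."""
    grid = gemmi.FloatGrid(*dmap.shape)
    grid.set_unit_cell(dmap.cell)
    grid.spacegroup = dmap.sg
    np.asarray(grid.array)[:] = dmap.values.astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


def read_mrc(path: str | Path) -> DensityMap:
    """Read an MRC/CCP4 map into a DensityMap."""
    ccp4 = gemmi.read_ccp4_map(str(path))
    ccp4.setup(float("nan"))
    vals = np.array(ccp4.grid.array, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"{path}: map has missing/non-finite voxels")
    sg = ccp4.grid.spacegroup or spacegroup("P 1")
    return DensityMap(vals, ccp4.grid.unit_cell, sg, label=str(path))
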