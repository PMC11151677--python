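"""Put two observed datasets on a common scale and resolution range.

The ON dataset is scaled onto the OFF dataset by fitting an overall scale
k and an isotropic (default) or anisotropic B against the common
reflections; both sets are then truncated to the shared resolution range
so the difference map does not preferentially display high-resolution
features of the better dataset.  Outlier |dF| reflections are flagged from
a robust (MAD-based) sigma but never deleted: large amplitude differences
ARE the difference signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .crystal_core import ReflectionSet, resolution_of
from .structure_factors import ScaleModel, reciprocal_vectors

__all__ = ["CommonScaleResult", "common_resolution_truncate", "scale_datasets"]


@dataclass
class CommonScaleResult:
    """Outcome of placing the ON dataset on the OFF scale."""

    on_scaled: ReflectionSet
    scale: ScaleModel
    outliers: np.ndarray  # (m, 3) Miller indices flagged, never removed
    d_limits: tuple[float, float]  # (d_max, d_min) shared range
    n_common: int = 0

    def to_dict(self) -> dict:
        return {
            "scale": self.scale.to_dict(),
            "n_outliers": int(len(self.outliers)),
            "outliers": [list(map(int, h)) for h in self.outliers],
            "d_max": self.d_limits[0],
            "d_min": self.d_limits[1],
            "n_common": self.n_common,
        }


def common_resolution_truncate(off: ReflectionSet, on: ReflectionSet
                               ) -> tuple[ReflectionSet, ReflectionSet]:
    """Truncate both sets to the intersection of their resolution ranges."""
    d_min = max(off.d_min, on.d_min)
    d_max = min(off.d_max, on.d_max)
    if d_min > d_max:
        raise ValueError(
            f"no resolution overlap: OFF [{off.d_max:.2f}-{off.d_min:.2f}] A, "
            f"ON [{on.d_max:.2f}-{on.d_min:.2f}] A")
    eps = 1e-9

    def cut(rs: ReflectionSet) -> ReflectionSet:
        d = rs.d
        keep = (d >= d_min - eps) & (d <= d_max + eps)
        return ReflectionSet(rs.df[keep].reset_index(drop=True), rs.cell, rs.sg)

    return cut(off), cut(on)


def scale_datasets(off: ReflectionSet, on: ReflectionSet,
                   anisotropic: bool = False,
                   outlier_sigma: float = 6.0) -> CommonScaleResult:
    """Scale ON amplitudes onto OFF over their common reflections.

    Minimizes sum w (|F_off| - k exp(-B s^2/4) |F_on|)^2 with w = 1/sigma^2
    when both sigmas are present (else 1), over k and isotropic B (or an
    anisotropic tensor restricted to the lattice symmetry).  The fitted
    model is applied multiplicatively to the full ON set (sigmas scaled by
    the same factors; indices and phases untouched).  Reflections with
    |dF| > ``outlier_sigma`` robust sigmas after scaling are reported as
    outliers but kept.
    """
    common = off.common_with(on)
    n_common = len(common)
    if n_common < 50:
        raise ValueError(f"too few common reflections to scale: {n_common} < 50")
    hkl = common[["H", "K", "L"]].to_numpy(dtype=int)
    f_off = common["F_1"].to_numpy(dtype=float)
    f_on = common["F_2"].to_numpy(dtype=float)
    if "SIGF_1" in common and "SIGF_2" in common:
        w = 1.0 / (common["SIGF_1"].to_numpy() ** 2 + common["SIGF_2"].to_numpy() ** 2)
    else:
        w = np.ones(n_common)
    sw = np.sqrt(w)
    svec = reciprocal_vectors(off.cell, hkl)
    s2 = np.einsum("ij,ij->i", svec, svec)

    if anisotropic:
        ortho = all(abs(a - 90.0) < 1e-6 for a in
                    (off.cell.alpha, off.cell.beta, off.cell.gamma))
        n_b = 3 if ortho else 6

        def quad(p):
            expo = (p[1] * svec[:, 0] ** 2 + p[2] * svec[:, 1] ** 2
                    + p[3] * svec[:, 2] ** 2)
            if not ortho:
                expo += (2 * p[4] * svec[:, 0] * svec[:, 1]
                         + 2 * p[5] * svec[:, 0] * svec[:, 2]
                         + 2 * p[6] * svec[:, 1] * svec[:, 2])
            return expo

        def resid(p):
            return sw * (f_off - np.exp(p[0]) * np.exp(-quad(p) / 4.0) * f_on)

        sol = least_squares(resid, x0=np.zeros(1 + n_b), method="lm")
        p = sol.x
        b = np.diag(p[1:4])
        if not ortho:
            b[0, 1] = b[1, 0] = p[4]
            b[0, 2] = b[2, 0] = p[5]
            b[1, 2] = b[2, 1] = p[6]
        scale = ScaleModel(k=float(np.exp(p[0])), b_iso=float(np.trace(b) / 3),
                           b_aniso=b,
                           residual=float(np.sqrt(np.mean(sol.fun**2))))
    else:
        def resid(p):
            return sw * (f_off - np.exp(p[0]) * np.exp(-p[1] * s2 / 4.0) * f_on)

        sol = least_squares(resid, x0=np.array([0.0, 0.0]), method="lm")
        scale = ScaleModel(k=float(np.exp(sol.x[0])), b_iso=float(sol.x[1]),
                           residual=float(np.sqrt(np.mean(sol.fun**2))))

    factors = scale.factors(off.cell, hkl)
    dflt = f_off - factors * f_on
    mad = np.median(np.abs(dflt - np.median(dflt)))
    robust_sigma = 1.4826 * mad if mad > 0 else np.std(dflt)
    if robust_sigma > 0:
        outliers = hkl[np.abs(dflt - np.median(dflt)) > outlier_sigma * robust_sigma]
    else:
        outliers = np.empty((0, 3), dtype=int)

    df = on.df.copy()
    full_factors = scale.factors(on.cell, on.hkl)
    df["F"] = df["F"].to_numpy() * full_factors
    if "SIGF" in df:
        df["SIGF"] = df["SIGF"].to_numpy() * full_factors
    on_scaled = ReflectionSet(df, on.cell, on.sg)
    d_max = min(off.d_max, on.d_max)
    d_min = max(off.d_min, on.d_min)
    return CommonScaleResult(on_scaled, scale, outliers, (d_max, d_min), n_common)
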