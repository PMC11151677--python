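"""Isomorphism diagnostics between two reflection datasets.

Two crystals are isomorphous when one set of phases serves both.  These
statistics quantify how far a pair of datasets is from that ideal:
per-resolution-bin Pearson correlations of amplitudes and of phase
cosines, a figure of merit <cos(dphi)> (the primary phase statistic --
the cosine correlation is liable to small phase-wrapping artifacts), a
global R_iso, and the joint (|dF|, |dphi|) sample behind the
Rould-Carter criterion: a meaningful isomorphous difference map requires
that large amplitude differences coincide only with small phase
differences and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crystal_core import ReflectionSet, resolution_of
from .data_prep import scale_datasets

__all__ = ["IsomorphismReport", "isomorphism_report", "rould_carter_table"]


def _wrap_deg(phi: np.ndarray) -> np.ndarray:
    return (np.asarray(phi, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass
class IsomorphismReport:
    """Binned and global isomorphism statistics for a dataset pair."""

    bins: pd.DataFrame  # columns: d_mean, n, cc_amp, cc_cos_phi, fom
    r_iso: float
    n_common: int
    rould_carter: pd.DataFrame | None = None  # columns: dF_norm, abs_dphi_deg
    violation_score: float | None = None

    def to_dict(self) -> dict:
        return {"r_iso": self.r_iso, "n_common": self.n_common,
                "violation_score": self.violation_score,
                "bins": self.bins.to_dict(orient="list")}

    def to_csv(self, path) -> None:
        self.bins.to_csv(path, index=False)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3 or x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def isomorphism_report(set1: ReflectionSet, set2: ReflectionSet,
                       n_bins: int = 15, prescale: bool = True
                       ) -> IsomorphismReport:
    """Binned amplitude/phase agreement statistics between two datasets.

    Bins hold equal reflection counts (stabler CC estimates than
    equal-width 1/d^2 bins).  If both sets carry PHI columns, the phase
    statistics and the Rould-Carter sample are included.  Datasets are
    placed on a common scale first (disable with ``prescale=False``).
    """
    if prescale:
        set2 = scale_datasets(set1, set2).on_scaled
    common = set1.common_with(set2)
    if len(common) < 10 * n_bins:
        raise ValueError(
            f"too few common reflections ({len(common)}) for {n_bins} bins")
    hkl = common[["H", "K", "L"]].to_numpy(dtype=int)
    d = np.asarray(resolution_of(set1.cell, hkl))
    f1 = common["F_1"].to_numpy(dtype=float)
    f2 = common["F_2"].to_numpy(dtype=float)
    has_phi = "PHI_1" in common and "PHI_2" in common
    if has_phi:
        p1 = common["PHI_1"].to_numpy(dtype=float)
        p2 = common["PHI_2"].to_numpy(dtype=float)
        dphi = _wrap_deg(p1 - p2)

    order = np.argsort(-d)  # low resolution (large d) first
    edges = np.array_split(order, n_bins)
    rows = []
    for idx in edges:
        row = {"d_mean": float(d[idx].mean()), "n": len(idx),
               "cc_amp": _pearson(f1[idx], f2[idx])}
        if has_phi:
            row["cc_cos_phi"] = _pearson(np.cos(np.radians(p1[idx])),
                                         np.cos(np.radians(p2[idx])))
            row["fom"] = float(np.mean(np.cos(np.radians(dphi[idx]))))
        rows.append(row)
    bins = pd.DataFrame(rows)
    r_iso = float(np.sum(np.abs(f1 - f2)) / np.sum((f1 + f2) / 2.0))
    rc = None
    score = None
    if has_phi:
        rc, score = rould_carter_table(f1, f2, p1, p2)
    return IsomorphismReport(bins=bins, r_iso=r_iso, n_common=len(common),
                             rould_carter=rc, violation_score=score)


def rould_carter_table(f1, f2, phi1_deg, phi2_deg,
                       amp_quantile: float = 0.75,
                       phase_threshold_deg: float = 60.0
                       ) -> tuple[pd.DataFrame, float]:
    """Joint (normalized |dF|, |dphi|) sample plus a violation score.

    The score is the fraction of reflections with BOTH a normalized
    amplitude difference above its ``amp_quantile`` quantile AND a phase
    difference beyond ``phase_threshold_deg`` -- reflections that break
    the premise of the isomorphous difference map.
    """
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    if len(f1) == 0 or len(f1) != len(f2):
        raise ValueError("need matched, non-empty amplitude arrays")
    dphi = np.abs(_wrap_deg(np.asarray(phi1_deg) - np.asarray(phi2_deg)))
    df_norm = np.abs(f1 - f2) / np.mean((f1 + f2) / 2.0)
    table = pd.DataFrame({"dF_norm": df_norm, "abs_dphi_deg": dphi})
    cut = np.quantile(df_norm, amp_quantile)
    violation = float(np.mean((df_norm > cut) & (dphi > phase_threshold_deg)))
    return table, violation
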