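"""Orchestration of the three difference-map products.

* :func:`matchmaps_run` -- the generalized difference map: scale and
  truncate the two observed datasets, rigid-body refine the reference
  model against each, build hybrid coefficients (observed amplitudes +
  rigid-body calculated phases), synthesize both maps, overlay the ON map
  onto the OFF frame through the pose relating the two refined models,
  subtract voxel-wise, mask the solvent and sigma-scale.
* :func:`isomorphous_run` / :func:`isomorphous_difference_map` -- the
  classical map with coefficients (|F_on| - |F_off|) exp(i phi_off,calc).
* :func:`fo_fc_coefficients` -- the rigid-body Fo-Fc map coefficients.
* :func:`matchmaps_ncs` -- internal difference map across an NCS relation.
* :func:`matchmaps_mr` -- cross-crystal-form variant with a user-supplied
  placement (the molecular-replacement search itself is an external step).

Sign convention: OFF is always the reference frame and positive density
means more density in the ON state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .crystal_core import (ReflectionSet, Structure, expand_to_p1,
                           write_model, write_reflections)
from .data_prep import (CommonScaleResult, common_resolution_truncate,
                        scale_datasets)
from .map_algebra import (DensityMap, resample_map, sigma_scale,
                          solvent_mask_map, subtract_maps, synthesize_map,
                          write_mrc)
from .rigid_body import (Pose, RefinementResult, RigidGroups, apply_pose,
                         pose_between, rigid_body_refine)
from .structure_factors import ScaleModel, SolventModel

__all__ = ["RunConfig", "RunReport", "hybrid_coefficients",
           "isomorphous_difference_map", "isomorphous_run",
           "fo_fc_coefficients", "matchmaps_run", "matchmaps_ncs",
           "matchmaps_mr"]


@dataclass
class RunConfig:
    """Knobs shared by the pipeline variants."""

    solvent: SolventModel | None = None  # None/disabled = no bulk solvent
    per_chain_rigid_groups: bool = False
    anisotropic_scaling: bool = False
    grid_spacing: float | None = None  # default: d_min / 3
    mask_margin: float = 1.5  # A beyond van der Waals
    # sigma reference for the final map: the surviving (unmasked) region by
    # default -- the toy molecule fills a small fraction of the cell, so a
    # whole-cell sigma over mostly-zeroed voxels would inflate sigma units
    sigma_region_masked_only: bool = True
    keep_temp_files: bool = False
    output_dir: Path | None = None
    seed: int = 0

    def spacing(self, d_min: float) -> float:
        return self.grid_spacing if self.grid_spacing else d_min / 3.0


@dataclass
class RunReport:
    """Serializable record of a pipeline run."""

    stages: dict = field(default_factory=dict)
    files: list[str] = field(default_factory=list)
    version: str = __version__

    def log(self, stage: str, **info) -> None:
        self.stages[stage] = info

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"version": self.version, "stages": self.stages,
                       "files": self.files}, fh, indent=2, default=_jsonable)
        self.files.append(str(path))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _signed_to_coeffs(hkl: np.ndarray, amp: np.ndarray, phi_deg: np.ndarray,
                      refl_like: ReflectionSet) -> ReflectionSet:
    """Fold negative amplitude coefficients into a 180 deg phase shift."""
    amp = np.asarray(amp, dtype=float)
    phi = np.asarray(phi_deg, dtype=float) + np.where(amp < 0, 180.0, 0.0)
    df = pd.DataFrame({"H": hkl[:, 0], "K": hkl[:, 1], "L": hkl[:, 2],
                       "F": np.abs(amp),
                       "PHI": (phi + 180.0) % 360.0 - 180.0})
    df = df[df["F"] > 0].reset_index(drop=True)
    return ReflectionSet(df, refl_like.cell, refl_like.sg)


def hybrid_coefficients(f_obs: ReflectionSet,
                        refinement: RefinementResult) -> ReflectionSet:
    """Observed amplitudes combined with rigid-body calculated phases."""
    if len(f_obs) != len(refinement.hkl) or not np.array_equal(
            f_obs.hkl, refinement.hkl):
        merged = f_obs.df.merge(
            pd.DataFrame({"H": refinement.hkl[:, 0], "K": refinement.hkl[:, 1],
                          "L": refinement.hkl[:, 2],
                          "PHIC": refinement.phases_deg}),
            on=["H", "K", "L"])
        df = merged[["H", "K", "L", "F"]].copy()
        df["PHI"] = merged["PHIC"]
    else:
        df = f_obs.df[["H", "K", "L", "F"]].copy()
        df["PHI"] = refinement.phases_deg
    return ReflectionSet(df.reset_index(drop=True), f_obs.cell, f_obs.sg)


def fo_fc_coefficients(f_obs: ReflectionSet,
                       refinement: RefinementResult) -> ReflectionSet:
    """Unweighted rigid-body Fo-Fc coefficients.

    (|F_obs| - k exp(-B s^2/4) |F_calc|) exp(i phi_calc) per reflection of
    the refinement; negative differences are folded into the phase.
    """
    if refinement.scale is None:
        raise ValueError("refinement carries no scale model")
    common = f_obs.df.merge(
        pd.DataFrame({"H": refinement.hkl[:, 0], "K": refinement.hkl[:, 1],
                      "L": refinement.hkl[:, 2],
                      "FC": np.abs(refinement.f_calc),
                      "PHIC": refinement.phases_deg}),
        on=["H", "K", "L"])
    hkl = common[["H", "K", "L"]].to_numpy(dtype=int)
    fc_scaled = refinement.scale.factors(f_obs.cell, hkl) * common["FC"].to_numpy()
    diff = common["F"].to_numpy() - fc_scaled
    return _signed_to_coeffs(hkl, diff, common["PHIC"].to_numpy(), f_obs)


def isomorphous_difference_map(off: ReflectionSet, on: ReflectionSet,
                               phases: ReflectionSet,
                               grid_spacing: float | None = None,
                               shape: tuple[int, int, int] | None = None
                               ) -> DensityMap:
    """Classical isomorphous difference map.

    Coefficients (|F_on| - |F_off|) exp(i phi_off,calc) over the common
    reflections; ``phases`` is any ReflectionSet carrying a PHI column on
    the OFF indices (typically hybrid coefficients from a rigid-body
    refinement of the OFF model against the OFF data).  Inputs should
    already be scaled and truncated to a common resolution range.
    """
    if "PHI" not in phases.df:
        raise ValueError("phases ReflectionSet lacks a PHI column")
    common = off.common_with(on)
    merged = common.merge(
        phases.df[["H", "K", "L", "PHI"]], on=["H", "K", "L"])
    hkl = merged[["H", "K", "L"]].to_numpy(dtype=int)
    diff = merged["F_2"].to_numpy() - merged["F_1"].to_numpy()
    coeffs = _signed_to_coeffs(hkl, diff, merged["PHI"].to_numpy(), off)
    spacing = grid_spacing or min(off.d_min, on.d_min) / 3.0
    return synthesize_map(expand_to_p1(coeffs), grid_spacing=spacing,
                          shape=shape, label="isomorphous_difference")


def _refine(model: Structure, refl: ReflectionSet, config: RunConfig
            ) -> RefinementResult:
    groups = (RigidGroups.per_chain(model) if config.per_chain_rigid_groups
              else None)
    return rigid_body_refine(model, refl, groups=groups,
                             solvent=config.solvent)


def isomorphous_run(model: Structure, off: ReflectionSet, on: ReflectionSet,
                    config: RunConfig | None = None
                    ) -> tuple[DensityMap, RunReport]:
    """Scale, truncate, phase from the OFF model and synthesize Eq.-style
    isomorphous difference coefficients."""
    config = config or RunConfig()
    report = RunReport()
    scale_res = scale_datasets(off, on, anisotropic=config.anisotropic_scaling)
    report.log("scaling", **scale_res.to_dict())
    off_t, on_t = common_resolution_truncate(off, scale_res.on_scaled)
    ref_off = _refine(model, off_t, config)
    report.log("refine_off", **ref_off.to_dict())
    phases = hybrid_coefficients(off_t, ref_off)
    dmap = isomorphous_difference_map(
        off_t, on_t, phases, grid_spacing=config.spacing(
            max(off_t.d_min, on_t.d_min)))
    dmap, sigma = sigma_scale(dmap)
    report.log("map", sigma=sigma, shape=list(dmap.shape))
    _write_outputs(config, report, dmap, "isomorphous_difference.ccp4")
    return dmap, report


def _write_outputs(config: RunConfig, report: RunReport, dmap: DensityMap,
                   name: str, extras: dict | None = None) -> None:
    if config.output_dir is None:
        return
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    map_path = outdir / name
    write_mrc(dmap, map_path)
    report.files.append(str(map_path))
    if config.keep_temp_files and extras:
        for fname, (kind, obj) in extras.items():
            path = outdir / fname
            if kind == "model":
                write_model(obj, path)
            elif kind == "reflections":
                write_reflections(obj, path)
            report.files.append(str(path))
    report.to_json(outdir / (Path(name).stem + "_report.json"))


def matchmaps_run(model: Structure, off: ReflectionSet, on: ReflectionSet,
                  config: RunConfig | None = None,
                  on_start: Structure | None = None,
                  scale_mode: str = "matched"
                  ) -> tuple[DensityMap, RunReport]:
    """The generalized (rigid-body phased, real-space aligned) difference map.

    ``on_start`` optionally overrides the starting placement for the ON
    refinement (used by the cross-crystal-form variant).  ``scale_mode``
    is "matched" (index-matched scaling; requires a shared indexing
    convention) or "binned" (resolution-shell mean-amplitude scaling, for
    datasets in different space groups).
    """
    config = config or RunConfig()
    report = RunReport()

    if scale_mode == "matched":
        scale_res = scale_datasets(off, on,
                                   anisotropic=config.anisotropic_scaling)
        on_scaled = scale_res.on_scaled
        report.log("scaling", **scale_res.to_dict())
    elif scale_mode == "binned":
        on_scaled, scale = _binned_scale(off, on)
        report.log("scaling", scale=scale.to_dict(), mode="binned")
    else:
        raise ValueError(f"unknown scale_mode {scale_mode!r}")

    off_t, on_t = common_resolution_truncate(off, on_scaled)
    d_min = max(off_t.d_min, on_t.d_min)
    spacing = config.spacing(d_min)
    report.log("truncation", d_min=d_min,
               d_max=min(off_t.d_max, on_t.d_max),
               n_off=len(off_t), n_on=len(on_t))

    ref_off = _refine(model, off_t, config)
    report.log("refine_off", **ref_off.to_dict())
    ref_on = _refine(on_start if on_start is not None else model, on_t, config)
    report.log("refine_on", **ref_on.to_dict())

    coeff_off = hybrid_coefficients(off_t, ref_off)
    coeff_on = hybrid_coefficients(on_t, ref_on)
    map_off = synthesize_map(expand_to_p1(coeff_off), grid_spacing=spacing,
                             label="off_hybrid")
    map_on = synthesize_map(expand_to_p1(coeff_on), grid_spacing=spacing,
                            label="on_hybrid")

    pose, rmsd = pose_between(ref_off.model, ref_on.model)
    report.log("overlay", pose=pose.to_dict(), rmsd=rmsd)
    map_on_aligned = resample_map(map_on, pose, target_shape=map_off.shape,
                                  target_cell=map_off.cell)
    diff = subtract_maps(map_on_aligned, map_off)
    report.log("subtraction", sigma_off=map_off.sigma, sigma_on=map_on.sigma,
               raw_diff_sigma=diff.sigma,
               raw_diff_max=float(np.abs(diff.values).max()))
    # The rigid overlay aligns the reference copy of the molecule; when the
    # cells differ, symmetry mates are displaced differently and their
    # neighbourhoods carry alignment artifacts, so the final mask keeps
    # only the reference copy's footprint.
    diff, masked_fraction = solvent_mask_map(diff, ref_off.model,
                                             margin=config.mask_margin,
                                             include_symmetry=False)
    region = None
    if config.sigma_region_masked_only:
        region = diff.values != 0
    if diff.values.std() > 0:
        diff, sigma = sigma_scale(diff, region=region)
    else:  # exactly-null difference: nothing to normalize
        sigma = 0.0
    report.log("map", sigma=sigma, masked_fraction=masked_fraction,
               shape=list(diff.shape), grid_spacing=spacing)

    extras = None
    if config.keep_temp_files:
        extras = {
            "refined_off.pdb": ("model", ref_off.model),
            "refined_on.pdb": ("model", ref_on.model),
            "hybrid_off.mtz": ("reflections", coeff_off),
            "hybrid_on.mtz": ("reflections", coeff_on),
            "fo_fc_on.mtz": ("reflections", fo_fc_coefficients(on_t, ref_on)),
        }
    _write_outputs(config, report, diff, "matchmaps_difference.ccp4", extras)
    return diff, report


def _binned_scale(off: ReflectionSet, on: ReflectionSet, n_bins: int = 12
                  ) -> tuple[ReflectionSet, ScaleModel]:
    """Wilson-style scaling of ON onto OFF via shell mean intensities.

    Works across crystal forms: since <|F|^2> scales with the number of
    symmetry copies per cell, each form's shell means are divided by its
    operator count so the per-molecule scattering is compared.
    """
    d_off, d_on = off.d, on.d
    d_min = max(d_off.min(), d_on.min())
    d_max = min(d_off.max(), d_on.max())
    mult_off = len(off.sg.operations())
    mult_on = len(on.sg.operations())
    s2_edges = np.linspace(1 / d_max**2, 1 / d_min**2, n_bins + 1)
    ratios, centers = [], []
    for lo, hi in zip(s2_edges[:-1], s2_edges[1:]):
        m_off = (1 / d_off**2 >= lo) & (1 / d_off**2 < hi)
        m_on = (1 / d_on**2 >= lo) & (1 / d_on**2 < hi)
        if m_off.sum() < 5 or m_on.sum() < 5:
            continue
        i_off = np.mean(off.df["F"].to_numpy()[m_off] ** 2) / mult_off
        i_on = np.mean(on.df["F"].to_numpy()[m_on] ** 2) / mult_on
        ratios.append(0.5 * np.log(i_off / i_on))
        centers.append((lo + hi) / 2)
    if len(ratios) < 3:
        raise ValueError("too few populated shells for binned scaling")
    coef = np.polyfit(np.array(centers) / 4.0, np.array(ratios), 1)
    scale = ScaleModel(k=float(np.exp(coef[1])), b_iso=float(-coef[0]))
    df = on.df.copy()
    factors = scale.factors(on.cell, on.hkl)
    df["F"] = df["F"].to_numpy() * factors
    if "SIGF" in df:
        df["SIGF"] = df["SIGF"].to_numpy() * factors
    return ReflectionSet(df, on.cell, on.sg), scale


def matchmaps_mr(model: Structure, off: ReflectionSet, on: ReflectionSet,
                 placement: Pose | Structure | None = None,
                 config: RunConfig | None = None
                 ) -> tuple[DensityMap, RunReport]:
    """Cross-crystal-form difference map with a supplied ON placement.

    ``placement`` is either a Pose mapping the OFF model into the ON
    crystal frame, or an already-placed Structure in the ON cell.  The
    molecular-replacement *search* is out of scope: without a placement
    this raises.
    """
    if placement is None:
        raise ValueError(
            "matchmaps_mr requires a placement (Pose or placed model); "
            "running a molecular-replacement search is out of scope -- "
            "supply the pose from an external MR program")
    if isinstance(placement, Pose):
        on_start = apply_pose(model.with_cell(on.cell, on.sg), placement)
    else:
        on_start = placement
    return matchmaps_run(model, off, on, config=config, on_start=on_start,
                         scale_mode="binned")


def matchmaps_ncs(model: Structure, refl: ReflectionSet,
                  chain_a: str, chain_b: str,
                  config: RunConfig | None = None
                  ) -> tuple[DensityMap, RunReport]:
    """Internal difference map between two NCS-related chains.

    One dataset, one model: the whole model is rigid-body refined for
    phases, one map is synthesized, and the density around chain B is
    carried through the NCS pose onto chain A's frame and subtracted.
    Positive density = present around chain A but absent at the
    NCS-equivalent position of chain B.
    """
    config = config or RunConfig()
    report = RunReport()
    sel_a = np.where(model.chain_mask(chain_a))[0]
    sel_b = np.where(model.chain_mask(chain_b))[0]
    if len(sel_a) < 3 or len(sel_b) < 3:
        raise ValueError(f"chains {chain_a!r}/{chain_b!r} have fewer than 3 atoms")
    if len(sel_a) != len(sel_b):
        raise ValueError("NCS chains must have matching atom counts/ordering")

    ref = _refine(model, refl, config)
    report.log("refine", **ref.to_dict())
    coeffs = hybrid_coefficients(refl, ref)
    spacing = config.spacing(refl.d_min)
    dmap = synthesize_map(expand_to_p1(coeffs), grid_spacing=spacing,
                          label="ncs_source")
    pose_ncs, rmsd = pose_between(ref.model.select(sel_a),
                                  ref.model.select(sel_b), trim=True)
    report.log("ncs_pose", pose=pose_ncs.to_dict(), rmsd=rmsd)
    mapped_b = resample_map(dmap, pose_ncs)
    diff = subtract_maps(dmap, mapped_b)
    diff, masked_fraction = solvent_mask_map(diff, ref.model.select(sel_a),
                                             margin=config.mask_margin)
    region = diff.values != 0 if config.sigma_region_masked_only else None
    if diff.values.std() > 0:
        diff, sigma = sigma_scale(diff, region=region)
    else:
        sigma = 0.0
    report.log("map", sigma=sigma, masked_fraction=masked_fraction,
               shape=list(diff.shape), grid_spacing=spacing)
    _write_outputs(config, report, diff, "ncs_difference.ccp4")
    return diff, report
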