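# Methods

## The problem

A crystallographic difference map asks: where did electron density appear
or disappear between a reference (OFF) dataset and a perturbed (ON)
dataset?  Only structure-factor *amplitudes* |F(h)| are measured; phases
must come from a model.  The classical isomorphous difference map uses the
coefficients

    dF(h) = (|F_ON,obs(h)| - |F_OFF,obs(h)|) exp(i phi_OFF,calc(h))

and therefore assumes the two crystals are isomorphous — same cell, same
molecular placement — so one set of phases serves both.  Cell changes of
even 1–2% (from temperature, pressure, radiation damage or the
conformational change itself) break this assumption: phases decorrelate at
high resolution and the map fills with packing artifacts.

## The generalized algorithm

Because the Fourier transform and subtraction are both linear, the
difference can equally be formed in real space: synthesize a map per
dataset, align them, subtract voxel-wise.  This reordering removes the
isomorphism requirement, provided each dataset gets phases appropriate to
*its own* cell.  The pipeline (`matchmaps_run`) is:

1. **Scaling** — fit an overall scale k and smearing B minimizing
   `sum w (|F_off| - k exp(-B s^2/4) |F_on|)^2` over the common
   reflections (`scale_datasets`); anisotropic B optional, constrained to
   the lattice symmetry.  Outlier |dF| (beyond 6 robust sigma from the
   MAD) are reported, never removed: large amplitude differences ARE the
   signal.
2. **Truncation** — both datasets cut to the shared resolution range so
   the difference map does not preferentially display the
   higher-resolution dataset's features.
3. **Rigid-body phasing** — the OFF model is refined against each dataset
   allowing only whole-group rotation + translation (per-chain groups
   optional).  Internal geometry is bit-identical before and after; that
   is the no-model-bias guarantee — the resulting phases cannot encode any
   modelled internal change.  Before refining against a dataset the
   model's cell metadata is replaced by the data's cell with orthogonal
   coordinates kept, preserving the molecule's true geometry under a
   changed lattice.
4. **Hybrid coefficients** — per dataset, |F_obs| exp(i phi_rigid); each
   set expanded to P1 and Fourier-synthesized into a full-cell map
   (rho(x) = (1/V) sum_h F(h) exp(-2 pi i h.x)).
5. **Overlay** — Kabsch superposition of the two refined models (trivial
   atom matching: both descend from one parent model) gives the rigid pose
   mapping the ON frame onto the OFF frame; the ON map is pulled through
   it with periodic tricubic-spline interpolation (trilinear optional).
6. **Subtraction** — voxel-wise, ON minus OFF: positive density = more in
   the ON state.
7. **Masking and scaling** — voxels beyond (vdW radius + 1.5 A) of every
   atom of the refined OFF model are zeroed; the map is divided by its
   standard deviation so contour levels read in sigma units.

In the isomorphous limit (identical cells, identity pose) this reduces to
the classical map computed through real space.

Variants: `matchmaps_mr` accepts an externally supplied placement of the
OFF model in a different ON crystal form (the molecular-replacement search
itself is an external step) and proceeds identically; `matchmaps_ncs`
repurposes the real-space half to subtract the density of one
NCS-related chain from another within a single dataset, using a robust
(trimmed) superposition of the two chains for the internal pose.
`fo_fc_coefficients` provides the rigid-body Fo–Fc coefficients
`(|F_obs| - k exp(-Bs^2/4)|F_calc|) exp(i phi_calc)` (unweighted; no
maximum-likelihood m/D weights) for comparison: unlike the generalized
map it inherits every modelling error of the reference model.

## Structure factors

Direct summation (`fcalc_direct`) is the reference:
`F(h) = sum_sym sum_j occ_j f_j(s) exp(-B_j s^2/4) exp(2 pi i h.(Rx_j+t))`
with International-Tables 4-Gaussian form factors (from gemmi's tables;
hydrogens included only if present in the model).  The FFT route samples
each atom as its inverse-transform Gaussians on a grid of spacing
d_min/3, with an anti-aliasing augmentation B_extra chosen so every
Gaussian is attenuated to 1e-5 at the grid Nyquist frequency; B_extra is
divided out exactly in reciprocal space.  The two routes agree to an
amplitude-weighted R below 1e-10 on the test fixtures — far inside the
0.002 documented tolerance.

The flat bulk-solvent model adds
`F_sol(h) = k_sol exp(-B_sol s^2/4) FT[mask](h)`, where the mask is 1
farther than (vdW + 1.0 A probe) from every atom and then eroded back by
1.1 A (Jiang–Brünger style); defaults k_sol = 0.35 e/A^3, B_sol = 46 A^2.
It is on by default in the pipeline and off in the synthetic tests (the
toy data contain no solvent continuum).  During pose optimization the
solvent term is held out and recomputed at the final pose — its gradient
with respect to a rigid pose is negligible at the poses involved, and
recomputing the mask per evaluation would dominate the runtime.

## Rigid-body refinement

Target: unweighted least squares on amplitudes,
`sum (|F_obs| - k exp(-Bs^2/4) |F_calc(pose)|)^2`, with (k, B) re-fitted
log-linearly at every evaluation, making the target invariant to the
overall scale of the data.  Unit weights are deliberate: with
sigma(F) proportional to F, 1/sigma^2 weighting hands the search to the
weakest reflections and decouples the target from the amplitude R-factor.
Parameterization: axis-angle rotation (degrees) about the group centroid
plus an orthogonal-frame translation — no gimbal issues near identity,
and degrees/angstroms give the six parameters comparable scales.

The search is deliberately *local* (rotation bounded at 15 deg,
translation at 5 A around the start): amplitude-only targets possess
distant pseudo-symmetric minima (e.g. near-centrosymmetric mirror poses
with amplitude agreement almost as good as the truth), and the method's
premise is that the model is near-isomorphous or MR-placed.  The schedule:

1. Powell search from the starting pose on data truncated to 4 A, then at
   full resolution (unbounded line searches — scipy's bounded Powell is
   markedly less precise — with out-of-range results discarded).  A
   strict-improvement guard keeps the smaller pose on flat directions:
   pure translation in P1 leaves amplitudes exactly unchanged, and
   without the guard the optimizer drifts along that manifold.
2. If the polished amplitude R still exceeds 0.08 — far above the noise
   floor of a correctly placed rigid model — a coarse joint 6-D grid
   (1 A / 3 deg cells) seeds additional local searches; candidates are
   ranked by amplitude R, and within an R margin of 0.02 the smallest
   pose wins (the near-isomorphism prior resolving near-degenerate mirror
   solutions).
3. A high-precision Powell pass, then trust-region least-squares (LM)
   polish started from the result and from ±0.5 deg perturbations of each
   rotation axis.  Amplitude noise roughens the target into shallow
   micro-minima a fraction of a degree wide; LM descends the deepest
   nearby basin without the ridge-jumping of direction-set methods.

If the final R is worse than the starting R the identity pose is returned
with a warning rather than an error.  On the standard test fixture
(3 deg / 1.5 A perturbation, 12 atoms, 2 A data) recovery is ~1e-6 deg
noiseless and <=0.12 deg / 0.005 A at 5% amplitude noise across seeds.

Multi-chain models refine each chain sequentially with the others fixed,
two sweeps.

## Synthetic crystals

`make_fixture` builds the study conditions: by default 12 atoms (C/N/O/S
mix, B in 8–16 A^2) clustered in ~1/8 of a 30 x 34 x 40 A orthorhombic
cell, space group P2_1 2_1 2_1, amplitudes = exact direct-summation
|F_calc| to 2.0 A (~3000 unique reflections — large enough for stable
scaling and refinement, small enough for seconds-scale summation).  The
ON state applies, in order: atom displacements / additions / removals
(interesting signal), per-axis cell strain, and a rigid pose
(uninteresting packing signal).  Under strain the molecule stays rigid
and its centroid keeps its fractional position — emulating
solvent-dominated cell changes around an unchanged molecule, which is the
physical situation the method addresses.  Noise is multiplicative
Gaussian on amplitudes (approximating counting statistics on strong
data), clipped at zero; reported sigma(F) = 0.02 F.  Identical spec +
seed is bit-identical.

What the fixtures do **not** emulate: solvent continuum scattering,
intensity-space (French–Wilson) statistics, measurement-dependent sigma
models, anisotropic displacement, or the thousands-of-atoms scale of real
proteins.  Passing tests therefore demonstrate the algorithmic
correctness and the bias properties of the method at toy scale, not
performance on real diffraction data.

Scenario sizes used by the validation suite (chosen as the smallest at
which each effect is cleanly expressed): the poorly-isomorphous contrast
uses 80 atoms with one compact S/C/N triad (total 31 electrons, ~4% of
the scattering) displaced 3.6 A — far enough that the cluster's new site
clears its own old footprint, as a real side-chain flip does; the
no-model-bias check uses a 2%-noisy isomorphous pair with one spurious
carbon added to the model only.

## Numerical choices and degenerate cases

- Orthogonalization: PDB convention (a along x, b in the x–y plane).
- Reflections are reduced to gemmi's reciprocal asymmetric unit at read
  time; phases transform as phi(hR) = phi(h) - 360 h.t with Friedel
  conjugation; duplicates after reduction are averaged with a warning.
- Synthesis grid: d_min/3 spacing, FFT-friendly dimensions; coefficients
  within one Nyquist of the grid are rejected as too coarse.
- Friedel consistency of synthesis input is verified through the
  imaginary residue of the synthesized map (>1e-6 of the real part's
  scale is an error); missing mates are completed by conjugation.
- The final difference map is masked around the *reference copy only* of
  the molecule: when cells differ, the rigid overlay aligns one copy and
  the symmetry mates are displaced differently, so their neighbourhoods
  carry alignment artifacts by construction.
- Sigma scaling uses the surviving (unmasked) region by default; the toy
  molecule fills 1–2% of the cell, and a whole-cell sigma over zeroed
  voxels would inflate sigma units several-fold.  (Whole-cell remains an
  option.)
- Cross-form (MR-variant) scaling is Wilson-style on shell mean
  intensities with each form's means divided by its symmetry-operator
  count, since <|F|^2> scales with the number of copies per cell.
  The cross-form null residual is ~15% of map sigma in-mask at toy
  scale — the two lattices sample reciprocal space differently, so
  series-termination ripples do not cancel exactly.
- An exactly-null difference (identical inputs) skips sigma scaling
  (zero variance) and reports sigma = 0.
- In P1, translations are invisible to amplitudes; the refiner's
  strict-improvement guard pins the pose at its start along such flat
  directions instead of drifting.

## Known limitations

- Amplitude least squares, not a maximum-likelihood target; no sigma-A
  weighting.  Pose recovery, not numerical equivalence to any particular
  refinement program, is the validated property.
- The unweighted Fo–Fc map has no m/D weights.
- No anomalous data handling, twinning, or unmerged data.
- Alternate-conformer atoms are kept with their input occupancies during
  rigid-body refinement.
- The bulk-solvent model is the flat two-parameter form; it can flatten
  genuine solvent-region signal (e.g. a large ligand), so it can be
  switched off.
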