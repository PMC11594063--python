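# Methods

This note records what `surfdelta` computes, the assumptions behind each
stage, the parameters that matter, and the choices made where the design
was genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Surface generation

The solvent-excluded surface (SES) is the boundary traced by the inward
face of a probe sphere rolling over the atoms. We compute it on a regular
voxel grid in three steps: (1) the solvent-accessible solid — the union of
atom spheres inflated by the probe radius — is evaluated as a signed
distance field; (2) the depth of interior voxels below the accessible
boundary is measured and shifted by the probe radius, which is exactly the
morphological erosion that converts the accessible surface to the SES;
(3) the zero level of the resulting field is triangulated with marching
cubes (Lewiner variant, which yields watertight, orientation-consistent
meshes).

Numerical accuracy. A plain binary-voxel distance transform quantizes the
accessible boundary to voxel centers, costing up to half a voxel of
surface placement. We avoid most of that error with two exact identities:
outside a union of balls, the distance to the union is exactly
min_i(|x − c_i| − R_i); and the Euclidean distance transform's
nearest-outside-voxel link lets us subtract that voxel's exact overshoot
beyond the true boundary. The corrected field places iso-surface vertices
well inside half a grid cell of the true surface; on an isolated atom
(whose SES is analytically a sphere) the mesh area error is ~2.7% at
0.3 Å spacing and decreases under refinement (asserted in the tests).

Parameters: `grid_spacing` (default 0.5 Å — comparable to the resolution
of grid-based SES tools at desk-scale cost; halving it roughly ×8 the
cost), `probe_radius` (default 1.4 Å, water), `max_voxels` budget
(1.5×10⁸, a guard against accidentally huge grids). Meshing is
deterministic: identical inputs give bit-identical meshes.

Vertex ownership: each vertex is labeled with the residue of the atom
whose *surface* (center distance minus radius) is nearest; ties go to the
lower atom serial. Interior-cavity surfaces, when present, are separate
closed components and are included in global comparisons.

## Electrostatics

The built-in model is a screened Coulomb (Debye–Hückel) sum over partial
charges in a uniform solvent dielectric, reported in k_BT/e_c at the
configured temperature. The prefactor e²/(4πε₀k_BT) is 557.0 Å·k_BT/e_c²
at 300 K (CODATA constants); the inverse Debye length κ follows from
κ² = 2 N_A e² I / (ε₀ ε_r k_B T) with I in mol/L (κ⁻¹ ≈ 7.9 Å at 0.15 M).
Defaults: ε_r = 78.5, I = 0.150 M, T = 300 K — conventional aqueous
values; none of these defaults is privileged by the method, and reports
carry the full configuration.

What this model is not: a Poisson–Boltzmann solution. There is no
low-dielectric solute cavity, so absolute surface potentials are
attenuated relative to PB values. The comparison statistics only require
a consistent potential on both sides of a WT/variant pair; users who want
PB physics import APBS OpenDX grids, which are mapped onto the mesh by
trilinear interpolation (exact for affine fields; vertices outside the
grid are an error by default, clamp-to-edge behind a flag). DX grids are
assumed to be in k_BT/e_c, the APBS default output unit.

## Local region

The local surface of a variant is defined by residues, not by geometric
distance to vertices: every residue with any atom within the cutoff
(default 4.0 Å, inclusive, atom center to atom center) of any atom of the
mutated residue, plus that residue itself; the region's vertices are the
ones those residues own. Hydrogens count when present (flag to exclude);
neighbors on other chains count by default, because surfaces are physical
rather than per-chain (relevant for oligomers). For a WT/variant pair the
residue set is the union of both sides' selections, so both potential
samples describe the same nominal patch; a residue deleted in the variant
contributes atoms only on the WT side. For ensembles, the residue set is
computed once from the first frame and held fixed across conformers so
the region keeps a stable identity while the geometry breathes
(recompute-per-frame is available via the `residues` override).

A fully buried site (no surface vertices in the region) is a real,
reportable outcome and raises a dedicated error rather than returning an
empty sample.

## Resampling statistics

Each iteration draws `n_points` (default 100) values from each side's
potential sample — with replacement by default, so regions smaller than
the draw size remain usable — and computes three two-sample tests:
Welch's t (two-sided, unequal variances), Kolmogorov–Smirnov, and the
midrank two-sample Anderson–Darling. This is repeated `n_iterations`
(default 1000) times with a seeded generator; the whole procedure is
bit-reproducible given the seed. Drawing a fixed number of points per
iteration is what keeps the procedure honest: otherwise any surface
difference could be made arbitrarily significant by measuring the surface
at more vertices or more time points.

AD p-values use the Scholz–Stephens asymptotic interpolation of the
standardized statistic (the k = 2 critical values), evaluated as a
quadratic of log p in the statistic through the published points and
continued *linearly on the log scale* beyond them, never floored or
capped; extrapolated values are flagged in the result. Silent clipping
would hide exactly the extreme signals this method chases. The
interpolation's accuracy is checked in the tests against pooled-
permutation oracles (exhaustive at n = 5+5, 2×10⁴ permutations at
n = 30+30).

Aggregation across iterations is the one genuinely open design point.
Two rules are implemented and every report states which produced its
headline values:

* `median_p` (default): the median of per-iteration p-values. Calibrated
  under the null (it concentrates near 0.5) and robust; its detection
  boundary is where the per-iteration rejection rate crosses 50%, so for
  marginal effects (e.g. a 0.41 k_BT/e_c shift on unit-variance samples,
  where per-iteration AD rejection is ~0.6) its power sits near, not
  comfortably above, that threshold.
* `fisher`: −2Σ log p against χ² with 2·n_iterations d.f. This reaches
  the extreme combined magnitudes that strong surface changes produce,
  but the iterations share the same parent samples and are not
  independent, so it is anti-conservative under the null; the result
  carries an explicit warning saying so.

The effect size, `median_shift` = median(variant) − median(WT), is always
computed on the full samples, never on resamples. Significance is strict:
p < α with α = 0.01 by default. No multiple-testing correction is applied
across variants; reports note this. Degenerate inputs have fixed
conventions: two identical constant samples give p = 1 for every test;
constant unequal samples give p = 0 for t. p-values below 10⁻³⁰⁰ are
serialized as the string `"<1e-300"`, never as float 0.

## Ensembles

Conformers arrive as multi-model PDB files; charges and radii are joined
from a companion PQR by (chain, residue, atom name) — fixed-charge
force-field semantics: conformations change geometry, not charge.
Unmatched atoms fall back to an element radius table with zero charge and
a warning. Frames are superposed onto the first WT frame by Kabsch
alignment over Cα atoms (proper rotation guaranteed; alignment of a frame
onto itself is skipped to avoid numerical noise), and the final quarter
of each trajectory is kept (ceil rule) as the production ensemble.
Replicate trajectories should be concatenated at the frame level before
input. Per-frame region vertex counts are *not* equalized before pooling;
the fixed 100-point draw already prevents frame-count inflation. The
static pipeline is exactly the one-frame special case of the ensemble
pipeline, bit for bit — asserted in the tests.

## Synthetic inputs

The generators produce every input class the pipeline consumes, at a size
where the full surface→potential→statistics chain runs in seconds: toy
"proteins" of 20–60 residues × 3 atoms laid on a wide helix or a sphere
shell (author-style numbering from 1, per-residue formal charges spread
over atoms, residue names chosen so one-letter variant labels are
meaningful), single-site mutants (charge/radius deltas, bounded jitter,
deletions), wobble ensembles (frame 1 unperturbed, Gaussian per-atom
displacement after), and potential-value samples with controlled location
shifts and tail shapes (normal, Student-t heavy tails, symmetric bimodal
with a mode-separation knob for equal-mean shape changes). Coordinates
are rounded to 3 decimals so PQR and PDB serializations are exact.

What the toys do *not* emulate: real protein geometry (packing, secondary
structure, buried cores), force-field charge distributions, or PB
electrostatics. Passing tests therefore demonstrate the correctness and
calibration of the *procedure* — geometry oracles, statistical behaviour,
pipeline plumbing — not the biological accuracy of any particular
variant call; that depends on the quality of the structures, charges and
potentials supplied.

## Problem sizes and determinism

The test suite and the acceptance script run desk-scale problems by
choice: 500 seeded runs for null calibration (the 99% binomial envelope
at α = 0.01 is then roughly 0–2.2% rejection), 20 runs per shift for
power, 12 for the AD-vs-t comparison, toys of 20 residues for the
pipeline. Every stochastic step takes an explicit seed and derives
sub-seeds deterministically from it.

## Known limitations

* The uniform-dielectric potential model understates surface potentials
  relative to PB; comparisons remain valid, absolute values do not.
* The AD p-value beyond the published interpolation range is a log-linear
  extrapolation — a smooth, monotone convention, flagged in results, not
  an exact tail probability.
* Median-p aggregation has a hard power boundary at 50% per-iteration
  rejection (see above); Fisher aggregation trades calibration for
  sensitivity. There is no single rule that is both exactly calibrated
  and maximally sensitive here.
* mmCIF, compressed trajectory formats (DCD/XTC) and PDB writing are out
  of scope, as are shape-based (non-electrostatic) surface descriptors.
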