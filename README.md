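# surfdelta

Score how missense variants change the electrostatics of a protein's
molecular surface — and decide whether the change is statistically real.

Clinical sequencing produces far more missense variants than can be
functionally characterized, and most structure-based annotation ignores
the protein *surface*, where electrostatics govern solubility, binding and
membrane interactions. `surfdelta` implements a standardized, resampling-
based procedure for comparing the surface electrostatic potential of a
wild-type structure against a variant, either on single static structures
or on conformational ensembles (e.g. MD trajectory frames), and reports an
effect size in physical units together with per-test p-values. It is aimed
at structural bioinformaticians triaging variants of uncertain
significance and at anyone quantifying surface-charge differences between
related structures (orthologs, engineered mutants).

## The method

1. **Surface.** A solvent-excluded surface (SES) is built on a regular
   grid: atoms inflated by the probe radius (1.4 Å) give the
   solvent-accessible solid, a signed Euclidean distance field to its
   boundary is eroded by the probe radius, and the zero iso-surface is
   extracted with marching cubes. Each vertex is assigned to the residue
   whose atom surface is nearest.
2. **Potential.** Every vertex gets an electrostatic potential φ in
   k<sub>B</sub>T/e<sub>c</sub>, either from the built-in screened-Coulomb
   (Debye–Hückel) model,

   φ(r) = Σ<sub>i</sub> q<sub>i</sub> e<sup>−κ|r−r<sub>i</sub>|</sup> / (4π ε₀ ε<sub>r</sub> |r−r<sub>i</sub>|),

   with κ from the ionic strength, or by trilinear interpolation of an
   externally computed Poisson–Boltzmann grid (APBS OpenDX format).
3. **Region.** The comparison is *global* (all vertices) or *local*: the
   residues with any atom within 4 Å of the mutated residue (WT ∪ variant
   union), and the vertices they own. For ensembles, region values are
   pooled across conformers after Cα superposition and selection of the
   final quarter of frames.
4. **Statistics.** Each of 1000 iterations draws 100 points from each
   side's potential sample and applies Welch's t test (mean differences),
   Kolmogorov–Smirnov (maximum ECDF difference) and Anderson–Darling
   (tail-weighted ECDF difference). Fixed-size draws keep significance
   from being inflated by simply measuring more surface points.
   Per-iteration p-values are aggregated (median by default, Fisher's
   combination optionally) into p_T, p_KS, p_AD, compared against
   α = 0.01. The effect size is the median potential shift,
   median(variant) − median(WT), on the full samples.

## Worked example

```bash
python examples/01_static_variant_comparison.py
```

builds a 20-residue toy protein, applies a −2e charge flip at residue 7
(a K→D-like substitution) and runs the static local comparison:

```
variant K7D: 396 WT / 396 variant region vertices
median potential shift: -4.773 kBT/ec
p_T  = 1.09e-188
p_KS = 2.21e-59
p_AD = 1.88e-35
significant at alpha=0.01: {'t': True, 'ks': True, 'ad': True}
```

The local surface around the site becomes ~4.8 k<sub>B</sub>T/e<sub>c</sub>
more electronegative — the sign and rough magnitude expected for removing
two positive elementary charges from a small exposed patch — and all three
tests call the change significant. The other examples cover the dynamic
ensemble route (`02`), the geometry/export layer (`03`) and the statistics
layer on controlled distributions (`04`).

Real structures enter the same way: a PQR per side
(`surfdelta compare --wt wt.pqr --mut mut.pqr --site A:306 --wt-aa D
--mut-aa Y`), optionally multi-model PDB ensembles (`--wt-ensemble`,
`--mut-ensemble`) and APBS potential grids (`--wt-dx`, `--mut-dx`).

## Scope

`surfdelta` consumes prepared inputs: PQR files (from e.g. PDB2PQR),
mutant coordinates (from e.g. FoldX), multi-model PDB ensembles (from MD),
and optional APBS grids. It does not run simulations, build mutants, or
solve the Poisson–Boltzmann equation itself. See `docs/methods.md` for
assumptions, parameter choices and limitations.
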