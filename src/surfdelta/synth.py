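"""Synthetic fixtures: toy charged proteins, point mutants, wobble
ensembles and potential-value samples with controlled distributional
differences.

These generators stand in for the real inputs of the pipeline — deposited
or modelled structures, in-silico mutants, and MD trajectory frames — at a
size where the full surface-to-statistics pipeline runs in seconds. They
make no attempt at physically realistic protein geometry or force-field
charges; what they preserve is the *structure* of the problem: residues
with author-style numbering, per-atom charges and radii, single-site
mutants, topologically identical conformers, and location/shape-controlled
potential distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .region import AA_1TO3, SiteSpec
from .structure_io import Ensemble, StructureModel, model_from_atoms, pqr_text

logger = logging.getLogger(__name__)

__all__ = [
    "ToySpec",
    "make_toy_protein",
    "make_mutant",
    "make_wobble_ensemble",
    "sample_potential_pair",
    "write_ensemble_pdb",
]

# Residue names by formal charge so one-letter variant labels are meaningful.
_NAME_BY_CHARGE = {1: "LYS", -1: "ASP", 0: "SER"}
_ATOM_NAMES = ["CA", "CB", "CG", "CD", "CE", "CZ", "CH", "CT"]


@dataclass
class ToySpec:
    """Parameters of a toy charged protein.

    ``charge_pattern`` is cycled over residues (default alternating
    +1 / 0 / -1, a crude mix of basic, polar and acidic residues);
    ``backbone`` lays residues along a helical curve or packs them on a
    sphere shell.
    """

    n_residues: int = 24
    atoms_per_residue: int = 3
    backbone: str = "helix_curve"        # or "sphere_packing"
    charge_pattern: Optional[Sequence[float]] = None
    radius: float = 1.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.atoms_per_residue < 1:
            raise ValueError("atoms_per_residue must be >= 1")
        if self.backbone not in ("helix_curve", "sphere_packing"):
            raise ValueError(f"unknown backbone {self.backbone!r}")


def _residue_centers(spec: ToySpec) -> np.ndarray:
    n = spec.n_residues
    if spec.backbone == "helix_curve":
        # Wide helix: ~100 degrees per residue, generous rise, so residues
        # stay surface-exposed and clearly separated.
        turn = np.deg2rad(100.0)
        angles = turn * np.arange(n)
        helix_radius = 6.0
        rise = 2.2
        return np.column_stack([
            helix_radius * np.cos(angles),
            helix_radius * np.sin(angles),
            rise * np.arange(n),
        ])
    # Fibonacci sphere shell sized so nearest neighbors sit ~6 A apart.
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r_xy = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    theta = golden * i
    shell_radius = max(6.0, 3.3 * np.sqrt(n))
    return shell_radius * np.column_stack(
        [r_xy * np.cos(theta), r_xy * np.sin(theta), z]
    )


# Tetrahedral-ish unit directions for intra-residue atom placement.
_OFFSET_DIRS = np.array([
    [0.0, 0.0, 0.0],
    [1.0, 1.0, 1.0],
    [1.0, -1.0, -1.0],
    [-1.0, 1.0, -1.0],
    [-1.0, -1.0, 1.0],
    [0.0, 1.4, -0.6],
    [1.4, 0.0, 0.6],
    [-0.6, 1.4, 0.0],
]) / np.sqrt(3.0)


def make_toy_protein(spec: ToySpec) -> tuple[StructureModel, str]:
    """Build a toy protein; returns the model and its PQR serialization.

    Residues are numbered from 1 on chain A; each residue's formal charge
    (from ``charge_pattern``) is spread equally over its atoms.
    Deterministic for a given seed. Raises if any two atoms of different
    residues approach closer than the atom radius.
    """
    rng = np.random.default_rng(spec.seed)
    pattern = list(spec.charge_pattern) if spec.charge_pattern is not None else [1.0, 0.0, -1.0]
    centers = _residue_centers(spec)
    atoms = []
    serial = 1
    offset_scale = 1.3
    for r in range(spec.n_residues):
        q_res = pattern[r % len(pattern)]
        name3 = _NAME_BY_CHARGE.get(int(np.sign(q_res)), "SER")
        jitter = rng.uniform(-0.05, 0.05, size=(spec.atoms_per_residue, 3))
        for a in range(spec.atoms_per_residue):
            # Rounded to 3 decimals so PQR and PDB serializations are exact.
            pos = np.round(
                centers[r]
                + offset_scale * _OFFSET_DIRS[a % len(_OFFSET_DIRS)]
                + jitter[a], 3,
            )
            atoms.append(dict(
                serial=serial, name=_ATOM_NAMES[a % len(_ATOM_NAMES)],
                res_name=name3, chain_id="A", res_id=r + 1,
                coord=tuple(pos), charge=q_res / spec.atoms_per_residue,
                radius=spec.radius,
            ))
            serial += 1
    model = model_from_atoms(atoms, source_path=f"toy(seed={spec.seed})")
    _check_overlaps(model, spec.radius)
    return model, pqr_text(model)


def _check_overlaps(model: StructureModel, radius: float) -> None:
    if model.n_atoms < 2:
        return
    d = squareform(pdist(model.coord))
    res = model.residue_index()
    inter = res[:, None] != res[None, :]
    np.fill_diagonal(d, np.inf)
    min_inter = d[inter].min() if inter.any() else np.inf
    if min_inter <= radius:
        raise ValueError(
            f"toy geometry overlap: closest inter-residue atom pair at "
            f"{min_inter:.2f} A <= radius {radius:.2f} A; increase backbone spacing"
        )


def make_mutant(model: StructureModel, site: SiteSpec,
                delta_charge: float = 0.0, delta_radius: float = 0.0,
                displacement: float = 0.0, seed: int = 0) -> StructureModel:
    """Perturb one residue: charge, radius and bounded positional jitter.

    Emulates a point mutation (e.g. a charge-losing D->Y substitution is a
    ``delta_charge`` of +1 on an acidic site). All other residues are
    untouched, bit for bit. ``site.mut_aa == "-"`` deletes the residue.
    """
    mask = (
        (model.chain_id == site.chain_id)
        & (model.res_id == site.residue_number)
        & (model.ins_code == site.insertion_code)
    )
    if not mask.any():
        raise KeyError(
            f"site {site.chain_id}:{site.residue_number} not present in model"
        )
    if site.mut_aa == "-":
        return model.select(~mask)
    mut = model.copy()
    n_site = int(mask.sum())
    mut.charge[mask] = mut.charge[mask] + delta_charge / n_site
    mut.radius[mask] = mut.radius[mask] + delta_radius
    if displacement > 0:
        rng = np.random.default_rng(seed)
        step = rng.normal(size=(n_site, 3))
        step /= np.maximum(np.linalg.norm(step, axis=1, keepdims=True), 1e-12)
        step *= rng.uniform(0, displacement, size=(n_site, 1))
        mut.coord[mask] = np.round(mut.coord[mask] + step, 3)
    if site.mut_aa and site.mut_aa in AA_1TO3:
        mut.res_name[mask] = AA_1TO3[site.mut_aa]
    return mut


def make_wobble_ensemble(model: StructureModel, n_frames: int,
                         amplitude: float, seed: int = 0) -> Ensemble:
    """A fake trajectory: frame 1 is the model, later frames add Gaussian
    per-atom displacement of the given amplitude (Angstrom, std per axis)."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_frames):
        frame = model.copy()
        frame.model_index = i + 1
        if i > 0 and amplitude > 0:
            frame.coord = np.round(
                frame.coord + rng.normal(scale=amplitude, size=frame.coord.shape), 3
            )
        frames.append(frame)
    return Ensemble(models=frames, aligned=False)


def write_ensemble_pdb(ensemble: Ensemble, path) -> None:
    """Write an ensemble as a minimal multi-model PDB (MODEL/ENDMDL blocks).

    Emulates how MD frames arrive from upstream tooling; charges/radii are
    not representable in PDB and must travel in a companion PQR.
    """
    with open(path, "w") as fh:
        for m in ensemble.models:
            fh.write(f"MODEL     {m.model_index:4d}\n")
            for a in m.atoms():
                fh.write(
                    f"ATOM  {a.serial:5d} {a.name:<4s} {a.residue_name:<3s} "
                    f"{a.chain_id:1s}{a.residue_number:4d}"
                    f"{a.insertion_code:1s}   "
                    f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
                    f"{1.0:6.2f}{0.0:6.2f}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def sample_potential_pair(n: int, shift: float, shape: str = "normal",
                          seed: int = 0, mode_scale: float = 1.0) -> tuple:
    """Two potential-value samples with a controlled difference.

    The second sample is the first family location-shifted by ``shift``
    (k_B T / e_c). ``shape`` controls the tails: ``normal`` (unit
    variance), ``heavy_tail`` (Student t, 3 d.f., unit variance) or
    ``bimodal`` (symmetric two-mode mixture). For the bimodal family,
    ``mode_scale`` multiplies the mode separation of the second sample
    only — an equal-mean, equal-median shape change that mean-based tests
    cannot see.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    rng = np.random.default_rng(seed)

    def draw(scale_modes: float, loc: float) -> np.ndarray:
        if shape == "normal":
            return rng.normal(loc=loc, size=n)
        if shape == "heavy_tail":
            return loc + rng.standard_t(df=3, size=n) / np.sqrt(3.0)
        if shape == "bimodal":
            signs = rng.choice([-1.0, 1.0], size=n)
            return loc + signs * 1.5 * scale_modes + rng.normal(scale=0.5, size=n)
        raise ValueError(f"unknown shape {shape!r}")

    x = draw(1.0, 0.0)
    y = draw(mode_scale, shift)
    return x, y
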