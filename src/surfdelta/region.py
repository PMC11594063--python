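"""Local surface selection around a mutated site.

The local region is the set of residues with any atom within a cutoff
(default 4 Angstrom, center-to-center, inclusive) of any atom of the
mutated residue, plus the site itself; the local surface is the set of
mesh vertices owned by those residues. For wild-type/variant pairs the
residue set is the union of both sides' selections so that both potential
samples describe the same nominal patch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import StructureModel
from .surface import SurfaceMesh

logger = logging.getLogger(__name__)

__all__ = [
    "SiteSpec",
    "RegionMask",
    "local_residues",
    "region_vertices",
    "consensus_region",
    "SiteNotFoundError",
    "BuriedRegionError",
    "AA_3TO1",
    "AA_1TO3",
]

DEFAULT_CUTOFF = 4.0  # Angstrom

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}


class SiteNotFoundError(KeyError):
    """The requested residue does not exist in the model."""


class BuriedRegionError(ValueError):
    """The selected residues own no surface vertices (fully buried site)."""


@dataclass(frozen=True)
class SiteSpec:
    """A variant site: chain, author residue number, WT and mutant amino acid.

    ``mut_aa`` of ``"-"`` denotes a deletion (e.g. F135del).
    """

    chain_id: str
    residue_number: int
    insertion_code: str = ""
    wt_aa: Optional[str] = None
    mut_aa: Optional[str] = None

    @property
    def residue_key(self) -> tuple:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def label(self) -> str:
        wt = self.wt_aa or "X"
        mut = "del" if self.mut_aa == "-" else (self.mut_aa or "X")
        return f"{wt}{self.residue_number}{self.insertion_code}{mut}"


@dataclass
class RegionMask:
    """A local region: its residues, the vertices they own, and the cutoff."""

    residues: frozenset
    vertex_indices: np.ndarray
    cutoff: float


def _site_atom_mask(model: StructureModel, site: SiteSpec) -> np.ndarray:
    mask = (
        (model.chain_id == site.chain_id)
        & (model.res_id == site.residue_number)
        & (model.ins_code == site.insertion_code)
    )
    return mask


def resolve_site(model: StructureModel, site: SiteSpec,
                 expect_wt: bool = False) -> np.ndarray:
    """Return the atom mask of the site residue; raise if absent.

    With ``expect_wt=True``, a residue type that contradicts ``site.wt_aa``
    raises; otherwise (the mutant structure, where a different type is the
    point) it only warns when it matches neither wt nor mut.
    """
    mask = _site_atom_mask(model, site)
    if not mask.any():
        available = sorted(
            {int(r) for c, r, i in model.residue_keys() if c == site.chain_id}
        )
        raise SiteNotFoundError(
            f"residue {site.residue_number}{site.insertion_code} not found on "
            f"chain {site.chain_id!r}; available residues: {available}"
        )
    res_name = str(model.res_name[mask][0]).upper()
    one = AA_3TO1.get(res_name)
    if site.wt_aa and one is not None:
        if expect_wt and one != site.wt_aa:
            raise ValueError(
                f"site {site.label}: structure has {res_name} ({one}) at "
                f"{site.chain_id}:{site.residue_number}, expected {site.wt_aa}"
            )
        if not expect_wt and one not in (site.wt_aa, site.mut_aa):
            warnings.warn(
                f"site {site.label}: mutant structure has {res_name} ({one}) at "
                f"{site.chain_id}:{site.residue_number}", stacklevel=2,
            )
    return mask


def local_residues(model: StructureModel, site: SiteSpec,
                   cutoff: float = DEFAULT_CUTOFF,
                   include_hydrogens: bool = True,
                   same_chain_only: bool = False,
                   expect_wt: bool = False) -> frozenset:
    """Residues with any atom within ``cutoff`` of any site atom, plus the site.

    Distances are between atom centers and the cutoff is inclusive
    (a 4.00 A closest pair is in). Hydrogens count when present unless
    excluded; neighbors on other chains count unless ``same_chain_only``.
    """
    site_mask = resolve_site(model, site, expect_wt=expect_wt)
    site_coords = model.coord[site_mask]
    atom_mask = np.ones(model.n_atoms, dtype=bool)
    if not include_hydrogens:
        atom_mask &= ~model.is_hydrogen
        site_coords = model.coord[site_mask & atom_mask]
        if len(site_coords) == 0:
            site_coords = model.coord[site_mask]
    if same_chain_only:
        atom_mask &= model.chain_id == site.chain_id
    d = cdist(model.coord[atom_mask], site_coords).min(axis=1)
    res_index = model.residue_index()[atom_mask]
    keys = model.residue_keys()
    near = {keys[i] for i in np.unique(res_index[d <= cutoff])}
    near.add(site.residue_key)
    return frozenset(near)


def region_vertices(mesh: SurfaceMesh, residues: frozenset) -> np.ndarray:
    """Ascending indices of the vertices owned by the given residues."""
    if mesh.vertex_residue_index is None:
        raise ValueError("mesh vertices are not assigned to residues")
    if not residues:
        raise BuriedRegionError("empty residue set selects no vertices")
    wanted = np.array(
        [key in residues for key in mesh.residue_keys], dtype=bool
    )
    idx = np.flatnonzero(wanted[mesh.vertex_residue_index])
    if idx.size == 0:
        raise BuriedRegionError(
            "region is buried: no surface vertices belong to the selected residues"
        )
    return idx


def consensus_region(wt: StructureModel, mut: StructureModel, site: SiteSpec,
                     cutoff: float = DEFAULT_CUTOFF,
                     wt_mesh: Optional[SurfaceMesh] = None,
                     mut_mesh: Optional[SurfaceMesh] = None,
                     include_hydrogens: bool = True,
                     same_chain_only: bool = False) -> tuple:
    """The shared local region of a WT/variant pair.

    The residue set is the union of each side's cutoff selection so both
    potential samples cover the same nominal patch; a residue deleted in
    the variant simply contributes no variant-side atoms. Returns a
    ``(RegionMask, RegionMask)`` pair; vertex indices are filled in when
    the labeled meshes are supplied and left empty otherwise.
    """
    wt_set = local_residues(wt, site, cutoff, include_hydrogens,
                            same_chain_only, expect_wt=True)
    try:
        mut_set = local_residues(mut, site, cutoff, include_hydrogens,
                                 same_chain_only, expect_wt=False)
    except SiteNotFoundError:
        if site.mut_aa == "-":
            # Deleted site: the variant-side selection is anchored on the
            # WT-derived residue set alone.
            mut_set = frozenset()
        else:
            raise
    union = wt_set | mut_set
    wt_names = _residue_name_map(wt)
    mut_names = _residue_name_map(mut)
    for key in sorted(union, key=lambda k: (k[0], k[1], k[2])):
        if key == site.residue_key:
            continue
        a, b = wt_names.get(key), mut_names.get(key)
        if a is not None and b is not None and a != b:
            raise ValueError(
                f"residue numbering mismatch in region: {key} is {a} in WT "
                f"but {b} in variant"
            )
        if a is None or b is None:
            warnings.warn(
                f"region residue {key} is present in only one structure",
                stacklevel=2,
            )
    masks = []
    for mesh in (wt_mesh, mut_mesh):
        if mesh is None:
            idx = np.array([], dtype=np.intp)
        else:
            idx = region_vertices(mesh, union)
        masks.append(RegionMask(residues=union, vertex_indices=idx, cutoff=cutoff))
    logger.info("consensus_region: %s -> %d residues (%d WT / %d variant vertices)",
                site.label, len(union),
                len(masks[0].vertex_indices), len(masks[1].vertex_indices))
    return masks[0], masks[1]


def _residue_name_map(model: StructureModel) -> dict:
    names = {}
    for key, name in zip(
        zip(model.chain_id, model.res_id, model.ins_code), model.res_name
    ):
        names.setdefault((str(key[0]), int(key[1]), str(key[2])), str(name))
    return names
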