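"""Conformational-ensemble handling: superposition, production-frame
selection, and pooling of local surface potentials across conformers.

Dynamic-mode comparisons treat a protein as the set of conformers visited
by a simulation rather than a single structure. Each kept frame gets its
own surface and potential; the potential values of the local region are
pooled over frames ("combined values across time") and the pooled samples
are what the resampling comparison consumes. The region's residue set is
fixed from the first frame so the region keeps a stable identity while
the geometry breathes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .electrostatics import ElectrostaticsConfig, screened_coulomb_potential
from .region import BuriedRegionError, RegionMask, SiteSpec, local_residues, region_vertices
from .structure_io import Ensemble, StructureModel
from .surface import SurfaceConfig, SurfaceMesh, assign_vertices_to_residues, compute_ses

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleSurfaceSet",
    "kabsch_superpose",
    "align_ensemble",
    "select_production_frames",
    "ensemble_region_values",
]


@dataclass
class EnsembleSurfaceSet:
    """Per-conformer surfaces plus the pooled region potential sample."""

    conformer_meshes: list
    frame_indices: list
    region: RegionMask
    pooled_values: np.ndarray
    frame_tags: np.ndarray     # source frame index of each pooled value

    def __post_init__(self) -> None:
        if len(self.conformer_meshes) != len(self.frame_indices):
            raise ValueError("one mesh per kept frame required")
        if len(self.pooled_values) != len(self.frame_tags):
            raise ValueError("every pooled value needs a frame tag")


def _matched_selection(mobile: StructureModel, reference: StructureModel,
                       selection: str) -> tuple[np.ndarray, np.ndarray]:
    def keys(m):
        out = {}
        for i, (c, r, ic, n) in enumerate(m.atom_keys()):
            if selection == "all" or n == selection:
                out[(c, r, ic, n)] = i
        return out

    mob, ref = keys(mobile), keys(reference)
    common = [k for k in ref if k in mob]
    ref_idx = np.array([ref[k] for k in common], dtype=np.intp)
    mob_idx = np.array([mob[k] for k in common], dtype=np.intp)
    return mobile.coord[mob_idx], reference.coord[ref_idx]


def kabsch_superpose(mobile: StructureModel, reference: StructureModel,
                     selection: str = "CA") -> tuple[StructureModel, float]:
    """Least-squares rigid superposition (Kabsch) onto a reference.

    Atoms are matched by (chain, residue number, insertion code, atom
    name) restricted to ``selection`` (an atom name, typically "CA", or
    "all"). Returns the transformed copy of ``mobile`` and the RMSD over
    the matched selection. The rotation is always proper (determinant +1).
    """
    mob_sel, ref_sel = _matched_selection(mobile, reference, selection)
    if len(mob_sel) < 3:
        raise ValueError(
            f"superposition needs >= 3 matched '{selection}' atoms, "
            f"found {len(mob_sel)}"
        )
    mob_centroid = mob_sel.mean(axis=0)
    ref_centroid = ref_sel.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_sel - ref_centroid, mob_sel - mob_centroid)
    out = mobile.copy()
    out.coord = rot.apply(mobile.coord - mob_centroid) + ref_centroid
    moved_sel = rot.apply(mob_sel - mob_centroid) + ref_centroid
    rmsd = float(np.sqrt(np.mean(np.sum((moved_sel - ref_sel) ** 2, axis=1))))
    return out, rmsd


def align_ensemble(ensemble: Ensemble, reference: Optional[StructureModel] = None,
                   selection: str = "CA") -> Ensemble:
    """Superpose every frame onto a reference (frame 1 by default)."""
    ref = reference if reference is not None else ensemble.models[0]
    aligned = []
    for m in ensemble.models:
        if np.array_equal(m.coord, ref.coord):
            # Already coincident (e.g. the reference itself): avoid the
            # numerical noise of applying a near-identity rotation.
            aligned.append(m.copy())
            continue
        moved, rmsd = kabsch_superpose(m, ref, selection=selection)
        logger.debug("align_ensemble: frame %d RMSD %.3f A", m.model_index, rmsd)
        aligned.append(moved)
    return Ensemble(models=aligned, aligned=True)


def select_production_frames(ensemble: Ensemble, fraction: float = 0.25) -> Ensemble:
    """Keep the final fraction of the trajectory (ceil rule, order kept).

    The default quarter discards the equilibration phase of a simulation;
    a fraction of 1 keeps everything.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if ensemble.n_models == 0:
        raise ValueError("empty ensemble")
    keep = ceil(fraction * ensemble.n_models)
    return Ensemble(models=ensemble.models[-keep:], aligned=ensemble.aligned)


def ensemble_region_values(ensemble: Ensemble, site: Optional[SiteSpec],
                           e_cfg: Optional[ElectrostaticsConfig] = None,
                           s_cfg: Optional[SurfaceConfig] = None,
                           cutoff: float = 4.0,
                           residues: Optional[frozenset] = None,
                           global_surface: bool = False) -> EnsembleSurfaceSet:
    """Surface the conformers and pool the local-region potentials.

    The residue set is taken from ``residues`` when given (e.g. a
    WT/variant consensus), otherwise computed once from frame 1 and held
    fixed across conformers. Frames in which the region is buried
    contribute no values (logged); a region buried in every frame is an
    error. With ``global_surface=True`` all vertices are pooled and no
    site is needed.
    """
    e_cfg = e_cfg or ElectrostaticsConfig()
    s_cfg = s_cfg or SurfaceConfig()
    if ensemble.n_models == 0:
        raise ValueError("empty ensemble")
    work = ensemble if ensemble.aligned else align_ensemble(ensemble)

    frame1 = work.models[0]
    if global_surface:
        region_set = frozenset(frame1.residue_keys())
    elif residues is not None:
        region_set = frozenset(residues)
    else:
        if site is None:
            raise ValueError("a site (or explicit residue set) is required")
        region_set = local_residues(frame1, site, cutoff=cutoff)

    meshes, frame_ids, values, tags = [], [], [], []
    n_buried = 0
    for m in work.models:
        mesh = compute_ses(m, grid_spacing=s_cfg.grid_spacing,
                           probe_radius=s_cfg.probe_radius,
                           max_voxels=s_cfg.max_voxels)
        mesh = assign_vertices_to_residues(mesh, m)
        phi = screened_coulomb_potential(m, mesh.vertices, e_cfg)
        mesh = mesh.with_potential(phi)
        meshes.append(mesh)
        frame_ids.append(m.model_index)
        try:
            idx = region_vertices(mesh, region_set)
        except BuriedRegionError:
            n_buried += 1
            logger.info("ensemble_region_values: region buried in frame %d",
                        m.model_index)
            continue
        values.append(phi[idx])
        tags.append(np.full(len(idx), m.model_index, dtype=np.int64))
    if n_buried == ensemble.n_models:
        raise BuriedRegionError("region is buried in every conformer")
    pooled = np.concatenate(values) if values else np.array([])
    tag_arr = np.concatenate(tags) if tags else np.array([], dtype=np.int64)
    try:
        frame1_idx = region_vertices(meshes[0], region_set)
    except BuriedRegionError:
        frame1_idx = np.array([], dtype=np.intp)
    region = RegionMask(residues=region_set, vertex_indices=frame1_idx,
                        cutoff=cutoff)
    logger.info("ensemble_region_values: %d frames, %d pooled values "
                "(%d buried frames)", ensemble.n_models, len(pooled), n_buried)
    return EnsembleSurfaceSet(
        conformer_meshes=meshes, frame_indices=frame_ids,
        region=region, pooled_values=pooled, frame_tags=tag_arr,
    )
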