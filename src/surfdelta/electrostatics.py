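"""Electrostatic potential on molecular surfaces.

Two routes attach a potential (in k_B T / e_c) to surface vertices:

* a built-in screened-Coulomb (Debye-Hueckel) model evaluated directly from
  the atomic partial charges,

      phi(r) = sum_i q_i * exp(-kappa * |r - r_i|) / (4 pi eps0 eps_r |r - r_i|)

  with the Debye parameter kappa derived from ionic strength, solvent
  dielectric and temperature. This is a uniform-dielectric model: it has no
  low-dielectric solute cavity, so absolute values near the surface differ
  from a Poisson-Boltzmann solution, while the comparative statistics
  downstream only need a consistent potential on both sides of a
  wild-type/variant pair.

* trilinear interpolation of an externally computed potential grid (OpenDX
  as written by APBS), for users who want full Poisson-Boltzmann physics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .structure_io import PotentialGrid, StructureModel
from .surface import SurfaceMesh

logger = logging.getLogger(__name__)

__all__ = [
    "ElectrostaticsConfig",
    "screened_coulomb_potential",
    "map_grid_to_mesh",
    "potential_distribution",
    "potential_grid_from_model",
    "debye_kappa",
    "coulomb_prefactor",
    "PointOnAtomError",
]

# CODATA 2018 constants (SI)
ELEMENTARY_CHARGE = 1.602176634e-19   # C
EPSILON_0 = 8.8541878128e-12          # F / m
BOLTZMANN = 1.380649e-23              # J / K
AVOGADRO = 6.02214076e23              # 1 / mol

_MIN_DISTANCE = 1e-6  # Angstrom; evaluation points may not sit on atom centers


class PointOnAtomError(ValueError):
    """An evaluation point coincides with an atom center."""


@dataclass
class ElectrostaticsConfig:
    """Physics parameters for the built-in potential model.

    ``solvent_dielectric`` 78.5 and ``ionic_strength`` 0.150 mol/L are the
    conventional aqueous-physiology values; ``temperature`` 300 K matches
    typical simulation thermostats.
    """

    mode: str = "screened_coulomb"        # or "dx_grid"
    solvent_dielectric: float = 78.5
    ionic_strength: float = 0.150          # mol / L
    temperature: float = 300.0             # K

    def __post_init__(self) -> None:
        if self.mode not in ("screened_coulomb", "dx_grid"):
            raise ValueError(f"unknown electrostatics mode {self.mode!r}")
        if self.solvent_dielectric < 1:
            raise ValueError("solvent_dielectric must be >= 1")
        if self.ionic_strength < 0:
            raise ValueError("ionic_strength must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def coulomb_prefactor(temperature: float) -> float:
    """e_c^2 / (4 pi eps0 k_B T) in Angstrom * (k_B T / e_c) per unit charge.

    This is the Bjerrum-length-style prefactor: the potential of a unit
    charge at distance d (Angstrom) in a medium of dielectric eps_r is
    ``prefactor / (eps_r * d)`` in units of k_B T / e_c.
    """
    joule_metre = ELEMENTARY_CHARGE**2 / (4 * np.pi * EPSILON_0)
    return joule_metre / (BOLTZMANN * temperature) * 1e10


def debye_kappa(ionic_strength: float, solvent_dielectric: float,
                temperature: float) -> float:
    """Inverse Debye length in 1/Angstrom.

    kappa^2 = 2 N_A e^2 I / (eps0 eps_r k_B T), with the ionic strength I
    converted from mol/L to 1/m^3. Zero ionic strength gives kappa = 0
    (plain Coulomb).
    """
    if ionic_strength == 0:
        return 0.0
    number_density = ionic_strength * 1000.0 * AVOGADRO  # 1 / m^3
    kappa_sq = (
        2 * number_density * ELEMENTARY_CHARGE**2
        / (EPSILON_0 * solvent_dielectric * BOLTZMANN * temperature)
    )
    return float(np.sqrt(kappa_sq) * 1e-10)


def screened_coulomb_potential(model: StructureModel,
                               points: np.ndarray,
                               cfg: Optional[ElectrostaticsConfig] = None,
                               chunk: int = 2048) -> np.ndarray:
    """Debye-Hueckel potential of the model's charges at each point.

    Returns one value per point in k_B T / e_c at ``cfg.temperature``.
    Linear in the charges; reduces to plain Coulomb at zero ionic strength.
    """
    cfg = cfg or ElectrostaticsConfig()
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    pref = coulomb_prefactor(cfg.temperature) / cfg.solvent_dielectric
    kappa = debye_kappa(cfg.ionic_strength, cfg.solvent_dielectric, cfg.temperature)
    out = np.empty(len(points))
    for start in range(0, len(points), chunk):
        pp = points[start:start + chunk]
        d = np.linalg.norm(pp[:, None, :] - model.coord[None, :, :], axis=2)
        too_close = d < _MIN_DISTANCE
        if too_close.any():
            i, j = np.argwhere(too_close)[0]
            raise PointOnAtomError(
                f"evaluation point {start + i} at {pp[i]} coincides with atom "
                f"serial {model.serial[j]} (distance < {_MIN_DISTANCE} A)"
            )
        if kappa > 0:
            contrib = model.charge[None, :] * np.exp(-kappa * d) / d
        else:
            contrib = model.charge[None, :] / d
        out[start:start + chunk] = pref * contrib.sum(axis=1)
    return out


def map_grid_to_mesh(grid: PotentialGrid, mesh: SurfaceMesh,
                     clamp: bool = False) -> SurfaceMesh:
    """Attach per-vertex potential by trilinear interpolation of a grid.

    Every vertex must lie inside the grid box; with ``clamp=True``,
    out-of-box vertices are instead clipped to the box edge and a warning
    reports how many.
    """
    verts = mesh.vertices
    lo = grid.origin
    hi = grid.upper_corner
    under = lo[None, :] - verts
    over = verts - hi[None, :]
    overshoot = np.maximum(under, over).max(axis=1)
    outside = overshoot > 0
    if outside.any():
        n_out = int(outside.sum())
        worst = float(overshoot.max())
        msg = (f"{n_out} of {len(verts)} vertices lie outside the potential grid "
               f"(worst overshoot {worst:.3f} A)")
        if not clamp:
            raise ValueError(msg + "; enlarge the grid or pass clamp=True")
        warnings.warn(msg + "; clamping to the grid edge", stacklevel=2)
        verts = np.clip(verts, lo, hi)
    interp = RegularGridInterpolator(grid.axes, grid.values, method="linear",
                                     bounds_error=False, fill_value=None)
    return mesh.with_potential(interp(verts))


def potential_distribution(mesh: SurfaceMesh,
                           vertex_subset: Optional[Sequence[int]] = None) -> np.ndarray:
    """The multiset of per-vertex potentials, in vertex order.

    ``vertex_subset`` restricts to the given vertex indices (e.g. a local
    region); the whole surface is used when absent.
    """
    if mesh.vertex_potential is None:
        raise ValueError("mesh has no vertex_potential; map a potential first")
    if vertex_subset is None:
        return mesh.vertex_potential.copy()
    idx = np.asarray(vertex_subset, dtype=np.intp)
    if idx.size == 0:
        raise ValueError("empty vertex subset")
    if idx.min() < 0 or idx.max() >= mesh.n_vertices:
        raise IndexError(
            f"vertex subset index out of range 0..{mesh.n_vertices - 1}"
        )
    return mesh.vertex_potential[idx]


def potential_grid_from_model(model: StructureModel,
                              cfg: Optional[ElectrostaticsConfig] = None,
                              spacing: float = 0.5,
                              padding: float = 5.0) -> PotentialGrid:
    """Sample the screened-Coulomb potential of a model onto a regular grid.

    Convenience for tests and for exporting OpenDX files; the grid covers
    the model's bounding box plus ``padding`` on each side.
    """
    cfg = cfg or ElectrostaticsConfig()
    lo = model.coord.min(axis=0) - padding
    hi = model.coord.max(axis=0) + padding
    counts = np.ceil((hi - lo) / spacing).astype(int) + 1
    axes = [lo[d] + spacing * np.arange(counts[d]) for d in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    vals = screened_coulomb_potential(model, pts, cfg)
    return PotentialGrid(origin=lo, spacing=np.full(3, spacing),
                         counts=tuple(counts), values=vals.reshape(tuple(counts)))
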