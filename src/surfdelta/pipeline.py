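"""Orchestration: run configuration, the end-to-end comparison, batch
tables and machine-readable reports.

A run compares the wild-type to one variant, globally (whole surface) or
locally (the region around the mutated site), on static structures or on
pooled dynamic ensembles — the four comparison designs. The report carries
the three aggregated p-values, the median potential shift, sample sizes,
and a configuration fingerprint so every number is regenerable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .electrostatics import (ElectrostaticsConfig, map_grid_to_mesh,
                             potential_distribution, screened_coulomb_potential)
from .ensemble import align_ensemble, ensemble_region_values, select_production_frames
from .region import SiteSpec, consensus_region, local_residues, region_vertices
from .resample_stats import (ComparisonResult, ResamplingConfig, format_p,
                             is_significant, resampled_comparison)
from .structure_io import (Ensemble, apply_pqr_charges, read_dx_grid,
                           read_pdb_models, read_pqr, write_mesh)
from .surface import SurfaceConfig, assign_vertices_to_residues, compute_ses

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "VariantReport", "run_compare", "batch_table",
           "write_batch_tsv", "validate_report", "REPORT_FIELDS"]

TSV_COLUMNS = ["protein", "variant", "level", "p_T", "p_AD", "p_KS", "median_shift"]

# Required keys and types of a JSON report (lightweight schema).
REPORT_FIELDS = {
    "variant": str, "protein": str, "mode": str, "level": str,
    "n_wt": int, "n_mut": int,
    "median_wt": float, "median_mut": float, "median_shift": float,
    "p_T": (float, str), "p_KS": (float, str), "p_AD": (float, str),
    "significant": dict, "alpha": float, "aggregation": str,
    "config_fingerprint": str, "seed": int, "version": str,
    "warnings": list,
}


@dataclass
class RunConfig:
    """Everything one comparison run needs.

    ``mode`` chooses the surface extent (global vs. the local site
    region); ``level`` chooses static single structures vs. pooled
    dynamic ensembles (which require multi-model PDBs plus companion PQR
    charge templates on both sides).
    """

    wt_pqr: str = ""
    mut_pqr: str = ""
    mode: str = "local"                 # "global" | "local"
    level: str = "static"               # "static" | "dynamic"
    site: Optional[SiteSpec] = None
    wt_ensemble: str = ""               # multi-model PDB paths (dynamic level)
    mut_ensemble: str = ""
    wt_dx: str = ""                     # optional external potential grids
    mut_dx: str = ""
    cutoff: float = 4.0
    production_fraction: float = 0.25
    resampling: ResamplingConfig = field(default_factory=ResamplingConfig)
    electrostatics: ElectrostaticsConfig = field(default_factory=ElectrostaticsConfig)
    surface: SurfaceConfig = field(default_factory=SurfaceConfig)
    protein: str = ""
    out_dir: str = ""
    write_surfaces: bool = False
    include_hydrogens: bool = True
    same_chain_only: bool = False

    def validate(self) -> None:
        if self.mode not in ("global", "local"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.level not in ("static", "dynamic"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.mode == "local" and self.site is None:
            raise ValueError("local mode requires a site specification")
        if self.level == "dynamic" and not (self.wt_ensemble and self.mut_ensemble):
            raise ValueError("dynamic level requires ensembles on both sides")
        if not (self.wt_pqr and self.mut_pqr):
            raise ValueError("WT and variant PQR paths are required")

    def fingerprint(self) -> str:
        payload = _as_jsonable(self)
        # output destination does not affect the science
        payload.pop("out_dir", None)
        payload.pop("write_surfaces", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    return obj


@dataclass
class VariantReport:
    """One comparison outcome in the shape of a results-table row."""

    variant: str
    protein: str
    mode: str
    level: str
    result: ComparisonResult
    config_fingerprint: str
    seed: int
    warnings: list = field(default_factory=list)

    @property
    def median_shift(self) -> float:
        return self.result.median_shift

    def significant(self) -> dict:
        return self.result.significant()

    def to_dict(self) -> dict:
        r = self.result

        def render(p: float):
            return "<1e-300" if p < 1e-300 else p

        return {
            "variant": self.variant,
            "protein": self.protein,
            "mode": self.mode,
            "level": self.level,
            "n_wt": r.n_wt,
            "n_mut": r.n_mut,
            "median_wt": r.median_wt,
            "median_mut": r.median_mut,
            "median_shift": r.median_shift,
            "p_T": render(r.p_t),
            "p_KS": render(r.p_ks),
            "p_AD": render(r.p_ad),
            "ad_extrapolated": r.ad_extrapolated,
            "significant": r.significant(),
            "alpha": r.config.alpha,
            "aggregation": r.config.aggregation,
            "n_points": r.config.n_points,
            "n_iterations": r.config.n_iterations,
            "config_fingerprint": self.config_fingerprint,
            "seed": self.seed,
            "version": _pkg_version,
            "warnings": list(self.warnings) + list(r.warnings),
        }

    def to_tsv_row(self) -> dict:
        r = self.result
        return {
            "protein": self.protein,
            "variant": self.variant,
            "level": self.level,
            "p_T": format_p(r.p_t),
            "p_AD": format_p(r.p_ad),
            "p_KS": format_p(r.p_ks),
            "median_shift": f"{r.median_shift:+.4f}",
        }


def validate_report(report: dict) -> None:
    """Check a report dict against the bundled field schema."""
    for key, typ in REPORT_FIELDS.items():
        if key not in report:
            raise ValueError(f"report missing required field {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(
                f"report field {key!r} has type {type(report[key]).__name__}, "
                f"expected {typ}"
            )
    for p_key in ("p_T", "p_KS", "p_AD"):
        v = report[p_key]
        if isinstance(v, float) and not 0 <= v <= 1:
            raise ValueError(f"{p_key} outside [0, 1]")


def _static_surface_values(model, cfg: RunConfig, dx_path: str):
    t0 = time.perf_counter()
    mesh = compute_ses(model, grid_spacing=cfg.surface.grid_spacing,
                       probe_radius=cfg.surface.probe_radius,
                       max_voxels=cfg.surface.max_voxels)
    mesh = assign_vertices_to_residues(mesh, model)
    if dx_path:
        grid = read_dx_grid(dx_path)
        mesh = map_grid_to_mesh(grid, mesh, clamp=True)
    else:
        mesh = mesh.with_potential(
            screened_coulomb_potential(model, mesh.vertices, cfg.electrostatics)
        )
    logger.info("surface+potential: %d vertices in %.2f s",
                mesh.n_vertices, time.perf_counter() - t0)
    return mesh


def run_compare(cfg: RunConfig) -> VariantReport:
    """Run one full WT-vs-variant comparison.

    Reads structures, builds surfaces and potentials, selects the region
    (local mode), pools over conformers (dynamic level), runs the
    resampling comparison, and optionally writes JSON/TSV/PLY outputs to
    ``cfg.out_dir``. Deterministic for a given seed.
    """
    cfg.validate()
    warnings_list: list[str] = []
    if cfg.electrostatics.mode == "screened_coulomb" and not (cfg.wt_dx or cfg.mut_dx):
        warnings_list.append(
            "potentials from the built-in screened-Coulomb model "
            "(uniform dielectric, no solute cavity); import APBS DX grids "
            "for Poisson-Boltzmann physics"
        )

    wt_model = read_pqr(cfg.wt_pqr)
    mut_model = read_pqr(cfg.mut_pqr)

    if cfg.level == "static":
        wt_mesh = _static_surface_values(wt_model, cfg, cfg.wt_dx)
        mut_mesh = _static_surface_values(mut_model, cfg, cfg.mut_dx)
        if cfg.mode == "local":
            wt_mask, mut_mask = consensus_region(
                wt_model, mut_model, cfg.site, cutoff=cfg.cutoff,
                wt_mesh=wt_mesh, mut_mesh=mut_mesh,
                include_hydrogens=cfg.include_hydrogens,
                same_chain_only=cfg.same_chain_only,
            )
            wt_vals = potential_distribution(wt_mesh, wt_mask.vertex_indices)
            mut_vals = potential_distribution(mut_mesh, mut_mask.vertex_indices)
        else:
            wt_vals = potential_distribution(wt_mesh)
            mut_vals = potential_distribution(mut_mesh)
        surfaces = {"wt": wt_mesh, "mut": mut_mesh}
    else:
        wt_ens = apply_pqr_charges(read_pdb_models(cfg.wt_ensemble), wt_model)
        mut_ens = apply_pqr_charges(read_pdb_models(cfg.mut_ensemble), mut_model)
        wt_ens = select_production_frames(wt_ens, cfg.production_fraction)
        mut_ens = select_production_frames(mut_ens, cfg.production_fraction)
        # Trajectories are aligned to the initial WT conformation (CA atoms).
        wt_ens = align_ensemble(wt_ens, reference=wt_ens.models[0])
        mut_ens = align_ensemble(mut_ens, reference=wt_ens.models[0])
        if cfg.mode == "local":
            wt_mask, mut_mask = consensus_region(
                wt_ens.models[0], mut_ens.models[0], cfg.site, cutoff=cfg.cutoff,
                include_hydrogens=cfg.include_hydrogens,
                same_chain_only=cfg.same_chain_only,
            )
            residues = wt_mask.residues
            global_surface = False
        else:
            residues = None
            global_surface = True
        wt_set = ensemble_region_values(
            wt_ens, cfg.site, cfg.electrostatics, cfg.surface,
            cutoff=cfg.cutoff, residues=residues, global_surface=global_surface,
        )
        mut_set = ensemble_region_values(
            mut_ens, cfg.site, cfg.electrostatics, cfg.surface,
            cutoff=cfg.cutoff, residues=residues, global_surface=global_surface,
        )
        wt_vals, mut_vals = wt_set.pooled_values, mut_set.pooled_values
        surfaces = {"wt": wt_set.conformer_meshes[0],
                    "mut": mut_set.conformer_meshes[0]}

    result = resampled_comparison(wt_vals, mut_vals, cfg.resampling)
    variant = cfg.site.label if cfg.site is not None else "global"
    report = VariantReport(
        variant=variant, protein=cfg.protein or Path(cfg.wt_pqr).stem,
        mode=cfg.mode, level=cfg.level, result=result,
        config_fingerprint=cfg.fingerprint(), seed=cfg.resampling.seed,
        warnings=warnings_list,
    )
    if cfg.out_dir:
        _write_outputs(report, surfaces, cfg)
    return report


def _write_outputs(report: VariantReport, surfaces: dict, cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        d = report.to_dict()
        validate_report(d)
        json_path = out / f"{report.protein}_{report.variant}_{report.level}.json"
        json_path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
        written.append(json_path)
        tsv_path = json_path.with_suffix(".tsv")
        pd.DataFrame([report.to_tsv_row()])[TSV_COLUMNS].to_csv(
            tsv_path, sep="\t", index=False
        )
        written.append(tsv_path)
        if cfg.write_surfaces:
            for tag, mesh in surfaces.items():
                ply = out / f"{report.protein}_{report.variant}_{tag}.ply"
                write_mesh(mesh, ply, scalar="potential")
                written.append(ply)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def batch_table(configs: list[RunConfig]) -> pd.DataFrame:
    """Run many comparisons and tabulate them (one row per variant).

    Per-row failures are recorded in an ``error`` column and the batch
    continues. The returned frame carries the fraction of variants
    significant by p_AD in ``df.attrs["fraction_significant_ad"]``.
    """
    if not configs:
        raise ValueError("batch_table needs at least one run configuration")
    rows = []
    n_sig = n_ok = 0
    for cfg in configs:
        try:
            rep = run_compare(cfg)
            row = rep.to_tsv_row()
            row["error"] = ""
            n_ok += 1
            if is_significant(rep.result.p_ad, rep.result.config.alpha):
                n_sig += 1
        except Exception as exc:  # per-row failure, batch continues
            row = {c: "" for c in TSV_COLUMNS}
            row["protein"] = cfg.protein
            row["variant"] = cfg.site.label if cfg.site else "global"
            row["level"] = cfg.level
            row["error"] = f"{type(exc).__name__}: {exc}"
            logger.error("batch row failed: %s", row["error"])
        rows.append(row)
    df = pd.DataFrame(rows)[TSV_COLUMNS + ["error"]]
    df.attrs["fraction_significant_ad"] = n_sig / n_ok if n_ok else float("nan")
    df.attrs["n_significant_ad"] = n_sig
    df.attrs["n_ok"] = n_ok
    return df


def write_batch_tsv(df: pd.DataFrame, path) -> None:
    """Write the batch table with a trailing summary comment line."""
    with open(path, "w") as fh:
        df.to_csv(fh, sep="\t", index=False)
        frac = df.attrs.get("fraction_significant_ad", float("nan"))
        fh.write(f"# {df.attrs.get('n_significant_ad', 0)}/"
                 f"{df.attrs.get('n_ok', 0)} variants significant by p_AD "
                 f"(fraction {frac:.3f})\n")
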