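"""Readers and writers for the structural and grid formats the pipeline touches.

Covers PQR (charge/radius-bearing coordinates), multi-model PDB ensembles,
OpenDX scalar potential grids as written by APBS, and ascii PLY surface
export. Parsing is deliberately tolerant of the dialect drift seen in real
files (whitespace vs. fixed-column PQR, CRLF line endings, missing chain
identifiers) but strict about the invariants downstream code relies on:
unique serials, consistent ensemble topology, grid value counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "StructureModel",
    "Ensemble",
    "PotentialGrid",
    "ParseError",
    "TopologyError",
    "UnsupportedFormatError",
    "read_pqr",
    "parse_pqr_text",
    "write_pqr",
    "read_pdb_models",
    "apply_pqr_charges",
    "read_dx_grid",
    "write_mesh",
    "read_mesh",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class TopologyError(ValueError):
    """Models of an ensemble disagree in atom count, order or identity."""


class UnsupportedFormatError(ValueError):
    """A recognised format uses a feature this package does not support."""


# Bondi-style van der Waals radii (Angstrom), used only to back-fill atoms
# that cannot be matched against a PQR template.
ELEMENT_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_RADIUS = 1.70


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[:2].upper() in ELEMENT_RADII:
        return stripped[:2].upper()
    return stripped[:1].upper()


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, position (Angstrom), charge (e) and radius (Angstrom)."""

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    position: np.ndarray
    charge: float
    radius: float

    @property
    def is_hydrogen(self) -> bool:
        return _element_from_name(self.name) == "H"

    @property
    def residue_key(self) -> tuple:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class StructureModel:
    """A single conformer stored as parallel numpy arrays.

    Atom order is file order. ``(chain_id, res_id, ins_code)`` identifies a
    residue; residues are contiguous runs of atoms.
    """

    serial: np.ndarray          # (N,) int
    name: np.ndarray            # (N,) str
    res_name: np.ndarray        # (N,) str
    chain_id: np.ndarray        # (N,) str
    res_id: np.ndarray          # (N,) int
    ins_code: np.ndarray        # (N,) str
    coord: np.ndarray           # (N, 3) float, Angstrom
    charge: np.ndarray          # (N,) float, e
    radius: np.ndarray          # (N,) float, Angstrom
    model_index: int = 1
    source_path: str = ""

    def __post_init__(self) -> None:
        n = len(self.serial)
        if self.coord.shape != (n, 3):
            raise ValueError("coord must be (n_atoms, 3)")
        if n and len(np.unique(self.serial)) != n:
            raise ValueError("atom serials must be unique within a model")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("non-finite coordinates")
        if np.any(self.radius < 0):
            raise ValueError("negative atom radius")

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    @property
    def is_hydrogen(self) -> np.ndarray:
        return np.array([_element_from_name(n) == "H" for n in self.name])

    def net_charge(self) -> float:
        return float(self.charge.sum())

    def residue_keys(self) -> list[tuple]:
        """Residue identifiers in order of first appearance."""
        seen: dict = {}
        for c, r, i in zip(self.chain_id, self.res_id, self.ins_code):
            seen.setdefault((str(c), int(r), str(i)), None)
        return list(seen)

    def residue_index(self) -> np.ndarray:
        """Per-atom index into :meth:`residue_keys`."""
        keys = {k: i for i, k in enumerate(self.residue_keys())}
        return np.array(
            [keys[(str(c), int(r), str(i))]
             for c, r, i in zip(self.chain_id, self.res_id, self.ins_code)],
            dtype=np.intp,
        )

    def atom_keys(self) -> list[tuple]:
        """Per-atom (chain, res_id, ins_code, atom name) identity tuples."""
        return [
            (str(c), int(r), str(i), str(n))
            for c, r, i, n in zip(self.chain_id, self.res_id, self.ins_code, self.name)
        ]

    def atoms(self) -> Iterator[AtomRecord]:
        for i in range(self.n_atoms):
            yield AtomRecord(
                serial=int(self.serial[i]),
                name=str(self.name[i]),
                residue_name=str(self.res_name[i]),
                chain_id=str(self.chain_id[i]),
                residue_number=int(self.res_id[i]),
                insertion_code=str(self.ins_code[i]),
                position=self.coord[i].copy(),
                charge=float(self.charge[i]),
                radius=float(self.radius[i]),
            )

    def select(self, mask: np.ndarray) -> "StructureModel":
        return StructureModel(
            serial=self.serial[mask], name=self.name[mask],
            res_name=self.res_name[mask], chain_id=self.chain_id[mask],
            res_id=self.res_id[mask], ins_code=self.ins_code[mask],
            coord=self.coord[mask], charge=self.charge[mask],
            radius=self.radius[mask], model_index=self.model_index,
            source_path=self.source_path,
        )

    def copy(self) -> "StructureModel":
        return StructureModel(
            serial=self.serial.copy(), name=self.name.copy(),
            res_name=self.res_name.copy(), chain_id=self.chain_id.copy(),
            res_id=self.res_id.copy(), ins_code=self.ins_code.copy(),
            coord=self.coord.copy(), charge=self.charge.copy(),
            radius=self.radius.copy(), model_index=self.model_index,
            source_path=self.source_path,
        )


def model_from_atoms(atoms: Sequence[dict], model_index: int = 1,
                     source_path: str = "") -> StructureModel:
    """Assemble a StructureModel from a sequence of per-atom dicts."""
    return StructureModel(
        serial=np.array([a["serial"] for a in atoms], dtype=np.int64),
        name=np.array([a["name"] for a in atoms], dtype="U6"),
        res_name=np.array([a["res_name"] for a in atoms], dtype="U4"),
        chain_id=np.array([a["chain_id"] for a in atoms], dtype="U4"),
        res_id=np.array([a["res_id"] for a in atoms], dtype=np.int64),
        ins_code=np.array([a.get("ins_code", "") for a in atoms], dtype="U2"),
        coord=np.array([a["coord"] for a in atoms], dtype=np.float64).reshape(-1, 3),
        charge=np.array([a.get("charge", 0.0) for a in atoms], dtype=np.float64),
        radius=np.array([a.get("radius", 0.0) for a in atoms], dtype=np.float64),
        model_index=model_index,
        source_path=source_path,
    )


@dataclass
class Ensemble:
    """An ordered set of conformers sharing one atom topology."""

    models: list[StructureModel]
    aligned: bool = False

    def __post_init__(self) -> None:
        validate_topology(self.models)

    @property
    def n_models(self) -> int:
        return len(self.models)


def validate_topology(models: Sequence[StructureModel]) -> None:
    """Raise TopologyError at the first atom identity mismatch between models."""
    if not models:
        return
    ref = models[0]
    ref_keys = ref.atom_keys()
    for m in models[1:]:
        if m.n_atoms != ref.n_atoms:
            raise TopologyError(
                f"model {m.model_index} has {m.n_atoms} atoms, "
                f"model {ref.model_index} has {ref.n_atoms}"
            )
        for j, (a, b) in enumerate(zip(ref_keys, m.atom_keys())):
            if a != b:
                raise TopologyError(
                    f"model {m.model_index} atom {j + 1}: {b} does not match "
                    f"model {ref.model_index} atom {a}"
                )


@dataclass
class PotentialGrid:
    """Regular 3-D scalar grid with OpenDX gridpositions semantics.

    ``values`` has shape ``counts`` with the z index fastest in the flat
    file layout, i.e. C order over (x, y, z).
    """

    origin: np.ndarray    # (3,) Angstrom
    spacing: np.ndarray   # (3,) Angstrom
    counts: tuple         # (nx, ny, nz)
    values: np.ndarray    # (nx, ny, nz), k_B T / e_c

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        self.counts = tuple(int(c) for c in self.counts)
        self.values = np.asarray(self.values, dtype=np.float64)
        if any(c <= 0 for c in self.counts):
            raise ValueError("grid counts must be positive")
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        if self.values.shape != self.counts:
            raise ValueError(
                f"values shape {self.values.shape} does not match counts {self.counts}"
            )

    @property
    def axes(self) -> tuple:
        return tuple(
            self.origin[d] + self.spacing[d] * np.arange(self.counts[d])
            for d in range(3)
        )

    @property
    def upper_corner(self) -> np.ndarray:
        return self.origin + self.spacing * (np.array(self.counts) - 1)


# ---------------------------------------------------------------------------
# PQR
# ---------------------------------------------------------------------------

def _split_numeric_resid(token: str) -> tuple[int, str]:
    """Split a residue-number token that may carry an insertion code (``52A``)."""
    if token and token[-1].isalpha():
        return int(token[:-1]), token[-1]
    return int(token), ""


def _parse_pqr_line(line: str, lineno: int) -> dict:
    tokens = line.split()
    # Whitespace dialect: ATOM serial name resName [chain] resSeq x y z q r
    if len(tokens) in (10, 11):
        try:
            if len(tokens) == 11:
                _, serial, name, res_name, chain, res_tok = tokens[:6]
                rest = tokens[6:]
            else:
                _, serial, name, res_name, res_tok = tokens[:5]
                chain = ""
                rest = tokens[5:]
            res_id, icode = _split_numeric_resid(res_tok)
            x, y, z, q, r = (float(v) for v in rest[:5])
            return dict(
                serial=int(serial), name=name, res_name=res_name,
                chain_id=chain, res_id=res_id, ins_code=icode,
                coord=(x, y, z), charge=q, radius=r,
            )
        except (ValueError, IndexError):
            pass
    # Fixed-column fallback (PDB columns; charge/radius in the occupancy
    # and temperature-factor fields).
    try:
        return dict(
            serial=int(line[6:11]),
            name=line[12:16].strip(),
            res_name=line[17:20].strip(),
            chain_id=line[21:22].strip(),
            res_id=int(line[22:26]),
            ins_code=line[26:27].strip(),
            coord=(float(line[30:38]), float(line[38:46]), float(line[46:54])),
            charge=float(line[54:62]),
            radius=float(line[62:70]),
        )
    except (ValueError, IndexError):
        raise ParseError(f"line {lineno}: malformed PQR atom record: {line.rstrip()!r}")


def parse_pqr_text(text: str, source_path: str = "") -> StructureModel:
    atoms = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            atoms.append(_parse_pqr_line(line, lineno))
    if not atoms:
        raise ParseError(f"no ATOM/HETATM records found in {source_path or 'input'}")
    return model_from_atoms(atoms, source_path=source_path)


def read_pqr(path) -> StructureModel:
    """Read a PQR file (whitespace or fixed-column dialect) into a model."""
    with open(path, "r", newline=None) as fh:
        text = fh.read()
    model = parse_pqr_text(text, source_path=str(path))
    logger.info("read_pqr: %s -> %d atoms, net charge %+.3f e",
                path, model.n_atoms, model.net_charge())
    return model


def write_pqr(model: StructureModel, path) -> None:
    """Write a whitespace-delimited PQR file (APBS-readable)."""
    with open(path, "w") as fh:
        fh.write(pqr_text(model))


def pqr_text(model: StructureModel) -> str:
    lines = []
    for a in model.atoms():
        res_tok = f"{a.residue_number}{a.insertion_code}"
        lines.append(
            f"ATOM  {a.serial:5d} {a.name:<4s} {a.residue_name:<3s} "
            f"{a.chain_id:<1s} {res_tok:>5s} "
            f"{a.position[0]:10.4f} {a.position[1]:10.4f} {a.position[2]:10.4f} "
            f"{a.charge:12.8f} {a.radius:10.6f}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Multi-model PDB
# ---------------------------------------------------------------------------

def read_pdb_models(path) -> Ensemble:
    """Read a PDB file into an Ensemble (one model per MODEL block).

    A file without MODEL records yields a one-model ensemble. Charges and
    radii are zero; join them from a PQR template with
    :func:`apply_pqr_charges`.
    """
    import biotite.structure.io.pdb as bpdb

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*guessed from atom name.*")
        pdb_file = bpdb.PDBFile.read(str(path))
        n_models = pdb_file.get_model_count()
    if n_models == 0:
        raise ParseError(f"no coordinates found in {path}")
    models = []
    n_ref = None
    for i in range(1, n_models + 1):
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*guessed from atom name.*")
            arr = pdb_file.get_structure(model=i)
        if n_ref is None:
            n_ref = arr.array_length()
        elif arr.array_length() != n_ref:
            raise TopologyError(
                f"model {i} has {arr.array_length()} atoms, model 1 has {n_ref}"
            )
        n = arr.array_length()
        models.append(StructureModel(
            serial=np.arange(1, n + 1, dtype=np.int64),
            name=arr.atom_name.astype("U6"),
            res_name=arr.res_name.astype("U4"),
            chain_id=arr.chain_id.astype("U4"),
            res_id=arr.res_id.astype(np.int64),
            ins_code=arr.ins_code.astype("U2"),
            # biotite keeps float32 coordinates; PDB prints exactly 3
            # decimals, so rounding recovers the file values exactly.
            coord=np.round(np.asarray(arr.coord, dtype=np.float64), 3),
            charge=np.zeros(n),
            radius=np.zeros(n),
            model_index=i,
            source_path=str(path),
        ))
    ensemble = Ensemble(models=models, aligned=False)
    logger.info("read_pdb_models: %s -> %d models x %d atoms",
                path, ensemble.n_models, models[0].n_atoms)
    return ensemble


def apply_pqr_charges(ensemble: Ensemble, template: StructureModel) -> Ensemble:
    """Join charges/radii from a PQR template by (chain, residue, atom name).

    MD trajectories are commonly exported as PDB without charges; force
    fields keep charges fixed over time, so one template serves all frames.
    Unmatched atoms fall back to an element radius table with charge 0 and a
    warning.
    """
    lut = {}
    for a in template.atoms():
        lut[(a.chain_id, a.residue_number, a.insertion_code, a.name)] = (a.charge, a.radius)
    ref = ensemble.models[0]
    charge = np.zeros(ref.n_atoms)
    radius = np.zeros(ref.n_atoms)
    missing = []
    for j, key in enumerate(ref.atom_keys()):
        if key in lut:
            charge[j], radius[j] = lut[key]
        else:
            charge[j] = 0.0
            radius[j] = ELEMENT_RADII.get(_element_from_name(key[3]), DEFAULT_RADIUS)
            missing.append(key)
    if missing:
        warnings.warn(
            f"{len(missing)} atoms not found in PQR template (first: {missing[0]}); "
            "assigned element radii and zero charge",
            stacklevel=2,
        )
    new_models = []
    for m in ensemble.models:
        mm = m.copy()
        mm.charge = charge.copy()
        mm.radius = radius.copy()
        new_models.append(mm)
    return Ensemble(models=new_models, aligned=ensemble.aligned)


# ---------------------------------------------------------------------------
# OpenDX scalar grids
# ---------------------------------------------------------------------------

def read_dx_grid(path) -> PotentialGrid:
    """Read an OpenDX ``gridpositions`` scalar file (APBS potential output).

    Values are stored z-fastest: flat position ``i*ny*nz + j*nz + k`` holds
    grid node ``(i, j, k)``.
    """
    counts = None
    origin = None
    deltas = []
    values: list[float] = []
    in_data = False
    with open(path, "r", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            low = line.lower()
            if low.startswith("object") and "gridpositions" in low:
                toks = line.split()
                try:
                    counts = tuple(int(t) for t in toks[-3:])
                except ValueError:
                    raise ParseError(f"line {lineno}: malformed counts line")
                in_data = False
                continue
            if low.startswith("origin"):
                origin = np.array([float(t) for t in line.split()[1:4]])
                continue
            if low.startswith("delta"):
                deltas.append(np.array([float(t) for t in line.split()[1:4]]))
                continue
            if low.startswith("object") and "class array" in low:
                in_data = "data follows" in low
                continue
            if low.startswith(("object", "attribute", "component", "end")):
                in_data = False
                continue
            if in_data:
                try:
                    values.extend(float(t) for t in line.split())
                except ValueError:
                    raise ParseError(f"line {lineno}: non-numeric grid value")
    if counts is None or origin is None or len(deltas) != 3:
        raise ParseError(f"{path}: missing gridpositions/origin/delta header")
    delta = np.vstack(deltas)
    off_diag = delta - np.diag(np.diag(delta))
    if np.any(off_diag != 0):
        raise UnsupportedFormatError(
            f"{path}: non-orthogonal delta vectors are not supported"
        )
    spacing = np.diag(delta)
    n_expected = int(np.prod(counts))
    if len(values) != n_expected:
        raise ParseError(
            f"{path}: {len(values)} data values but counts {counts} require {n_expected}"
        )
    vals = np.array(values, dtype=np.float64).reshape(counts)  # C order = z fastest
    return PotentialGrid(origin=origin, spacing=spacing, counts=counts, values=vals)


def write_dx_grid(grid: PotentialGrid, path, comment: str = "") -> None:
    """Write a grid back out in OpenDX scalar format (APBS-compatible)."""
    nx, ny, nz = grid.counts
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6e} {:.6e} {:.6e}\n".format(*grid.origin))
        fh.write(f"delta {grid.spacing[0]:.6e} 0.0 0.0\n")
        fh.write(f"delta 0.0 {grid.spacing[1]:.6e} 0.0\n")
        fh.write(f"delta 0.0 0.0 {grid.spacing[2]:.6e}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {nx * ny * nz} "
                 "data follows\n")
        flat = grid.values.reshape(-1)
        for i in range(0, len(flat), 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "regular positions regular connections" class field\n')


# ---------------------------------------------------------------------------
# PLY surface export
# ---------------------------------------------------------------------------

def write_mesh(mesh, path, scalar: str = "potential") -> None:
    """Write a surface mesh as ascii PLY with one per-vertex scalar property.

    ``scalar`` may be ``"potential"`` (requires vertex_potential) or
    ``"residue"`` (the integer residue index per vertex).
    """
    if scalar == "potential":
        if mesh.vertex_potential is None:
            raise ValueError("mesh has no vertex_potential attached")
        values = np.asarray(mesh.vertex_potential, dtype=np.float64)
        prop = "property float potential"
        fmt = "{:.6e}"
    elif scalar == "residue":
        if mesh.vertex_residue_index is None:
            raise ValueError("mesh has no residue assignment")
        values = mesh.vertex_residue_index
        prop = "property int residue"
        fmt = "{:d}"
    else:
        raise ValueError(f"unknown per-vertex scalar {scalar!r}")
    v = np.asarray(mesh.vertices, dtype=np.float64)
    f = np.asarray(mesh.faces, dtype=np.int64)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(v)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(prop + "\n")
        fh.write(f"element face {len(f)}\n")
        fh.write("property list uchar int vertex_indices\n")
        fh.write("end_header\n")
        for (x, y, z), val in zip(v, values):
            fh.write(f"{x:.6e} {y:.6e} {z:.6e} " + fmt.format(val) + "\n")
        for a, b, c in f:
            fh.write(f"3 {a} {b} {c}\n")


def read_mesh(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read back an ascii PLY written by :func:`write_mesh`.

    Returns (vertices, faces, scalar values).
    """
    with open(path, "r", newline=None) as fh:
        lines = fh.read().splitlines()
    n_v = n_f = None
    header_end = None
    for i, line in enumerate(lines):
        if line.startswith("element vertex"):
            n_v = int(line.split()[-1])
        elif line.startswith("element face"):
            n_f = int(line.split()[-1])
        elif line.strip() == "end_header":
            header_end = i
            break
    if n_v is None or n_f is None or header_end is None:
        raise ParseError(f"{path}: not a PLY file written by write_mesh")
    verts = np.array(
        [[float(t) for t in lines[header_end + 1 + j].split()] for j in range(n_v)]
    )
    faces = np.array(
        [[int(t) for t in lines[header_end + 1 + n_v + j].split()[1:4]]
         for j in range(n_f)], dtype=np.int64,
    ).reshape(n_f, 3)
    return verts[:, :3], faces, verts[:, 3]
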