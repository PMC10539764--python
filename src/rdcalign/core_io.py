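"""Domain types and file I/O for small-molecule RDC analysis.

Formats handled here:

* PDB (``ATOM``/``HETATM`` subset) for solute and medium-particle structures,
* plain-text RDC tables (whitespace columns ``atomA atomB D sigma``, ``#``
  comments; extra leading residue/segment columns as written by PALES are
  tolerated by ignoring them),
* OpenDX scalar grids as produced by APBS (z index varies fastest in the
  data block),
* two-column atomic partial-charge files (``name charge``).

All coordinates are Cartesian Å; potentials are kT/e; couplings are Hz.
Parsers raise :class:`ParseError` (with a location) on malformed input —
they never silently truncate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .constants import vdw_radius

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Molecule",
    "RDCRecord",
    "RDCSet",
    "PotentialGrid",
    "MediumModel",
    "ParseError",
    "read_pdb",
    "write_pdb",
    "read_rdc_table",
    "write_rdc_table",
    "read_dx",
    "write_dx",
    "read_charges",
]


class ParseError(ValueError):
    """Malformed input file; message carries file and line context."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    """A solute atom: name, element, position (Å), vdW radius (Å), charge (e)."""

    name: str
    element: str
    position: np.ndarray
    vdw_radius: float
    charge: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.name!r}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name!r}: non-finite coordinates")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.name!r}: vdw_radius must be > 0")


@dataclass(frozen=True)
class Molecule:
    """An ordered collection of uniquely named atoms."""

    id: str
    atoms: tuple[Atom, ...]
    conformer_tag: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(self.atoms))
        if len(self.atoms) < 1:
            raise ValueError(f"molecule {self.id!r} has no atoms")
        names = [a.name for a in self.atoms]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"molecule {self.id!r}: duplicate atom names {dupes}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Å."""
        return np.array([a.position for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"molecule {self.id!r} has no atom named {name!r}")

    def with_positions(self, positions: np.ndarray, conformer_tag: str | None = None) -> "Molecule":
        """Copy of the molecule with new coordinates (same atom order)."""
        positions = np.asarray(positions, float)
        if positions.shape != (len(self.atoms), 3):
            raise ValueError("position array shape mismatch")
        atoms = tuple(replace(a, position=p) for a, p in zip(self.atoms, positions))
        return Molecule(self.id, atoms, conformer_tag if conformer_tag is not None else self.conformer_tag)

    def with_charges(self, charges: Sequence[float]) -> "Molecule":
        charges = np.asarray(charges, float)
        if charges.shape != (len(self.atoms),):
            raise ValueError("charge array shape mismatch")
        atoms = tuple(replace(a, charge=float(q)) for a, q in zip(self.atoms, charges))
        return Molecule(self.id, atoms, self.conformer_tag)


@dataclass(frozen=True)
class RDCRecord:
    """One experimental or predicted coupling for an atom pair."""

    atom_a: str
    atom_b: str
    d_exp: float  # Hz
    sigma: float = 1.0  # Hz, estimated accuracy

    def __post_init__(self):
        if self.atom_a == self.atom_b:
            raise ValueError(f"RDC pair must involve two distinct atoms, got {self.atom_a!r} twice")
        if self.sigma < 0:
            raise ValueError(f"RDC ({self.atom_a}, {self.atom_b}): sigma must be >= 0")


@dataclass(frozen=True)
class RDCSet:
    """RDCs of one molecule in one alignment medium."""

    molecule_id: str
    medium: str
    records: tuple[RDCRecord, ...]

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        if not self.records:
            raise ValueError("RDCSet needs at least one record")
        pairs = [(r.atom_a, r.atom_b) for r in self.records]
        if len(set(pairs)) != len(pairs):
            dupes = sorted({p for p in pairs if pairs.count(p) > 1})
            raise ValueError(f"duplicate atom pairs in RDC set: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [(r.atom_a, r.atom_b) for r in self.records]

    @property
    def values(self) -> np.ndarray:
        return np.array([r.d_exp for r in self.records])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([r.sigma for r in self.records])

    def with_values(self, values: Sequence[float], medium: str | None = None) -> "RDCSet":
        values = np.asarray(values, float)
        if values.shape != (len(self.records),):
            raise ValueError("value array shape mismatch")
        recs = tuple(replace(r, d_exp=float(v)) for r, v in zip(self.records, values))
        return RDCSet(self.molecule_id, medium if medium is not None else self.medium, recs)


@dataclass(frozen=True)
class PotentialGrid:
    """Regular 3D scalar field (kT/e) on an axis-aligned grid.

    ``values`` has shape ``counts`` with C index order (x, y, z), so the last
    (z) index varies fastest in the flattened array, matching the APBS/OpenDX
    data-block convention.
    """

    origin: np.ndarray  # Å
    spacing: np.ndarray  # Å, per axis
    values: np.ndarray  # shape = counts

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, float))
        object.__setattr__(self, "spacing", np.asarray(self.spacing, float))
        object.__setattr__(self, "values", np.asarray(self.values, float))
        if self.origin.shape != (3,) or self.spacing.shape != (3,):
            raise ValueError("origin and spacing must be 3-vectors")
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be strictly positive")
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")

    @property
    def counts(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Node coordinates along each axis."""
        return tuple(
            self.origin[i] + self.spacing[i] * np.arange(self.values.shape[i]) for i in range(3)
        )


@dataclass(frozen=True)
class MediumModel:
    """Alignment-medium particle: steric spheres + electrostatic potential + director."""

    spheres: tuple[tuple[np.ndarray, float], ...]  # (center Å, radius Å)
    potential: PotentialGrid
    director: np.ndarray  # unit vector along the magnetic field

    def __post_init__(self):
        spheres = tuple((np.asarray(c, float), float(r)) for c, r in self.spheres)
        if not spheres:
            raise ValueError("medium needs at least one steric sphere")
        object.__setattr__(self, "spheres", spheres)
        d = np.asarray(self.director, float)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or n == 0:
            raise ValueError("director must be a nonzero vector")
        object.__setattr__(self, "director", d / n)

    @property
    def sphere_centers(self) -> np.ndarray:
        return np.array([c for c, _ in self.spheres])

    @property
    def sphere_radii(self) -> np.ndarray:
        return np.array([r for _, r in self.spheres])


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------


def read_pdb(path: str | Path, molecule_id: str | None = None) -> Molecule:
    """Read a small-molecule PDB file into a :class:`Molecule`.

    Every ``ATOM``/``HETATM`` record becomes one atom; the element is taken
    from the element column (falling back to the leading letter of the atom
    name) and mapped to its Bondi van der Waals radius. Charges are zero
    until assigned with :func:`read_charges`.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(molecule_id or path.stem, str(path))
    atoms = []
    for pdb_atom in structure.get_atoms():
        element = (pdb_atom.element or "").strip()
        if not element:
            element = "".join(ch for ch in pdb_atom.get_name() if ch.isalpha())[:1]
        try:
            radius = vdw_radius(element)
        except KeyError as exc:
            raise ParseError(f"{path}: atom {pdb_atom.get_name()!r}: {exc.args[0]}") from None
        name = pdb_atom.get_name().strip()
        if any(a.name == name for a in atoms):
            # disambiguate duplicated names across residues/copies
            name = f"{name}_{len(atoms)}"
        atoms.append(Atom(name=name, element=element.upper(), position=np.array(pdb_atom.coord, float), vdw_radius=radius))
    if not atoms:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    return Molecule(molecule_id or path.stem, tuple(atoms))


def write_pdb(mol: Molecule, path: str | Path) -> None:
    """Write a molecule as HETATM records (coordinates at PDB's 1e-3 Å precision)."""
    path = Path(path)
    lines = []
    for i, a in enumerate(mol.atoms, start=1):
        name = a.name[:4]
        pad = f" {name:<3s}" if len(name) < 4 else name
        x, y, z = a.position
        lines.append(
            f"HETATM{i:5d} {pad:<4s} LIG A   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element.rjust(2)}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# RDC tables
# ---------------------------------------------------------------------------


def read_rdc_table(
    path: str | Path,
    molecule_id: str = "",
    medium: str = "",
    default_sigma: float = 1.0,
) -> RDCSet:
    """Read a whitespace-separated RDC table.

    Each data row is ``atomA atomB D [sigma]``; ``#`` starts a comment. Rows
    with extra *leading* columns (residue numbers / segment names, as in the
    PALES dipolar-coupling dialect) are accepted: the two right-most
    non-numeric fields before the numeric tail are used as atom names.
    A missing sigma column falls back to ``default_sigma`` (logged).
    """
    path = Path(path)
    records: list[RDCRecord] = []
    missing_sigma = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        # numeric tail: trailing fields parseable as floats
        tail: list[float] = []
        while fields:
            try:
                tail.append(float(fields[-1]))
            except ValueError:
                break
            fields.pop()
        tail.reverse()
        if len(fields) < 2 or len(fields) % 2 != 0 or not tail:
            raise ParseError(f"{path}:{lineno}: expected 'atomA atomB D [sigma]', got {raw!r}")
        # plain dialect: two name fields; PALES dialect: two equal groups of
        # (resid, resname, atomname) — the atom name closes each group
        half = len(fields) // 2
        atom_a, atom_b = fields[half - 1], fields[-1]
        d_exp = tail[0]
        if len(tail) >= 2:
            sigma = tail[1]
        else:
            sigma = default_sigma
            missing_sigma = True
        try:
            rec = RDCRecord(atom_a=atom_a, atom_b=atom_b, d_exp=d_exp, sigma=sigma)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if (atom_a, atom_b) in {(r.atom_a, r.atom_b) for r in records}:
            raise ParseError(f"{path}:{lineno}: duplicate atom pair ({atom_a}, {atom_b})")
        records.append(rec)
    if not records:
        raise ParseError(f"{path}: no RDC rows found")
    if missing_sigma:
        logger.warning("%s: sigma column absent for some rows; defaulting to %.3g Hz", path, default_sigma)
    return RDCSet(molecule_id or path.stem, medium or "unknown", tuple(records))


def write_rdc_table(rdcs: RDCSet, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# molecule {rdcs.molecule_id}  medium {rdcs.medium}", "# atomA atomB D(Hz) sigma(Hz)"]
    for r in rdcs.records:
        lines.append(f"{r.atom_a:<8s} {r.atom_b:<8s} {r.d_exp: .8f} {r.sigma:.8f}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# OpenDX scalar grids
# ---------------------------------------------------------------------------


def read_dx(path: str | Path) -> PotentialGrid:
    """Read an OpenDX scalar grid (APBS dialect).

    The data block lists values with the z index varying fastest; the value
    count must match the header counts exactly.
    """
    path = Path(path)
    counts = None
    origin = None
    deltas: list[np.ndarray] = []
    values: list[float] = []
    in_data = False
    n_expected = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("object") and "gridpositions" in line:
            toks = line.split()
            try:
                counts = tuple(int(t) for t in toks[-3:])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: cannot parse grid counts from {raw!r}") from None
        elif line.startswith("origin"):
            origin = np.array([float(t) for t in line.split()[1:4]])
        elif line.startswith("delta"):
            deltas.append(np.array([float(t) for t in line.split()[1:4]]))
        elif line.startswith("object") and "array" in line:
            if counts is None:
                raise ParseError(f"{path}:{lineno}: data array before gridpositions header")
            toks = line.split()
            if "items" in toks:
                n_expected = int(toks[toks.index("items") + 1])
            in_data = True
        elif line.startswith(("attribute", "component", "object", "end")):
            in_data = False
        elif in_data:
            try:
                values.extend(float(t) for t in line.split())
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric data value in {raw!r}") from None
    if counts is None or origin is None or len(deltas) != 3:
        raise ParseError(f"{path}: incomplete OpenDX header (need gridpositions, origin, 3 deltas)")
    n_nodes = counts[0] * counts[1] * counts[2]
    if n_expected is not None and n_expected != n_nodes:
        raise ParseError(
            f"{path}: header declares {n_expected} items but grid counts give {n_nodes}"
        )
    if len(values) != n_nodes:
        raise ParseError(
            f"{path}: data block has {len(values)} values but grid counts require {n_nodes}"
        )
    delta_mat = np.array(deltas)
    if not np.allclose(delta_mat, np.diag(np.diag(delta_mat))):
        raise ParseError(f"{path}: only axis-aligned (diagonal delta) grids are supported")
    spacing = np.diag(delta_mat)
    # z fastest => C order with shape (nx, ny, nz)
    data = np.array(values).reshape(counts)
    return PotentialGrid(origin=origin, spacing=spacing, values=data)


def write_dx(grid: PotentialGrid, path: str | Path, comment: str = "scalar potential, kT/e") -> None:
    path = Path(path)
    nx, ny, nz = grid.counts
    n = nx * ny * nz
    lines = [f"# {comment}"]
    lines.append(f"object 1 class gridpositions counts {nx} {ny} {nz}")
    lines.append("origin {:.6e} {:.6e} {:.6e}".format(*grid.origin))
    lines.append(f"delta {grid.spacing[0]:.6e} 0.000000e+00 0.000000e+00")
    lines.append(f"delta 0.000000e+00 {grid.spacing[1]:.6e} 0.000000e+00")
    lines.append(f"delta 0.000000e+00 0.000000e+00 {grid.spacing[2]:.6e}")
    lines.append(f"object 2 class gridconnections counts {nx} {ny} {nz}")
    lines.append(f"object 3 class array type double rank 0 items {n} data follows")
    flat = grid.values.reshape(-1)  # C order: z fastest
    for i in range(0, n, 3):
        chunk = flat[i : i + 3]
        lines.append(" ".join(f"{v:.17e}" for v in chunk))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "regular positions regular connections" class field')
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# charge files
# ---------------------------------------------------------------------------


def read_charges(path: str | Path, mol: Molecule) -> Molecule:
    """Assign partial charges from a two-column ``name charge`` file.

    Atoms absent from the file keep charge 0 (logged). A file entry naming an
    atom not present in the molecule is an error. A non-zero net charge is
    accepted and logged.
    """
    path = Path(path)
    charge_map: dict[str, float] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 'name charge', got {raw!r}")
        name = fields[0]
        try:
            q = float(fields[-1])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric charge {fields[-1]!r}") from None
        charge_map[name] = q
    mol_names = {a.name for a in mol.atoms}
    unknown = sorted(set(charge_map) - mol_names)
    if unknown:
        raise ParseError(f"{path}: charge entries for atoms not in molecule {mol.id!r}: {unknown}")
    missing = sorted(mol_names - set(charge_map))
    if missing:
        logger.warning("%s: no charge for atoms %s; set to 0", path, missing)
    charges = [charge_map.get(a.name, 0.0) for a in mol.atoms]
    net = float(np.sum(charges))
    if abs(net) > 1e-6:
        logger.info("%s: net molecular charge %+.4f e", path, net)
    return mol.with_charges(charges)
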