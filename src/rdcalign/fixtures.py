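"""Synthetic test systems: media, solutes, RDC generators and benchmark tables.

Everything here is generated programmatically and deterministically so the
full pipeline — grid I/O, steric/electrostatic weighting, tensor fitting,
ensemble analysis — can be exercised without external structure files,
Poisson–Boltzmann solvers or downloads.

The medium stand-ins are sphere-packed rods or walls with an analytic
screened-Coulomb (Yukawa) surface-charge potential evaluated on a regular
grid; they exercise the same steric-exclusion and grid-interpolation code
paths as a real helical-polymer particle without requiring its atomistic
model. The benchmark tables registered in :func:`load_benchmark_table` are
likewise *synthetic stand-ins*: they mimic the layout of published
multi-medium RDC panels (medium labels, per-medium site counts, a
compressed-gel medium with inverted sign, a three-conformer flexible-sugar
system with eight one-bond CH couplings) but their numerical values are
generated, not measured.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np

from .core_io import Atom, MediumModel, Molecule, PotentialGrid, RDCRecord, RDCSet
from .constants import vdw_radius
from .ensemble import ConformerSet
from .tensor_fit import SaupeTensor, rdc_from_tensor

__all__ = [
    "SyntheticMediumSpec",
    "make_medium",
    "make_solute",
    "make_synthetic_rdcs",
    "load_benchmark_table",
    "benchmark_registry",
]

#: Bjerrum length of water at ~300 K, Å: converts e²/Å to kT.
BJERRUM_LENGTH = 7.0


@dataclass(frozen=True)
class SyntheticMediumSpec:
    """Geometry and electrostatics of a synthetic alignment-medium particle.

    ``kind`` is ``"helical_rod"`` (spheres stacked along z, the director) or
    ``"planar_wall"`` (a square sphere lattice in the x–z plane). The
    potential is the screened-Coulomb sum of the sphere surface charges with
    Debye length ``debye_length``, evaluated on a grid that encloses the
    particle plus ``grid_padding`` on every side.
    """

    kind: str = "helical_rod"
    length: float = 40.0  # Å
    radius: float = 4.0  # Å, sphere radius
    sphere_spacing: float = 4.0  # Å
    surface_charge_density: float = 0.0  # e / Å^2
    grid_spacing: float = 1.0  # Å
    grid_padding: float = 6.0  # Å
    debye_length: float = 10.0  # Å
    grid_counts: tuple[int, int, int] | None = None  # override; must enclose the particle

    def __post_init__(self):
        if self.kind not in ("helical_rod", "planar_wall"):
            raise ValueError(f"unknown medium kind {self.kind!r}")
        if min(self.length, self.radius, self.sphere_spacing, self.grid_spacing) <= 0:
            raise ValueError("geometry parameters must be positive")


def _sphere_centers(spec: SyntheticMediumSpec) -> np.ndarray:
    n = math.ceil(spec.length / spec.sphere_spacing)
    line = (np.arange(n) - (n - 1) / 2.0) * spec.sphere_spacing
    if spec.kind == "helical_rod":
        centers = np.zeros((n, 3))
        centers[:, 2] = line
        return centers
    # planar_wall: square lattice in the x-z plane, normal along y
    xx, zz = np.meshgrid(line, line, indexing="ij")
    centers = np.column_stack([xx.ravel(), np.zeros(xx.size), zz.ravel()])
    return centers


def yukawa_potential(points: np.ndarray, centers: np.ndarray, radius: float,
                     charge_per_sphere: float, debye_length: float) -> np.ndarray:
    """Screened-Coulomb potential (kT/e) of uniformly charged spheres.

    ``phi(x) = l_B * q * exp(-(d - a)/lambda) / ((1 + a/lambda) * d)`` per
    sphere of radius ``a`` (Debye–Hückel exterior solution); the value is
    clamped at the sphere surface for interior points.
    """
    points = np.atleast_2d(points)
    d = np.sqrt(np.sum((points[:, None, :] - centers[None, :, :]) ** 2, axis=-1))
    d = np.maximum(d, radius)
    a = radius
    lam = debye_length
    phi = BJERRUM_LENGTH * charge_per_sphere * np.exp(-(d - a) / lam) / ((1.0 + a / lam) * d)
    return phi.sum(axis=1)


def make_medium(spec: SyntheticMediumSpec) -> MediumModel:
    """Build a synthetic medium particle: steric spheres, potential grid, director.

    The director is the z axis (rod axis; in-plane axis for a wall). Raises if
    an explicitly requested grid does not enclose the particle.
    """
    centers = _sphere_centers(spec)
    lo = centers.min(axis=0) - spec.radius - spec.grid_padding
    hi = centers.max(axis=0) + spec.radius + spec.grid_padding
    if spec.grid_counts is not None:
        counts = np.asarray(spec.grid_counts, int)
        span = spec.grid_spacing * (counts - 1)
        needed = hi - lo
        if np.any(span < needed - 1e-9):
            raise ValueError(
                f"grid of counts {tuple(counts)} at spacing {spec.grid_spacing} Å spans "
                f"{span} Å but the particle plus padding needs {needed} Å"
            )
        center = 0.5 * (lo + hi)
        origin = center - span / 2.0
    else:
        counts = np.ceil((hi - lo) / spec.grid_spacing).astype(int) + 1
        origin = lo
    axes = [origin[i] + spec.grid_spacing * np.arange(counts[i]) for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    if spec.surface_charge_density != 0.0:
        q = spec.surface_charge_density * 4.0 * np.pi * spec.radius**2
        phi = yukawa_potential(pts, centers, spec.radius, q, spec.debye_length).reshape(tuple(counts))
    else:
        phi = np.zeros(tuple(counts))
    grid = PotentialGrid(origin=origin, spacing=np.full(3, spec.grid_spacing), values=phi)
    spheres = tuple((c, spec.radius) for c in centers)
    return MediumModel(spheres=spheres, potential=grid, director=np.array([0.0, 0.0, 1.0]))


# ---------------------------------------------------------------------------
# solutes
# ---------------------------------------------------------------------------


def _charges(pattern: str, positions: np.ndarray) -> np.ndarray:
    n = len(positions)
    if pattern == "neutral" or n == 1:
        return np.zeros(n)
    if pattern == "dipolar":
        # charge proportional to position along the longest axis, net zero
        axis = positions[:, np.argmax(np.ptp(positions, axis=0))]
        q = axis - axis.mean()
        return 0.2 * q / np.abs(q).max()
    if pattern == "quadrupolar":
        axis = positions[:, np.argmax(np.ptp(positions, axis=0))]
        q = np.abs(axis - axis.mean())
        q = q - q.mean()
        return 0.2 * q / np.abs(q).max()
    raise ValueError(f"unknown charge pattern {pattern!r}")


def make_solute(shape: str, n_atoms: int, charge_pattern: str = "neutral", seed: int = 0) -> Molecule:
    """Deterministic synthetic solute of a given overall shape.

    Shapes: ``rod`` (atoms along z, 1.5 Å apart), ``disc`` (flat ring(s) in
    the x–y plane), ``sphere`` (points quasi-uniform on a 2 Å sphere; 1 atom
    allowed), ``bent`` (a 90° arc). Elements alternate C/H so consecutive
    pairs carry standard one-bond-like dipolar constants; a small seeded
    jitter (0.05 Å) breaks exact symmetry. Charges follow ``charge_pattern``
    (``neutral`` / ``dipolar`` / ``quadrupolar``) and always sum to zero.
    """
    if n_atoms < 1 or (n_atoms < 2 and shape != "sphere"):
        raise ValueError("need n_atoms >= 2 (>= 1 for sphere)")
    k = np.arange(n_atoms)
    if shape == "rod":
        pos = np.column_stack([np.zeros(n_atoms), np.zeros(n_atoms), 1.5 * (k - (n_atoms - 1) / 2)])
    elif shape == "disc":
        ang = 2 * np.pi * k / n_atoms
        pos = np.column_stack([2.5 * np.cos(ang), 2.5 * np.sin(ang), np.zeros(n_atoms)])
    elif shape == "sphere":
        if n_atoms == 1:
            pos = np.zeros((1, 3))
        else:
            z = 1 - 2 * (k + 0.5) / n_atoms
            phi = k * np.pi * (3 - np.sqrt(5))
            rho = np.sqrt(1 - z * z)
            pos = 2.0 * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    elif shape == "bent":
        ang = (np.pi / 2) * k / max(n_atoms - 1, 1)
        pos = np.column_stack([3.0 * np.cos(ang), 3.0 * np.sin(ang), 0.15 * (k - (n_atoms - 1) / 2)])
    else:
        raise ValueError(f"unknown shape {shape!r}")
    rng = np.random.default_rng(seed)
    pos = pos + 0.05 * rng.standard_normal(pos.shape)
    charges = _charges(charge_pattern, pos)
    atoms = []
    for i in range(n_atoms):
        element = "C" if i % 2 == 0 else "H"
        atoms.append(
            Atom(
                name=f"{element}{i + 1}",
                element=element,
                position=pos[i],
                vdw_radius=vdw_radius(element),
                charge=float(charges[i]),
            )
        )
    return Molecule(f"{shape}_{n_atoms}_{charge_pattern}_{seed}", tuple(atoms))


def consecutive_pairs(mol: Molecule) -> list[tuple[str, str]]:
    """Bonded-like atom pairs (i, i+1) of a synthetic solute."""
    names = [a.name for a in mol.atoms]
    return [(names[i], names[i + 1]) for i in range(len(names) - 1)]


def make_synthetic_rdcs(
    mol: Molecule,
    tensor: SaupeTensor,
    pairs: list[tuple[str, str]],
    noise_sigma: float = 0.0,
    seed: int = 0,
    medium: str = "synthetic",
) -> RDCSet:
    """Ground-truth couplings from a known tensor, plus optional Gaussian noise.

    The record sigmas are ``noise_sigma`` (1.0 Hz when noise-free, as a
    generic accuracy placeholder for Monte Carlo error bars).
    """
    rng = np.random.default_rng(seed)
    sig = noise_sigma if noise_sigma > 0 else 1.0
    records = []
    for a, b in pairs:
        d = rdc_from_tensor(tensor, mol, (a, b))
        if noise_sigma > 0:
            d += rng.normal(0.0, noise_sigma)
        records.append(RDCRecord(a, b, d, sig))
    return RDCSet(mol.id, medium, tuple(records))


# ---------------------------------------------------------------------------
# benchmark tables (synthetic stand-ins)
# ---------------------------------------------------------------------------

_STRYCHNINE_MEDIA = ("PBLG", "PELG", "PMMA", "PIAF", "PS", "PA1", "PL1", "PALV", "PADV")
_IPC_MEDIA = ("PBLG", "PBDG", "PELG", "PALF300", "PALF316", "PL1", "PALV", "PADV", "PPEMG")
#: site counts per medium: most media report a full CH set, PA1/PL1 are sparse
_STRYCHNINE_SITES = {"PA1": 5, "PL1": 6}
#: ensemble composition used to generate the flexible-sugar stand-in; plays the
#: role of literature reference populations in ensemble-averaging examples
SUCROSE_REFERENCE_WEIGHTS = (0.2, 0.3, 0.5)


def _random_tensor(rng: np.random.Generator, scale: float = 1e-3) -> SaupeTensor:
    m = rng.standard_normal((3, 3))
    m = 0.5 * (m + m.T)
    m -= np.eye(3) * (np.trace(m) / 3.0)
    return SaupeTensor(scale * m)


def _panel_molecule(name: str, shape: str, n_atoms: int, seed: int) -> Molecule:
    mol = make_solute(shape, n_atoms, "neutral", seed=seed)
    return Molecule(name, mol.atoms)


def _medium_tensor(base: SaupeTensor, rng: np.random.Generator, similarity: float) -> SaupeTensor:
    """A tensor correlated with ``base``: convex blend with a random tensor."""
    other = _random_tensor(rng)
    m = similarity * base.matrix + (1.0 - similarity) * other.matrix
    return SaupeTensor(m)


def _build_panel(molecule: str) -> dict[str, RDCSet]:
    if molecule == "strychnine":
        media, shape, n_atoms, base_seed = _STRYCHNINE_MEDIA, "disc", 12, 11
        sparse = _STRYCHNINE_SITES
    else:
        media, shape, n_atoms, base_seed = _IPC_MEDIA, "sphere", 8, 23
        sparse = {}
    mol = _panel_molecule(molecule, shape, n_atoms, seed=base_seed)
    pairs = consecutive_pairs(mol)
    rng = np.random.default_rng(base_seed)
    base = _random_tensor(rng)
    # similarity loosely mirrors how clustered the published media panels are:
    # the disc-shaped solute aligns similarly across media, the spherical one less so
    similarity = 0.8 if molecule == "strychnine" else 0.4
    sets = {}
    for medium in media:
        t = _medium_tensor(base, rng, similarity)
        if medium == "PMMA":  # compressed gel: inverted axial component
            t = SaupeTensor(-t.matrix)
        n_sites = sparse.get(medium, len(pairs))
        use_pairs = pairs[:n_sites]
        full = make_synthetic_rdcs(mol, t, use_pairs, noise_sigma=0.0, seed=base_seed, medium=medium)
        med_seed = zlib.crc32(f"{molecule}:{medium}".encode()) % 2**31
        noisy = full.values + np.random.default_rng(med_seed).normal(0.0, 0.3, len(use_pairs))
        sets[medium] = full.with_values(noisy)
    return sets


def _build_sucrose() -> dict[str, object]:
    mol = _panel_molecule("sucrose", "bent", 16, seed=7)
    pairs = consecutive_pairs(mol)[:8]  # eight one-bond CH couplings
    rng = np.random.default_rng(7)
    conf_sets = []
    for i in range(3):
        t = _random_tensor(rng)
        conf_sets.append(
            make_synthetic_rdcs(mol, t, pairs, noise_sigma=0.0, seed=7, medium="PBLG")
        )
    conformers = ConformerSet(labels=("conf1", "conf2", "conf3"), d_pred=tuple(conf_sets))
    p = np.asarray(SUCROSE_REFERENCE_WEIGHTS)
    avg = p @ conformers.prediction_matrix
    exp_noise = np.random.default_rng(77).normal(0.0, 0.5, len(pairs))
    exp = conf_sets[0].with_values(avg + exp_noise, medium="PBLG")
    return {"conformers": conformers, "experimental": exp, "weights": tuple(p)}


def benchmark_registry() -> dict[str, str]:
    """Available benchmark table names with one-line descriptions."""
    names = {}
    for medium in _STRYCHNINE_MEDIA:
        names[f"strychnine_{medium}"] = f"synthetic stand-in: disc-shaped solute RDCs in {medium}"
    for medium in _IPC_MEDIA:
        names[f"ipc_{medium}"] = f"synthetic stand-in: near-spherical solute RDCs in {medium}"
    names["sucrose_exp"] = "synthetic stand-in: flexible-sugar experimental CH RDCs (8 sites)"
    names["sucrose_conformers"] = "synthetic stand-in: per-conformer predicted CH RDCs (3 conformers)"
    return names


def load_benchmark_table(name: str):
    """Load a registered synthetic benchmark table.

    Returns an :class:`RDCSet` for per-medium entries and ``sucrose_exp``, or
    a :class:`ConformerSet` for ``sucrose_conformers``. All tables are
    generated deterministically; they are stand-ins that mimic published
    panel layouts, not transcriptions of measured data.
    """
    registry = benchmark_registry()
    if name not in registry:
        raise KeyError(f"unknown benchmark table {name!r}; available: {sorted(registry)}")
    if name.startswith("strychnine_"):
        return _build_panel("strychnine")[name.split("_", 1)[1]]
    if name.startswith("ipc_"):
        return _build_panel("ipc")[name.split("_", 1)[1]]
    data = _build_sucrose()
    if name == "sucrose_exp":
        return data["experimental"]
    return data["conformers"]
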