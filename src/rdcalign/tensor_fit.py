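"""Saupe alignment-tensor algebra, SVD fitting to RDCs, and fit-quality statistics.

A residual dipolar coupling between nuclei a and b with internuclear unit
vector u (in the molecular frame) under an order matrix S is

    D = Dmax(a, b, r) * u^T S u,     Dmax = mu0 * gamma_a * gamma_b * h / (16 pi^3 r^3),

with S symmetric and traceless (5 independent elements). Given >= 5
independent couplings, S is determined by linear least squares (solved by
singular value decomposition). Fit quality is summarised by Pearson's R, the
quality factor Q = rms(D_exp - D_calc)/rms(D_exp), its slope-rescaled variant
QS, and the composite score RQ = (R + 1)^2 / QS which rewards both high
correlation and low scaled deviation. Uncertainties come from a Monte Carlo
scheme that re-fits after perturbing the couplings within their stated
accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .constants import MU_0, PLANCK_H, gyromagnetic_ratio
from .core_io import Molecule, RDCSet

__all__ = [
    "SaupeTensor",
    "FitResult",
    "dmax",
    "rdc_from_tensor",
    "design_matrix",
    "svd_fit",
    "quality_stats",
    "monte_carlo_errors",
    "eigen_frame",
]

#: floor for QS in RQ = (R+1)^2 / QS, so perfect fits give a large finite RQ
QS_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# Saupe tensor
# ---------------------------------------------------------------------------


def _canonical_eigen(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-ordered eigenvalues (|Sxx| <= |Syy| <= |Szz|) and canonical axes.

    Ties in |eigenvalue| break by descending signed value; each axis is
    flipped into the hemisphere with non-negative z component (axes are
    headless), tie-breaking on y then x.
    """
    vals, vecs = np.linalg.eigh(matrix)
    # sort ascending by (|v|, -v): stable, deterministic for degenerate pairs
    order = sorted(range(3), key=lambda i: (abs(vals[i]), -vals[i]))
    vals = vals[order]
    vecs = vecs[:, order]
    for i in range(3):
        v = vecs[:, i]
        if v[2] < 0 or (v[2] == 0 and (v[1] < 0 or (v[1] == 0 and v[0] < 0))):
            vecs[:, i] = -v
    return vals, vecs


@dataclass(frozen=True)
class SaupeTensor:
    """Symmetric traceless 3x3 order matrix with its eigen frame.

    ``eigenvalues`` are ordered (Sxx, Syy, Szz) with |Sxx| <= |Syy| <= |Szz|;
    ``eigenvectors[:, i]`` is the axis of ``eigenvalues[i]``, canonicalized to
    the z >= 0 hemisphere. ``da = Szz / 2`` is the axial component and
    ``rhombicity = (2/3) (Sxx - Syy) / Szz``.
    """

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, float)
        if m.shape != (3, 3):
            raise ValueError("Saupe matrix must be 3x3")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("Saupe matrix must be symmetric")
        if abs(np.trace(m)) > 1e-9 * max(1.0, np.abs(m).max()):
            raise ValueError(f"Saupe matrix must be traceless, trace = {np.trace(m):g}")
        m = 0.5 * (m + m.T)
        m = m - np.eye(3) * (np.trace(m) / 3.0)  # exact traceless within float
        object.__setattr__(self, "matrix", m)

    @property
    def eigenvalues(self) -> np.ndarray:
        """(Sxx, Syy, Szz), |Sxx| <= |Syy| <= |Szz|."""
        return _canonical_eigen(self.matrix)[0]

    @property
    def eigenvectors(self) -> np.ndarray:
        """Columns are the Sxx, Syy, Szz axes (canonical hemisphere)."""
        return _canonical_eigen(self.matrix)[1]

    @property
    def da(self) -> float:
        """Axial component Szz / 2 (same units as the matrix)."""
        return float(self.eigenvalues[2]) / 2.0

    @property
    def rhombicity(self) -> float:
        sxx, syy, szz = self.eigenvalues
        return float(2.0 / 3.0 * (sxx - syy) / szz) if szz != 0 else 0.0

    @staticmethod
    def from_parameters(szz: float, eta: float = 0.0, rotation: np.ndarray | None = None) -> "SaupeTensor":
        """Build a tensor from principal values Szz and asymmetry, optionally rotated."""
        sxx = -szz / 2.0 * (1.0 - eta)
        syy = -szz / 2.0 * (1.0 + eta)
        m = np.diag([sxx, syy, szz])
        if rotation is not None:
            rotation = np.asarray(rotation, float)
            m = rotation @ m @ rotation.T
        return SaupeTensor(m)


def eigen_frame(tensor: SaupeTensor | np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigen-decompose an order matrix.

    Returns ``(eigenvalues, axes, euler_angles)``: magnitude-ordered
    eigenvalues (Sxx, Syy, Szz), canonical hemisphere axes as columns, and the
    z-y-z Euler angles (radians) of the rotation from the molecular frame to
    the principal frame.
    """
    m = tensor.matrix if isinstance(tensor, SaupeTensor) else np.asarray(tensor, float)
    vals, vecs = _canonical_eigen(m)
    rot = vecs[:, [0, 1, 2]]  # columns x', y', z'
    if np.linalg.det(rot) < 0:
        rot = rot.copy()
        rot[:, 0] = -rot[:, 0]
    # z-y-z Euler angles of rotation matrix R with columns = principal axes
    beta = float(np.arccos(np.clip(rot[2, 2], -1.0, 1.0)))
    if abs(rot[2, 2]) < 1.0 - 1e-12:
        alpha = float(np.arctan2(rot[1, 2], rot[0, 2]))
        gamma = float(np.arctan2(rot[2, 1], -rot[2, 0]))
    else:
        alpha = float(np.arctan2(rot[1, 0], rot[0, 0]))
        gamma = 0.0
    return vals, vecs, np.array([alpha, beta, gamma])


# ---------------------------------------------------------------------------
# dipolar couplings
# ---------------------------------------------------------------------------


def dmax(atom_a: str, atom_b: str, mol: Molecule) -> float:
    """Static dipolar coupling magnitude (Hz) for an atom pair at its distance.

    ``Dmax = mu0 * gamma_a * gamma_b * h / (16 pi^3 r^3)``; for a C-H pair at
    1.09 Å this is about 23.3 kHz.
    """
    a = mol.atom(atom_a)
    b = mol.atom(atom_b)
    r = float(np.linalg.norm(a.position - b.position)) * 1e-10  # Å -> m
    if r == 0:
        raise ValueError(f"atoms {atom_a!r} and {atom_b!r} are coincident")
    ga = gyromagnetic_ratio(a.element)
    gb = gyromagnetic_ratio(b.element)
    return abs(MU_0 * ga * gb * PLANCK_H / (16.0 * np.pi**3 * r**3))


def _pair_geometry(mol: Molecule, pair: tuple[str, str]) -> tuple[np.ndarray, float]:
    a = mol.atom(pair[0])
    b = mol.atom(pair[1])
    vec = b.position - a.position
    norm = float(np.linalg.norm(vec))
    if norm == 0:
        raise ValueError(f"zero-length internuclear vector for pair {pair}")
    return vec / norm, dmax(pair[0], pair[1], mol)


def rdc_from_tensor(tensor: SaupeTensor | np.ndarray, mol: Molecule, pair: tuple[str, str]) -> float:
    """Back-calculate one RDC (Hz): ``D = Dmax * u^T S u``."""
    m = tensor.matrix if isinstance(tensor, SaupeTensor) else np.asarray(tensor, float)
    u, scale = _pair_geometry(mol, pair)
    return float(scale * u @ m @ u)


def design_matrix(mol: Molecule, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
    """(n, 5) linear map from (Syy, Szz, Sxy, Sxz, Syz) to couplings in Hz.

    Uses Sxx = -Syy - Szz to eliminate the trace.
    """
    rows = []
    for pair in pairs:
        u, scale = _pair_geometry(mol, pair)
        ux, uy, uz = u
        rows.append(
            scale
            * np.array(
                [uy * uy - ux * ux, uz * uz - ux * ux, 2 * ux * uy, 2 * ux * uz, 2 * uy * uz]
            )
        )
    return np.array(rows)


def _matrix_from_params(params: np.ndarray) -> np.ndarray:
    syy, szz, sxy, sxz, syz = params
    sxx = -syy - szz
    return np.array([[sxx, sxy, sxz], [sxy, syy, syz], [sxz, syz, szz]])


@dataclass(frozen=True)
class FitResult:
    """Alignment tensor fitted to one RDC set, with quality statistics."""

    tensor: SaupeTensor
    d_calc: np.ndarray  # Hz, per record
    r: float
    q: float
    qs: float
    rq: float
    slope: float
    r_err: float = 0.0
    qs_err: float = 0.0
    rq_err: float = 0.0


def svd_fit(
    rdcs: RDCSet,
    mol: Molecule,
    n_monte_carlo: int = 0,
    seed: int | None = None,
) -> FitResult:
    """Fit a Saupe tensor to experimental RDCs by linear least squares (SVD).

    Requires at least five linearly independent couplings. With
    ``n_monte_carlo > 0``, Monte Carlo standard deviations of R, QS and RQ are
    attached to the result.
    """
    pairs = rdcs.pairs
    if len(pairs) < 5:
        raise ValueError(
            f"{len(pairs)} RDCs given but SVD fitting needs >= 5; "
            "compare simulation-predicted couplings directly instead"
        )
    A = design_matrix(mol, pairs)
    d_exp = rdcs.values
    rank = np.linalg.matrix_rank(A, tol=1e-8 * np.abs(A).max())
    if rank < 5:
        raise ValueError(
            f"design matrix is rank-deficient (rank {rank} < 5): the coupling "
            "vectors do not span 5 independent tensor components"
        )
    params, *_ = np.linalg.lstsq(A, d_exp, rcond=None)
    tensor = SaupeTensor(_matrix_from_params(params))
    d_calc = A @ params
    r, q, slope, qs, rq = quality_stats(d_exp, d_calc)
    result = FitResult(tensor=tensor, d_calc=d_calc, r=r, q=q, qs=qs, rq=rq, slope=slope)
    if n_monte_carlo > 0:
        def refit(noisy: RDCSet) -> tuple[float, float, float]:
            p, *_ = np.linalg.lstsq(A, noisy.values, rcond=None)
            rr, _, _, qq, rrqq = quality_stats(noisy.values, A @ p)
            return rr, qq, rrqq

        r_err, qs_err, rq_err = monte_carlo_errors(refit, rdcs, n_rep=n_monte_carlo, seed=seed, base=(r, qs, rq))
        result = FitResult(
            tensor=tensor, d_calc=d_calc, r=r, q=q, qs=qs, rq=rq, slope=slope,
            r_err=r_err, qs_err=qs_err, rq_err=rq_err,
        )
    return result


# ---------------------------------------------------------------------------
# quality statistics
# ---------------------------------------------------------------------------


def quality_stats(
    d_exp: np.ndarray, d_pred: np.ndarray, qs_floor: float = QS_FLOOR
) -> tuple[float, float, float, float, float]:
    """Fit-quality statistics ``(r, q, slope, qs, rq)``.

    * ``r``: Pearson correlation of experimental vs predicted couplings;
    * ``q = rms(d_exp - d_pred) / rms(d_exp)``;
    * ``slope``: through-origin least-squares slope of d_exp on d_pred
      (couplings have no physical offset);
    * ``qs = rms(d_exp - slope * d_pred) / rms(d_exp)`` — Q after absorbing a
      uniform scale error of the prediction;
    * ``rq = (r + 1)^2 / max(qs, qs_floor)``.
    """
    d_exp = np.asarray(d_exp, float)
    d_pred = np.asarray(d_pred, float)
    if d_exp.shape != d_pred.shape or d_exp.ndim != 1 or d_exp.size < 2:
        raise ValueError("need two equal-length 1D arrays with >= 2 couplings")
    if np.allclose(d_exp, d_exp[0]):
        raise ValueError("experimental couplings are all equal; statistics undefined")
    denom2 = float(np.sum(d_pred**2))
    if denom2 == 0:
        raise ValueError("all predicted couplings are zero; slope undefined")
    rms_exp = float(np.sqrt(np.mean(d_exp**2)))
    q = float(np.sqrt(np.mean((d_exp - d_pred) ** 2))) / rms_exp
    slope = float(np.sum(d_exp * d_pred)) / denom2
    qs = float(np.sqrt(np.mean((d_exp - slope * d_pred) ** 2))) / rms_exp
    if np.allclose(d_pred, d_pred[0]):
        r = 0.0  # degenerate predictor: no linear association measurable
    else:
        r = float(np.corrcoef(d_exp, d_pred)[0, 1])
    rq = (r + 1.0) ** 2 / max(qs, qs_floor)
    return r, q, slope, qs, rq


def propagate_rq_error(r: float, qs: float, rq: float, r_err: float, qs_err: float) -> float:
    """First-order propagation of R and QS errors into RQ = (R+1)^2/QS."""
    qs = max(qs, QS_FLOOR)
    return float(rq * np.sqrt((2.0 * r_err / (r + 1.0)) ** 2 + (qs_err / qs) ** 2))


def monte_carlo_errors(
    fit_fn: Callable[[RDCSet], tuple[float, float, float]],
    rdcs: RDCSet,
    n_rep: int = 100,
    seed: int | None = None,
    base: tuple[float, float, float] | None = None,
) -> tuple[float, float, float]:
    """Monte Carlo standard deviations of (R, QS, RQ) under RDC noise.

    Each replicate perturbs every coupling with Gaussian noise of its stated
    accuracy and re-evaluates ``fit_fn(noisy_set) -> (r, qs, rq)``. The RQ
    error is obtained by first-order propagation of the R and QS errors
    around the unperturbed statistics (``base``, or the replicate means).
    """
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2")
    rng = np.random.default_rng(seed)
    values = rdcs.values
    sigmas = rdcs.sigmas
    stats = np.empty((n_rep, 3))
    for i in range(n_rep):
        noisy = rdcs.with_values(values + rng.normal(0.0, 1.0, size=values.shape) * sigmas)
        stats[i] = fit_fn(noisy)[:3]
    r_err = float(stats[:, 0].std(ddof=0))
    qs_err = float(stats[:, 1].std(ddof=0))
    if base is None:
        r0, qs0 = float(stats[:, 0].mean()), float(stats[:, 1].mean())
        rq0 = (r0 + 1.0) ** 2 / max(qs0, QS_FLOOR)
    else:
        r0, qs0, rq0 = base
    rq_err = propagate_rq_error(r0, qs0, rq0, r_err, qs_err)
    return r_err, qs_err, rq_err
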