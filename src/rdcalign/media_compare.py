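"""Cross-media comparison of RDC data sets.

Different alignment media order the same solute differently; comparing the
couplings measured in two media site-by-site shows whether the media induce
similar alignment. Because a compressed gel inverts the sign of the axial
alignment component relative to a stretched gel or a field-aligned liquid
crystal (the same tensor, opposite Da), cross-media matrices report |R| and
flag the raw negative correlations separately — the sign is physically
meaningful and is never discarded from the underlying records.

Tensor orientations are compared by projecting the three principal axes onto
an equirectangular (plate carrée) longitude/latitude map, and by detecting
axis swaps: when two eigenvalues have similar magnitude, experimental noise
can relabel the corresponding axes between media without much effect on the
back-calculated couplings.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import RDCSet
from .tensor_fit import SaupeTensor

__all__ = [
    "MediaPanel",
    "AxisProjection",
    "correlation_matrix",
    "project_axes",
    "detect_axis_swap",
]

MIN_COMMON_SITES = 3


@dataclass(frozen=True)
class MediaPanel:
    """RDC sets of one molecule across several alignment media.

    Site coverage may differ between media; pairwise comparisons use the
    common sites only and entries with fewer than 3 shared sites are
    undefined (NaN) rather than an error.
    """

    molecule_id: str
    sets: dict[str, RDCSet]
    label_map: dict[str, dict[str, str]] | None = None  # per-medium atom-name normalization

    def __post_init__(self):
        if len(self.sets) < 2:
            raise ValueError("a media panel needs at least 2 media")

    @property
    def media(self) -> list[str]:
        return list(self.sets)

    def normalized_values(self, medium: str) -> dict[tuple[str, str], float]:
        """Pair -> coupling map with per-medium site labels normalized."""
        table = (self.label_map or {}).get(medium, {})
        out = {}
        for rec in self.sets[medium].records:
            a = table.get(rec.atom_a, rec.atom_a)
            b = table.get(rec.atom_b, rec.atom_b)
            out[(a, b)] = rec.d_exp
        return out


def _pairwise_pearson(
    va: dict[tuple[str, str], float], vb: dict[tuple[str, str], float]
) -> tuple[float, int]:
    common = sorted(set(va) & set(vb))
    n = len(common)
    if n < MIN_COMMON_SITES:
        return np.nan, n
    x = np.array([va[p] for p in common])
    y = np.array([vb[p] for p in common])
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return np.nan, n
    return float(np.corrcoef(x, y)[0, 1]), n


def correlation_matrix(
    panel: MediaPanel,
    include_reference: RDCSet | None = None,
    reference_label: str = "predicted",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cross-media |R| matrix with negative-correlation flags.

    Returns ``(abs_r, negative, n_common)`` DataFrames indexed by medium
    label. ``abs_r`` holds |Pearson R| over the common sites of each pair
    (diagonal 1, NaN where fewer than 3 sites overlap); ``negative`` is True
    where the raw correlation is negative (e.g. a compressed vs a stretched
    gel); ``n_common`` counts the shared sites. An optional reference set
    (e.g. simulation-predicted couplings) is included as an extra row/column.
    """
    values = {m: panel.normalized_values(m) for m in panel.media}
    if include_reference is not None:
        values[reference_label] = {(r.atom_a, r.atom_b): r.d_exp for r in include_reference.records}
    labels = list(values)
    k = len(labels)
    absr = np.ones((k, k))
    neg = np.zeros((k, k), dtype=bool)
    ncom = np.zeros((k, k), dtype=int)
    for i, a in enumerate(labels):
        ncom[i, i] = len(values[a])
        for j in range(i + 1, k):
            r, n = _pairwise_pearson(values[a], values[labels[j]])
            absr[i, j] = absr[j, i] = abs(r) if np.isfinite(r) else np.nan
            neg[i, j] = neg[j, i] = bool(np.isfinite(r) and r < 0)
            ncom[i, j] = ncom[j, i] = n
    idx = pd.Index(labels, name="medium")
    return (
        pd.DataFrame(absr, index=idx, columns=idx),
        pd.DataFrame(neg, index=idx, columns=idx),
        pd.DataFrame(ncom, index=idx, columns=idx),
    )


@dataclass(frozen=True)
class AxisProjection:
    """One principal axis as an equirectangular map point (degrees)."""

    axis: str  # "Sxx" | "Syy" | "Szz"
    longitude: float  # [-180, 180), x axis at 0
    latitude: float  # [-90, 90], canonical antipode with latitude >= 0


def _to_lonlat(v: np.ndarray) -> tuple[float, float]:
    v = np.asarray(v, float)
    v = v / np.linalg.norm(v)
    # axes are headless: use the antipodal representative with z >= 0
    if v[2] < 0 or (v[2] == 0 and v[0] < 0) or (v[2] == 0 and v[0] == 0 and v[1] < 0):
        v = -v
    lat = float(np.degrees(np.arcsin(np.clip(v[2], -1.0, 1.0))))
    lon = float(np.degrees(np.arctan2(v[1], v[0])))
    if lon >= 180.0:
        lon -= 360.0
    return lon, lat


def project_axes(tensor: SaupeTensor) -> tuple[AxisProjection, AxisProjection, AxisProjection]:
    """Project the Sxx/Syy/Szz eigen-axes onto longitude/latitude.

    Longitude 0 is the molecular x axis; each (headless) axis is represented
    by its hemisphere point with latitude >= 0 so both signs of an eigenvector
    project identically.
    """
    vecs = tensor.eigenvectors
    names = ("Sxx", "Syy", "Szz")
    out = []
    for i, name in enumerate(names):
        lon, lat = _to_lonlat(vecs[:, i])
        out.append(AxisProjection(axis=name, longitude=lon, latitude=lat))
    return tuple(out)


def detect_axis_swap(
    tensor_a: SaupeTensor,
    tensor_b: SaupeTensor,
    tol_eig: float = 0.2,
    tol_angle: float = 30.0,
) -> dict:
    """Compare the eigen frames of two alignment tensors and detect axis swaps.

    The axes of ``tensor_b`` are assigned to those of ``tensor_a`` by the
    permutation minimizing the total inter-axis angle (axes are headless, so
    the angle uses |cos|). A swap is reported when the best assignment is not
    the identity, the assigned axes agree within ``tol_angle`` degrees, and
    the permuted eigenvalue magnitudes of ``b`` agree with those of ``a``
    within a relative ``tol_eig`` — the situation where two eigenvalues of
    similar magnitude let noise relabel consecutive axes.
    """
    va, vb = tensor_a.eigenvectors, tensor_b.eigenvectors
    ea, eb = tensor_a.eigenvalues, tensor_b.eigenvalues
    cos = np.abs(va.T @ vb)  # (3, 3): |cos angle| between axis i of a, j of b
    best_perm, best_total = None, np.inf
    for perm in itertools.permutations(range(3)):
        total = sum(float(np.degrees(np.arccos(np.clip(cos[i, perm[i]], 0.0, 1.0)))) for i in range(3))
        if total < best_total - 1e-12:
            best_total = total
            best_perm = perm
    angles = [float(np.degrees(np.arccos(np.clip(cos[i, best_perm[i]], 0.0, 1.0)))) for i in range(3)]
    scale_a = max(abs(ea[2]), 1e-300)
    eig_match = all(
        abs(abs(eb[best_perm[i]]) - abs(ea[i])) <= tol_eig * scale_a for i in range(3)
    )
    is_swap = best_perm != (0, 1, 2) and eig_match and all(a <= tol_angle for a in angles)
    return {
        "assignment": best_perm,
        "angles_deg": angles,
        "total_angle_deg": best_total,
        "eigenvalue_match": eig_match,
        "swap": bool(is_swap),
    }
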