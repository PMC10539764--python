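"""Physical constants and element tables used across the package.

Units: lengths in Å, couplings in Hz, energies in kT, charges in elementary
charge units, magnetic-field-related constants in SI.
"""

from __future__ import annotations

import math

# SI constants
MU_0 = 4.0e-7 * math.pi  # vacuum permeability, T m / A
PLANCK_H = 6.62607015e-34  # J s
HBAR = PLANCK_H / (2.0 * math.pi)

#: Gyromagnetic ratios, rad s^-1 T^-1, for the NMR-active isotope commonly
#: measured for each element in small-molecule RDC work.
GYROMAGNETIC_RATIOS: dict[str, float] = {
    "H": 2.6752218744e8,   # 1H
    "C": 6.728284e7,       # 13C
    "N": -2.7116e7,        # 15N
    "F": 2.51815e8,        # 19F
    "P": 1.08291e8,        # 31P
}

#: Bondi van der Waals radii, Å. Unknown elements are an error, never a default.
BONDI_VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "HE": 1.40,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "NE": 1.54,
    "SI": 2.10,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "AR": 1.88,
    "BR": 1.85,
    "KR": 2.02,
    "I": 1.98,
    "XE": 2.16,
}


def vdw_radius(element: str) -> float:
    """Bondi van der Waals radius (Å) for an element symbol.

    Raises ``KeyError`` with the offending symbol for elements not in the
    Bondi table.
    """
    key = element.strip().upper()
    try:
        return BONDI_VDW_RADII[key]
    except KeyError:
        raise KeyError(f"no van der Waals radius tabulated for element {element!r}") from None


def gyromagnetic_ratio(element: str) -> float:
    """Gyromagnetic ratio (rad s^-1 T^-1) of the routinely measured isotope."""
    key = element.strip().upper()
    try:
        return GYROMAGNETIC_RATIOS[key]
    except KeyError:
        raise KeyError(
            f"unsupported nucleus for element {element!r}; "
            f"supported: {sorted(GYROMAGNETIC_RATIOS)}"
        ) from None
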