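"""Atomic masses and van der Waals radii.

Masses are CIAAW 2021 standard atomic weights (abridged). Unknown elements
fall back to the mass of carbon with a warning, so that a mis-typed element
in a deposited file perturbs a mass-weighted center of mass as little as
possible instead of aborting the analysis.

vdW radii are the fixed set used by the interface module: C 1.70, N 1.55,
O 1.52, S 1.80 A; anything else 1.80 A. Interface areas are reproducible
within tolerance, not bit-exact against other programs, which use their own
(unpublished) radii.
"""

from __future__ import annotations

import warnings

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "NA": 22.990,
    "MG": 24.305,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "K": 39.098,
    "CA": 40.078,
    "MN": 54.938,
    "FE": 55.845,
    "ZN": 65.38,
    "SE": 78.971,
}

DEFAULT_MASS = 12.011

VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
}

DEFAULT_VDW_RADIUS = 1.80


def atomic_mass(element: str) -> float:
    """Mass in amu for an element symbol (case-insensitive).

    Unknown symbols return the carbon mass with a warning.
    """
    key = element.strip().upper()
    try:
        return ATOMIC_MASSES[key]
    except KeyError:
        warnings.warn(
            f"unknown element {element!r}; using default mass {DEFAULT_MASS}",
            stacklevel=2,
        )
        return DEFAULT_MASS


def vdw_radius(element: str) -> float:
    """van der Waals radius in Angstrom for an element symbol."""
    return VDW_RADII.get(element.strip().upper(), DEFAULT_VDW_RADIUS)
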