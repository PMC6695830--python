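"""Element masses and Bondi van der Waals radii.

Covers the elements that occur in protein/nucleoside crystal structures plus
the monatomic ions relevant to GPCR work. Unknown elements fall back to
carbon-like values rather than failing, since coarse-grained pseudo-atoms
carry their own radii in the file sidecar.
"""

from __future__ import annotations

#: Atomic masses, amu.
MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "NA": 22.990, "CL": 35.45, "K": 39.098, "MG": 24.305,
    "CA": 40.078, "ZN": 65.38, "F": 18.998, "BR": 79.904, "I": 126.904,
    "FE": 55.845, "SE": 78.971,
}

#: Bondi van der Waals radii, A. Ions use Bondi/Shannon-style values.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "NA": 2.27, "CL": 1.75, "K": 2.75, "MG": 1.73,
    "CA": 2.31, "ZN": 1.39, "F": 1.47, "BR": 1.85, "I": 1.98,
    "FE": 2.00, "SE": 1.90,
}

DEFAULT_MASS = 12.011
DEFAULT_VDW = 1.70


def guess_element(atom_name: str, element_field: str = "") -> str:
    """Infer an element symbol from a PDB atom name or element column."""
    if element_field.strip():
        return element_field.strip().upper()
    name = atom_name.strip()
    # two-letter ions/metals written flush-left in the name column
    two = name[:2].upper()
    if two in MASSES and not name[:1].isdigit() and two not in {"CA", "CL"}:
        # CA/CL clash with Calpha / chlorine-vs-carbon ambiguity: resolve below
        pass
    if name.upper() in ("NA", "NA+", "CL", "CL-", "K", "K+", "MG", "ZN", "CA2+"):
        return name.upper().rstrip("+-").rstrip("2")
    stripped = name.lstrip("0123456789")
    return stripped[:1].upper() if stripped else "C"


def mass_of(element: str) -> float:
    return MASSES.get(element.upper(), DEFAULT_MASS)


def vdw_radius_of(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)
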