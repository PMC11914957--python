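"""Energy units and physical constants.

All energies are stored internally in Hartree.  Reporting functions convert
to kcal/mol on demand using the single fixed constant below; no other
conversion factor appears anywhere in the package.
"""

HARTREE_TO_KCAL: float = 627.509474
"""1 Hartree in kcal/mol (fixed package-wide constant)."""

COULOMB_KCAL_ANGSTROM: float = 332.0637
"""Coulomb constant in kcal*Angstrom/(mol*e^2)."""

COULOMB_HARTREE_ANGSTROM: float = COULOMB_KCAL_ANGSTROM / HARTREE_TO_KCAL
"""Coulomb constant in Hartree*Angstrom/e^2 (used by the toy emulator)."""

#: Unit labels accepted in canonical files.
KNOWN_UNITS = ("hartree", "kcal/mol")


def hartree_to_kcal(x: float) -> float:
    """Convert an energy from Hartree to kcal/mol."""
    return x * HARTREE_TO_KCAL


def kcal_to_hartree(x: float) -> float:
    """Convert an energy from kcal/mol to Hartree."""
    return x / HARTREE_TO_KCAL
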