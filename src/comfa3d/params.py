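"""Shared physical constants and force-field parameters.

The van der Waals table is a small Tripos-style parameter set covering the
elements occurring in the packaged series (C, H, N, O, S, F, Cl, Br).
Radii are in Angstrom, well depths in kcal/mol.
"""

from __future__ import annotations

# element -> (vdW radius [A], well depth epsilon [kcal/mol])
VDW_PARAMS: dict[str, tuple[float, float]] = {
    "C": (1.70, 0.107),
    "H": (1.50, 0.042),
    "N": (1.55, 0.095),
    "O": (1.52, 0.116),
    "S": (1.80, 0.314),
    "F": (1.47, 0.109),
    "Cl": (1.75, 0.314),
    "Br": (1.85, 0.434),
}

#: Coulomb conversion constant, kcal * A * mol^-1 * e^-2
COULOMB_CONSTANT = 332.0

#: truncation bound for both field types, kcal/mol
ENERGY_CUTOFF = 30.0

#: probe geometry fixed by the reproduced protocol
PROBE_RADIUS = 1.52
PROBE_CHARGE = 1.0
PROBE_WELL_DEPTH = VDW_PARAMS["C"][1]


class ParameterTableError(KeyError):
    """An element is missing from an embedded parameter table."""


def vdw_for(element: str) -> tuple[float, float]:
    try:
        return VDW_PARAMS[element]
    except KeyError:
        raise ParameterTableError(
            f"no van der Waals parameters for element {element!r}"
        ) from None
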