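"""Physical constants, element tables, and the standard-tetrahedral geometry data.

Internal units are atomic units throughout (bohr, hartree); I/O converts to and
from ångström with the conversion factor below.
"""

import math

#: bohr → ångström conversion (Bohr radius in Å).
BOHR_ANGSTROM = 0.529177249

#: The unique tetrahedron bond angle θ = arccos(−1/3), radians (≈ 109.471°).
TETRA_ANGLE = math.acos(-1.0 / 3.0)

#: The unique dihedral angle δ = 2π/3, radians (exactly 120°).
DIHEDRAL_ANGLE = 2.0 * math.pi / 3.0

#: Distance of a lone-pair vertex from its parent atom, bohr (one Bohr radius).
LONE_PAIR_DISTANCE = 1.0

#: Elements allowed as central (tetrahedral) atoms, i.e. the eight anchor hydrides.
CENTRAL_ELEMENTS = ("C", "N", "O", "F", "Si", "P", "S", "Cl")

#: Valence charge Z_val = main-group column index of the periodic table, e.
Z_VAL = {
    "H": 1,
    "C": 4, "N": 5, "O": 6, "F": 7,
    "Si": 4, "P": 5, "S": 6, "Cl": 7,
}

#: Principal valence shell n_val = row index of the periodic table.
N_VAL = {
    "H": 1,
    "C": 2, "N": 2, "O": 2, "F": 2,
    "Si": 3, "P": 3, "S": 3, "Cl": 3,
}

#: Lone pairs carried by each central atom (octet bookkeeping: 4 − #bonds).
LONE_PAIRS = {
    "C": 0, "Si": 0,
    "N": 1, "P": 1,
    "O": 2, "S": 2,
    "F": 3, "Cl": 3,
}

#: Terminal group → heavy element of the group.
TERMINAL_ELEMENT = {
    "CH3": "C", "NH2": "N", "OH": "O", "F": "F",
    "SiH3": "Si", "PH2": "P", "SH": "S", "Cl": "Cl",
}

#: Default bond-length table, Å.  Fully overridable through the molecule config.
DEFAULT_BOND_LENGTHS = {
    ("C", "C"): 1.54,
    ("C", "H"): 1.09,
    ("N", "H"): 1.01,
    ("O", "H"): 0.96,
    ("C", "N"): 1.47,
    ("C", "O"): 1.43,
    ("C", "F"): 1.38,
    ("Si", "H"): 1.48,
    ("P", "H"): 1.42,
    ("S", "H"): 1.34,
    ("H", "Cl"): 1.27,
    ("C", "Cl"): 1.77,
    ("C", "Si"): 1.87,
    ("C", "P"): 1.84,
    ("C", "S"): 1.82,
    ("H", "F"): 0.92,
    ("F", "F"): 1.42,
    ("Cl", "Cl"): 1.99,
    ("F", "Cl"): 1.63,
    ("H", "Si"): 1.48,
    ("H", "P"): 1.42,
    ("H", "S"): 1.34,
}


def bond_length_bohr(el_a: str, el_b: str, table: dict | None = None) -> float:
    """Bond length between two elements in bohr.

    ``table`` entries (Å) override the defaults; keys are unordered pairs.
    """
    merged = dict(DEFAULT_BOND_LENGTHS)
    if table:
        for key, val in table.items():
            pair = tuple(key) if not isinstance(key, str) else tuple(key.split("-"))
            merged[tuple(pair)] = float(val)
    for key in ((el_a, el_b), (el_b, el_a)):
        if key in merged:
            return merged[key] / BOHR_ANGSTROM
    raise KeyError(f"no bond length tabulated for pair {el_a}-{el_b}")
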