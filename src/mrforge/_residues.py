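"""Heavy-atom chemistry tables for the 20 standard amino acids.

Connectivity and planar-group membership drive constraint extraction in
:mod:`mrforge.dg_ensemble`; van der Waals radii are shared between the
distance-geometry exclusion term and the accessible-surface calculation.
"""

from __future__ import annotations

# Bondi radii for the elements that occur in heavy-atom protein models.
VDW_RADII: dict[str, float] = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}
DEFAULT_VDW_RADIUS = 1.8

# Side-chain heavy-atom bonds (backbone N-CA, CA-C, C-O, CA-CB and the
# peptide link are added generically).
SIDE_CHAIN_BONDS: dict[str, tuple[tuple[str, str], ...]] = {
    "ALA": (),
    "ARG": (("CB", "CG"), ("CG", "CD"), ("CD", "NE"), ("NE", "CZ"),
            ("CZ", "NH1"), ("CZ", "NH2")),
    "ASN": (("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")),
    "ASP": (("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")),
    "CYS": (("CB", "SG"),),
    "GLN": (("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2")),
    "GLU": (("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")),
    "GLY": (),
    "HIS": (("CB", "CG"), ("CG", "ND1"), ("ND1", "CE1"), ("CE1", "NE2"),
            ("NE2", "CD2"), ("CD2", "CG")),
    "ILE": (("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")),
    "LEU": (("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")),
    "LYS": (("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")),
    "MET": (("CB", "CG"), ("CG", "SD"), ("SD", "CE")),
    "PHE": (("CB", "CG"), ("CG", "CD1"), ("CD1", "CE1"), ("CE1", "CZ"),
            ("CZ", "CE2"), ("CE2", "CD2"), ("CD2", "CG")),
    "PRO": (("CB", "CG"), ("CG", "CD"), ("CD", "N")),
    "SER": (("CB", "OG"),),
    "THR": (("CB", "OG1"), ("CB", "CG2")),
    "TRP": (("CB", "CG"), ("CG", "CD1"), ("CD1", "NE1"), ("NE1", "CE2"),
            ("CE2", "CD2"), ("CD2", "CG"), ("CE2", "CZ2"), ("CZ2", "CH2"),
            ("CH2", "CZ3"), ("CZ3", "CE3"), ("CE3", "CD2")),
    "TYR": (("CB", "CG"), ("CG", "CD1"), ("CD1", "CE1"), ("CE1", "CZ"),
            ("CZ", "CE2"), ("CE2", "CD2"), ("CD2", "CG"), ("CZ", "OH")),
    "VAL": (("CB", "CG1"), ("CB", "CG2")),
}

STANDARD_RESIDUES = frozenset(SIDE_CHAIN_BONDS)

# Rigid/planar side-chain groups: all intra-group pairs are treated as
# near-rigid (tier 2) even when separated by >2 bonds.
PLANAR_GROUPS: dict[str, tuple[tuple[str, ...], ...]] = {
    "PHE": (("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),),
    "TRP": (("CB", "CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ2",
             "CZ3", "CH2"),),
    "HIS": (("CB", "CG", "ND1", "CD2", "CE1", "NE2"),),
    "ARG": (("CD", "NE", "CZ", "NH1", "NH2"),),
    "ASP": (("CB", "CG", "OD1", "OD2"),),
    "GLU": (("CG", "CD", "OE1", "OE2"),),
    "ASN": (("CB", "CG", "OD1", "ND2"),),
    "GLN": (("CG", "CD", "OE1", "NE2"),),
}

# Atom subset kept by poly-alanine side-chain stripping.
POLYALA_ATOMS = frozenset({"N", "CA", "C", "O", "CB"})

# Residue types whose side-chain rotamers are comparatively predictable
# (few well-occupied rotamers); kept intact under the "reliable" mode.
RELIABLE_SIDE_CHAINS = frozenset(
    {"CYS", "MET", "PHE", "TRP", "TYR", "ILE", "LEU", "VAL", "PRO"})

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


def vdw_radius(element: str) -> float:
    """Van der Waals radius in Å for an element symbol (case-insensitive)."""
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)
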