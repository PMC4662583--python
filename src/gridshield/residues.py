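"""Static per-residue chemistry tables.

Everything the rest of the package needs to know about the canonical 20
amino acids lives here: side-chain torsion definitions, aromatic ring
membership, hydrogen-bond donor/acceptor atom sets.
"""

from __future__ import annotations

STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

#: Atom quadruples defining chi1..chi4 (IUPAC).  The torsion count of a
#: residue type is the length of its entry.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ALA": [],
    "GLY": [],
    "SER": [("N", "CA", "CB", "OG")],
    "CYS": [("N", "CA", "CB", "SG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
}

CHI_COUNT = {res: len(v) for res, v in CHI_ATOMS.items()}

#: Aromatic ring membership.  Trp contributes two rings that are treated
#: as independent point dipoles.
RING_ATOMS: dict[str, list[tuple[str, tuple[str, ...]]]] = {
    "PHE": [("PHE", ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"))],
    "TYR": [("TYR", ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"))],
    "HIS": [("HIS", ("CG", "ND1", "CD2", "CE1", "NE2"))],
    "TRP": [
        ("TRP5", ("CG", "CD1", "CD2", "NE1", "CE2")),
        ("TRP6", ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")),
    ],
}

#: Side-chain acceptor oxygens: atom -> (carbon, rho reference atom(s),
#: acceptor class).  The rho dihedral is H..O-C-ref; for hydroxyls the
#: reference is the hydroxyl hydrogen when present, with a heavy-atom
#: fallback.  Backbone carbonyls are handled separately (the rho
#: reference is the following residue's amide nitrogen).
SIDECHAIN_ACCEPTORS: dict[str, list[tuple[str, str, tuple[str, ...], str]]] = {
    "ASP": [("OD1", "CG", ("CB",), "carboxyl"), ("OD2", "CG", ("CB",), "carboxyl")],
    "GLU": [("OE1", "CD", ("CG",), "carboxyl"), ("OE2", "CD", ("CG",), "carboxyl")],
    "ASN": [("OD1", "CG", ("ND2",), "amide_carbonyl")],
    "GLN": [("OE1", "CD", ("NE2",), "amide_carbonyl")],
    "SER": [("OG", "CB", ("HG", "CA"), "hydroxyl")],
    "THR": [("OG1", "CB", ("HG1", "CA"), "hydroxyl")],
    "TYR": [("OH", "CZ", ("HH", "CE1"), "hydroxyl")],
}

#: Side-chain N-H hydrogens usable as secondary-term donors (amine class).
AMINE_HYDROGENS: dict[str, list[tuple[str, str]]] = {
    "LYS": [("HZ1", "NZ"), ("HZ2", "NZ"), ("HZ3", "NZ")],
    "ARG": [("HE", "NE"), ("HH11", "NH1"), ("HH12", "NH1"),
            ("HH21", "NH2"), ("HH22", "NH2")],
    "ASN": [("HD21", "ND2"), ("HD22", "ND2")],
    "GLN": [("HE21", "NE2"), ("HE22", "NE2")],
    "HIS": [("HD1", "ND1"), ("HE2", "NE2")],
    "TRP": [("HE1", "NE1")],
}

#: Atom types the predictor reports.  "HN" is the backbone amide proton
#: (PDB atom name "H"); all others coincide with their PDB names.
ATOM_TYPES = ("CA", "CB", "C", "HA", "HN", "N")

#: PDB atom name carrying each predicted atom type.
ATOM_TYPE_TO_PDB = {"CA": "CA", "CB": "CB", "C": "C", "HA": "HA", "HN": "H", "N": "N"}
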