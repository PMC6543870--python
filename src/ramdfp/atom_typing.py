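"""Pharmacophore typing tables for standard amino acids and table-driven ligand typing.

Protein atoms are assigned hydrogen-bond donor/acceptor, formal-charge and
apolar-carbon roles from residue/atom-name dictionaries (protonation states
at pH 7: Lys/Arg cationic, Asp/Glu anionic, His neutral). Ligands are typed
from an explicit per-atom table (JSON or dict) because small-molecule
perception is not this package's job; the table states, for each heavy
atom, whether it can donate or accept a hydrogen bond, its formal-charge
class, whether it is an apolar carbon, and which atoms form aromatic rings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AtomTypingError",
    "LigandTyping",
    "protein_flags",
    "protein_rings",
    "one_letter",
]


class AtomTypingError(ValueError):
    """Raised when atom typing information is missing or inconsistent."""


# hydrogen-bond donor heavy atoms (side chains; backbone N handled separately)
_SIDECHAIN_DONORS = {
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "TRP": {"NE1"},
    "HIS": {"ND1", "NE2"},
}

# hydrogen-bond acceptor heavy atoms (backbone O/OXT handled separately)
_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
    "MET": {"SD"},
}

# formal-charge centres at pH 7
_CATIONIC = {
    "LYS": {"NZ"},
    "ARG": {"CZ", "NH1", "NH2", "NE"},
}
_ANIONIC = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}

# aromatic ring atom names per residue (TRP contributes two rings)
_AROMATIC_RINGS = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TRP": [
        ["CG", "CD1", "CD2", "NE1", "CE2"],
        ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    ],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
}

# carbons with no bonded N/O/S polar neighbour ("apolar" carbons)
_APOLAR_CARBONS = {
    "ALA": {"CB"},
    "VAL": {"CB", "CG1", "CG2"},
    "LEU": {"CB", "CG", "CD1", "CD2"},
    "ILE": {"CB", "CG1", "CG2", "CD1", "CD"},
    "PRO": {"CB", "CG"},
    "MET": {"CB", "CG", "CE"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2"},
    "THR": {"CG2"},
    "LYS": {"CB", "CG", "CD"},
    "ARG": {"CB", "CG"},
    "GLU": {"CB", "CG"},
    "GLN": {"CB", "CG"},
    "ASP": {"CB"},
    "ASN": {"CB"},
    "HIS": {"CB"},
    "CYS": {"CB"},
}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
           "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904}


def one_letter(resname: str) -> str:
    """One-letter code for a residue name; unknown residues keep their name."""
    return _THREE_TO_ONE.get(resname.upper(), resname)


def element_mass(element: str) -> float:
    return _MASSES.get(element.upper(), 12.011)


def protein_flags(resnames, atom_names, elements):
    """Boolean role arrays (donor, acceptor, cationic, anionic, apolar) for protein atoms.

    Backbone N is a donor for every residue except proline; backbone O and
    OXT are acceptors for every residue.
    """
    n = len(atom_names)
    donor = np.zeros(n, bool)
    acceptor = np.zeros(n, bool)
    cation = np.zeros(n, bool)
    anion = np.zeros(n, bool)
    apolar = np.zeros(n, bool)
    for i, (res, name) in enumerate(zip(resnames, atom_names)):
        res = res.upper()
        if name == "N" and res != "PRO":
            donor[i] = True
        if name in ("O", "OXT"):
            acceptor[i] = True
        donor[i] |= name in _SIDECHAIN_DONORS.get(res, ())
        acceptor[i] |= name in _SIDECHAIN_ACCEPTORS.get(res, ())
        cation[i] = name in _CATIONIC.get(res, ())
        anion[i] = name in _ANIONIC.get(res, ())
        apolar[i] = name in _APOLAR_CARBONS.get(res, ())
    return donor, acceptor, cation, anion, apolar


def protein_rings(resids, resnames, atom_names):
    """Aromatic ring index groups: list of (resid, index array) per complete ring."""
    by_res: dict[int, dict[str, int]] = {}
    res_name: dict[int, str] = {}
    for i, (rid, rname, aname) in enumerate(zip(resids, resnames, atom_names)):
        by_res.setdefault(int(rid), {})[aname] = i
        res_name[int(rid)] = rname.upper()
    rings = []
    for rid, atoms in by_res.items():
        for ring_names in _AROMATIC_RINGS.get(res_name[rid], ()):
            if all(a in atoms for a in ring_names):
                rings.append((rid, np.array([atoms[a] for a in ring_names])))
    return rings


@dataclass
class LigandTyping:
    """Per-atom pharmacophore table for one ligand.

    ``atoms`` maps atom name -> flag dict with optional keys ``donor``,
    ``acceptor``, ``cationic``, ``anionic``, ``apolar``; ``rings`` lists
    aromatic rings as atom-name lists; ``masses`` optionally overrides
    element-derived masses.
    """

    atoms: dict = field(default_factory=dict)
    rings: list = field(default_factory=list)
    masses: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path) -> "LigandTyping":
        data = json.loads(Path(path).read_text())
        return cls(atoms=data.get("atoms", {}),
                   rings=data.get("rings", []),
                   masses=data.get("masses", {}))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"atoms": self.atoms, "rings": self.rings, "masses": self.masses},
            indent=1))

    def flag_arrays(self, atom_names):
        n = len(atom_names)
        out = {k: np.zeros(n, bool)
               for k in ("donor", "acceptor", "cationic", "anionic", "apolar")}
        for i, name in enumerate(atom_names):
            flags = self.atoms.get(name, {})
            for k in out:
                out[k][i] = bool(flags.get(k, False))
        return (out["donor"], out["acceptor"], out["cationic"],
                out["anionic"], out["apolar"])

    def ring_indices(self, atom_names):
        index = {name: i for i, name in enumerate(atom_names)}
        rings = []
        for ring in self.rings:
            missing = [a for a in ring if a not in index]
            if missing:
                raise AtomTypingError(
                    f"ligand ring atoms not found in structure: {missing}")
            rings.append(np.array([index[a] for a in ring]))
        return rings
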