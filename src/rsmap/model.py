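"""Atomic models: records, residue chemistry, classification and model I/O.

Coordinates are Å throughout.  Models are read and written with gemmi
(PDB fixed-column and mmCIF, transparently gzipped), then held in a light
array-friendly container.  Bonds come from fixed residue templates for the
20 standard amino acids plus water — never from distances, so toy fixtures
cannot acquire spurious bonds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "ATOM_CLASSES",
    "read_model",
    "write_model",
    "classify_atoms",
    "derive_bonds",
    "neighbor_b_rmsd",
    "select_atoms",
]

ATOM_CLASSES = (
    "backbone",
    "side_chain_C",
    "side_chain_other",
    "protein_H",
    "solvent_O",
    "solvent_H",
    "ion",
)

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
WATER_NAMES = {"HOH", "WAT", "DOD"}
ION_NAMES = {"MG", "ZN", "CA", "NA", "CL", "K", "MN", "FE", "FE2", "NI", "CU", "CO"}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

# Heavy-atom side-chain connectivity; backbone N-CA-C(-O)(-OXT) and CA-CB are implicit.
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
    "HIS": (("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"), ("ND1", "CE1"),
            ("CE1", "NE2"), ("NE2", "CD2")),
    "ILE": (("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")),
    "LEU": (("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")),
    "LYS": (("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")),
    "MET": (("CB", "CG"), ("CG", "SD"), ("SD", "CE")),
    "PHE": (("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")),
    "PRO": (("CB", "CG"), ("CG", "CD"), ("CD", "N")),
    "SER": (("CB", "OG"),),
    "THR": (("CB", "OG1"), ("CB", "CG2")),
    "TRP": (("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "NE1"),
            ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"), ("CE2", "CZ2"),
            ("CZ2", "CH2"), ("CH2", "CZ3"), ("CZ3", "CE3")),
    "TYR": (("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"), ("CZ", "OH")),
    "VAL": (("CB", "CG1"), ("CB", "CG2")),
}

ELEMENT_Z = {
    "H": 1, "C": 6, "N": 7, "O": 8, "NA": 11, "MG": 12, "P": 15, "S": 16,
    "CL": 17, "K": 19, "CA": 20, "MN": 25, "FE": 26, "NI": 28, "CU": 29,
    "ZN": 30, "D": 1,
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, position, displacement and occupancy.

    ``b_iso`` is the isotropic displacement parameter B in Å²; ``occupancy``
    is the fractional occupancy q in [0, 1]; ``atomic_number`` Z counts the
    electrons of the neutral atom.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain: str
    xyz: tuple[float, float, float]
    b_iso: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""
    atomic_number: int = 0

    def __post_init__(self):
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1] for atom {self.name}")
        if self.b_iso < 0:
            raise ValueError(f"negative B-factor for atom {self.name}")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if self.atomic_number == 0:
            z = ELEMENT_Z.get(self.element.upper())
            if z is None:
                raise ValueError(f"unknown element {self.element!r} for atom {self.name}")
            object.__setattr__(self, "atomic_number", z)
        elif self.element.upper() in ELEMENT_Z and ELEMENT_Z[self.element.upper()] != self.atomic_number:
            raise ValueError(
                f"atomic number {self.atomic_number} inconsistent with element "
                f"{self.element} for atom {self.name}")


class StructureModel:
    """An ordered collection of atoms with template-derived bonds and class tags.

    Array views (``xyz``, ``b_iso``, ``occupancy``, ...) are rebuilt lazily;
    mutate through :meth:`with_xyz` / :meth:`with_occupancy` style copies or
    call :meth:`invalidate` after editing ``atoms`` in place.
    """

    def __init__(self, atoms: Sequence[AtomRecord],
                 bonds: Sequence[tuple[int, int]] | None = None,
                 class_tags: Sequence[str] | None = None):
        self.atoms: list[AtomRecord] = list(atoms)
        n = len(self.atoms)
        if bonds is not None:
            for i, j in bonds:
                if not (0 <= i < n and 0 <= j < n):
                    raise ValueError(f"bond ({i}, {j}) references invalid atom index")
        self.bonds: list[tuple[int, int]] = list(bonds) if bonds is not None else []
        if class_tags is not None:
            if len(class_tags) != n:
                raise ValueError("class_tags length mismatch")
            for t in class_tags:
                if t not in ATOM_CLASSES:
                    raise ValueError(f"unknown atom class {t!r}")
        self.class_tags: list[str] | None = list(class_tags) if class_tags is not None else None
        self._cache: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.atoms)

    def invalidate(self) -> None:
        self._cache.clear()

    def _arr(self, key: str, build) -> np.ndarray:
        if key not in self._cache:
            self._cache[key] = build()
        return self._cache[key]

    @property
    def xyz(self) -> np.ndarray:
        return self._arr("xyz", lambda: np.array([a.xyz for a in self.atoms], float).reshape(-1, 3))

    @property
    def b_iso(self) -> np.ndarray:
        return self._arr("b", lambda: np.array([a.b_iso for a in self.atoms], float))

    @property
    def occupancy(self) -> np.ndarray:
        return self._arr("q", lambda: np.array([a.occupancy for a in self.atoms], float))

    @property
    def atomic_number(self) -> np.ndarray:
        return self._arr("z", lambda: np.array([a.atomic_number for a in self.atoms], int))

    @property
    def elements(self) -> np.ndarray:
        return self._arr("el", lambda: np.array([a.element.upper() for a in self.atoms]))

    def tags(self) -> np.ndarray:
        if self.class_tags is None:
            classify_atoms(self)
        return np.asarray(self.class_tags)

    def with_xyz(self, xyz: np.ndarray) -> "StructureModel":
        xyz = np.asarray(xyz, float)
        if xyz.shape != (len(self), 3):
            raise ValueError("xyz shape mismatch")
        atoms = [replace(a, xyz=tuple(p)) for a, p in zip(self.atoms, xyz)]
        return StructureModel(atoms, self.bonds, self.class_tags)

    def with_occupancy(self, q: np.ndarray) -> "StructureModel":
        q = np.asarray(q, float)
        atoms = [replace(a, occupancy=float(v)) for a, v in zip(self.atoms, q)]
        return StructureModel(atoms, self.bonds, self.class_tags)

    def select(self, **kw) -> np.ndarray:
        return select_atoms(self, **kw)


def select_atoms(model: StructureModel, *, class_tag: str | None = None,
                 residue_names: Iterable[str] | None = None,
                 residue_range: tuple[int, int] | None = None,
                 chain: str | None = None,
                 heavy_only: bool = False) -> np.ndarray:
    """Boolean mask over atoms; criteria combine with AND."""
    keep = np.ones(len(model), bool)
    if class_tag is not None:
        keep &= model.tags() == class_tag
    if residue_names is not None:
        names = {r.upper() for r in residue_names}
        keep &= np.array([a.residue_name.upper() in names for a in model.atoms])
    if residue_range is not None:
        lo, hi = residue_range
        keep &= np.array([lo <= a.residue_seq <= hi for a in model.atoms])
    if chain is not None:
        keep &= np.array([a.chain == chain for a in model.atoms])
    if heavy_only:
        keep &= model.elements != "H"
    return keep


def _infer_element(atom_name: str, residue_name: str) -> str:
    """Element from a PDB atom name when the element column is absent."""
    name = atom_name.strip()
    if residue_name.upper() in ION_NAMES and name.upper() in ELEMENT_Z:
        return name.upper().capitalize()
    stripped = name.lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    first = stripped[0].upper()
    if first in ("H", "D"):
        return "H"
    if first in ("C", "N", "O", "S", "P"):
        return first
    two = stripped[:2].upper()
    if two in ELEMENT_Z:
        return two.capitalize()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def read_model(path: str | Path, dialect: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF model (gzip ok) into a :class:`StructureModel`.

    ``dialect`` forces ``"pdb"`` or ``"mmcif"``; by default the format is
    detected from the extension.  Altloc records are all retained; analyses
    that need a single conformer reduce with :func:`primary_conformer`.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {None: gemmi.CoorFormat.Detect,
           "pdb": gemmi.CoorFormat.Pdb,
           "mmcif": gemmi.CoorFormat.Mmcif}[dialect]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse model file {path}: {exc}") from exc
    st.setup_entities()
    atoms: list[AtomRecord] = []
    serial = 0
    for mdl in st:
        for ch in mdl:
            for res in ch:
                for at in res:
                    serial += 1
                    el = "H" if at.element.is_hydrogen else at.element.name
                    if el in ("X", ""):
                        el = _infer_element(at.name, res.name)
                    atoms.append(AtomRecord(
                        serial=serial, name=at.name, element=el,
                        residue_name=res.name, residue_seq=res.seqid.num,
                        chain=ch.name, xyz=(at.pos.x, at.pos.y, at.pos.z),
                        b_iso=max(at.b_iso, 0.0), occupancy=min(max(at.occ, 0.0), 1.0),
                        altloc=at.altloc if at.altloc != "\x00" else ""))
        break  # first model only
    if not atoms:
        raise ValueError(f"no atoms parsed from {path}")
    m = StructureModel(atoms)
    classify_atoms(m)
    derive_bonds(m)
    return m


def write_model(model: StructureModel, path: str | Path, dialect: str | None = None) -> None:
    """Write to PDB (fixed-column) or mmCIF, chosen from the extension."""
    import gemmi

    path = Path(path)
    st = gemmi.Structure()
    st.name = "rsmap"
    mdl = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    last_res_key = None
    res = None
    for a in model.atoms:
        if a.chain not in chains:
            chains[a.chain] = gemmi.Chain(a.chain)
        ch = chains[a.chain]
        key = (a.chain, a.residue_seq, a.residue_name)
        if key != last_res_key:
            r = gemmi.Residue()
            r.name = a.residue_name
            r.seqid = gemmi.SeqId(a.residue_seq, " ")
            res = ch.add_residue(r)
            last_res_key = key
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.xyz)
        at.b_iso = a.b_iso
        at.occ = a.occupancy
        at.altloc = a.altloc if a.altloc else "\x00"
        res.add_atom(at)
    for ch in chains.values():
        mdl.add_chain(ch)
    st.add_model(mdl)
    st.setup_entities()
    if dialect == "mmcif" or (dialect is None and path.suffix.lower() in (".cif", ".mmcif")):
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


def classify_atoms(model: StructureModel) -> StructureModel:
    """Tag each atom with exactly one analysis class.

    Backbone is N, CA, C, O (+OXT); carbons outside the backbone are
    ``side_chain_C``; hydrogens split protein vs solvent; single-atom ion
    residues are ``ion``; anything in a nonstandard residue is
    ``side_chain_other`` (warned, never dropped).
    """
    tags: list[str] = []
    warned: set[str] = set()
    for a in model.atoms:
        res = a.residue_name.upper()
        el = a.element.upper()
        if res in WATER_NAMES:
            tags.append("solvent_H" if el == "H" else "solvent_O")
        elif res in ION_NAMES:
            tags.append("ion")
        elif res in STANDARD_AA:
            if el == "H":
                tags.append("protein_H")
            elif a.name.strip().upper() in BACKBONE_ATOMS:
                tags.append("backbone")
            elif el == "C":
                tags.append("side_chain_C")
            else:
                tags.append("side_chain_other")
        else:
            if res not in warned:
                warnings.warn(f"nonstandard residue {res}: atoms tagged side_chain_other")
                warned.add(res)
            tags.append("side_chain_other")
    model.class_tags = tags
    return model


def _hydrogen_parent(res_atoms: dict[str, int], hname: str) -> int | None:
    """Parent heavy atom of a hydrogen, by PDB v3 naming (riding convention)."""
    name = hname.strip().upper().lstrip("0123456789")
    rem = name[1:]  # drop leading H
    candidates = [rem]
    while rem and rem[-1].isdigit():
        rem = rem[:-1]
        candidates.append(rem)
    for cand in candidates:
        for heavy, idx in res_atoms.items():
            h = heavy.strip().upper()
            if h and h[0] in "CNOS" and h[1:] == cand:
                return idx
        if cand == "":
            if "N" in res_atoms:
                return res_atoms["N"]
            if "O" in res_atoms:  # water
                return res_atoms["O"]
    return None


def derive_bonds(model: StructureModel) -> StructureModel:
    """Populate the bond list from residue templates (+ inter-residue peptide bonds)."""
    bonds: list[tuple[int, int]] = []
    # group indices per (chain, seq, resname, altloc-insensitive)
    groups: dict[tuple, dict[str, int]] = {}
    order: list[tuple] = []
    for i, a in enumerate(model.atoms):
        key = (a.chain, a.residue_seq, a.residue_name.upper())
        if key not in groups:
            groups[key] = {}
            order.append(key)
        groups[key].setdefault(a.name.strip().upper(), i)
    by_pos = {(k[0], k[1]): k for k in order}
    for key in order:
        chain, seq, res = key
        idx = groups[key]
        pairs: list[tuple[str, str]] = []
        if res in STANDARD_AA:
            pairs += [("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT"), ("CA", "CB")]
            pairs += list(SIDE_CHAIN_BONDS.get(res, ()))
        elif res in WATER_NAMES:
            pass
        for x, y in pairs:
            if x in idx and y in idx:
                bonds.append((idx[x], idx[y]))
        # hydrogens ride their name-matched heavy atom
        for name, i in idx.items():
            if model.atoms[i].element.upper() == "H":
                p = _hydrogen_parent(idx, name)
                if p is not None:
                    bonds.append((p, i))
        # peptide bond to the next residue in the same chain
        key2 = by_pos.get((chain, seq + 1))
        if key2 is not None and res in STANDARD_AA and key2[2] in STANDARD_AA:
            if "C" in idx and "N" in groups[key2]:
                bonds.append((idx["C"], groups[key2]["N"]))
    model.bonds = bonds
    return model


def neighbor_b_rmsd(model: StructureModel) -> float:
    """Root-mean-square B-factor difference over bonded atom pairs (Å²).

    The smoothness diagnostic used when restraining neighboring atomic
    displacement parameters toward each other.
    """
    if not model.bonds:
        raise ValueError("model has no bonds; run derive_bonds first")
    b = model.b_iso
    d = np.array([b[i] - b[j] for i, j in model.bonds])
    return float(np.sqrt(np.mean(d * d)))


def primary_conformer(model: StructureModel) -> StructureModel:
    """Reduce altloc groups to the highest-occupancy conformer (ties → 'A')."""
    best: dict[tuple, int] = {}
    for i, a in enumerate(model.atoms):
        key = (a.chain, a.residue_seq, a.residue_name, a.name)
        if key not in best:
            best[key] = i
        else:
            b = model.atoms[best[key]]
            if (a.occupancy, -ord(a.altloc or "A")) > (b.occupancy, -ord(b.altloc or "A")):
                best[key] = i
    keep = sorted(best.values())
    m = StructureModel([model.atoms[i] for i in keep])
    classify_atoms(m)
    derive_bonds(m)
    return m
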