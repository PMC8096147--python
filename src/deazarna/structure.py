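"""Crystal-structure superposition and minor-groove hydration analysis.

Compares a deazapurine-modified RNA structure with its unmodified
counterpart: rigid-body least-squares superposition (Kabsch) over a
paired atom selection, Euclidean atom-atom distances, and a census of
ordered water molecules contacting the minor-groove face of a chosen
base pair.  The minor-groove face comprises the purine N3 (or the C3
carbon that replaces it in a 3-deazapurine), the pyrimidine O2 carbonyl
and both riboses' 2'-OH oxygens — the anchor points of the hydration
spine of an A-form double helix.

PDB and mmCIF files are read through gemmi; coordinates are held in a
plain atom table so the geometry code has no file-format dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Atom",
    "StructureModel",
    "AtomSelection",
    "HydrationReport",
    "WaterContact",
    "read_structure",
    "write_pdb",
    "kabsch",
    "superpose",
    "atom_distance",
    "minor_groove_waters",
    "MINOR_GROOVE_ATOMS_PURINE",
    "MINOR_GROOVE_ATOMS_PYRIMIDINE",
]

#: Minor-groove-face atom names.  N3 is the canonical purine acceptor;
#: C3 is its carbon replacement in 3-deazapurines; O2' is the 2'-OH.
MINOR_GROOVE_ATOMS_PURINE = ("N3", "C3", "O2'")
MINOR_GROOVE_ATOMS_PYRIMIDINE = ("O2", "O2'")

_PURINES = {"A", "G", "C3A", "C7A", "C3G", "C7G", "ADE", "GUA"}
_PYRIMIDINES = {"C", "U", "CYT", "URA", "URI"}


@dataclass(frozen=True)
class Atom:
    element: str
    name: str
    residue_name: str
    residue_number: int
    chain: str
    xyz: tuple
    occupancy: float = 1.0
    altloc: str = ""
    is_water: bool = False


@dataclass
class StructureModel:
    """A flat list of atoms with their source identifier."""

    atoms: List[Atom]
    source_id: str = ""

    def __post_init__(self):
        for a in self.atoms:
            if not all(np.isfinite(a.xyz)):
                raise ValueError(f"non-finite coordinates on atom {a}")

    def __len__(self):
        return len(self.atoms)

    def coords(self, atoms: Optional[Sequence[Atom]] = None) -> np.ndarray:
        atoms = self.atoms if atoms is None else atoms
        return np.array([a.xyz for a in atoms], dtype=float).reshape(-1, 3)

    def waters(self, min_occupancy: float = 0.5) -> List[Atom]:
        """Ordered-water oxygen atoms at or above the occupancy floor."""
        return [a for a in self.atoms
                if a.is_water and a.element != "H"
                and a.occupancy >= min_occupancy]

    def residue(self, residue_number: int,
                chain: Optional[str] = None) -> List[Atom]:
        out = [a for a in self.atoms
               if a.residue_number == residue_number and not a.is_water
               and (chain is None or a.chain == chain)]
        if not out:
            raise KeyError(f"residue {residue_number}"
                           + (f" in chain {chain}" if chain else "")
                           + " not found")
        return _best_altloc(out)

    def transformed(self, rotation: np.ndarray,
                    translation: np.ndarray) -> "StructureModel":
        rot = np.asarray(rotation, float)
        tr = np.asarray(translation, float)
        atoms = [
            Atom(a.element, a.name, a.residue_name, a.residue_number, a.chain,
                 tuple(rot @ np.asarray(a.xyz) + tr), a.occupancy, a.altloc,
                 a.is_water)
            for a in self.atoms
        ]
        return StructureModel(atoms, source_id=self.source_id)


def _best_altloc(atoms: List[Atom]) -> List[Atom]:
    # keep one conformer per atom name: highest occupancy, ties -> altloc "A"
    by_name: dict = {}
    for a in atoms:
        prev = by_name.get(a.name)
        if prev is None or (a.occupancy, -ord(a.altloc or "A")) > \
                (prev.occupancy, -ord(prev.altloc or "A")):
            by_name[a.name] = a
    return list(by_name.values())


@dataclass
class AtomSelection:
    """A predicate over atoms, resolved to an ordered atom list.

    Any of ``chain``, ``residue_number``, ``atom_name``, ``element`` may
    be given (scalars or collections); ``predicate`` adds an arbitrary
    callable.  Waters are excluded unless ``include_waters``.
    """

    chain: Optional[object] = None
    residue_number: Optional[object] = None
    atom_name: Optional[object] = None
    element: Optional[object] = None
    include_waters: bool = False
    predicate: Optional[Callable[[Atom], bool]] = None

    @staticmethod
    def _match(value, spec) -> bool:
        if spec is None:
            return True
        if isinstance(spec, (str, int)):
            return value == spec
        return value in spec

    def resolve(self, model: StructureModel,
                best_altloc: bool = True) -> List[Atom]:
        picked = [
            a for a in model.atoms
            if (self.include_waters or not a.is_water)
            and self._match(a.chain, self.chain)
            and self._match(a.residue_number, self.residue_number)
            and self._match(a.name, self.atom_name)
            and self._match(a.element, self.element)
            and (self.predicate is None or self.predicate(a))
        ]
        if best_altloc:
            by_res: dict = {}
            for a in picked:
                by_res.setdefault((a.chain, a.residue_number, a.is_water,
                                   a.residue_name), []).append(a)
            picked = [a for group in by_res.values()
                      for a in _best_altloc(group)]
            picked.sort(key=lambda a: (a.chain, a.residue_number, a.name))
        return picked


@dataclass(frozen=True)
class WaterContact:
    water_id: str
    nearest_atom: str
    nearest_residue: int
    distance: float


@dataclass
class HydrationReport:
    """Ordered waters on the minor-groove face of one base pair."""

    base_pair: Tuple[int, int]
    waters: List[WaterContact]
    cutoff: float

    @property
    def n_waters(self) -> int:
        return len(self.waters)

    def summary(self) -> str:
        lines = [
            f"Minor-groove hydration of base pair {self.base_pair} "
            f"(cutoff {self.cutoff:.1f} A): {self.n_waters} ordered "
            f"water(s)"
        ]
        for w in self.waters:
            lines.append(
                f"  {w.water_id:<14s} -> {w.nearest_atom} of residue "
                f"{w.nearest_residue} at {w.distance:.1f} A"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# file I/O via gemmi
# ---------------------------------------------------------------------------

def read_structure(path, source_id: str = "") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    All altloc conformers are retained, with occupancies; waters are
    recognised by residue name HOH (or WAT).  The first model of a
    multi-model file is used.
    """
    import gemmi

    path = str(path)
    try:
        st = gemmi.read_structure(path)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: file contains no coordinate model")
    atoms: List[Atom] = []
    model = st[0]
    for chain in model:
        for res in chain:
            is_water = res.name.strip().upper() in ("HOH", "WAT")
            for at in res:
                atoms.append(Atom(
                    element=at.element.name,
                    name=at.name,
                    residue_name=res.name.strip(),
                    residue_number=res.seqid.num,
                    chain=chain.name,
                    xyz=(at.pos.x, at.pos.y, at.pos.z),
                    occupancy=at.occ,
                    altloc=at.altloc if at.altloc != "\x00" else "",
                    is_water=is_water,
                ))
    if not atoms:
        raise ValueError(f"{path}: no atoms found")
    return StructureModel(atoms, source_id=source_id or st.name or path)


def write_pdb(model: StructureModel, path) -> None:
    """Write the model as a minimal PDB file (ATOM/HETATM + END)."""
    with open(path, "w") as fh:
        for i, a in enumerate(model.atoms, start=1):
            record = "HETATM" if a.is_water else "ATOM  "
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            x, y, z = a.xyz
            fh.write(
                f"{record}{i:5d} {name:<4s}{a.altloc or ' ':1s}"
                f"{a.residue_name:>3s} {a.chain[:1] or 'A':1s}"
                f"{a.residue_number:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch(mobile_xyz: np.ndarray, target_xyz: np.ndarray):
    """Optimal rigid-body superposition of paired coordinate sets.

    Returns ``(rmsd, rotation, translation)`` such that
    ``rotation @ x + translation`` maps mobile onto target in the
    least-squares sense.  The rotation is proper (det = +1).
    """
    p = np.asarray(mobile_xyz, float)
    q = np.asarray(target_xyz, float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("paired coordinate sets must both be (n, 3)")
    if p.shape[0] < 3:
        raise ValueError("need at least 3 atom pairs for superposition")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    if np.linalg.matrix_rank(p0, tol=1e-8) < 2:
        raise ValueError("selection is collinear; rotation ill-defined")
    h = p0.T @ q0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    tr = qc - rot @ pc
    moved = (rot @ p.T).T + tr
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    return rmsd, rot, tr


def superpose(mobile: StructureModel, target: StructureModel,
              selection: Optional[AtomSelection] = None,
              atom_map: Optional[dict] = None):
    """Superpose two structures over matched atoms.

    Atoms are paired by ``(residue_number, atom_name)`` within the
    resolved selections (default: all non-hydrogen, non-water atoms,
    highest-occupancy altloc).  ``atom_map`` renames mobile atom names
    before matching — e.g. ``{"C3": "N3"}`` pairs a 3-deazapurine's C3
    with the parent purine's N3, the isosteric replacement.

    Returns ``(rmsd, rotation, translation)``; raises with the list of
    unmatched atoms if the pairing is incomplete on both sides.
    """
    sel = selection or AtomSelection(predicate=lambda a: a.element != "H")
    amap = atom_map or {}
    mob = sel.resolve(mobile)
    tar = sel.resolve(target)

    def key(a: Atom, mapped: bool):
        name = amap.get(a.name, a.name) if mapped else a.name
        return (a.residue_number, name)

    mob_by_key = {key(a, True): a for a in mob}
    tar_by_key = {key(a, False): a for a in tar}
    shared = sorted(set(mob_by_key) & set(tar_by_key))
    if len(shared) < 3:
        missing_m = sorted(set(tar_by_key) - set(mob_by_key))[:10]
        missing_t = sorted(set(mob_by_key) - set(tar_by_key))[:10]
        raise ValueError(
            "fewer than 3 shared atoms to superpose; unmatched in mobile: "
            f"{missing_m}; unmatched in target: {missing_t}"
        )
    p = np.array([mob_by_key[k].xyz for k in shared])
    q = np.array([tar_by_key[k].xyz for k in shared])
    return kabsch(p, q)


def atom_distance(model: StructureModel, sel1: AtomSelection,
                  sel2: AtomSelection) -> float:
    """Euclidean distance between two uniquely selected atoms, in A."""
    atoms1 = sel1.resolve(model)
    atoms2 = sel2.resolve(model)
    for label, atoms in (("first", atoms1), ("second", atoms2)):
        if len(atoms) != 1:
            raise ValueError(
                f"{label} selection resolves to {len(atoms)} atoms, not 1: "
                f"{[(a.residue_number, a.name) for a in atoms[:5]]}"
            )
    return float(np.linalg.norm(
        np.asarray(atoms1[0].xyz) - np.asarray(atoms2[0].xyz)
    ))


# ---------------------------------------------------------------------------
# hydration
# ---------------------------------------------------------------------------

def minor_groove_waters(model: StructureModel,
                        base_pair: Tuple[int, int],
                        cutoff: float = 3.6,
                        chain: Optional[str] = None,
                        min_occupancy: float = 0.5) -> HydrationReport:
    """Ordered waters on the minor-groove face of one base pair.

    A water counts if its oxygen lies within ``cutoff`` of any
    minor-groove-face atom of either residue (purine N3/C3 and 2'-OH;
    pyrimidine O2 and 2'-OH).  Each water is reported once, with its
    nearest contact, sorted by distance.  Waters below ``min_occupancy``
    are excluded (partially occupied sites are not part of the ordered
    hydration spine).
    """
    face_atoms: List[Atom] = []
    for resnum in base_pair:
        res = model.residue(resnum, chain=chain)   # raises if absent
        resname = res[0].residue_name.upper()
        if resname in _PURINES or resname.startswith(("C3", "C7")):
            wanted = MINOR_GROOVE_ATOMS_PURINE
        elif resname in _PYRIMIDINES:
            wanted = MINOR_GROOVE_ATOMS_PYRIMIDINE
        else:
            wanted = MINOR_GROOVE_ATOMS_PURINE + MINOR_GROOVE_ATOMS_PYRIMIDINE
        face_atoms.extend(a for a in res if a.name in wanted)
    if not face_atoms:
        raise ValueError(
            f"no minor-groove-face atoms found on residues {base_pair}"
        )
    face_xyz = np.array([a.xyz for a in face_atoms])
    contacts = []
    for w in model.waters(min_occupancy=min_occupancy):
        d = np.linalg.norm(face_xyz - np.asarray(w.xyz), axis=1)
        i = int(np.argmin(d))
        if d[i] <= cutoff:
            contacts.append(WaterContact(
                water_id=f"{w.residue_name}{w.residue_number}"
                         + (f".{w.chain}" if w.chain else ""),
                nearest_atom=face_atoms[i].name,
                nearest_residue=face_atoms[i].residue_number,
                distance=float(d[i]),
            ))
    contacts.sort(key=lambda c: c.distance)
    return HydrationReport(base_pair=tuple(base_pair), waters=contacts,
                           cutoff=cutoff)
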