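"""Binding-pocket model: structure parsing, site extraction and the
three-point residue representation.

A pocket is the set of protein residues whose heavy atoms lie within a
distance cutoff (default 4.5 Å) of a bound ligand's heavy atoms.  Every
pocket residue is reduced to three labelled points:

* ``ca`` -- the Cα position,
* ``cb`` -- the Cβ position (reconstructed at ideal tetrahedral geometry
  when the atom is missing),
* ``cn`` -- the unweighted centroid of the side-chain heavy atoms
  (Cβ and beyond).

Glycine carries no side chain, so ``cb == cn == ca``; for alanine the
side chain is just Cβ, so ``cn == cb``.  These identities are enforced at
construction time and everything downstream may rely on them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

log = logging.getLogger("pocketmotif")

__all__ = [
    "PocketError",
    "ResidueId",
    "Residue3P",
    "Pocket",
    "LoadedStructure",
    "load_structure",
    "extract_binding_site",
    "find_ligands",
    "three_point_representation",
    "read_pocket_file",
    "write_pocket_file",
]


class PocketError(ValueError):
    """Raised for malformed structures, empty sites and invalid pockets."""


STANDARD_AA3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1TO3 = {v: k for k, v in STANDARD_AA3.items()}
AA1TO3["X"] = "UNK"
STANDARD_AA1 = "ACDEFGHIKLMNPQRSTVWY"

# Nonstandard (modified) residues are mapped to their parent amino acid;
# anything unknown becomes 'X', which scores worst-case in BLOSUM lookups.
try:  # biopython ships a curated het-to-parent table
    from Bio.Data.PDBData import protein_letters_3to1_extended as _EXT3TO1
except ImportError:  # pragma: no cover
    _EXT3TO1 = {}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
_CB_BOND = 1.53  # ideal Cα-Cβ bond length, Å


def residue_letter(resname: str) -> str:
    """One-letter code for a 3-letter residue name ('X' when unknown)."""
    resname = resname.strip().upper()
    if resname in STANDARD_AA3:
        return STANDARD_AA3[resname]
    one = _EXT3TO1.get(resname, "X")
    return one if (len(one) == 1 and one in STANDARD_AA1) else "X"


@dataclass(frozen=True, order=True)
class ResidueId:
    """Identity of one pocket residue within its source structure."""

    structure_id: str
    chain: str
    resseq: int
    icode: str = ""
    aa: str = "X"

    def __post_init__(self):
        if self.aa not in STANDARD_AA1 and self.aa != "X":
            raise PocketError(f"invalid amino-acid code {self.aa!r}")

    @property
    def sort_key(self):
        return (self.chain, self.resseq, self.icode)

    def label(self) -> str:
        return f"{self.chain}{self.resseq}{self.icode}:{self.aa}"


@dataclass(frozen=True)
class Residue3P:
    """One pocket residue as three labelled 3D points (Å)."""

    id: ResidueId
    ca: np.ndarray
    cb: np.ndarray
    cn: np.ndarray

    def __post_init__(self):
        for name in ("ca", "cb", "cn"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
            if getattr(self, name).shape != (3,):
                raise PocketError(f"{name} must be a 3-vector")
        aa = self.id.aa
        if aa == "G":
            if not (np.array_equal(self.cb, self.ca)
                    and np.array_equal(self.cn, self.ca)):
                raise PocketError("glycine requires cb == cn == ca")
        else:
            if aa == "A" and not np.array_equal(self.cn, self.cb):
                raise PocketError("alanine requires cn == cb")
            bond = float(np.linalg.norm(self.ca - self.cb))
            if bond > 2.0:
                raise PocketError(
                    f"implausible Cα–Cβ distance {bond:.2f} Å for {self.id.label()}")

    def moved(self, delta: np.ndarray) -> "Residue3P":
        """Rigidly translate all three points by ``delta``."""
        d = np.asarray(delta, dtype=float)
        return Residue3P(self.id, self.ca + d, self.cb + d, self.cn + d)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Residue3P":
        r, t = np.asarray(rotation), np.asarray(translation)
        return Residue3P(self.id, r @ self.ca + t, r @ self.cb + t, r @ self.cn + t)


@dataclass
class Pocket:
    """An ordered set of three-point residues with provenance.

    Residues are kept in (chain, resseq, icode) order, so sequence
    separations are computable directly from ``resseq``.
    """

    pocket_id: str
    residues: list[Residue3P]
    ligand_id: str = ""
    source: str = ""

    def __post_init__(self):
        if len(self.residues) < 3:
            raise PocketError(
                f"pocket {self.pocket_id!r} has {len(self.residues)} residues; "
                "at least 3 are required")
        self.residues = sorted(self.residues, key=lambda r: r.id.sort_key)
        keys = [r.id.sort_key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise PocketError(f"duplicate residue identifiers in {self.pocket_id!r}")

    def __len__(self):
        return len(self.residues)

    @property
    def n(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.id.aa for r in self.residues)

    def coords(self, channel: str = "ca") -> np.ndarray:
        """(n, 3) array of one point channel ('ca', 'cb' or 'cn')."""
        return np.array([getattr(r, channel) for r in self.residues])

    def with_id(self, pocket_id: str) -> "Pocket":
        return Pocket(pocket_id, list(self.residues), self.ligand_id, self.source)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Pocket":
        return Pocket(self.pocket_id,
                      [r.transformed(rotation, translation) for r in self.residues],
                      self.ligand_id, self.source)


@dataclass
class LoadedStructure:
    """A parsed PDB model (model 1, highest-occupancy altlocs selected)."""

    structure_id: str
    model: object  # Bio.PDB model
    has_hydrogens: bool = False
    path: str = ""


def _is_hydrogen(atom) -> bool:
    elem = (atom.element or "").strip().upper()
    if elem:
        return elem in ("H", "D")
    return atom.get_name().lstrip("0123456789").startswith(("H", "D"))


def load_structure(path, model_policy: str = "first") -> LoadedStructure:
    """Parse a PDB file into a structure handle.

    Only the first model is used (``model_policy='first'`` is the sole
    policy).  For alternate locations the highest-occupancy conformer is
    kept, ties broken by the first conformer encountered.  Hydrogens are
    retained and flagged on the handle.
    """
    if model_policy != "first":
        raise ValueError(f"unsupported model policy {model_policy!r}")
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.is_file():
        raise PocketError(f"structure file not found: {path}")
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # biopython raises several flavours here
        raise PocketError(f"cannot parse PDB file {path}: {exc}") from exc

    models = list(structure)
    if not models:
        raise PocketError(f"empty structure (no models) in {path}")
    model = models[0]
    atoms = list(model.get_atoms())
    if not atoms:
        raise PocketError(f"empty structure (no atoms in model 1) of {path}")

    # Resolve altlocs to the highest-occupancy conformer (first wins ties).
    for residue in model.get_residues():
        for atom in residue.get_unpacked_list():
            pass  # force construction of disordered children
        for atom in list(residue):
            if atom.is_disordered():
                children = atom.disordered_get_list()
                best = max(children, key=lambda a: (a.get_occupancy() or 0.0))
                atom.disordered_select(best.get_altloc())

    has_h = any(_is_hydrogen(a) for a in model.get_atoms())
    return LoadedStructure(path.stem, model, has_h, str(path))


def _heavy_atoms(residue):
    out = []
    for atom in residue:
        child = atom.disordered_get() if atom.is_disordered() else atom
        if not _is_hydrogen(child):
            out.append(child)
    return out


def _is_protein_residue(residue) -> bool:
    hetflag = residue.id[0]
    resname = residue.get_resname().strip().upper()
    if resname in WATER_NAMES or hetflag == "W":
        return False
    if hetflag == " ":
        return True
    # modified residues appear as HETATM but are part of the chain
    return resname in STANDARD_AA3 or resname in _EXT3TO1


def find_ligands(structure: LoadedStructure) -> list[tuple[str, str, int]]:
    """List (het code, chain, resseq) for every non-water HETATM group."""
    out = []
    for chain in structure.model:
        for residue in chain:
            hetflag, resseq, _ = residue.id
            resname = residue.get_resname().strip().upper()
            if hetflag.startswith("H_") and resname not in WATER_NAMES \
                    and not _is_protein_residue(residue):
                out.append((resname, chain.id, resseq))
    return out


def reconstruct_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Place Cβ from backbone N, CA, C at ideal tetrahedral geometry."""
    v1 = ca - n
    v2 = ca - c
    v1 = v1 / np.linalg.norm(v1)
    v2 = v2 / np.linalg.norm(v2)
    bisector = v1 + v2
    bisector /= np.linalg.norm(bisector)
    normal = np.cross(v1, v2)
    normal /= np.linalg.norm(normal)
    # Cβ sits ~54.75° out of the N-CA-C bisector plane (tetrahedral carbon).
    ang = np.deg2rad(54.75)
    direction = np.cos(ang) * bisector + np.sin(ang) * normal
    return ca + _CB_BOND * direction


def three_point_representation(residue, structure_id: str = "") -> Residue3P | None:
    """Reduce a parsed residue to its (Cα, Cβ, side-chain centroid) triplet.

    Returns ``None`` (with a logged warning) when the residue lacks a Cα.
    The centroid includes Cβ.  Residues whose side chain is entirely
    missing beyond Cβ are treated like alanine (``cn = cb``).
    """
    atoms = {a.get_name(): a for a in _heavy_atoms(residue)}
    resname = residue.get_resname().strip().upper()
    hetflag, resseq, icode = residue.id
    chain = residue.get_parent().id if residue.get_parent() is not None else ""
    aa = residue_letter(resname)

    if "CA" not in atoms:
        log.warning("residue %s %s%s%s has no Cα atom; skipped",
                    resname, chain, resseq, icode.strip())
        return None
    rid = ResidueId(structure_id, chain, resseq, icode.strip(), aa)
    ca = np.asarray(atoms["CA"].get_coord(), dtype=float)

    if aa == "G":
        return Residue3P(rid, ca, ca, ca)

    side = [np.asarray(a.get_coord(), dtype=float)
            for name, a in sorted(atoms.items())
            if name not in BACKBONE_ATOMS]
    if "CB" in atoms:
        cb = np.asarray(atoms["CB"].get_coord(), dtype=float)
    else:
        if "N" in atoms and "C" in atoms:
            cb = reconstruct_cb(np.asarray(atoms["N"].get_coord(), float), ca,
                                np.asarray(atoms["C"].get_coord(), float))
        else:
            log.warning("residue %s %s%s cannot reconstruct Cβ (missing N/C); "
                        "treating as glycine-like", resname, chain, resseq)
            return Residue3P(ResidueId(structure_id, chain, resseq,
                                       icode.strip(), aa), ca, ca, ca) \
                if aa == "G" else None
        side = side + [cb]

    beyond_cb = [p for p in side if not np.array_equal(p, cb)]
    if aa == "A" or not beyond_cb:
        cn = cb
    else:
        cn = np.mean(side, axis=0)
    return Residue3P(rid, ca, cb, cn)


def extract_binding_site(structure: LoadedStructure,
                         ligand_selector: tuple[str, str, int],
                         cutoff: float = 4.5) -> Pocket:
    """Extract the pocket around one ligand copy.

    The pocket contains every protein residue having at least one heavy
    atom within ``cutoff`` Å of any heavy ligand atom.  Waters, ions and
    other heteroatoms never count as pocket residues.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    het, chain_id, resseq = ligand_selector
    het = het.strip().upper()

    ligand = None
    for chain in structure.model:
        if chain.id != chain_id:
            continue
        for residue in chain:
            hetflag, rseq, _ = residue.id
            if residue.get_resname().strip().upper() == het and rseq == int(resseq):
                ligand = residue
                break
    if ligand is None:
        available = find_ligands(structure)
        listing = ", ".join(f"{h}:{c}:{r}" for h, c, r in available) or "none"
        raise PocketError(
            f"ligand {het}:{chain_id}:{resseq} not found in {structure.structure_id}; "
            f"available het groups: {listing}")

    lig_coords = np.array([a.get_coord() for a in _heavy_atoms(ligand)], dtype=float)
    if lig_coords.size == 0:
        raise PocketError(f"ligand {het}:{chain_id}:{resseq} has no heavy atoms")

    residues: list[Residue3P] = []
    for chain in structure.model:
        for residue in chain:
            if residue is ligand or not _is_protein_residue(residue):
                continue
            coords = np.array([a.get_coord() for a in _heavy_atoms(residue)],
                              dtype=float)
            if coords.size == 0:
                continue
            if cdist(coords, lig_coords).min() <= cutoff:
                r3p = three_point_representation(residue, structure.structure_id)
                if r3p is not None:
                    residues.append(r3p)

    if not residues:
        raise PocketError(
            f"empty site: no protein residue within {cutoff} Å of "
            f"{het}:{chain_id}:{resseq}")
    pocket_id = f"{structure.structure_id}_{het}_{chain_id}{resseq}"
    return Pocket(pocket_id, residues, ligand_id=het,
                  source=f"{structure.path} cutoff={cutoff}")


# ---------------------------------------------------------------------------
# Pocket files: PDB fragments of the site residues, with the pocket id in a
# REMARK line.  Glycine is written as a single CA record; alanine as CA+CB;
# all other residues additionally carry a CN pseudo-atom for the side-chain
# centroid.  Any PDB viewer can display these fragments.
# ---------------------------------------------------------------------------

def write_pocket_file(pocket: Pocket, path) -> None:
    lines = [f"REMARK 900 POCKET_ID {pocket.pocket_id}"]
    if pocket.ligand_id:
        lines.append(f"REMARK 900 LIGAND_ID {pocket.ligand_id}")
    if pocket.source:
        lines.append(f"REMARK 900 SOURCE {pocket.source}")
    serial = 0
    for res in pocket.residues:
        resname = AA1TO3[res.id.aa]
        points = [("CA", res.ca)]
        if res.id.aa != "G":
            points.append(("CB", res.cb))
            if res.id.aa != "A":
                points.append(("CN", res.cn))
        for name, xyz in points:
            serial += 1
            icode = res.id.icode or " "
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s}{resname:>4s} {res.id.chain[:1]:1s}"
                f"{res.id.resseq:4d}{icode:1s}   "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {'C':>2s}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pocket_file(path) -> Pocket:
    """Read a pocket file written by :func:`write_pocket_file`.

    The write → read round trip reproduces residue identifiers and
    coordinates to PDB precision (3 decimals).
    """
    path = Path(path)
    if not path.is_file():
        raise PocketError(f"pocket file not found: {path}")
    pocket_id, ligand_id, source = path.stem, "", ""
    for line in path.read_text().splitlines():
        if line.startswith("REMARK 900 POCKET_ID"):
            pocket_id = line.split("POCKET_ID", 1)[1].strip()
        elif line.startswith("REMARK 900 LIGAND_ID"):
            ligand_id = line.split("LIGAND_ID", 1)[1].strip()
        elif line.startswith("REMARK 900 SOURCE"):
            source = line.split("SOURCE", 1)[1].strip()

    structure = load_structure(path)
    residues = []
    for residue in structure.model.get_residues():
        atoms = {a.get_name(): np.asarray(a.get_coord(), float)
                 for a in _heavy_atoms(residue)}
        if "CA" not in atoms:
            log.warning("pocket file %s: residue %s has no CA; skipped",
                        path.name, residue.id)
            continue
        resname = residue.get_resname().strip().upper()
        aa = residue_letter(resname)
        _, resseq, icode = residue.id
        rid = ResidueId(pocket_id, residue.get_parent().id, resseq,
                        icode.strip(), aa)
        ca = atoms["CA"]
        if aa == "G":
            cb = cn = ca
        else:
            cb = atoms.get("CB", ca)
            cn = cb if aa == "A" else atoms.get("CN", cb)
        residues.append(Residue3P(rid, ca, cb, cn))
    return Pocket(pocket_id, residues, ligand_id=ligand_id, source=source)
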