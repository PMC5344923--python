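"""Protein structure model and PDB input/output.

Internal representation used throughout the package: a :class:`Conformation`
is an ordered list of residues with heavy-atom coordinates plus, for every
residue that has one, the backbone amide-hydrogen position. Amide hydrogens
are the reference point of the exchange model, so crystal structures (which
lack hydrogens) get them placed with ideal geometry by
:func:`place_amide_hydrogens`.

Residues are renumbered 1..n internally; the author numbering of the source
file is retained on each residue so experimental tables keyed by author
numbering can be joined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Optional

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Conformation",
    "Ensemble",
    "StructureError",
    "read_conformations",
    "place_amide_hydrogens",
    "write_ensemble",
    "N_H_BOND_LENGTH",
]

#: Ideal backbone amide N-H bond length (Angstrom).
N_H_BOND_LENGTH = 1.01

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Common non-standard residues mapped to their parent amino acid.
NONSTANDARD_PARENT = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO",
    "SEP": "SER", "TPO": "THR", "PTR": "TYR", "CSO": "CYS",
    "MLY": "LYS", "M3L": "LYS", "KCX": "LYS", "CME": "CYS",
}

_AMIDE_H_NAMES = {"H", "HN", "1H", "H1"}


class StructureError(ValueError):
    """Raised for unreadable, empty or inconsistent structure input."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coords must be a finite 3-vector")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass
class Residue:
    """One amino-acid residue.

    ``index`` is the 1-based internal position in the chain; ``author_id``
    keeps the numbering of the source file (string, may carry an insertion
    code). ``amide_h`` holds the backbone amide-hydrogen coordinates, absent
    for prolines and the chain's first residue.
    """

    index: int
    resname: str
    atoms: list[Atom] = field(default_factory=list)
    amide_h: Optional[np.ndarray] = None
    author_id: Optional[str] = None
    incomplete: bool = False

    def __post_init__(self) -> None:
        if self.amide_h is not None:
            self.amide_h = np.asarray(self.amide_h, dtype=float)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> Optional[np.ndarray]:
        a = self.atom(name)
        return None if a is None else a.coords

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.resname, "X")

    @property
    def is_proline(self) -> bool:
        return self.resname == "PRO"

    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in ("N", "CA", "C", "O"))


@dataclass
class Conformation:
    residues: list[Residue]
    label: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def residue(self, index: int) -> Residue:
        r = self.residues[index - 1]
        if r.index != index:
            raise StructureError(f"residue indices not contiguous at {index}")
        return r

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def heavy_atoms(self) -> tuple[np.ndarray, np.ndarray]:
        """All heavy-atom coordinates and their 1-based residue indices."""
        coords, owner = [], []
        for r in self.residues:
            for a in r.atoms:
                if a.is_heavy:
                    coords.append(a.coords)
                    owner.append(r.index)
        return np.asarray(coords, dtype=float), np.asarray(owner, dtype=int)

    def copy(self, label: Optional[str] = None) -> "Conformation":
        residues = [
            Residue(
                index=r.index,
                resname=r.resname,
                atoms=[Atom(a.name, a.element, a.coords.copy()) for a in r.atoms],
                amide_h=None if r.amide_h is None else r.amide_h.copy(),
                author_id=r.author_id,
                incomplete=r.incomplete,
            )
            for r in self.residues
        ]
        return Conformation(residues, label=self.label if label is None else label)


@dataclass
class Ensemble:
    conformations: list[Conformation]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.conformations:
            raise StructureError("ensemble must contain at least one conformation")
        seqs = {c.sequence for c in self.conformations}
        if len(seqs) > 1:
            raise StructureError("conformations in an ensemble must share one sequence")

    def __len__(self) -> int:
        return len(self.conformations)

    def __iter__(self) -> Iterator[Conformation]:
        return iter(self.conformations)

    def __getitem__(self, i: int) -> Conformation:
        return self.conformations[i]


# ---------------------------------------------------------------------------
# reading


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties broken by altloc 'A'
    (lowest altloc letter)."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
        # higher occupancy wins; at equal occupancy the lexicographically
        # smaller altloc (i.e. 'A') wins
        elif atom.occ > prev.occ or (
            atom.occ == prev.occ and (atom.altloc or "~") < (prev.altloc or "~")
        ):
            by_name[atom.name] = atom
    return list(by_name.values())


def _convert_model(model: gemmi.Model, label: str) -> Conformation:
    residues: list[Residue] = []
    chain_used = None
    for chain in model:
        out_chain: list[Residue] = []
        for res in chain:
            resname = res.name.strip().upper()
            if resname in NONSTANDARD_PARENT:
                resname = NONSTANDARD_PARENT[resname]
            if resname not in THREE_TO_ONE:
                info = gemmi.find_tabulated_residue(res.name)
                if info is not None and info.is_amino_acid():
                    raise StructureError(
                        f"unmapped non-standard amino acid {res.name!r} "
                        f"at {chain.name} {res.seqid}"
                    )
                continue  # waters / ligands / nucleic acids dropped
            atoms = []
            amide_h = None
            for atom in _resolve_altlocs(res):
                el = atom.element.name or "X"
                coords = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                if el.upper() in ("H", "D"):
                    if atom.name in _AMIDE_H_NAMES:
                        amide_h = coords
                    continue  # non-amide hydrogens are not needed downstream
                atoms.append(Atom(atom.name, el, coords))
            author = str(res.seqid.num) + (res.seqid.icode.strip() or "")
            out_chain.append(
                Residue(index=0, resname=resname, atoms=atoms,
                        amide_h=amide_h, author_id=author)
            )
        if out_chain and chain_used is None:
            chain_used = chain.name
            residues = out_chain
        elif out_chain:
            logger.warning("multiple protein chains in %s; using chain %s only",
                           label, chain_used)
    if not residues:
        raise StructureError("no protein residues found (empty structure)")
    for i, r in enumerate(residues, start=1):
        r.index = i
        r.incomplete = not r.has_backbone()
        if r.incomplete:
            logger.warning("residue %s%d is missing backbone atoms", r.resname, i)
    # first residue and prolines never carry an amide H
    residues[0].amide_h = None
    for r in residues:
        if r.is_proline:
            r.amide_h = None
    return Conformation(residues, label=label)


def read_conformations(
    path: str | Path, model_selector: Literal["all", "first"] = "all"
) -> Ensemble:
    """Read a (possibly multi-model) PDB file into an :class:`Ensemble`.

    Waters and hetero groups are dropped, altloc duplicates resolved (highest
    occupancy, ties to 'A'), residues renumbered 1..n with author numbering
    kept as metadata. ``model_selector='first'`` keeps only the first model.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: file contains no models")
    models = [st[0]] if model_selector == "first" else list(st)
    confs = [_convert_model(m, label=f"model{i + 1}") for i, m in enumerate(models)]
    seqs = {c.sequence for c in confs}
    if len(seqs) > 1:
        raise StructureError(f"{path}: models disagree on sequence")
    return Ensemble(confs, source=str(path))


# ---------------------------------------------------------------------------
# hydrogen placement


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise StructureError("degenerate geometry (zero-length vector)")
    return v / n


def place_amide_hydrogens(conf: Conformation) -> Conformation:
    """Place missing backbone amide hydrogens with ideal geometry.

    For every non-proline residue i >= 2 the H is set 1.01 A from N, in the
    peptide plane spanned by C(i-1), N(i), CA(i), anti-parallel to the
    C(i-1)=O(i-1) carbonyl direction — the ideal trans-peptide convention.
    Experimentally determined H positions already present are preserved.
    Residues with missing backbone atoms are flagged and left without H.
    """
    out = conf.copy()
    for i in range(2, len(out) + 1):
        res = out.residues[i - 1]
        if res.is_proline or res.amide_h is not None:
            continue
        prev = out.residues[i - 2]
        n = res.coord("N")
        ca = res.coord("CA")
        c_prev = prev.coord("C")
        o_prev = prev.coord("O")
        if n is None or ca is None or c_prev is None or o_prev is None:
            res.incomplete = True
            logger.warning("cannot place amide H on residue %d: missing backbone", i)
            continue
        # anti-parallel to C=O, projected into the C(i-1)/N/CA plane
        direction = c_prev - o_prev
        normal = np.cross(c_prev - n, ca - n)
        nn = np.linalg.norm(normal)
        if nn > 1e-9:
            normal /= nn
            direction = direction - np.dot(direction, normal) * normal
        res.amide_h = n + N_H_BOND_LENGTH * _unit(direction)
    return out


# ---------------------------------------------------------------------------
# writing


def write_ensemble(ens: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a (multi-model) PDB file.

    A 1-member ensemble is written without MODEL records; coordinates
    round-trip through :func:`read_conformations` to PDB precision (1e-3 A).
    """
    st = gemmi.Structure()
    st.name = "pfkit"
    for mi, conf in enumerate(ens, start=1):
        model = gemmi.Model(mi)
        chain = gemmi.Chain("A")
        for res in conf:
            g = gemmi.Residue()
            g.name = res.resname
            g.seqid = gemmi.SeqId(res.index, " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = 1.0
                g.add_atom(ga)
            if res.amide_h is not None:
                ga = gemmi.Atom()
                ga.name = "H"
                ga.element = gemmi.Element("H")
                ga.pos = gemmi.Position(*res.amide_h)
                ga.occ = 1.0
                g.add_atom(ga)
            chain.add_residue(g)
        model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    doc_path = Path(path)
    try:
        st.write_pdb(str(doc_path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write {doc_path}: {exc}") from exc
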