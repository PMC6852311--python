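"""Read, represent and write protein structures.

The in-memory model is deliberately small: an :class:`Atom` carries a name,
element and coordinate; a :class:`Residue` keys its atoms by ``(name,
altloc)``; a :class:`ChainStructure` is an ordered list of residues from a
single chain of a single model.  Parsing of PDB and mmCIF files is delegated
to :mod:`gemmi`; only the polymer (amino-acid residues, including modified
ones such as MSE) is retained — waters and non-polymer heteroatoms are
dropped on read.

Coordinates are in Å throughout and author residue numbers are 1-based, as
in the PDB convention.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import ChainLookupError, KinoforgeError, NoProteinError, StructureParseError

__all__ = [
    "Atom",
    "Residue",
    "ChainStructure",
    "Structure",
    "read_structure",
    "select_chain",
    "extract_sequence",
    "write_structure",
    "read_provenance",
]

#: Modified residues mapped onto their standard parent for sequence purposes.
#: gemmi's tabulated one-letter codes cover these; the explicit map is only a
#: fallback for names gemmi does not know.
_PARENT_FALLBACK = {
    "MSE": "M", "SEP": "S", "TPO": "T", "PTR": "Y", "CSO": "C",
    "MLY": "K", "HYP": "P", "KCX": "K", "PCA": "Q",
}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}

#: Grammar for provenance records:
#: ``REMARK  99 KINOFORGE SEGMENT <label> SOURCE <tag> RESIDUES <first>:<last>``
#: one line per contiguous run of residues sharing a provenance label.
_PROV_PREFIX = "REMARK  99 KINOFORGE SEGMENT"


@dataclass
class Atom:
    """A single atom: PDB name, element symbol, coordinate in Å."""

    name: str
    element: str
    coord: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise KinoforgeError(f"atom {self.name}: coordinate must be a finite 3-vector")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coord.copy(), self.altloc,
                    self.occupancy, self.bfactor)


@dataclass
class Residue:
    """One residue: author id + insertion code, 3-letter name, atom map."""

    author_id: int
    name: str
    icode: str = ""
    atoms: dict = field(default_factory=dict)  # (atom_name, altloc) -> Atom

    @property
    def key(self):
        return (self.author_id, self.icode)

    def add_atom(self, atom: Atom) -> None:
        k = (atom.name, atom.altloc)
        if k in self.atoms:
            raise KinoforgeError(
                f"duplicate atom {k} in residue {self.name} {self.author_id}{self.icode}")
        self.atoms[k] = atom

    def atom(self, name: str) -> Atom | None:
        """Highest-occupancy conformer of the named atom (ties: first altloc
        alphabetically, blank altloc sorting first)."""
        candidates = [a for (n, _alt), a in self.atoms.items() if n == name]
        if not candidates:
            return None
        return max(candidates, key=lambda a: (a.occupancy, -ord(a.altloc or " ")))

    def coord(self, name: str) -> np.ndarray | None:
        a = self.atom(name)
        return None if a is None else a.coord

    def one_letter(self) -> str:
        if self.name in _THREE_TO_ONE:
            return _THREE_TO_ONE[self.name]
        info = gemmi.find_tabulated_residue(self.name)
        if info is not None and info.is_amino_acid():
            code = info.one_letter_code.upper()
            if code.isalpha():
                return code
        return _PARENT_FALLBACK.get(self.name, "X")

    def copy(self) -> "Residue":
        r = Residue(self.author_id, self.name, self.icode)
        r.atoms = {k: a.copy() for k, a in self.atoms.items()}
        return r


@dataclass
class ChainStructure:
    """Single-chain, single-model ordered residue list."""

    chain_id: str
    model_index: int
    residues: list
    source: tuple = ("<memory>", "memory")  # (path, format tag)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise KinoforgeError(f"chain {self.chain_id}: duplicate residue keys")
        if keys != sorted(keys):
            raise KinoforgeError(f"chain {self.chain_id}: residues not ordered by author id")

    def __len__(self) -> int:
        return len(self.residues)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ChainStructure":
        """Copy of the chain with every coordinate rigidly moved."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        out = ChainStructure(self.chain_id, self.model_index,
                             [r.copy() for r in self.residues], self.source)
        for res in out.residues:
            for atom in res.atoms.values():
                atom.coord = rotation @ atom.coord + translation
        return out

    def copy(self) -> "ChainStructure":
        return ChainStructure(self.chain_id, self.model_index,
                              [r.copy() for r in self.residues], self.source)


class Structure:
    """Multi-model, multi-chain container returned by :func:`read_structure`."""

    def __init__(self, models: list, source: tuple, remarks: list | None = None):
        # models: list of dict chain_id -> list[Residue]
        self.models = models
        self.source = source
        self.remarks = list(remarks or [])

    @property
    def n_models(self) -> int:
        return len(self.models)

    def chain_ids(self, model_index: int = 0) -> list:
        return sorted(self.models[model_index].keys())


def _is_amino_acid(name: str) -> bool:
    if name in _THREE_TO_ONE or name in _PARENT_FALLBACK:
        return True
    info = gemmi.find_tabulated_residue(name)
    return info is not None and info.is_amino_acid()


def read_structure(path, fmt: str = "auto") -> Structure:
    """Read a PDB or mmCIF file, keeping only amino-acid residues.

    Waters and non-polymer heteroatoms are excluded; altloc groups are
    preserved (collapse happens in :func:`select_chain`).
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = fmt.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "auto":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
        else:
            raise StructureParseError(f"unknown format {fmt!r} (use pdb, mmcif or auto)")
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc

    models = []
    for model in st:
        chains: dict = {}
        for chain in model:
            residues = []
            for res in chain:
                if not _is_amino_acid(res.name):
                    continue
                r = Residue(res.seqid.num, res.name, (res.seqid.icode or " ").strip())
                for at in res:
                    altloc = (at.altloc or "").strip()
                    key = (at.name, altloc)
                    if key in r.atoms:  # duplicated record; keep the first
                        continue
                    r.atoms[key] = Atom(at.name, at.element.name,
                                        np.array([at.pos.x, at.pos.y, at.pos.z]),
                                        altloc, at.occ, at.b_iso)
                if r.atoms:
                    residues.append(r)
            if residues:
                residues.sort(key=lambda r: r.key)
                chains[chain.name] = residues
        models.append(chains)
    if not any(m for m in models):
        raise NoProteinError(f"{path}: no protein chains")
    return Structure(models, (str(path), fmt), remarks=list(st.raw_remarks))


def _collapse_altlocs(residue: Residue) -> Residue:
    out = Residue(residue.author_id, residue.name, residue.icode)
    names = {n for (n, _alt) in residue.atoms}
    for n in sorted(names):
        best = residue.atom(n)
        a = best.copy()
        a.altloc = ""
        out.atoms[(n, "")] = a
    return out


def select_chain(structure, chain_id: str, model_index: int = 0) -> ChainStructure:
    """Single-chain, single-model view with altlocs collapsed to the
    highest-occupancy conformer (ties broken alphabetically)."""
    if isinstance(structure, ChainStructure):
        if structure.chain_id != chain_id:
            raise ChainLookupError(
                f"chain {chain_id!r} not found; available: {{{structure.chain_id}}}")
        return structure
    if model_index < 0 or model_index >= structure.n_models:
        raise ChainLookupError(
            f"model {model_index} not found; available: 0..{structure.n_models - 1}")
    chains = structure.models[model_index]
    if chain_id not in chains:
        avail = ",".join(sorted(chains))
        raise ChainLookupError(f"chain {chain_id!r} not found; available: {{{avail}}}")
    residues = [_collapse_altlocs(r) for r in chains[chain_id]]
    return ChainStructure(chain_id, model_index, residues, structure.source)


@dataclass
class SequenceRecord:
    """One-letter sequence plus per-position author numbering."""

    sequence: str
    author_ids: list  # (author_id, icode) per position
    gaps: list  # (position_before, position_after) 1-based, numbering jumps

    def __len__(self) -> int:
        return len(self.sequence)


def extract_sequence(chain: ChainStructure) -> SequenceRecord:
    """One-letter sequence of the chain; nonstandard residues become 'X'
    (modified amino acids map to their parent, e.g. MSE → M).  Numbering
    gaps are recorded as annotations, not inserted letters."""
    seq = []
    ids = []
    gaps = []
    prev = None
    for i, res in enumerate(chain.residues):
        seq.append(res.one_letter())
        ids.append(res.key)
        if prev is not None and res.icode == "" and prev[1] == "" \
                and res.author_id > prev[0] + 1:
            gaps.append((i, i + 1))  # 1-based positions flanking the jump
        prev = res.key
    return SequenceRecord("".join(seq), ids, gaps)


def three_letter(one: str) -> str:
    return _ONE_TO_THREE.get(one.upper(), "UNK")


def write_structure(residues: Sequence[Residue], path,
                    provenance: Iterable[tuple] | None = None,
                    chain_id: str = "A") -> None:
    """Write residues as a valid single-chain PDB file.

    ``provenance`` is an iterable of ``(label, source_tag, first_key,
    last_key)`` runs emitted as REMARK 99 lines (see module docstring for the
    grammar).  Atom serial numbers are contiguous from 1; coordinates
    round-trip through :func:`read_structure` to 3 decimals.
    """
    residues = list(residues)
    if not residues:
        raise KinoforgeError("write_structure: empty residue list")
    for r in residues:
        if not r.atoms:
            raise KinoforgeError(f"write_structure: residue {r.author_id} has no atoms")

    st = gemmi.Structure()
    st.name = "kinoforge"
    model = gemmi.Model("1")
    chain = gemmi.Chain(chain_id)
    for res in residues:
        gr = gemmi.Residue()
        gr.name = res.name
        gr.seqid = gemmi.SeqId(res.author_id, res.icode or " ")
        for (name, altloc), atom in sorted(res.atoms.items()):
            ga = gemmi.Atom()
            ga.name = name
            ga.element = gemmi.Element(atom.element or "X")
            ga.pos = gemmi.Position(*atom.coord)
            ga.altloc = altloc or "\0"
            ga.occ = atom.occupancy
            ga.b_iso = atom.bfactor
            gr.add_atom(ga)
        chain.add_residue(gr)
    model.add_chain(chain)
    st.add_model(model)
    remarks = []
    for label, tag, first, last in (provenance or []):
        remarks.append(f"{_PROV_PREFIX} {label} SOURCE {tag} "
                       f"RESIDUES {_fmt_key(first)}:{_fmt_key(last)}")
    st.raw_remarks = remarks
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise KinoforgeError(f"cannot write {path}: {exc}") from exc


def _fmt_key(key) -> str:
    if isinstance(key, tuple):
        num, icode = key
        return f"{num}{icode}" if icode else str(num)
    return str(key)


def read_provenance(structure: Structure) -> list:
    """Parse REMARK 99 provenance runs written by :func:`write_structure`.

    Returns ``(label, source_tag, first_id_text, last_id_text)`` tuples.
    """
    out = []
    for line in structure.remarks:
        line = line.rstrip()
        if not line.startswith(_PROV_PREFIX):
            continue
        rest = line[len(_PROV_PREFIX):].split()
        # <label> SOURCE <tag...> RESIDUES <first>:<last>
        try:
            label = rest[0]
            s_idx = rest.index("SOURCE")
            r_idx = rest.index("RESIDUES")
            tag = " ".join(rest[s_idx + 1:r_idx])
            first, last = rest[r_idx + 1].split(":")
        except (ValueError, IndexError):
            continue
        out.append((label, tag, first, last))
    return out
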