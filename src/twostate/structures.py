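"""Structure model: read and pair open/closed conformations.

A two-lobe binding protein is represented twice — once per conformational
state — and all downstream bookkeeping (fixed positions, mutation tables,
reports) is expressed in the *open-state* author residue numbering. The
closed state is tied to the open state through an alignment-derived residue
mapping, mirroring the common practice of renumbering the closed structure
onto the open one.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from Bio import Align

from .errors import PairingError, ParseError

#: canonical one-letter amino-acid alphabet, alphabetical by letter
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass(frozen=True)
class Atom:
    """A single atom: label, element symbol, Cartesian coordinates in Å."""

    name: str
    element: str
    coords: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("atom element must be nonempty")
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    """One residue (protein or ligand) with its atoms.

    ``number`` is the author residue number as printed in the source file;
    ``icode`` the insertion code ('' if none).
    """

    chain_id: str
    number: int
    icode: str
    name: str
    atoms: list[Atom]
    is_ligand: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name.upper(), "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    def heavy_coords(self) -> np.ndarray:
        """Coordinates of non-hydrogen atoms, shape (n, 3)."""
        return np.array(
            [a.coords for a in self.atoms if not a.is_hydrogen], dtype=float
        ).reshape(-1, 3)


@dataclass
class Structure:
    """An ordered list of residues as read from one PDB file."""

    residues: list[Residue]
    label: str = ""

    def protein_residues(self, chain: str | None = None) -> list[Residue]:
        """Protein residues of one chain (default: the first protein chain)."""
        prot = [r for r in self.residues if not r.is_ligand]
        if not prot:
            return []
        if chain is None:
            chain = prot[0].chain_id
        return [r for r in prot if r.chain_id == chain]

    def ligand_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_ligand]

    def sequence(self, chain: str | None = None) -> str:
        return "".join(r.one_letter for r in self.protein_residues(chain))

    def ca_coords(self, chain: str | None = None) -> np.ndarray:
        coords = []
        for r in self.protein_residues(chain):
            ca = r.ca
            if ca is None:
                raise ParseError(
                    f"protein residue {r.chain_id}{r.number}{r.icode} has no CA atom"
                )
            coords.append(ca.coords)
        return np.asarray(coords, dtype=float)


def read_structure(pdb_text: str, label: str = "", chain: str | None = None) -> Structure:
    """Parse PDB text into a :class:`Structure`.

    Waters are dropped, other HETATM residues are flagged as ligands, and for
    alternate locations the highest-occupancy conformer is kept (ties resolved
    in file order). Duplicate atoms within a residue raise a warning and the
    first copy wins.

    Parameters
    ----------
    pdb_text:
        PDB-format text with at least one ATOM record.
    label:
        Free-text tag, e.g. ``"open"`` or ``"closed"``.
    chain:
        If given, keep only protein residues of this chain (ligands of any
        chain are always kept).
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # gemmi raises RuntimeError
        raise ParseError(f"could not parse PDB text: {exc}") from None
    if len(st) == 0:
        raise ParseError("no models in PDB text")

    model = st[0]
    residues: list[Residue] = []
    n_atom_records = 0
    for ch in model:
        for res in ch:
            is_het = res.het_flag == "H"
            if not is_het:
                n_atom_records += len(res)
            if res.name.upper() in _WATER_NAMES or res.is_water():
                continue
            if not is_het and chain is not None and ch.name != chain:
                continue
            # altloc resolution: per atom name keep highest occupancy
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for at in res:
                prev = best.get(at.name)
                if prev is None:
                    best[at.name] = at
                    order.append(at.name)
                elif at.altloc and prev.altloc and at.occ > prev.occ:
                    best[at.name] = at
                elif not at.altloc and not prev.altloc:
                    warnings.warn(
                        f"duplicate atom {at.name} in residue "
                        f"{ch.name}{res.seqid.num}; keeping first",
                        stacklevel=2,
                    )
            atoms = [
                Atom(
                    name=name,
                    element=best[name].element.name or "X",
                    coords=(best[name].pos.x, best[name].pos.y, best[name].pos.z),
                )
                for name in order
            ]
            if not atoms:
                continue
            residues.append(
                Residue(
                    chain_id=ch.name,
                    number=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    name=res.name,
                    atoms=atoms,
                    is_ligand=is_het,
                )
            )
    if n_atom_records == 0:
        raise ParseError("no ATOM records found")
    return Structure(residues=residues, label=label)


def load_structure(path: str | Path, label: str = "", chain: str | None = None) -> Structure:
    """Read a PDB file from disk; ``.gz`` is transparently decompressed."""
    path = Path(path)
    if path.suffix == ".gz":
        text = gzip.open(path, "rt").read()
    else:
        text = path.read_text()
    return read_structure(text, label=label or path.stem, chain=chain)


def strip_ligands(s: Structure) -> tuple[Structure, list[Residue]]:
    """Split a structure into its protein part and a list of ligand residues."""
    protein = Structure(
        residues=[r for r in s.residues if not r.is_ligand], label=s.label
    )
    return protein, s.ligand_residues()


@dataclass
class StructurePair:
    """Open and closed conformations plus the residue mapping between them.

    ``mapping`` relates 0-based indices into the protein residue lists of the
    two states; ``sequence`` is the 1-letter sequence of the open state, whose
    author numbering is the coordinate system for all reports.
    """

    open: Structure
    closed: Structure
    mapping: dict[int, int]
    sequence: str
    chain_open: str | None = None
    chain_closed: str | None = None
    _inv: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._inv = {v: k for k, v in self.mapping.items()}

    @property
    def open_protein(self) -> list[Residue]:
        return self.open.protein_residues(self.chain_open)

    @property
    def closed_protein(self) -> list[Residue]:
        return self.closed.protein_residues(self.chain_closed)

    @property
    def author_numbers(self) -> list[int]:
        """Open-state author numbers, indexed by internal open index."""
        return [r.number for r in self.open_protein]

    def index_to_author(self, i: int) -> int:
        return self.open_protein[i].number

    def author_to_index(self, num: int) -> int:
        for i, r in enumerate(self.open_protein):
            if r.number == num:
                return i
        raise KeyError(f"no open-state residue numbered {num}")

    def closed_index_for(self, open_index: int) -> int | None:
        return self.mapping.get(open_index)

    def open_index_for(self, closed_index: int) -> int | None:
        return self._inv.get(closed_index)

    def inverse_mapping(self) -> dict[int, int]:
        return dict(self._inv)


def _global_alignment(seq_a: str, seq_b: str):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    return aligner.align(seq_a, seq_b)[0]


def pair_states(
    open_structure: Structure,
    closed_structure: Structure,
    chain_open: str | None = None,
    chain_closed: str | None = None,
    min_identity: float = 0.95,
    min_coverage: float = 0.90,
) -> StructurePair:
    """Pair the open- and closed-state structures of one protein.

    The 1-letter sequences are globally aligned (match +1, mismatch −1,
    gap −2); identically matched columns form the residue mapping. Raises
    :class:`PairingError` if sequence identity over the aligned columns is
    below ``min_identity`` or the mapping covers less than ``min_coverage``
    of either state's protein residues.
    """
    prot_open = open_structure.protein_residues(chain_open)
    prot_closed = closed_structure.protein_residues(chain_closed)
    if not prot_open or not prot_closed:
        raise PairingError("both structures must contain protein residues")
    seq_open = "".join(r.one_letter for r in prot_open)
    seq_closed = "".join(r.one_letter for r in prot_closed)

    aln = _global_alignment(seq_open, seq_closed)
    mapping: dict[int, int] = {}
    n_aligned = 0
    n_match = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for off in range(a1 - a0):
            i, j = a0 + off, b0 + off
            n_aligned += 1
            if seq_open[i] == seq_closed[j]:
                n_match += 1
                mapping[i] = j
    if n_aligned == 0 or n_match / n_aligned < min_identity:
        ident = 0.0 if n_aligned == 0 else n_match / n_aligned
        raise PairingError(
            f"sequence identity over aligned columns is {ident:.1%} "
            f"(< {min_identity:.0%}); the two structures do not appear to be "
            "the same protein"
        )
    cov_open = len(mapping) / len(prot_open)
    cov_closed = len(mapping) / len(prot_closed)
    if min(cov_open, cov_closed) < min_coverage:
        raise PairingError(
            f"mapping covers only {cov_open:.1%} of open / {cov_closed:.1%} of "
            f"closed protein residues (< {min_coverage:.0%})"
        )
    return StructurePair(
        open=open_structure,
        closed=closed_structure,
        mapping=mapping,
        sequence=seq_open,
        chain_open=chain_open or prot_open[0].chain_id,
        chain_closed=chain_closed or prot_closed[0].chain_id,
    )


def write_pdb(structure: Structure) -> str:
    """Serialize a structure to normalized PDB text (ATOM/HETATM/TER/END)."""
    lines = []
    serial = 1
    last_chain = None
    for res in structure.residues:
        if last_chain is not None and res.chain_id != last_chain:
            lines.append("TER")
        last_chain = res.chain_id
        record = "HETATM" if res.is_ligand else "ATOM  "
        for at in res.atoms:
            name = at.name if len(at.name) >= 4 else f" {at.name:<3s}"
            x, y, z = at.coords
            lines.append(
                f"{record}{serial:5d} {name:<4s} {res.name:<3s} "
                f"{res.chain_id:1s}{res.number:4d}{res.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {at.element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
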