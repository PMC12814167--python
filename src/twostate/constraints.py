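"""Position constraints: lobes, interface, binding pocket, termini, tiers.

Stability design on a hinge-bending protein must leave certain positions
untouched: the ligand pocket (to keep binding), the termini (qualitative
practice), and — for the most conservative design tier — the hinge region
and the inter-lobe interface, where local packing changes most between
conformational states. This module derives those sets and assembles them
per design tier. All emitted positions are open-state author residue
numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import TwoStateError
from .gnm import HingeSet
from .structures import Residue, Structure, StructurePair

PROVENANCE_TAGS = ("pocket", "hinge", "interface", "terminus")

DESIGN_TIERS = ("X.1", "X.2", "X.3", "X.4")


@dataclass
class LobePartition:
    """Disjoint split of all protein residues into two lobes and the hinge."""

    lobe_a: frozenset[int]
    lobe_b: frozenset[int]
    hinge: frozenset[int]

    def __post_init__(self) -> None:
        if (self.lobe_a & self.lobe_b) or (self.lobe_a & self.hinge) or (
            self.lobe_b & self.hinge
        ):
            raise TwoStateError("lobe/hinge sets must be disjoint")


def split_lobes(mode1: np.ndarray, hinges: HingeSet) -> LobePartition:
    """Assign residues to two lobes by the sign of the first GNM mode.

    Each maximal contiguous run of non-hinge residues goes to lobe A if its
    mean mode-1 component is positive, to lobe B if negative; a run with mean
    exactly zero inherits the preceding run's lobe (lobe A if it is first).
    """
    mode1 = np.asarray(mode1, dtype=float)
    n = len(mode1)
    hinge = set(hinges.residues)
    if not hinge:
        warnings.warn(
            "empty hinge set: structure is treated as a single lobe",
            stacklevel=2,
        )
    lobe_a: set[int] = set()
    lobe_b: set[int] = set()
    prev_lobe = lobe_a
    i = 0
    while i < n:
        if i in hinge:
            i += 1
            continue
        j = i
        while j < n and j not in hinge:
            j += 1
        seg = list(range(i, j))
        mean = float(np.mean(mode1[seg]))
        if mean > 0:
            target = lobe_a
        elif mean < 0:
            target = lobe_b
        else:
            target = prev_lobe
        target.update(seg)
        prev_lobe = target
        i = j
    return LobePartition(
        lobe_a=frozenset(lobe_a), lobe_b=frozenset(lobe_b), hinge=frozenset(hinge)
    )


def _residue_heavy_atoms(residues: list[Residue], indices) -> tuple[np.ndarray, np.ndarray]:
    """Stack heavy-atom coords of the given residue indices.

    Returns (coords, owner) where owner[i] is the residue index of atom i.
    """
    coords = []
    owner = []
    for idx in indices:
        xyz = residues[idx].heavy_coords()
        coords.append(xyz)
        owner.extend([idx] * len(xyz))
    if not coords:
        return np.empty((0, 3)), np.empty(0, dtype=int)
    return np.vstack(coords), np.asarray(owner, dtype=int)


def _interface_one_state(
    residues: list[Residue], idx_a: list[int], idx_b: list[int], cutoff: float
) -> set[int]:
    xyz_a, own_a = _residue_heavy_atoms(residues, idx_a)
    xyz_b, own_b = _residue_heavy_atoms(residues, idx_b)
    if len(xyz_a) == 0 or len(xyz_b) == 0:
        return set()
    tree_b = cKDTree(xyz_b)
    hits = tree_b.query_ball_point(xyz_a, r=cutoff)
    result: set[int] = set()
    for ai, blist in enumerate(hits):
        if blist:
            result.add(int(own_a[ai]))
            result.update(int(own_b[bi]) for bi in blist)
    return result


def interface_residues(
    pair: StructurePair,
    partition: LobePartition,
    cutoff: float = 6.0,
    state: str = "union",
) -> set[int]:
    """Residues at the inter-lobe interface, as open-state author numbers.

    A residue is interfacial if any of its heavy atoms lies within ``cutoff``
    Å of any heavy atom of a residue of the opposite lobe, evaluated in the
    open state, the closed state, or (default) the union of both.
    """
    if state not in ("open", "closed", "union"):
        raise TwoStateError(f"state must be open/closed/union, got {state!r}")
    if not partition.lobe_a or not partition.lobe_b:
        raise TwoStateError("interface detection requires two nonempty lobes")

    found: set[int] = set()  # internal open indices
    if state in ("open", "union"):
        found |= _interface_one_state(
            pair.open_protein,
            sorted(partition.lobe_a),
            sorted(partition.lobe_b),
            cutoff,
        )
    if state in ("closed", "union"):
        closed = pair.closed_protein
        inv = pair.inverse_mapping()
        idx_a = sorted(
            pair.mapping[i] for i in partition.lobe_a if i in pair.mapping
        )
        idx_b = sorted(
            pair.mapping[i] for i in partition.lobe_b if i in pair.mapping
        )
        closed_hits = _interface_one_state(closed, idx_a, idx_b, cutoff)
        found |= {inv[c] for c in closed_hits if c in inv}
    return {pair.index_to_author(i) for i in found}


def pocket_residues(
    closed: Structure,
    ligands: list[Residue],
    cutoff: float = 6.0,
    pair: StructurePair | None = None,
) -> set[int]:
    """Residues with any heavy atom within ``cutoff`` Å of a ligand heavy atom.

    Distances are measured in the closed (ligand-bound) state; if ``pair`` is
    given, positions are reported in open-state author numbering through the
    residue mapping (closed residues without a mapped partner are skipped),
    otherwise in the closed structure's own numbering.
    """
    if not ligands:
        warnings.warn("no ligands given; pocket set is empty", stacklevel=2)
        return set()
    if cutoff <= 0:
        return set()
    lig_xyz = np.vstack([r.heavy_coords() for r in ligands])
    tree = cKDTree(lig_xyz)
    residues = (
        pair.closed_protein if pair is not None else closed.protein_residues()
    )
    inv = pair.inverse_mapping() if pair is not None else None
    result: set[int] = set()
    for ci, res in enumerate(residues):
        xyz = res.heavy_coords()
        if len(xyz) == 0:
            continue
        dist, _ = tree.query(xyz, k=1)
        if np.min(dist) > cutoff:
            continue
        if inv is None:
            result.add(res.number)
        elif ci in inv:
            result.add(pair.index_to_author(inv[ci]))
    return result


def terminal_margin(n_residues: int, margin: int = 5) -> set[int]:
    """The first and last ``margin`` sequence positions (1-based).

    Raises if the two margins meet or overlap (2·margin ≥ N).
    """
    if margin < 0:
        raise TwoStateError("margin must be >= 0")
    if margin == 0:
        return set()
    if 2 * margin >= n_residues:
        raise TwoStateError(
            f"terminal margin {margin} covers the whole {n_residues}-residue chain"
        )
    return set(range(1, margin + 1)) | set(
        range(n_residues - margin + 1, n_residues + 1)
    )


@dataclass
class FixedPositionSet:
    """Positions barred from mutation, each tagged with its provenance."""

    positions: frozenset[int]
    provenance: dict[int, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pos in self.positions:
            tags = self.provenance.get(pos)
            if not tags:
                raise TwoStateError(f"fixed position {pos} has no provenance tag")
            unknown = set(tags) - set(PROVENANCE_TAGS)
            if unknown:
                raise TwoStateError(f"unknown provenance tags {unknown}")

    def __contains__(self, pos: int) -> bool:
        return pos in self.positions


def assemble_fixed_set(
    tier: str,
    pocket: set[int] = frozenset(),
    hinge: set[int] = frozenset(),
    interface: set[int] = frozenset(),
    terminal: set[int] = frozenset(),
) -> FixedPositionSet:
    """Per-tier fixed positions (all inputs in open-state author numbering).

    Tiers X.1–X.3 fix pocket ∪ terminal; tier X.4 additionally fixes the
    hinge and lobe-interface positions. A position reachable through several
    rules carries all its tags.
    """
    if tier not in DESIGN_TIERS:
        raise TwoStateError(f"unknown design tier {tier!r}")
    sources = [("pocket", pocket), ("terminus", terminal)]
    if tier == "X.4":
        sources += [("hinge", hinge), ("interface", interface)]
    prov: dict[int, set[str]] = {}
    for tag, positions in sources:
        for pos in positions:
            prov.setdefault(pos, set()).add(tag)
    return FixedPositionSet(
        positions=frozenset(prov),
        provenance={p: frozenset(t) for p, t in prov.items()},
    )
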