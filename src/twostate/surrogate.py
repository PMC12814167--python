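"""Transparent surrogate ΔΔG calculator.

A deliberately simple, geometry-only stand-in for an atomistic energy
function, so the pipeline can be exercised end to end. The score rewards
placing hydrophobic side chains at buried positions and penalizes exposing
them; because burial differs between the open and closed conformations, the
same substitution can score with opposite signs in the two states — the
state-dependent sign discordance the two-state filter exists to remove.
No thermodynamic accuracy is claimed or needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .design import DdGRecord, MutationCandidate
from .errors import DesignError
from .structures import AA_ALPHABET, StructurePair

#: Kyte–Doolittle hydropathy scale (positive = hydrophobic)
KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -0.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}


@dataclass
class ContactModel:
    """Parameters of the surrogate: contact radius (Å, Cβ-based),
    a hydrophobicity scale, and a burial coefficient."""

    contact_radius: float = 8.0
    hydrophobicity: dict[str, float] = field(
        default_factory=lambda: dict(KYTE_DOOLITTLE)
    )
    burial_weight: float = 0.05
    exposure_penalty: float = 0.3   # per unit hydrophobicity of exposed mutants
    exposure_burial: int = 3        # neighbor count below which = exposed

    def __post_init__(self) -> None:
        if self.contact_radius <= 0:
            raise DesignError("contact_radius must be positive")
        missing = set(AA_ALPHABET) - set(self.hydrophobicity)
        if missing:
            raise DesignError(f"hydrophobicity scale missing {sorted(missing)}")


def _sidechain_coords(residues) -> np.ndarray:
    coords = []
    for r in residues:
        at = r.atom("CB") or r.ca
        if at is None:
            raise DesignError(f"residue {r.chain_id}{r.number} has no CB or CA")
        coords.append(at.coords)
    return np.asarray(coords, dtype=float)


def burial_counts(pair: StructurePair, model: ContactModel | None = None) -> dict[str, np.ndarray]:
    """Cβ neighbor counts within the contact radius, per state.

    Arrays are indexed by the internal open-state residue index; closed-state
    counts are mapped through the pair mapping (unmapped → NaN).
    """
    model = model or ContactModel()
    out: dict[str, np.ndarray] = {}
    for state in ("open", "closed"):
        residues = pair.open_protein if state == "open" else pair.closed_protein
        xyz = _sidechain_coords(residues)
        tree = cKDTree(xyz)
        counts = np.array(
            [len(tree.query_ball_point(p, model.contact_radius)) - 1 for p in xyz],
            dtype=float,
        )
        if state == "open":
            out[state] = counts
        else:
            mapped = np.full(len(pair.open_protein), np.nan)
            for oi, ci in pair.mapping.items():
                mapped[oi] = counts[ci]
            out[state] = mapped
    return out


def surrogate_ddg(
    pair: StructurePair,
    candidate: MutationCandidate,
    model: ContactModel | None = None,
    _burial: dict[str, np.ndarray] | None = None,
) -> tuple[float, float]:
    """Surrogate (ΔΔG_open, ΔΔG_closed) for one substitution.

    Per state with burial b (Cβ neighbors within the contact radius):

        ddg = burial_weight · b · (h(wt) − h(mut)) + exposure penalty

    The penalty applies to hydrophobic mutant identities (h > 0) at exposed
    sites (b < 3) and equals exposure_penalty · h(mut). Disabling the
    penalty makes the score antisymmetric under swapping wt and mut.
    """
    model = model or ContactModel()
    burial = _burial if _burial is not None else burial_counts(pair, model)
    idx = pair.author_to_index(candidate.position)
    if np.isnan(burial["closed"][idx]):
        raise DesignError(
            f"position {candidate.position} is not mapped in the closed state"
        )
    h = model.hydrophobicity
    dh = h[candidate.wt_aa] - h[candidate.mut_aa]
    out = []
    for state in ("open", "closed"):
        b = float(burial[state][idx])
        ddg = model.burial_weight * b * dh
        if h[candidate.mut_aa] > 0 and b < model.exposure_burial:
            ddg += model.exposure_penalty * h[candidate.mut_aa]
        out.append(ddg)
    return out[0], out[1]


def scan_all(
    pair: StructurePair,
    allowed: dict[int, frozenset[str]] | None = None,
    model: ContactModel | None = None,
) -> list[DdGRecord]:
    """Surrogate ΔΔG for every single substitution at every mapped position.

    ``allowed`` (author position → identity set) restricts the mutant
    alphabet; by default all 19 non-wild-type identities are scanned.
    """
    model = model or ContactModel()
    burial = burial_counts(pair, model)
    records = []
    for idx, num in enumerate(pair.author_numbers):
        if np.isnan(burial["closed"][idx]):
            continue
        wt = pair.sequence[idx]
        alphabet = (
            allowed.get(num, frozenset()) if allowed is not None else AA_ALPHABET
        )
        for mut in sorted(alphabet):
            if mut == wt or mut not in KYTE_DOOLITTLE:
                continue
            cand = MutationCandidate(num, wt, mut)
            o, c = surrogate_ddg(pair, cand, model, _burial=burial)
            records.append(DdGRecord(candidate=cand, ddg_open=o, ddg_closed=c))
    return records
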