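"""Design engine: two-state ΔΔG filtering, cutoff enumeration, tier assembly.

Candidate point mutations arrive with a computed stability change (ΔΔG,
negative = stabilizing) in each of the two conformational states. Four
design tiers are assembled:

* X.1 — single-state design on the open structure (score = ΔΔG_open);
* X.2 — single-state design on the closed structure (score = ΔΔG_closed);
* X.3 — two-state filter: only mutations stabilizing in *both* states
  (ΔΔG < 0 strictly in each), scored conservatively by the worse state;
* X.4 — as X.3, with the hinge region and lobe interface additionally
  barred from mutation.

For tiers X.1–X.3, designs are enumerated at a ladder of energy cutoffs and
the strictest cutoff whose design carries a 4–10% mutational load is
selected. X.4 inherits X.3's cutoff so that the pair isolates the effect of
the structural constraint alone, making X.4's mutations a subset of X.3's.
X.0 denotes the unmutated wild-type control.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .constraints import (
    FixedPositionSet,
    LobePartition,
    assemble_fixed_set,
    interface_residues,
    pocket_residues,
    split_lobes,
    terminal_margin,
)
from .errors import DesignError, TwoStateError
from .gnm import (
    FluctuationProfile,
    GNMModel,
    HingeSet,
    detect_hinges,
    gnm_from_coords,
    square_fluctuations,
)
from .pssm import MSA, AllowedIdentitySet, PSSMatrix, allowed_identities, compute_pssm
from .structures import Structure, StructurePair

LAYER_LABELS = ("surface", "boundary", "core")


@dataclass(frozen=True, order=True)
class MutationCandidate:
    """One substitution: open-state author position, wild-type and mutant AA."""

    position: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa == self.mut_aa:
            raise DesignError(
                f"candidate at {self.position} mutates {self.wt_aa} to itself"
            )

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass(frozen=True)
class DdGRecord:
    """A candidate with its ΔΔG in the open and closed states."""

    candidate: MutationCandidate
    ddg_open: float
    ddg_closed: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ddg_open) and math.isfinite(self.ddg_closed)):
            raise DesignError(f"non-finite ΔΔG for {self.candidate}")

    def score(self, score_of: str) -> float:
        if score_of == "open":
            return self.ddg_open
        if score_of == "closed":
            return self.ddg_closed
        if score_of == "max_of_both":
            return max(self.ddg_open, self.ddg_closed)
        if score_of == "mean":
            return 0.5 * (self.ddg_open + self.ddg_closed)
        raise DesignError(f"unknown selection score {score_of!r}")


@dataclass
class DesignVariant:
    """One designed sequence: tier, chosen cutoff, mutations, load."""

    tier: str
    cutoff: float
    mutations: tuple[MutationCandidate, ...]
    sequence: str
    mutational_load: float
    layer_summary: dict[str, int] = field(default_factory=dict)
    out_of_range: bool = False

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)


def load_ddg_tables(
    open_tsv: str | Path,
    closed_tsv: str | Path,
    pair: StructurePair,
) -> tuple[list[DdGRecord], int]:
    """Join per-state ΔΔG tables into two-state records.

    Each table is TSV with columns ``position  wt  mut  ddg`` (open-state
    author numbering). Records are joined on (position, wt, mut); candidates
    present in only one table are dropped and counted. A wild-type letter
    disagreeing with the paired sequence raises :class:`DesignError`.

    Returns (records, n_dropped).
    """
    frames = []
    for src in (open_tsv, closed_tsv):
        if isinstance(src, Path) or (isinstance(src, str) and "\n" not in src):
            df = pd.read_csv(src, sep="\t", comment="#")
        else:
            df = pd.read_csv(io.StringIO(src), sep="\t", comment="#")
        missing = [c for c in ("position", "wt", "mut", "ddg") if c not in df.columns]
        if missing:
            raise DesignError(f"ΔΔG table is missing columns {missing}")
        frames.append(df)
    open_df, closed_df = frames
    merged = open_df.merge(
        closed_df, on=["position", "wt", "mut"], how="outer",
        suffixes=("_open", "_closed"), indicator=True,
    )
    n_dropped = int((merged["_merge"] != "both").sum())
    if n_dropped:
        warnings.warn(
            f"{n_dropped} candidate(s) present in only one state's table were "
            "dropped",
            stacklevel=2,
        )
    merged = merged[merged["_merge"] == "both"]

    authors = pair.author_numbers
    author_to_idx = {num: i for i, num in enumerate(authors)}
    records = []
    for row in merged.itertuples(index=False):
        pos = int(row.position)
        idx = author_to_idx.get(pos)
        if idx is None:
            raise DesignError(f"position {pos} not found in the open state")
        if pair.sequence[idx] != row.wt:
            raise DesignError(
                f"wild-type mismatch at position {pos}: table says {row.wt}, "
                f"sequence has {pair.sequence[idx]}"
            )
        records.append(
            DdGRecord(
                candidate=MutationCandidate(pos, str(row.wt), str(row.mut)),
                ddg_open=float(row.ddg_open),
                ddg_closed=float(row.ddg_closed),
            )
        )
    records.sort(key=lambda r: r.candidate)
    return records, n_dropped


def two_state_filter(records: list[DdGRecord]) -> list[DdGRecord]:
    """Keep only mutations stabilizing in both states (ΔΔG < 0, strictly).

    A mutation stabilizing one conformation but destabilizing the other
    would bias the conformational equilibrium; the strict sign test removes
    it. Records with ΔΔG exactly zero in either state are removed.
    """
    return [r for r in records if r.ddg_open < 0 and r.ddg_closed < 0]


def enumerate_cutoff_designs(
    records: list[DdGRecord],
    cutoffs: tuple[float, ...],
    fixed: FixedPositionSet,
    allowed: dict[int, frozenset[str]] | None,
    score_of: str = "max_of_both",
) -> dict[float, tuple[MutationCandidate, ...]]:
    """Per-cutoff mutation sets.

    At cutoff c a candidate enters if its selection score is ≤ c, its
    position is not fixed, and its mutant identity is in the allowed
    alphabet at that position (``allowed`` maps author position → identity
    set; ``None`` allows everything). At most one mutation per position: the
    lowest-scoring candidate wins, ties broken by alphabetical mutant AA.
    """
    if list(cutoffs) != sorted(cutoffs):
        raise DesignError("cutoffs must be ascending")
    eligible = []
    for r in records:
        pos = r.candidate.position
        if pos in fixed:
            continue
        if allowed is not None and r.candidate.mut_aa not in allowed.get(
            pos, frozenset()
        ):
            continue
        eligible.append((r.score(score_of), r.candidate))

    result: dict[float, tuple[MutationCandidate, ...]] = {}
    for c in cutoffs:
        best: dict[int, tuple[float, MutationCandidate]] = {}
        for score, cand in eligible:
            if score > c:
                continue
            incumbent = best.get(cand.position)
            if (
                incumbent is None
                or score < incumbent[0]
                or (score == incumbent[0] and cand.mut_aa < incumbent[1].mut_aa)
            ):
                best[cand.position] = (score, cand)
        result[c] = tuple(sorted(cand for _, cand in best.values()))
    return result


def select_design(
    per_cutoff: dict[float, tuple[MutationCandidate, ...]],
    length: int,
    load_range: tuple[float, float] = (4.0, 10.0),
) -> tuple[float, tuple[MutationCandidate, ...], bool]:
    """Pick the cutoff whose design lands in the target mutational load.

    Only cutoffs with at least one mutation count as designs (an empty set
    is the wild type, not a design). The strictest (most negative)
    qualifying cutoff wins. If no cutoff's load falls inside ``load_range``,
    the cutoff with the load closest to the range is chosen (ties → stricter
    cutoff) and flagged out-of-range.

    Returns (cutoff, mutations, out_of_range).
    """
    if not per_cutoff:
        raise DesignError("no cutoff designs to select from")
    per_cutoff = {c: m for c, m in per_cutoff.items() if m}
    if not per_cutoff:
        raise DesignError("all cutoff designs are empty")
    lo, hi = load_range
    cutoffs = sorted(per_cutoff)  # ascending = strictest first
    for c in cutoffs:
        load = 100.0 * len(per_cutoff[c]) / length
        if lo <= load <= hi:
            return c, per_cutoff[c], False
    best_c = None
    best_dist = math.inf
    for c in cutoffs:
        load = 100.0 * len(per_cutoff[c]) / length
        dist = max(lo - load, load - hi, 0.0)
        if dist < best_dist:
            best_dist, best_c = dist, c
    return best_c, per_cutoff[best_c], True


# ---------------------------------------------------------------------------
# burial-layer classification
# ---------------------------------------------------------------------------

def _distance_weight(d: float, lo: float, hi: float) -> float:
    """Sigmoid falling 1 → 0 over [lo, hi] (cosine ramp, midpoint centred)."""
    if d <= lo:
        return 1.0
    if d >= hi:
        return 0.0
    return 0.5 * (1.0 + math.cos(math.pi * (d - lo) / (hi - lo)))


def _cone_weight(cos_theta: float) -> float:
    w = (cos_theta + 0.5) / 1.5
    return min(max(w, 0.0), 1.0) ** 2


def _sidechain_point(res, neighbors_ca: np.ndarray | None = None):
    """(origin, direction) for the side-chain cone of one residue.

    Uses Cα→Cβ; for residues without a Cβ (glycine or stripped models) the
    direction points away from the local backbone, estimated from flanking
    Cα positions.
    """
    ca = res.ca
    if ca is None:
        return None, None
    ca = np.asarray(ca.coords)
    cb = res.atom("CB")
    if cb is not None:
        direction = np.asarray(cb.coords) - ca
        origin = np.asarray(cb.coords)
    else:
        if res.name.upper() != "GLY":
            warnings.warn(
                f"residue {res.chain_id}{res.number} lacks a CB atom; "
                "using a backbone-derived direction",
                stacklevel=2,
            )
        if neighbors_ca is not None and len(neighbors_ca):
            direction = ca - neighbors_ca.mean(axis=0)
        else:
            direction = np.array([0.0, 0.0, 1.0])
        origin = ca
    norm = np.linalg.norm(direction)
    direction = direction / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
    return origin, direction


def neighbor_count(
    structure: Structure,
    position: int,
    dist_lo: float = 9.0,
    dist_hi: float = 11.0,
    chain: str | None = None,
) -> float:
    """Weighted side-chain neighbor count n_i of one residue.

    n_i = Σ_{j≠i} f(d_ij)·g(θ_ij) with d_ij the side-chain point distance,
    f the 9→11 Å distance sigmoid and g the squared cone weight on the angle
    between residue i's Cα→Cβ direction and the vector to neighbor j.
    """
    residues = structure.protein_residues(chain)
    idx = next((k for k, r in enumerate(residues) if r.number == position), None)
    if idx is None:
        raise DesignError(f"position {position} not found in structure")

    def flanking(k: int) -> np.ndarray:
        pts = []
        for kk in (k - 1, k + 1):
            if 0 <= kk < len(residues) and residues[kk].ca is not None:
                pts.append(residues[kk].ca.coords)
        return np.asarray(pts, dtype=float)

    origin, direction = _sidechain_point(residues[idx], flanking(idx))
    if origin is None:
        raise DesignError(f"position {position} has no CA atom")
    total = 0.0
    for k, other in enumerate(residues):
        if k == idx:
            continue
        o_origin, _ = _sidechain_point(other, flanking(k))
        if o_origin is None:
            continue
        vec = o_origin - origin
        d = float(np.linalg.norm(vec))
        f = _distance_weight(d, dist_lo, dist_hi)
        if f == 0.0 or d == 0.0:
            continue
        g = _cone_weight(float(np.dot(direction, vec / d)))
        total += f * g
    return total


def classify_layer(
    structure: Structure,
    position: int,
    core_threshold: float = 5.2,
    surface_threshold: float = 2.0,
    dist_lo: float = 9.0,
    dist_hi: float = 11.0,
    chain: str | None = None,
) -> str:
    """Burial layer of a position: ``surface``, ``boundary`` or ``core``.

    Thresholds act on the weighted neighbor count: core if n_i ≥ 5.2,
    surface if n_i ≤ 2.0, boundary otherwise.
    """
    n = neighbor_count(structure, position, dist_lo, dist_hi, chain)
    if n >= core_threshold:
        return "core"
    if n <= surface_threshold:
        return "surface"
    return "boundary"


# ---------------------------------------------------------------------------
# sequence bookkeeping
# ---------------------------------------------------------------------------

def apply_mutations(
    sequence: str,
    mutations: tuple[MutationCandidate, ...],
    author_numbers: list[int],
) -> str:
    """Apply substitutions (author-numbered) to the open-state sequence."""
    index = {num: i for i, num in enumerate(author_numbers)}
    chars = list(sequence)
    for m in mutations:
        i = index.get(m.position)
        if i is None:
            raise DesignError(f"mutation {m} at unknown position")
        if chars[i] != m.wt_aa:
            raise DesignError(
                f"mutation {m}: sequence has {chars[i]} at {m.position}"
            )
        chars[i] = m.mut_aa
    return "".join(chars)


def count_mutations(wt_seq: str, designed_seq: str) -> int:
    """Number of substitutions between two equal-length sequences."""
    if len(wt_seq) != len(designed_seq):
        raise DesignError("sequences must have equal length")
    return sum(a != b for a, b in zip(wt_seq, designed_seq))


def mutational_load(n_mutations: int, length: int) -> float:
    """Mutational load in percent: 100 · n_mutations / length."""
    if length <= 0:
        raise DesignError("length must be positive")
    return 100.0 * n_mutations / length


# ---------------------------------------------------------------------------
# full workflow
# ---------------------------------------------------------------------------

@dataclass
class WorkflowResult:
    """Everything the end-to-end run produces."""

    variants: dict[str, DesignVariant]
    records: list[DdGRecord]
    scatter_table: pd.DataFrame     # per-candidate (ddg_open, ddg_closed, layer)
    mutation_table: pd.DataFrame    # per selected mutation, per tier
    profiles: dict[str, pd.DataFrame]  # per-state fluctuation tables
    fixed_sets: dict[str, FixedPositionSet]
    partition: LobePartition | None
    hinges: dict[str, HingeSet]
    models: dict[str, GNMModel]
    config: RunConfig
    n_dropped_records: int = 0


def _hinge_authors(pair: StructurePair, hinges: dict[str, HingeSet], which: str) -> set[int]:
    out: set[int] = set()
    if which in ("open", "union"):
        out |= {pair.index_to_author(i) for i in hinges["open"].residues}
    if which in ("closed", "union"):
        inv = pair.inverse_mapping()
        out |= {
            pair.index_to_author(inv[i])
            for i in hinges["closed"].residues
            if i in inv
        }
    return out


def run_workflow(
    pair: StructurePair,
    msa: MSA | None = None,
    pssm: PSSMatrix | None = None,
    records: list[DdGRecord] | None = None,
    ddg_open_tsv: str | Path | None = None,
    ddg_closed_tsv: str | Path | None = None,
    config: RunConfig | None = None,
) -> WorkflowResult:
    """Run the complete two-state stability-design workflow on one protein.

    Inputs: a paired open/closed structure, the conservation source (an MSA
    or a ready PSSM) and the ΔΔG source (records or the two per-state TSV
    tables). Produces the X.0–X.4 variants plus the per-mutation scatter
    table and per-state fluctuation profiles used for reporting.
    """
    config = config or RunConfig()
    if records is None:
        if ddg_open_tsv is None or ddg_closed_tsv is None:
            raise DesignError("provide records or both ΔΔG tables")
        records, n_dropped = load_ddg_tables(ddg_open_tsv, ddg_closed_tsv, pair)
    else:
        n_dropped = 0

    # --- dynamics: GNM per state, hinges, lobes, interface -----------------
    models: dict[str, GNMModel] = {}
    hinges: dict[str, HingeSet] = {}
    profiles: dict[str, pd.DataFrame] = {}
    for state, struct, chain in (
        ("open", pair.open, pair.chain_open),
        ("closed", pair.closed, pair.chain_closed),
    ):
        model = gnm_from_coords(
            struct.ca_coords(chain), cutoff=config.gnm_cutoff, gamma=config.gamma
        )
        models[state] = model
        hinges[state] = detect_hinges(
            model, merge_window=config.merge_window, amp_floor=config.amp_floor
        )
        n_modes = min(config.n_modes, model.n_modes)
        fluct = square_fluctuations(model, n_modes=n_modes)
        residues = struct.protein_residues(chain)
        profiles[state] = pd.DataFrame(
            {
                "residue_number": [r.number for r in residues],
                "chain": [r.chain_id for r in residues],
                f"sq_fluct_{n_modes}modes": fluct.values,
                "mode1_component": model.mode(1),
                "is_hinge": [
                    int(i in hinges[state].residues) for i in range(len(residues))
                ],
            }
        )

    partition = None
    interface_auth: set[int] = set()
    if hinges["open"].residues:
        partition = split_lobes(models["open"].mode(1), hinges["open"])
        if partition.lobe_a and partition.lobe_b:
            interface_auth = interface_residues(
                pair,
                partition,
                cutoff=config.interface_cutoff,
                state=config.interface_state,
            )
    hinge_auth = _hinge_authors(pair, hinges, config.hinge_state)

    # --- static constraints ------------------------------------------------
    ligands = pair.closed.ligand_residues()
    if ligands:
        pocket_auth = pocket_residues(
            pair.closed, ligands, cutoff=config.pocket_cutoff, pair=pair
        )
    else:
        pocket_auth = set()
    authors = pair.author_numbers
    term_auth = {
        authors[p - 1]
        for p in terminal_margin(len(authors), config.terminal_margin)
    }

    fixed_sets = {
        tier: assemble_fixed_set(
            tier,
            pocket=pocket_auth,
            hinge=hinge_auth,
            interface=interface_auth,
            terminal=term_auth,
        )
        for tier in ("X.1", "X.2", "X.3", "X.4")
    }

    # --- conservation ------------------------------------------------------
    allowed_by_author: dict[int, frozenset[str]] | None = None
    if pssm is None and msa is not None:
        pssm = compute_pssm(msa, tau=config.tau, weighting=config.weighting)
    if pssm is not None:
        allowed = allowed_identities(pssm, pair.sequence)
        allowed_by_author = {
            authors[i]: allowed[i + 1] for i in range(len(authors))
        }

    # --- tier enumeration and selection ------------------------------------
    filtered = two_state_filter(records)
    length = len(pair.sequence)

    tier_inputs = {
        "X.1": (records, "open", fixed_sets["X.1"]),
        "X.2": (records, "closed", fixed_sets["X.2"]),
        "X.3": (filtered, config.score_of_two_state, fixed_sets["X.3"]),
        "X.4": (filtered, config.score_of_two_state, fixed_sets["X.4"]),
    }
    variants: dict[str, DesignVariant] = {
        "X.0": DesignVariant(
            tier="X.0",
            cutoff=math.nan,
            mutations=(),
            sequence=pair.sequence,
            mutational_load=0.0,
            layer_summary={},
        )
    }
    selected_pool: set[MutationCandidate] = set()
    layer_cache: dict[int, str] = {}

    def layer_of(pos: int) -> str:
        if pos not in layer_cache:
            layer_cache[pos] = classify_layer(
                pair.open,
                pos,
                core_threshold=config.layer_core,
                surface_threshold=config.layer_surface,
                dist_lo=config.layer_dist_lo,
                dist_hi=config.layer_dist_hi,
                chain=pair.chain_open,
            )
        return layer_cache[pos]

    for tier in ("X.1", "X.2", "X.3", "X.4"):
        tier_records, score_of, fixed = tier_inputs[tier]
        if config.restrict_pool_to_selected and tier in ("X.3", "X.4"):
            tier_records = [
                r for r in tier_records if r.candidate in selected_pool
            ]
        per_cutoff = enumerate_cutoff_designs(
            tier_records, config.cutoffs, fixed, allowed_by_author, score_of
        )
        if tier == "X.4":
            # X.4 inherits X.3's energy cutoff so the two tiers differ only
            # by the hinge/interface constraint; with identical cutoff and
            # records, mutations(X.4) ⊆ mutations(X.3) by construction.
            cutoff = variants["X.3"].cutoff
            mutations = per_cutoff[cutoff]
            load = mutational_load(len(mutations), length)
            lo, hi = config.load_range
            out_of_range = not lo <= load <= hi
        else:
            cutoff, mutations, out_of_range = select_design(
                per_cutoff, length, config.load_range
            )
        sequence = apply_mutations(pair.sequence, mutations, authors)
        summary: dict[str, int] = {}
        for m in mutations:
            summary[layer_of(m.position)] = summary.get(layer_of(m.position), 0) + 1
        variants[tier] = DesignVariant(
            tier=tier,
            cutoff=cutoff,
            mutations=mutations,
            sequence=sequence,
            mutational_load=mutational_load(len(mutations), length),
            layer_summary=summary,
            out_of_range=out_of_range,
        )
        if tier in ("X.1", "X.2"):
            selected_pool.update(mutations)

    # --- report tables ------------------------------------------------------
    scatter_table = pd.DataFrame(
        {
            "position": [r.candidate.position for r in records],
            "wt": [r.candidate.wt_aa for r in records],
            "mut": [r.candidate.mut_aa for r in records],
            "ddg_open": [r.ddg_open for r in records],
            "ddg_closed": [r.ddg_closed for r in records],
            "layer": [layer_of(r.candidate.position) for r in records],
        }
    )
    rows = []
    rec_by_cand = {r.candidate: r for r in records}
    for tier in ("X.1", "X.2", "X.3", "X.4"):
        for m in variants[tier].mutations:
            r = rec_by_cand[m]
            rows.append(
                {
                    "tier": tier,
                    "position": m.position,
                    "wt": m.wt_aa,
                    "mut": m.mut_aa,
                    "ddg_open": r.ddg_open,
                    "ddg_closed": r.ddg_closed,
                    "layer": layer_of(m.position),
                }
            )
    mutation_table = pd.DataFrame(
        rows,
        columns=["tier", "position", "wt", "mut", "ddg_open", "ddg_closed", "layer"],
    )

    return WorkflowResult(
        variants=variants,
        records=records,
        scatter_table=scatter_table,
        mutation_table=mutation_table,
        profiles=profiles,
        fixed_sets=fixed_sets,
        partition=partition,
        hinges=hinges,
        models=models,
        config=config,
        n_dropped_records=n_dropped,
    )
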