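"""Synthetic two-lobe fixtures with planted ground truth.

Emulates the study system — a "Venus flytrap" binding protein captured in an
open and a closed conformation — with fully controlled geometry:

* two compact helical lobes joined by a short linker (the planted hinge);
* the closed state equals the open state with lobe B rigidly rotated about
  an axis through the linker midpoint, clamping a ligand in the cleft;
* a homolog MSA with a controllable fraction of conserved columns;
* per-state ΔΔG tables whose records are planted into four classes
  (both-stabilizing / both-destabilizing / open-only / closed-only) with
  values drawn from disjoint sign ranges.

Everything is seeded and bit-reproducible; the truth records are rich
enough to score hinge recovery, lobe assignment, pocket detection and
filter correctness without external data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from .design import DdGRecord, MutationCandidate
from .errors import FixtureError
from .pssm import MSA
from .structures import (
    AA_ALPHABET,
    Atom,
    ONE_TO_THREE,
    Residue,
    Structure,
    StructurePair,
    pair_states,
    write_pdb,
)

#: fixture sequences avoid G (no Cβ) and C (disulfide special-casing)
_FIXTURE_AA = "".join(a for a in AA_ALPHABET if a not in "CG")

_HELIX_RISE = 1.5       # Å per residue along the helix axis
_HELIX_RADIUS = 2.3     # Å
_HELIX_TWIST = np.deg2rad(100.0)
# Distance from the hinge point to the nearest residue of each lobe. Large
# enough that at full closure the lobes couple through the cleft ligand
# region rather than fusing at their inner ends (which would blur the
# mode-1 node away from the linker); small enough that a cleft ligand still
# contacts both lobes.
_END_CLEARANCE = 9.0
_CLASH_DIST = 2.0       # Å; regenerate with fresh jitter below this


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic open/closed fixture pair."""

    n_per_lobe: int = 30
    linker_len: int = 4
    closure_angle: float = 35.0   # degrees of rigid lobe-B rotation
    ligand: bool = True
    seed: int = 0
    msa_rows: int = 50
    conserved_fraction: float = 0.5
    n_candidates: int = 200
    frac_both_stabilizing: float = 0.30
    frac_both_destabilizing: float = 0.30
    frac_open_only: float = 0.20  # closed-only gets the remainder
    closed_numbering_offset: int = 0
    jitter: float = 0.12          # Å of Gaussian coordinate noise

    def __post_init__(self) -> None:
        if self.n_per_lobe < 15:
            raise FixtureError("n_per_lobe must be >= 15")
        if not 0 <= self.closure_angle <= 90:
            raise FixtureError("closure_angle must be in [0, 90] degrees")
        if self.linker_len < 1:
            raise FixtureError("linker_len must be >= 1")

    @property
    def n_residues(self) -> int:
        return 2 * self.n_per_lobe + self.linker_len


@dataclass
class FixtureTruth:
    """Planted ground truth of one fixture pair (internal 0-based indices,
    author numbers where noted)."""

    hinge_indices: tuple[int, ...]
    lobe_labels: str                 # per residue: 'A', 'H' (hinge) or 'B'
    pocket_authors: tuple[int, ...]  # open-state author numbers
    sequence: str


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _helix_points(n: int, origin: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Cα trace of an ideal helix starting at ``origin`` along ``axis``."""
    axis = _unit(axis)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = _unit(np.cross(axis, ref))
    e2 = np.cross(axis, e1)
    t = np.arange(n)
    return (
        origin[None, :]
        + np.outer(t * _HELIX_RISE, axis)
        + _HELIX_RADIUS
        * (np.outer(np.cos(t * _HELIX_TWIST), e1) + np.outer(np.sin(t * _HELIX_TWIST), e2))
    )


def _bezier(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, t: np.ndarray) -> np.ndarray:
    t = t[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _pseudo_cb(ca: np.ndarray) -> np.ndarray:
    """Cβ positions 1.5 Å from each Cα, pointing away from the local backbone."""
    n = len(ca)
    cb = np.empty_like(ca)
    for i in range(n):
        lo, hi = max(i - 1, 0), min(i + 1, n - 1)
        mid = 0.5 * (ca[lo] + ca[hi])
        d = ca[i] - mid
        norm = np.linalg.norm(d)
        if norm < 1e-6:  # straight segment: any perpendicular will do
            t = _unit(ca[hi] - ca[lo])
            d = np.cross(t, [0.0, 0.0, 1.0])
            if np.linalg.norm(d) < 1e-6:
                d = np.cross(t, [1.0, 0.0, 0.0])
            norm = np.linalg.norm(d)
        cb[i] = ca[i] + 1.5 * d / norm
    return cb


def _open_trace(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_per_lobe
    half = np.deg2rad(60.0)
    d1 = np.array([np.cos(half), np.sin(half), 0.0])
    d2 = np.array([np.cos(half), -np.sin(half), 0.0])

    far_a = _END_CLEARANCE + _HELIX_RISE * (n - 1)
    lobe_a = _helix_points(n, origin=d1 * far_a, axis=-d1)
    lobe_b = _helix_points(n, origin=d2 * _END_CLEARANCE, axis=d2)

    p0, p2 = lobe_a[-1], lobe_b[0]
    bulge = np.array([-0.55 * np.linalg.norm(p2 - p0) - 2.0, 0.0, 1.5])
    t = np.linspace(0.0, 1.0, spec.linker_len + 2)[1:-1]
    linker = _bezier(p0, bulge, p2, t)

    ca = np.vstack([lobe_a, linker, lobe_b])
    ca = ca + rng.normal(scale=spec.jitter, size=ca.shape)
    return ca


def _close_trace(ca_open: np.ndarray, spec: FixtureSpec) -> np.ndarray:
    """Closed state: lobe B rigidly rotated about the linker-midpoint z-axis;
    the rotation ramps linearly across the linker residues."""
    n, k = spec.n_per_lobe, spec.linker_len
    linker = ca_open[n : n + k]
    center = linker.mean(axis=0)
    ca = ca_open.copy()
    for j in range(k):
        frac = (j + 1) / (k + 1)
        rot = Rotation.from_rotvec(
            np.deg2rad(spec.closure_angle) * frac * np.array([0.0, 0.0, 1.0])
        )
        ca[n + j] = rot.apply(ca[n + j] - center) + center
    rot = Rotation.from_rotvec(
        np.deg2rad(spec.closure_angle) * np.array([0.0, 0.0, 1.0])
    )
    ca[n + k :] = rot.apply(ca[n + k :] - center) + center
    return ca


def _place_ligand(
    ca_closed: np.ndarray, cb_closed: np.ndarray, spec: FixtureSpec
) -> np.ndarray | None:
    """Ligand heavy atoms on the cleft bisector, contacting both lobes."""
    n, k = spec.n_per_lobe, spec.linker_len
    atoms_a = np.vstack([ca_closed[:n], cb_closed[:n]])
    atoms_b = np.vstack([ca_closed[n + k :], cb_closed[n + k :]])
    # the closed-state cleft bisector: lobe B rotated toward A by closure_angle
    theta = np.deg2rad(spec.closure_angle / 2.0)
    bisector = np.array([np.cos(theta), np.sin(theta), 0.0])
    across = np.array([-np.sin(theta), np.cos(theta), 0.0])  # lobe A side

    # centre the ligand where the cleft is narrowest (but clash-free)
    best = None
    best_spread = np.inf
    for r in np.arange(3.0, 40.0, 0.25):
        p = r * bisector
        da = np.min(np.linalg.norm(atoms_a - p, axis=1))
        db = np.min(np.linalg.norm(atoms_b - p, axis=1))
        if da >= 3.2 and db >= 3.2 and max(da, db) < best_spread:
            best_spread, best = max(da, db), p
    if best is None:
        return None
    prot = np.vstack([atoms_a, atoms_b])

    def clearance(p: np.ndarray) -> float:
        return float(np.min(np.linalg.norm(prot - p, axis=1)))

    # size the ligand to its cleft: grow an arm toward each lobe face until
    # just short of contact, so a bound ligand touches both lobes
    atoms = [best]
    for direction in (across, -across, bisector, -bisector):
        placed = None
        for s in np.arange(0.6, best_spread, 0.3):
            p = best + s * direction
            if clearance(p) < 3.0:
                break
            placed = p
        if placed is not None:
            atoms.append(placed)
            mid = best + 0.5 * (placed - best)
            if clearance(mid) >= 3.0:
                atoms.append(mid)
    xyz = np.array(atoms)
    da = np.linalg.norm(atoms_a[None, :, :] - xyz[:, None, :], axis=-1).min()
    db = np.linalg.norm(atoms_b[None, :, :] - xyz[:, None, :], axis=-1).min()
    if max(da, db) > 5.9:
        return None
    return np.round(xyz, 3)


def _build_structure(
    ca: np.ndarray,
    cb: np.ndarray,
    sequence: str,
    label: str,
    number_offset: int = 0,
    ligand_xyz: np.ndarray | None = None,
) -> Structure:
    residues = []
    for i, aa in enumerate(sequence):
        residues.append(
            Residue(
                chain_id="A",
                number=i + 1 + number_offset,
                icode="",
                name=ONE_TO_THREE[aa],
                atoms=[
                    Atom("CA", "C", tuple(np.round(ca[i], 3))),
                    Atom("CB", "C", tuple(np.round(cb[i], 3))),
                ],
            )
        )
    if ligand_xyz is not None:
        residues.append(
            Residue(
                chain_id="L",
                number=len(sequence) + 1 + number_offset,
                icode="",
                name="LIG",
                atoms=[
                    Atom(f"C{j + 1}", "C", tuple(np.round(p, 3)))
                    for j, p in enumerate(ligand_xyz)
                ],
                is_ligand=True,
            )
        )
    return Structure(residues=residues, label=label)


def make_structure_pair(spec: FixtureSpec) -> tuple[StructurePair, FixtureTruth]:
    """Generate one open/closed fixture pair plus its planted truth.

    Coordinates clashing below 2 Å trigger regeneration with fresh jitter
    (up to 10 attempts). Same spec → bit-identical output.
    """
    n, k = spec.n_per_lobe, spec.linker_len
    seq_rng = np.random.default_rng([spec.seed, 11])
    sequence = "".join(
        seq_rng.choice(list(_FIXTURE_AA), size=spec.n_residues)
    )

    for attempt in range(10):
        rng = np.random.default_rng([spec.seed, 13, attempt])
        ca_open = _open_trace(spec, rng)
        ca_closed = _close_trace(ca_open, spec)
        ok = all(
            pdist(coords).min() >= _CLASH_DIST for coords in (ca_open, ca_closed)
        )
        if ok:
            break
    else:
        raise FixtureError("could not generate a clash-free fixture in 10 attempts")

    cb_open = _pseudo_cb(ca_open)
    cb_closed = _pseudo_cb(ca_closed)
    ligand_xyz = (
        _place_ligand(ca_closed, cb_closed, spec) if spec.ligand else None
    )
    if spec.ligand and ligand_xyz is None:
        raise FixtureError("could not place a ligand in the closed-state cleft")

    open_structure = _build_structure(ca_open, cb_open, sequence, "open")
    closed_structure = _build_structure(
        ca_closed,
        cb_closed,
        sequence,
        "closed",
        number_offset=spec.closed_numbering_offset,
        ligand_xyz=ligand_xyz,
    )
    pair = pair_states(open_structure, closed_structure)

    # planted truth; the pocket is found with a plain double loop so it can
    # serve as an independent oracle for the KD-tree implementation
    pocket: set[int] = set()
    if ligand_xyz is not None:
        for i in range(spec.n_residues):
            for atom in (ca_closed[i], cb_closed[i]):
                if np.min(np.linalg.norm(ligand_xyz - atom, axis=1)) <= 6.0:
                    pocket.add(i + 1)
                    break
    labels = "A" * n + "H" * k + "B" * n
    truth = FixtureTruth(
        hinge_indices=tuple(range(n, n + k)),
        lobe_labels=labels,
        pocket_authors=tuple(sorted(pocket)),
        sequence=sequence,
    )
    return pair, truth


def make_msa(wt_seq: str, spec: FixtureSpec) -> MSA:
    """Seeded homolog MSA: a ``conserved_fraction`` of columns carry a
    single dominant identity (the wild type in every ungapped row); the
    rest sample 3–6 identities; gaps ≤ 5% of non-query cells."""
    rng = np.random.default_rng([spec.seed, 17])
    length = len(wt_seq)
    n_cons = int(round(spec.conserved_fraction * length))
    conserved = set(rng.choice(length, size=n_cons, replace=False).tolist())

    col_alphabets = []
    for j in range(length):
        if j in conserved:
            col_alphabets.append(None)
        else:
            others = [a for a in _FIXTURE_AA if a != wt_seq[j]]
            n_ident = int(rng.integers(2, 6))  # plus wt → 3..6 identities
            picks = rng.choice(others, size=n_ident, replace=False).tolist()
            col_alphabets.append([wt_seq[j]] + picks)

    rows = [wt_seq]
    names = ["query"]
    for s in range(spec.msa_rows - 1):
        chars = []
        for j in range(length):
            if rng.random() < 0.03:
                chars.append("-")
            elif col_alphabets[j] is None:
                chars.append(wt_seq[j])
            else:
                chars.append(rng.choice(col_alphabets[j]))
        rows.append("".join(chars))
        names.append(f"homolog{s + 1:04d}")
    return MSA(names=names, rows=rows, query_row=0)


def msa_to_fasta(msa: MSA) -> str:
    out = []
    for name, row in zip(msa.names, msa.rows):
        out.append(f">{name}")
        for i in range(0, len(row), 60):
            out.append(row[i : i + 60])
    return "\n".join(out) + "\n"


def sample_candidates(
    pair: StructurePair,
    spec: FixtureSpec,
    allowed: dict[int, frozenset[str]] | None = None,
) -> list[MutationCandidate]:
    """Seeded sample of distinct single substitutions over the open state.

    When an allowed-alphabet map is given, 70% of candidates draw their
    mutant identity from it (so enough survive the conservation filter);
    the rest are uniform over the remaining 19 identities.
    """
    rng = np.random.default_rng([spec.seed, 19])
    authors = pair.author_numbers
    seen: set[tuple[int, str]] = set()
    out: list[MutationCandidate] = []
    guard = 0
    while len(out) < spec.n_candidates and guard < 50 * spec.n_candidates:
        guard += 1
        i = int(rng.integers(0, len(authors)))
        pos = authors[i]
        wt = pair.sequence[i]
        pool: list[str]
        if allowed is not None and rng.random() < 0.7:
            pool = sorted(set(allowed.get(pos, frozenset())) - {wt})
        else:
            pool = [a for a in AA_ALPHABET if a != wt]
        if not pool:
            continue
        mut = str(rng.choice(pool))
        if (pos, mut) in seen:
            continue
        seen.add((pos, mut))
        out.append(MutationCandidate(pos, wt, mut))
    return sorted(out)


@dataclass
class PlantedDdG:
    """Two ΔΔG tables (TSV text) plus the planted class memberships."""

    open_tsv: str
    closed_tsv: str
    truth: dict[str, frozenset[MutationCandidate]]


_CLASSES = ("both_stabilizing", "both_destabilizing", "open_only", "closed_only")


def plant_ddg(candidates: list[MutationCandidate], spec: FixtureSpec) -> PlantedDdG:
    """Assign each candidate to one of four sign classes and draw values.

    Class values live in disjoint sign ranges — stabilizing states in
    [−4, −0.3], destabilizing states in [0.3, 3] — so the sign structure is
    unambiguous and the class counts are exact for the spec's fractions.
    Magnitudes are exponentially distributed (most mutations are mildly
    stabilizing or destabilizing, few strongly so), the shape a per-mutation
    stability scan typically produces, which lets the energy-cutoff ladder
    sweep a range of design sizes.
    """
    rng = np.random.default_rng([spec.seed, 23])
    n = len(candidates)
    n_bs = int(round(spec.frac_both_stabilizing * n))
    n_bd = int(round(spec.frac_both_destabilizing * n))
    n_oo = int(round(spec.frac_open_only * n))
    order = rng.permutation(n)
    assignment: dict[str, list[MutationCandidate]] = {c: [] for c in _CLASSES}
    for rank, idx in enumerate(order):
        if rank < n_bs:
            cls = "both_stabilizing"
        elif rank < n_bs + n_bd:
            cls = "both_destabilizing"
        elif rank < n_bs + n_bd + n_oo:
            cls = "open_only"
        else:
            cls = "closed_only"
        assignment[cls].append(candidates[idx])

    def stab() -> float:
        return -min(0.3 + float(rng.exponential(0.8)), 4.0)

    def destab() -> float:
        return min(0.3 + float(rng.exponential(0.5)), 3.0)

    rows_open, rows_closed = [], []
    for cls in _CLASSES:
        for cand in assignment[cls]:
            o = stab() if cls in ("both_stabilizing", "open_only") else destab()
            c = stab() if cls in ("both_stabilizing", "closed_only") else destab()
            rows_open.append((cand.position, cand.wt_aa, cand.mut_aa, o))
            rows_closed.append((cand.position, cand.wt_aa, cand.mut_aa, c))

    def to_tsv(rows) -> str:
        df = pd.DataFrame(rows, columns=["position", "wt", "mut", "ddg"])
        df = df.sort_values(["position", "mut"])
        return df.to_csv(sep="\t", index=False, float_format="%.4f")

    return PlantedDdG(
        open_tsv=to_tsv(rows_open),
        closed_tsv=to_tsv(rows_closed),
        truth={c: frozenset(v) for c, v in assignment.items()},
    )


@dataclass
class FixtureBundle:
    """One complete fixture: paired structures, MSA, ΔΔG tables, truth."""

    spec: FixtureSpec
    pair: StructurePair
    truth: FixtureTruth
    msa: MSA
    candidates: list[MutationCandidate]
    ddg: PlantedDdG


def make_fixture_bundle(spec: FixtureSpec) -> FixtureBundle:
    """Generate everything the workflow needs for one synthetic protein."""
    from .pssm import allowed_identities, compute_pssm

    pair, truth = make_structure_pair(spec)
    msa = make_msa(pair.sequence, spec)
    pssm = compute_pssm(msa)
    allowed = allowed_identities(pssm, pair.sequence)
    allowed_by_author = {
        num: allowed[i + 1] for i, num in enumerate(pair.author_numbers)
    }
    candidates = sample_candidates(pair, spec, allowed_by_author)
    ddg = plant_ddg(candidates, spec)
    return FixtureBundle(
        spec=spec, pair=pair, truth=truth, msa=msa, candidates=candidates, ddg=ddg
    )


PRESETS: dict[str, list[tuple[str, dict]]] = {
    "small": [("small", {"n_per_lobe": 20, "msa_rows": 20, "n_candidates": 80})],
    "pbplike": [("pbplike", {"n_per_lobe": 35, "linker_len": 4})],
    "fourprot": [
        ("protA", {"n_per_lobe": 28, "closure_angle": 25.0}),
        ("protB", {"n_per_lobe": 32, "closure_angle": 35.0}),
        ("protC", {"n_per_lobe": 36, "closure_angle": 45.0}),
        ("protD", {"n_per_lobe": 30, "closure_angle": 55.0}),
    ],
}


def preset_specs(preset: str, seed: int = 0) -> list[tuple[str, FixtureSpec]]:
    """Named :class:`FixtureSpec` list for a preset; seeds derive from ``seed``."""
    if preset not in PRESETS:
        raise FixtureError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    return [
        (name, FixtureSpec(seed=seed + i, **kwargs))
        for i, (name, kwargs) in enumerate(PRESETS[preset])
    ]


def write_fixture_dir(out_dir: str | Path, preset: str = "small", seed: int = 0) -> list[Path]:
    """Write a preset's fixture tree: per protein a directory with
    open.pdb, closed.pdb, msa.fasta, ddg_open.tsv, ddg_closed.tsv, truth.json."""
    out_dir = Path(out_dir)
    written = []
    for name, spec in preset_specs(preset, seed):
        bundle = make_fixture_bundle(spec)
        d = out_dir / name
        d.mkdir(parents=True, exist_ok=True)
        (d / "open.pdb").write_text(write_pdb(bundle.pair.open))
        (d / "closed.pdb").write_text(write_pdb(bundle.pair.closed))
        (d / "msa.fasta").write_text(msa_to_fasta(bundle.msa))
        (d / "ddg_open.tsv").write_text(bundle.ddg.open_tsv)
        (d / "ddg_closed.tsv").write_text(bundle.ddg.closed_tsv)
        truth = {
            "spec": asdict(bundle.spec),
            "hinge_indices": list(bundle.truth.hinge_indices),
            "lobe_labels": bundle.truth.lobe_labels,
            "pocket_authors": list(bundle.truth.pocket_authors),
            "sequence": bundle.truth.sequence,
            "ddg_classes": {
                cls: sorted(str(c) for c in cands)
                for cls, cands in bundle.ddg.truth.items()
            },
        }
        (d / "truth.json").write_text(json.dumps(truth, indent=1))
        written.append(d)
    return written
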