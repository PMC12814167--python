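"""Evolutionary conservation: MSA → PSSM → allowed design alphabet.

A multiple sequence alignment of homologs is condensed into a
position-specific scoring matrix of log₂-odds scores; identities scoring
below zero — i.e. rarer at that position than in the background — are
excluded from the design alphabet, restricting mutations to the sequence
space evolution has explored. The wild-type identity is always allowed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import MSAError, TwoStateError
from .structures import AA_ALPHABET

AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
GAP = "-"


@dataclass
class MSA:
    """An aligned set of homolog sequences.

    ``rows`` are the aligned sequences restricted to columns where the query
    (the design target) has a residue, so column j corresponds 1:1 to query
    position j+1. Non-standard letters are kept as-is and ignored in counts.
    """

    names: list[str]
    rows: list[str]
    query_row: int = 0

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_positions(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def query(self) -> str:
        return self.rows[self.query_row]


def read_msa(text: str, query: str | int = 0) -> MSA:
    """Parse an aligned FASTA into an :class:`MSA`.

    Sequences are uppercased and '.' is normalized to '-'. Columns where the
    query has a gap are dropped, so positions are the query's own
    coordinates. ``query`` selects the design target by record name or row
    index (default: the first record).
    """
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if len(records) < 2:
        raise MSAError("an MSA needs at least two sequences")
    names = [r.id for r in records]
    rows = [str(r.seq).upper().replace(".", GAP) for r in records]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise MSAError(f"ragged alignment: row lengths {sorted(lengths)}")
    if isinstance(query, int):
        if not 0 <= query < len(rows):
            raise MSAError(f"query row {query} out of range")
        query_row = query
    else:
        try:
            query_row = names.index(query)
        except ValueError:
            raise MSAError(f"query sequence {query!r} not found in MSA") from None
    keep = [j for j, c in enumerate(rows[query_row]) if c != GAP]
    rows = ["".join(row[j] for j in keep) for row in rows]
    return MSA(names=names, rows=rows, query_row=query_row)


@dataclass
class PSSMatrix:
    """Positions × 20 log₂-odds scores (bits) with effective counts.

    ``scores[i, AA_INDEX[a]]`` is the log₂-odds of amino acid ``a`` at
    position i+1. Finite everywhere because the pseudocount weight τ > 0.
    """

    scores: np.ndarray
    counts_effective: np.ndarray
    background: np.ndarray
    pseudocount_weight: float

    @property
    def n_positions(self) -> int:
        return self.scores.shape[0]

    def score(self, position: int, aa: str) -> float:
        """Score of ``aa`` at 1-based ``position``."""
        return float(self.scores[position - 1, AA_INDEX[aa]])


def _position_based_counts(rows: list[str], n_pos: int) -> np.ndarray:
    """Column-local position-based weighted counts.

    In each column c with k_c distinct residue identities, a sequence
    showing an identity shared by m_c sequences contributes 1/(k_c·m_c) to
    that identity's count — so every observed identity totals 1/k_c and the
    counts of each non-empty column sum to 1. Exact duplicates share,
    rather than multiply, their influence: adding a copy of a sequence
    changes no count at all.
    """
    counts = np.zeros((n_pos, 20))
    for i in range(n_pos):
        observed = {row[i] for row in rows} & set(AA_INDEX)
        k = len(observed)
        for ch in observed:
            counts[i, AA_INDEX[ch]] = 1.0 / k
    return counts


def compute_pssm(
    msa: MSA,
    tau: float = 10.0,
    background: np.ndarray | None = None,
    weighting: str = "position_based",
) -> PSSMatrix:
    """Log₂-odds PSSM with Dirichlet-style pseudocounts.

    With weighted counts n_{i,a} and N_i = Σ_a n_{i,a}:

        p_{i,a} = (n_{i,a} + τ·b_a) / (N_i + τ),   score_{i,a} = log₂(p_{i,a}/b_a)

    where b is the background distribution (default uniform) and τ > 0 the
    pseudocount weight. With ``weighting="none"`` every sequence counts 1,
    so scores track raw column frequencies; with the default
    ``"position_based"`` weighting every *observed identity* in a column
    totals 1/k (k = distinct identities there), which makes scores robust
    to redundant sequence sets — an exact duplicate changes nothing.
    """
    if tau <= 0:
        raise TwoStateError("pseudocount weight tau must be > 0")
    if weighting not in ("none", "position_based"):
        raise TwoStateError(f"unknown weighting {weighting!r}")
    if background is None:
        background = np.full(20, 1.0 / 20.0)
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or abs(background.sum() - 1.0) > 1e-9:
        raise TwoStateError("background must be 20 frequencies summing to 1")
    if np.any(background <= 0):
        raise TwoStateError("background frequencies must be positive")

    n_pos = msa.n_positions
    if weighting == "position_based":
        counts = _position_based_counts(msa.rows, n_pos)
    else:
        counts = np.zeros((n_pos, 20))
        for row in msa.rows:
            for i, ch in enumerate(row):
                a = AA_INDEX.get(ch)
                if a is not None:
                    counts[i, a] += 1.0
    n_eff = counts.sum(axis=1)
    p = (counts + tau * background) / (n_eff + tau)[:, None]
    scores = np.log2(p / background)
    return PSSMatrix(
        scores=scores,
        counts_effective=n_eff,
        background=background,
        pseudocount_weight=tau,
    )


@dataclass
class AllowedIdentitySet:
    """Per-position sets of permitted amino acids (wild type always in)."""

    allowed: list[frozenset[str]]
    wildtype: str

    def __getitem__(self, position: int) -> frozenset[str]:
        """Allowed identities at 1-based ``position``."""
        return self.allowed[position - 1]

    def __len__(self) -> int:
        return len(self.allowed)

    def permits(self, position: int, aa: str) -> bool:
        return aa in self[position]


def allowed_identities(pssm: PSSMatrix, wildtype_seq: str) -> AllowedIdentitySet:
    """Identities with PSSM score ≥ 0, plus the wild type at each position.

    Identities scoring below zero occur less often in the homolog family
    than expected by chance and are excluded from the design alphabet.
    """
    if len(wildtype_seq) != pssm.n_positions:
        raise TwoStateError(
            f"wild-type length {len(wildtype_seq)} != PSSM positions "
            f"{pssm.n_positions}"
        )
    allowed = []
    for i, wt in enumerate(wildtype_seq):
        ok = {AA_ALPHABET[a] for a in np.flatnonzero(pssm.scores[i] >= 0)}
        ok.add(wt)
        allowed.append(frozenset(ok))
    return AllowedIdentitySet(allowed=allowed, wildtype=wildtype_seq)


def write_pssm_tsv(pssm: PSSMatrix, wildtype_seq: str) -> str:
    """Serialize a PSSM as TSV: position, wt, then the 20 score columns."""
    df = pd.DataFrame(pssm.scores, columns=list(AA_ALPHABET))
    df.insert(0, "wt", list(wildtype_seq))
    df.insert(0, "position", np.arange(1, pssm.n_positions + 1))
    return df.to_csv(sep="\t", index=False, float_format="%.6f")


def read_pssm_tsv(text: str, tau: float = 10.0) -> tuple[PSSMatrix, str]:
    """Import an externally produced PSSM table (positions × 20 scores).

    Returns the matrix plus the wild-type sequence from the ``wt`` column.
    Effective counts are unknown for imported tables and reported as NaN.
    """
    df = pd.read_csv(io.StringIO(text), sep="\t", comment="#")
    missing = [c for c in ("position", "wt", *AA_ALPHABET) if c not in df.columns]
    if missing:
        raise TwoStateError(f"PSSM table is missing columns {missing}")
    df = df.sort_values("position")
    scores = df[list(AA_ALPHABET)].to_numpy(dtype=float)
    wt = "".join(df["wt"].astype(str))
    return (
        PSSMatrix(
            scores=scores,
            counts_effective=np.full(len(df), np.nan),
            background=np.full(20, 1.0 / 20.0),
            pseudocount_weight=tau,
        ),
        wt,
    )
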