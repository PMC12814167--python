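"""Gaussian Network Model on Cα atoms.

The GNM treats the protein as an elastic network: every Cα pair closer than
a cutoff distance r_c (default 10 Å) is joined by a spring of constant γ
(default 1). The connectivity (Kirchhoff) matrix Γ is the graph Laplacian of
this contact graph scaled by γ; its eigenmodes describe equilibrium backbone
fluctuations. The slowest non-trivial modes capture collective domain
motions, and residues where the first mode's eigenvector changes sign are
the hinge points between rigid lobes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.spatial import cKDTree

from .errors import DegenerateModelError, TwoStateError


def build_kirchhoff(
    ca_coords: np.ndarray, cutoff: float = 10.0, gamma: float = 1.0
) -> np.ndarray:
    """Kirchhoff (connectivity) matrix of the Cα contact graph.

    Γ_ij = −γ for i ≠ j with ‖r_i − r_j‖ ≤ cutoff, 0 otherwise;
    Γ_ii = −Σ_{j≠i} Γ_ij, so rows sum to zero.
    """
    coords = np.asarray(ca_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise TwoStateError("ca_coords must be an (N, 3) array")
    n = coords.shape[0]
    if n < 2:
        raise TwoStateError("at least two residues are required for a GNM")
    if not np.all(np.isfinite(coords)):
        raise TwoStateError("coordinates must be finite")
    tree = cKDTree(coords)
    kirchhoff = np.zeros((n, n), dtype=float)
    for i, j in tree.query_pairs(r=cutoff):
        kirchhoff[i, j] = kirchhoff[j, i] = -gamma
    np.fill_diagonal(kirchhoff, -kirchhoff.sum(axis=1))
    return kirchhoff


@dataclass
class GNMModel:
    """Eigendecomposition of a Kirchhoff matrix.

    ``eigenvalues`` are the retained (non-zero) eigenvalues in ascending
    order; ``eigenvectors[:, k]`` is the unit-norm eigenvector of mode k+1.
    Mode 1 is the slowest retained mode. Each eigenvector is oriented so that
    its first non-negligible component is positive (fluctuations and hinges
    are sign-invariant; the convention only makes reports deterministic).
    """

    kirchhoff: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_zero_modes: int
    gamma: float = 1.0
    cutoff: float = 10.0

    @property
    def n_residues(self) -> int:
        return self.kirchhoff.shape[0]

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def mode(self, k: int) -> np.ndarray:
        """Eigenvector of mode ``k`` (1-based; mode 1 = slowest)."""
        return self.eigenvectors[:, k - 1]


def decompose(
    kirchhoff: np.ndarray,
    zero_tol: float = 1e-8,
    gamma: float = 1.0,
    cutoff: float = 10.0,
) -> GNMModel:
    """Eigendecompose Γ, dropping the zero (rigid-body) modes.

    Eigenvalues λ ≤ zero_tol·λ_max are counted as zero modes and removed.
    A connected contact graph has exactly one zero mode; more than one means
    the graph is disconnected, which is tolerated with a warning.
    """
    kirchhoff = np.asarray(kirchhoff, dtype=float)
    if not np.allclose(kirchhoff, kirchhoff.T, atol=1e-10):
        raise TwoStateError("Kirchhoff matrix must be symmetric")
    evals, evecs = scipy.linalg.eigh(kirchhoff)
    lam_max = float(evals[-1])
    if lam_max <= 0 or np.all(evals <= zero_tol * lam_max):
        raise DegenerateModelError("all eigenvalues are numerically zero")
    keep = evals > zero_tol * lam_max
    n_zero = int(np.count_nonzero(~keep))
    if n_zero > 1:
        warnings.warn(
            f"contact graph has {n_zero} connected components; "
            "hinge detection uses mode 1 of the full spectrum",
            stacklevel=2,
        )
    evals, evecs = evals[keep], evecs[:, keep]
    # deterministic sign: first non-negligible component of each mode >= 0
    for k in range(evecs.shape[1]):
        v = evecs[:, k]
        idx = np.argmax(np.abs(v) > 1e-12)
        if v[idx] < 0:
            evecs[:, k] = -v
    return GNMModel(
        kirchhoff=kirchhoff,
        eigenvalues=evals,
        eigenvectors=evecs,
        n_zero_modes=n_zero,
        gamma=gamma,
        cutoff=cutoff,
    )


def gnm_from_coords(
    ca_coords: np.ndarray, cutoff: float = 10.0, gamma: float = 1.0
) -> GNMModel:
    """Convenience: build and decompose in one call."""
    return decompose(
        build_kirchhoff(ca_coords, cutoff=cutoff, gamma=gamma),
        gamma=gamma,
        cutoff=cutoff,
    )


@dataclass
class FluctuationProfile:
    """Per-residue square fluctuations ⟨ΔR_i²⟩ from the slowest modes."""

    values: np.ndarray
    n_modes: int


def square_fluctuations(model: GNMModel, n_modes: int = 5) -> FluctuationProfile:
    """⟨ΔR_i²⟩ = (1/γ) Σ_{k=1..n_modes} u_k,i² / λ_k over retained slow modes.

    Summed over all retained modes this equals the diagonal of the
    Moore–Penrose pseudo-inverse of Γ.
    """
    if n_modes < 1:
        raise TwoStateError("n_modes must be >= 1")
    if n_modes > model.n_modes:
        raise TwoStateError(
            f"requested {n_modes} modes but only {model.n_modes} retained "
            "modes are available"
        )
    u = model.eigenvectors[:, :n_modes]
    lam = model.eigenvalues[:n_modes]
    values = (u**2 / lam).sum(axis=1) / model.gamma
    return FluctuationProfile(values=values, n_modes=n_modes)


@dataclass
class HingeSet:
    """Hinge residues: sign crossings of the first GNM mode.

    ``crossings`` lists the adjacent index pairs (i, i+1) where mode 1
    changes sign; ``residues`` is the union of those pairs after merging
    nearby crossings into blocks. Indices are 0-based internal indices.
    """

    residues: frozenset[int]
    crossings: list[tuple[int, int]]

    def __bool__(self) -> bool:
        return bool(self.residues)


def detect_hinges(
    model: GNMModel, merge_window: int = 2, amp_floor: float = 0.0
) -> HingeSet:
    """Detect hinge residues from the sign structure of mode 1.

    Adjacent pairs with u_1,i · u_1,i+1 < 0 are crossings; crossings closer
    than ``merge_window`` residues merge into one hinge block spanning them.
    Residues adjacent to a block whose mode-1 amplitude is at most
    ``amp_floor`` times the maximum amplitude are absorbed into the block.
    """
    u1 = model.mode(1)
    prod = u1[:-1] * u1[1:]
    cross_idx = np.flatnonzero(prod < 0)
    crossings = [(int(i), int(i) + 1) for i in cross_idx]
    if not crossings:
        return HingeSet(residues=frozenset(), crossings=[])

    # merge crossings closer than merge_window into blocks [start, end]
    blocks: list[list[int]] = []
    for i in cross_idx:
        i = int(i)
        if blocks and i - blocks[-1][1] < merge_window:
            blocks[-1][1] = i + 1
        else:
            blocks.append([i, i + 1])

    amp_cut = amp_floor * float(np.max(np.abs(u1)))
    residues: set[int] = set()
    n = len(u1)
    for start, end in blocks:
        if amp_floor > 0:
            while start > 0 and abs(u1[start - 1]) <= amp_cut:
                start -= 1
            while end < n - 1 and abs(u1[end + 1]) <= amp_cut:
                end += 1
        residues.update(range(start, end + 1))
    return HingeSet(residues=frozenset(residues), crossings=crossings)
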