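# Methods

This note documents the models, parameters and design choices behind
`twostate`, and what the synthetic test universe does and does not show.

## Structure model and state pairing

Structures are read from PDB text (via gemmi). Waters are always dropped;
all other HETATM residues are treated as ligands so that bound small
molecules and ions are visible to pocket detection. For alternate
locations the highest-occupancy conformer is kept (ties go to file order).
By default the first protein chain is used; all four proteins this
workflow targets are monomeric single-chain constructs, and a `--chain`
flag overrides the default.

The two states are paired by global alignment of their one-letter
sequences (match +1, mismatch −1, gap −2). Identically matched columns
define the residue mapping; we require ≥ 95 % identity over aligned
columns and ≥ 90 % coverage of each state's protein residues, which
tolerates differing termini or expression tags between the two crystal
forms while rejecting genuinely different proteins. All positions in
reports use the open-state author numbering; the closed state is only
ever addressed through the mapping (equivalent to renumbering the closed
structure onto the open one).

## Gaussian Network Model

The Kirchhoff matrix is the graph Laplacian of the Cα contact graph:
Γ_ij = −γ for pairs within r_c, Γ_ii = −Σ_j Γ_ij, with r_c = 10 Å and
γ = 1 by default. Eigenvalues within 1e-8·λ_max of zero are treated as
rigid-body modes and removed; more than one zero mode means a
disconnected contact graph, which is tolerated with a warning (real
structures are connected at 10 Å; pathological fixtures may not be).
Square fluctuations sum the 5 slowest retained modes by default — fewer
modes miss features of the lobe dynamics, more add none. Summed over all
retained modes the profile equals the diagonal of the Moore–Penrose
pseudo-inverse of Γ, which the test suite verifies against an independent
construction at 1e-6 relative tolerance.

Eigenvector signs are arbitrary; each mode is oriented so its first
non-negligible component is positive. Fluctuations and hinge detection
are sign-invariant (tested), so the convention only makes reports
deterministic.

**Hinge detection.** Hinges are the sign crossings of mode 1: residue
pairs (i, i+1) with u₁,i·u₁,i+1 < 0. Crossings closer than
`merge_window = 2` residues are merged into one hinge block — near the
node the mode amplitude is close to zero and numerical noise can produce
double crossings that are one physical hinge. An optional `amp_floor`
absorbs adjacent residues whose amplitude is below a fraction of the
mode maximum (off by default).

**Lobes and interface.** Maximal contiguous runs of non-hinge residues
are assigned to lobe A or B by the sign of their mean mode-1 component
(a zero-mean run inherits the preceding run's lobe). Interface residues
have any heavy atom within 6 Å of the opposite lobe. The conformation in
which to measure the interface is genuinely open; the default is the
union over both states — conservative, since anything interfacial in
either conformation is fixed — with open-only and closed-only available.
Hinges are likewise detected independently on both states and unioned by
default.

## Conservation

The PSSM uses log₂-odds scores with pseudocounts:
p_{i,a} = (n_{i,a} + τ·b_a)/(N_i + τ), score = log₂(p/b), with a uniform
background and τ = 10 by default (both configurable); τ > 0 keeps every
score finite. The design alphabet at each position is the identities
scoring ≥ 0 plus, always, the wild type.

Two weighting schemes are provided. `"none"` counts each sequence once,
so scores track raw column frequencies. The default `"position_based"`
weighting is column-local: in a column with k distinct identities, each
observed identity receives a total count of 1/k regardless of how many
sequences carry it. This makes the matrix exactly invariant to duplicated
sequences — a redundant homolog set cannot shift any score — at the cost
of frequency resolution within a column: with a uniform background and
τ = 10, the allowed alphabet under this weighting is effectively the set
of identities observed at the position. Where frequency sensitivity
matters more than redundancy robustness, use `weighting="none"`.
Externally produced PSSM tables can be imported directly, bypassing the
MSA entirely.

## Design tiers

ΔΔG tables are joined on (position, wt, mut); candidates present in only
one state's table are dropped with a warning count, and a wild-type
letter disagreeing with the paired sequence is an error. The two-state
filter keeps records with ΔΔG strictly negative in both states: zero is
not stabilizing, so records at exactly 0 never pass the filter (they do
enter single-state designs at the cutoff 0, which is part of the printed
cutoff ladder).

Selection scores per tier: X.1 uses ΔΔG_open, X.2 ΔΔG_closed, X.3 and
X.4 default to max(ΔΔG_open, ΔΔG_closed) — a mutation enters at cutoff c
only if it is at least that stabilizing in its *worse* state; `mean`,
`open` and `closed` are available as alternatives. At each cutoff at most
one mutation per position is kept (lowest score, ties broken by
alphabetical mutant identity), making runs bit-reproducible. Combination
is additive — every passing mutation is applied, one per position;
modelling interactions between mutations would require the upstream
atomistic energy function and is out of scope.

For X.1–X.3 the selected design is the strictest cutoff whose mutational
load (100·mutations/length) lies in 4–10 %; cutoffs with empty designs
are not designs (an empty set is the wild type). If no cutoff lands in
the range, the closest one is chosen and flagged `out_of_range`. X.4
deliberately inherits X.3's cutoff instead of re-running the load rule:
the X.3/X.4 pair then differs only by the hinge+interface constraint,
mutations(X.4) ⊆ mutations(X.3) holds by construction, and the effect of
the structural constraint is isolated rather than confounded with a
cutoff change. An X.4 whose load falls outside the range is flagged, not
re-selected.

Fixed positions per tier: pocket (heavy atoms within 6 Å of the ligand in
the closed state) and a 5-residue margin at each terminus in all tiers;
X.4 adds the hinge and interface sets. The terminus rule mechanizes the
qualitative practice of avoiding mutations near chain ends; the margin is
a config value. Manual structure-gazing vetoes of individual mutations
are not modelled.

**Layer classification.** A position's burial layer comes from a weighted
side-chain neighbor count: n_i = Σ_j f(d_ij)·g(θ_ij) with d the Cβ–Cβ
distance (Cα when no Cβ exists), f a sigmoid falling 1→0 over 9→11 Å
(cosine ramp) and g = ((cos θ + 0.5)/1.5)², clamped to [0, 1], on the
angle between the Cα→Cβ direction and the vector to the neighbor.
Core if n ≥ 5.2, surface if n ≤ 2.0, boundary between — the published
defaults of the standard layer selector; all constants are configurable.
For residues without a Cβ the direction is estimated from the flanking
Cα positions.

## Surrogate energy model

The surrogate scores a substitution per state as
`burial_weight · b · (h(wt) − h(mut))` with b the Cβ neighbor count
within 8 Å and h the Kyte–Doolittle hydropathy, plus a penalty of
`0.3 · h(mut)` for hydrophobic identities placed at exposed sites
(b < 3). It is deliberately naive: monotone in burial, antisymmetric
under swapping wild type and mutant when the penalty is disabled, and
geometry-only — so state-dependent burial differences around the cleft
produce exactly the sign-discordant candidates the two-state filter
exists to remove. It claims no thermodynamic accuracy and is never
compared against real energy-function output.

## Synthetic fixtures

The generator emulates the study system: two compact helical lobes
(single α-helical arms, 1.5 Å rise, 2.3 Å radius) meeting at 120° with a
short Bézier-arc linker — the planted hinge — and a closed state obtained
by rigidly rotating lobe B about an axis through the linker midpoint
(20–60°), with the rotation ramped across the linker residues. A ligand
is grown in the closed-state cleft with arms sized to touch both lobes
within 6 Å. Lobe ends are kept 9 Å from the hinge point: with less
clearance the arms fuse at their inner ends under strong closure and the
slowest-mode node genuinely drifts off the linker, i.e. the fixture would
not have the hinge it claims to plant. This geometry was validated over
260 seeded fixtures (both states each) with exact hinge and lobe
recovery. Coordinates carry 0.12 Å Gaussian jitter; generation retries
with fresh jitter if any Cα pair falls below 2 Å.

MSA fixtures make a chosen fraction of columns single-identity (wild type
in every ungapped row) and let the rest sample 3–6 identities, with ≤ 5 %
gaps. ΔΔG fixtures assign candidates exactly (rounded fractions) to four
sign classes — both-stabilizing, both-destabilizing, open-only,
closed-only — with magnitudes drawn exponentially (most mutations mild,
a few strong, as per-mutation stability scans produce) in disjoint sign
ranges, so class membership is unambiguous and the cutoff ladder sweeps a
range of design sizes. Every fixture is a pure function of its spec
(seeded streams), so identical specs give bit-identical files.

What the fixtures do **not** emulate: real side-chain packing (only Cα
plus a pseudo-Cβ), sequence realism, β-sheet lobes, correlated energetic
couplings between mutations, or realistic ΔΔG distributions. Passing
tests therefore demonstrate the correctness of the bookkeeping, the
dynamics-derived constraints and the filtering logic — not the accuracy
of any energy model on real proteins.

## Problem sizes and determinism

The test suite and the acceptance script use fixtures of 44–84 residues,
20-fixture sweeps for hinge recovery and filter checks, and 200-candidate
tables for enumeration checks; the complete four-protein workflow runs in
under a second and the full suite in a few seconds. All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; repeated
runs with the same configuration produce byte-identical FASTA/TSV/JSON
outputs, which is itself a tested property.

## Known limitations

* ΔΔG values are consumed as given; no error model, no interaction terms,
  and the additive combination ignores epistasis between mutations.
* Hinge detection assumes the slowest mode is the inter-lobe motion; for
  multi-domain proteins with competing slow modes the first mode may mix
  motions and the detected hinges should be inspected.
* The interface/hinge state choice (union by default) is conservative;
  open-only or closed-only selections may free additional positions.
* mmCIF input is not supported; PDB (optionally gzipped) only.
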