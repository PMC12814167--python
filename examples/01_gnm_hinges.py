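"""Detect the hinge of a two-lobe binding protein from its GNM slow mode.

Builds a synthetic open/closed pair with a known 4-residue linker, runs the
Gaussian Network Model on each state and prints the detected hinge residues
and the square-fluctuation minimum. The detected hinge should bracket the
planted linker: low mode-1 amplitude and low fluctuation mark the pivot
between the two rigid lobes.
"""

import numpy as np

from twostate import (
    FixtureSpec,
    detect_hinges,
    gnm_from_coords,
    make_structure_pair,
    square_fluctuations,
)

spec = FixtureSpec(n_per_lobe=30, linker_len=4, closure_angle=35.0, seed=11)
pair, truth = make_structure_pair(spec)
print(f"protein: {len(pair.sequence)} residues, planted linker at internal "
      f"indices {truth.hinge_indices}")

for label, structure, chain in (
    ("open", pair.open, pair.chain_open),
    ("closed", pair.closed, pair.chain_closed),
):
    model = gnm_from_coords(structure.ca_coords(chain), cutoff=10.0, gamma=1.0)
    hinges = detect_hinges(model)
    fluct = square_fluctuations(model, n_modes=5)
    print(f"{label:>6s} state: hinge residues (0-based) {sorted(hinges.residues)}, "
          f"fluctuation minimum at index {int(np.argmin(fluct.values))}")

print("Hinge residues within +/-2 of the linker confirm that mode 1 is the "
      "inter-lobe opening motion; the fluctuation minimum is the pivot.")
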