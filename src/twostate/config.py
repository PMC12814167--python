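"""Run configuration: every tunable of the workflow in one place."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

#: the nine energy cutoffs (ascending) at which combinatorial designs are built
DEFAULT_CUTOFFS = (-4.0, -3.20, -2.88, -2.4, -2.0, -1.6, -1.2, -0.72, 0.0)


@dataclass
class RunConfig:
    """All workflow tunables with their defaults.

    Energies are in the (opaque) units of the upstream ΔΔG calculator;
    distances in Å.
    """

    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    load_range: tuple[float, float] = (4.0, 10.0)  # mutational load, percent
    terminal_margin: int = 5          # residues fixed at each terminus
    gnm_cutoff: float = 10.0          # Cα contact cutoff, Å
    gamma: float = 1.0                # GNM spring constant
    n_modes: int = 5                  # slow modes in fluctuation profiles
    merge_window: int = 2             # hinge crossing merge distance
    amp_floor: float = 0.0            # hinge low-amplitude absorption
    interface_cutoff: float = 6.0     # lobe-interface distance cutoff, Å
    pocket_cutoff: float = 6.0        # ligand pocket distance cutoff, Å
    interface_state: str = "union"    # open | closed | union
    hinge_state: str = "union"        # open | closed | union
    score_of_two_state: str = "max_of_both"  # open | closed | max_of_both | mean
    tau: float = 10.0                 # PSSM pseudocount weight
    weighting: str = "position_based"  # MSA sequence weighting
    layer_core: float = 5.2           # neighbor count above which = core
    layer_surface: float = 2.0        # neighbor count below which = surface
    layer_dist_lo: float = 9.0        # distance sigmoid start, Å
    layer_dist_hi: float = 11.0       # distance sigmoid end, Å
    restrict_pool_to_selected: bool = False  # X.3/X.4 pool = X.1∪X.2 selections
    seed: int = 0

    def __post_init__(self) -> None:
        self.cutoffs = tuple(float(c) for c in self.cutoffs)
        if list(self.cutoffs) != sorted(self.cutoffs):
            raise ConfigError("cutoffs must be ascending")
        lo, hi = self.load_range
        if not 0 <= lo <= hi:
            raise ConfigError("load_range must satisfy 0 <= lo <= hi")
        self.load_range = (float(lo), float(hi))
        for name in ("interface_state", "hinge_state"):
            if getattr(self, name) not in ("open", "closed", "union"):
                raise ConfigError(f"{name} must be open/closed/union")
        if self.score_of_two_state not in ("open", "closed", "max_of_both", "mean"):
            raise ConfigError(
                "score_of_two_state must be open/closed/max_of_both/mean"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cutoffs"] = list(self.cutoffs)
        d["load_range"] = list(self.load_range)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Short stable hash of the serialized config, for output headers."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
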