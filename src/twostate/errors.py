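"""Exception hierarchy for the twostate package."""


class TwoStateError(Exception):
    """Base class for all package errors."""


class ParseError(TwoStateError):
    """A structure or table file could not be parsed."""


class PairingError(TwoStateError):
    """Open and closed structures could not be paired (not the same protein,
    or the aligned core is too small)."""


class MSAError(TwoStateError):
    """A multiple sequence alignment is malformed."""


class DegenerateModelError(TwoStateError):
    """The elastic network has no non-trivial modes."""


class DesignError(TwoStateError):
    """A design-stage precondition failed (bad ΔΔG table, empty designs...)."""


class ConfigError(TwoStateError):
    """Invalid run configuration."""


class FixtureError(TwoStateError):
    """Synthetic fixture generation failed (e.g. unresolvable clashes)."""
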