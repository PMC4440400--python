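"""Exception types raised across the package."""


class SulfuroxError(ValueError):
    """Base class for all package-specific errors."""


class UnknownSpeciesError(SulfuroxError):
    """A reaction references a species with no thermodynamic entry."""


class InadmissibleParameterError(SulfuroxError):
    """A stoichiometric parameter (x, y, ratio, fraction) is out of its domain."""


class ThermodynamicError(SulfuroxError):
    """A Gibbs energy has the wrong sign for the requested efficiency."""


class NoSolutionError(SulfuroxError):
    """A root search found no solution in the admissible domain."""
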