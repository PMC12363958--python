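"""Exception hierarchy for the RETS design toolkit.

Everything derives from :class:`RETSDesignError` (itself a ``ValueError``)
so callers can catch design-rule violations with a single except clause
while still behaving sensibly under generic ``ValueError`` handling.
"""


class RETSDesignError(ValueError):
    """Base class for all design-rule and input violations."""


class AlphabetError(RETSDesignError):
    """A sequence contains characters outside the strict {A,C,G,T} alphabet."""


class ScaffoldDefinitionError(RETSDesignError):
    """A ribozyme scaffold segment has the wrong length or inconsistent stems."""


class InvalidSpliceSiteError(RETSDesignError):
    """A junction violates the splice-site rule (upstream exon must end in T/U)."""


class InsufficientContextError(RETSDesignError):
    """Too little sequence upstream of a junction to form the 6-nt IGSBS."""


class NoWindowError(RETSDesignError):
    """The target transcript is shorter than a single guide footprint."""


class ConsistencyError(RETSDesignError):
    """Components passed together were not derived from each other."""


class ParameterError(RETSDesignError):
    """A numeric parameter is outside its valid range."""


class CargoError(RETSDesignError):
    """The cargo ORF violates the CDS grammar (start/stop/frame)."""
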