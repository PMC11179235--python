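"""Exception hierarchy for nanocarve.

Every error raised by the library derives from :class:`NanocarveError` so
callers (and the CLI) can catch one base class. Subclasses map one-to-one
onto the failure modes of the pipeline stages.
"""


class NanocarveError(Exception):
    """Base class for all nanocarve errors."""


class CIFParseError(NanocarveError):
    """Malformed or incomplete CIF input (missing cell, unknown element...)."""


class UnsupportedFeatureError(NanocarveError):
    """Valid CIF but outside the supported dialect (e.g. partial occupancy)."""


class SubstitutionError(NanocarveError):
    """Element substitution outside the same-group/adjacent-period rule."""


class MemoryGuardError(NanocarveError):
    """Supercell would exceed the configured atom budget."""


class EmptyParticleError(NanocarveError):
    """A carving or neutralization step retained zero atoms."""


class CompositionError(NanocarveError):
    """Structure composition incompatible with the requested formula unit."""


class ParameterizationError(NanocarveError):
    """Missing potential parameters for a species pair."""


class UnstableConfigurationError(NanocarveError):
    """Non-finite energy at the start of minimization (overlapping atoms).

    Usually indicates a force-field/structure mismatch; try another
    potential or a less distorted starting geometry.
    """


class RadiusLookupError(NanocarveError):
    """No ionic or covalent radius available for an element/oxidation state."""


class StageOrderError(NanocarveError):
    """A pipeline stage was invoked before its prerequisite stage ran."""
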