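"""Exception hierarchy for nlm3d.

Every error raised by the library derives from :class:`NLMError` so callers
(and the CLI) can catch library failures without swallowing programming bugs.
"""


class NLMError(Exception):
    """Base class for all nlm3d errors."""


class InvalidPadError(NLMError):
    """Padding specification cannot be applied to the volume."""


class InvalidRangeError(NLMError):
    """Slab range is empty or outside the volume."""


class InvalidStrengthError(NLMError):
    """Filter-strength parameters are nonpositive (h**2 would be 0)."""


class InvalidParamsError(NLMError):
    """Window edges violate the oddness/ordering constraints."""


class BoxOutOfBoundsError(NLMError):
    """A similarity/search box exceeds the padded volume bounds."""


class BudgetTooSmallError(NLMError):
    """Memory budget cannot hold even one core slice plus halos (x2 copies)."""


class PlanMismatchError(NLMError):
    """A chunk plan was built for a different volume shape."""


class GatherError(NLMError):
    """Filtered chunks are missing, misshapen, or their cores overlap."""


class RunError(NLMError):
    """A worker failed while filtering a chunk."""


class IncompatibleVolumesError(NLMError):
    """Two volumes to be compared have different shapes."""


class DegenerateResidualError(NLMError):
    """Residual is constant; autocorrelation is undefined."""


class InvalidSpecError(NLMError):
    """Phantom specification is empty or out of bounds."""


class InvalidNoiseError(NLMError):
    """Noise model parameters are invalid (e.g. sigma <= 0)."""


class VolumeIOError(NLMError):
    """File cannot be read/written as a 3D volume."""
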