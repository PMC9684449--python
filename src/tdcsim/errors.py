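"""Exception hierarchy for tdcsim.

Every error raised by the library derives from :class:`TdcsimError` so callers
can catch the whole family with one clause.
"""


class TdcsimError(Exception):
    """Base class for all tdcsim errors."""


class InvalidSpecError(TdcsimError, ValueError):
    """A phantom/electrode/ROI specification violates its invariants."""


class GeometryError(TdcsimError):
    """A geometric construction failed (non-nesting shells, overlapping
    electrodes, off-scalp placements, non-separating surfaces, ...)."""


class LandmarkError(TdcsimError):
    """Missing or degenerate anatomical landmarks."""


class ConfigurationError(TdcsimError):
    """Invalid study configuration or montage definition."""


class SolverError(TdcsimError):
    """The linear solver failed to reach the requested residual."""


class DesignError(TdcsimError):
    """A statistical design requirement (complete pairing, >=2 conditions)
    is not met."""


class EmptyMaskError(TdcsimError):
    """A metric was requested over an empty tissue mask or ROI."""


class DegenerateDataError(TdcsimError):
    """Statistics requested on data with no usable variance."""
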