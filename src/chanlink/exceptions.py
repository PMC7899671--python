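"""Package-wide exception and warning types."""


class ChanlinkError(Exception):
    """Base class for all chanlink errors."""


class UnknownLigandError(ChanlinkError, ValueError):
    """A pulse names a ligand that is not PTX, GABA, DZ or buffer."""


class ProtocolError(ChanlinkError, ValueError):
    """Pulse events overlap, are out of order, or lie outside the trace."""


class BaselineWindowError(ChanlinkError, ValueError):
    """A pre-pulse baseline window overlaps another pulse or the trace edge."""


class PeakWindowError(ChanlinkError, ValueError):
    """A pulse's peak-search window falls outside the recorded trace."""


class RundownError(ChanlinkError, ValueError):
    """Rundown correction is impossible (<2 PTX peaks) or pathological
    (the fitted line crosses zero inside the recording)."""


class NonIdentifiableError(ChanlinkError, ValueError):
    """The data cannot constrain the requested fit (e.g. all responses equal)."""


class CurveScalingError(ChanlinkError, ValueError):
    """Scaling an estimated-Po curve produced a probability outside [0, 1]."""


class LinkageError(ChanlinkError, ValueError):
    """Current ratios imply an open probability outside (0, 1)."""


class ConfigError(ChanlinkError, ValueError):
    """A run configuration failed validation before any computation."""


class IdentifiabilityWarning(UserWarning):
    """A global fit has more free parameters than the curves can constrain,
    or a badly conditioned Jacobian at the solution."""
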