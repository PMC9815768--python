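"""Exception types raised across the package."""


class RBFRegimesError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(RBFRegimesError, ValueError):
    """A task or regime specification violates its preconditions."""


class InvalidParameterError(RBFRegimesError, ValueError):
    """A scalar parameter is outside its permitted range."""


class InsufficientDataError(RBFRegimesError, ValueError):
    """The training set is too small for the requested selection."""


class DegenerateLatticeError(RBFRegimesError, ValueError):
    """Fewer occupied lattice cells than requested centers; lower ``v``."""


class InvalidTaskError(RBFRegimesError, ValueError):
    """The task is degenerate for the regime (e.g. a single class present)."""


class RankDeficientError(RBFRegimesError, ValueError):
    """Normal equations are singular and no ridge was supplied."""
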