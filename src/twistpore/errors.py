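"""Package-wide exception types."""


class TwistporeError(Exception):
    """Base class for all package errors."""


class InvalidConfigurationError(TwistporeError, ValueError):
    """A pore configuration violates the design rules (twist range, adjacency)."""


class GeometryError(TwistporeError, ValueError):
    """Unphysical geometry (non-positive spacing, zero separation, ...)."""


class ResolutionError(TwistporeError, ValueError):
    """A grid or sampling step is too coarse for the requested measurement."""


class FormatError(TwistporeError, ValueError):
    """Unknown or malformed file format."""


class ProfileError(TwistporeError, ValueError):
    """A PMF profile violates its contract (empty reference, no extrema, ...)."""


class NoOscillationError(TwistporeError, ValueError):
    """A velocity series has no resolvable oscillatory structure."""


class DegenerateDesignError(TwistporeError, ValueError):
    """A regression design matrix is rank deficient or too small."""


class ElectrolyteError(TwistporeError, ValueError):
    """Unphysical electrolyte state (charge imbalance, packing, convergence)."""


class AnalysisError(TwistporeError, ValueError):
    """A trajectory analysis precondition is not met."""


class ConfigError(TwistporeError, ValueError):
    """Invalid pipeline configuration."""
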