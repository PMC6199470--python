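"""Exception types raised across the pipeline."""


class LegacyLagError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(LegacyLagError, ValueError):
    """A generator configuration violates an invariant."""


class InfeasibleDesignError(LegacyLagError, ValueError):
    """A sampling design cannot be realised on the given grid."""


class OutOfExtentError(LegacyLagError, ValueError):
    """A coordinate falls outside the climate grid extent."""


class IncompleteCoverageError(LegacyLagError, ValueError):
    """A climatology window is not fully covered by the monthly series."""


class ZeroVarianceError(LegacyLagError, ValueError):
    """A variable is constant where variation is required (PCA scaling, MESS)."""


class RankDeficiencyError(LegacyLagError, ValueError):
    """A regression design matrix is rank deficient / collinear."""
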