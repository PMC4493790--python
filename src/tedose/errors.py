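"""Exception hierarchy shared across the package."""


class TedoseError(Exception):
    """Base class for all package-specific errors."""


class MalformedInputError(TedoseError, ValueError):
    """Input data violate a structural precondition (short curve, mismatched ids...)."""


class ConfigurationError(TedoseError, ValueError):
    """A parameter value outside its admissible range."""


class InvalidEfficiencyError(TedoseError, ValueError):
    """Amplification efficiency incompatible with the dosage ratio equation."""


class UndefinedDistanceError(TedoseError, ValueError):
    """Dice-based distance undefined (both encodings carry no bands)."""


class SaturationError(TedoseError, ArithmeticError):
    """Sequence divergence beyond the reach of the K2P correction."""
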