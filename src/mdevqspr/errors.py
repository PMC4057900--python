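"""Exception hierarchy for mdevqspr."""


class MdevQsprError(Exception):
    """Base class for all mdevqspr domain errors."""


class InvalidPositionError(MdevQsprError):
    """A bromine locant outside the substitutable range 2-6."""


class DuplicateSubstitutionError(MdevQsprError):
    """The same locant listed twice on one ring."""


class EmptySpecError(MdevQsprError):
    """An empty congener string (no locants to parse)."""


class ConnectivityError(MdevQsprError):
    """A skeleton graph that is not connected."""


class DatasetError(MdevQsprError):
    """Malformed dataset input (CSV rows, group labels...)."""


class FixtureIntegrityError(MdevQsprError):
    """Packaged study data disagrees with recomputed descriptors."""


class SampleSizeError(MdevQsprError):
    """Too few records to fit the requested model."""


class SingularDesignError(MdevQsprError):
    """Rank-deficient or degenerate design matrix."""


class ConfigurationError(MdevQsprError):
    """Invalid training configuration (e.g. empty verification set)."""


class ProtocolError(MdevQsprError):
    """Validation protocol violated (e.g. overlapping train/test sets)."""


class DegenerateRegressionError(MdevQsprError):
    """Regression on degenerate data (constant predictor)."""


class ExhaustionError(MdevQsprError):
    """More distinct congeners requested than exist."""
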