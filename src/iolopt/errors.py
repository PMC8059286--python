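"""Exception hierarchy shared across the package."""


class IoloptError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(IoloptError, ValueError):
    """An argument violates a documented precondition or type invariant."""


class NonPhysicalEyeError(IoloptError, ValueError):
    """A vergence denominator became non-positive: the combination of
    biometry, ELP and IOL power does not describe a focusable eye."""


class DomainError(IoloptError, ValueError):
    """A singular denominator in a plane transposition (vertex conversion)."""


class StratumEmptyError(IoloptError, ValueError):
    """A required gender stratum contains no records."""


class SchemaError(IoloptError, ValueError):
    """A cohort table is missing required columns or is structurally unusable."""


class ConfigError(IoloptError, ValueError):
    """A generator or pipeline configuration is internally inconsistent."""


class PipelineAbortError(IoloptError, RuntimeError):
    """A pipeline stage removed every record; downstream stages cannot run."""
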