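"""Exception types shared across the package."""


class EmpathLearnError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EmpathLearnError, ValueError):
    """A spec/config object violates its invariants (e.g. impossible trial counts)."""


class InputError(EmpathLearnError, ValueError):
    """Data passed to an operation is invalid (out of range, too short, misaligned)."""


class SchemaError(EmpathLearnError, ValueError):
    """A CSV/table does not conform to the tidy trial or participant schema."""


class AbsentSeriesError(EmpathLearnError, ValueError):
    """A requested rating series is entirely missing (e.g. predictions in a
    no-prediction design)."""
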