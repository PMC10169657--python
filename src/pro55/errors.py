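"""Exception hierarchy shared across the package."""


class Pro55Error(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(Pro55Error, ValueError):
    """A numeric input violates its physical or statistical domain."""


class CodingError(Pro55Error, ValueError):
    """A questionnaire response cannot be coded under the active model."""


class IncompleteResponseError(Pro55Error, ValueError):
    """A questionnaire response has one or more missing items."""


class ConfigurationError(Pro55Error, ValueError):
    """A model or run configuration file violates its schema."""


class ContractError(Pro55Error, ValueError):
    """Aligned inputs disagree in length, keys, or dimension."""


class DegenerateDataError(Pro55Error, ValueError):
    """The data cannot support the requested computation (e.g. one class)."""
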