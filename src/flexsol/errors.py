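"""Exception hierarchy shared by the library and the CLI.

Each class maps to a CLI exit code so shell callers can distinguish bad
input, bad configuration and failed training.
"""


class FlexsolError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(FlexsolError):
    """Unusable input data (bad SMILES, unreadable CSV, empty table)."""

    exit_code = 2


class DescriptorMissingError(InputError):
    """A model was asked to predict a record lacking a required descriptor."""


class ConfigError(FlexsolError):
    """Malformed parameter bundle or simulation configuration."""

    exit_code = 3


class TrainingError(FlexsolError):
    """Regression failure: too few records, rank deficiency, non-convergence."""

    exit_code = 4


class MetricError(FlexsolError):
    """Metrics undefined for the given observed/predicted pairs."""

    exit_code = 2
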