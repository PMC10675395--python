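"""Exception hierarchy shared by all stages.

Exit-code mapping used by the CLI: input errors -> 2, configuration
errors -> 3, training errors -> 4.
"""


class EEGFatigueError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(EEGFatigueError):
    """Invalid data handed to a stage (bad shapes, values, files)."""

    exit_code = 2


class DegenerateInputError(InputError):
    """Input is formally valid but carries no usable information
    (constant signal, zero total power)."""


class ConfigurationError(EEGFatigueError):
    """Invalid parameter combination or config file contents."""

    exit_code = 3


class TrainingError(EEGFatigueError):
    """Optimization failed (diverging loss, NaN weights)."""

    exit_code = 4
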