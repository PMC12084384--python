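"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: :class:`InputError` -> 1,
:class:`ConfigurationError` -> 2 (usage), anything else -> 1.
"""


class NCTDError(Exception):
    """Base class for all package errors."""


class InputError(NCTDError):
    """The supplied data violates a precondition (missing cells, unseen
    categories, non-finite values, unreadable files...)."""


class ParseError(InputError):
    """A delimited file could not be parsed; the message names the line."""


class ConfigurationError(NCTDError):
    """A parameter or option is out of its valid range."""


class ContractViolation(NCTDError):
    """An internal value contract was broken (e.g. pixel outside [0, 1])."""


class TrainingError(NCTDError):
    """Optimization failed (non-finite loss)."""
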