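"""Exception hierarchy.

Everything raised on purpose derives from :class:`ModsepError`, so callers
(and the CLI exit-code mapping) can distinguish data problems from bugs.
"""


class ModsepError(Exception):
    """Base class for all errors raised by modsep."""


class ParseError(ModsepError):
    """A tabular input file could not be parsed; message names the line."""


class DataError(ModsepError):
    """Input data violates a precondition (empty sets, unreachable genes, ...)."""


class BudgetError(ModsepError):
    """A combinatorial search would exceed its evaluation budget."""
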