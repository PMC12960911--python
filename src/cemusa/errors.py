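"""Exception hierarchy.

Every failure surfaced to a caller is one of these three categories so the
CLI can map them to distinct exit messages: configuration (the user asked
for something inconsistent), parsing (a file is malformed), or validation
(the data violate a metric precondition).
"""


class CemusaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CemusaError):
    """Inconsistent or incomplete configuration (missing column, missing
    cost-table entry, expression weights requested without expression)."""


class ParseError(CemusaError):
    """Malformed input file; message names the offending row where known."""


class ValidationError(CemusaError):
    """Data violate a documented precondition or invariant."""
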