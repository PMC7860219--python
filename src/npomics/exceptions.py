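"""Exception hierarchy.

``ValidationError`` covers malformed inputs and configuration; the CLI maps
it to exit code 1. Anything else that escapes a stage maps to exit code 2.
"""


class NPOmicsError(Exception):
    """Base class for all package errors."""


class ValidationError(NPOmicsError, ValueError):
    """An input, configuration field, or precondition failed validation."""
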