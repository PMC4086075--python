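"""Exception hierarchy.

``FormatError`` covers malformed external files, ``ValidationError`` covers
semantically invalid but well-formed inputs (unknown class labels, broken
tree topologies, contract violations).  The CLI maps both to exit code 2.
"""


class LoctreeError(Exception):
    """Base class for all package errors."""


class FormatError(LoctreeError):
    """An external file does not conform to its format."""


class ValidationError(LoctreeError):
    """Well-formed input that violates a domain contract."""
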