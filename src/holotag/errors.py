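"""Exception hierarchy.

``InputError`` covers malformed user inputs (exit code 2 in the CLI);
``FormatError`` is its file-format subclass; ``InternalError`` flags
violated internal invariants (exit code 3).
"""


class HolotagError(Exception):
    """Base class for all package errors."""


class InputError(HolotagError):
    """Invalid user-supplied input (bad sequence, missing lineage, ...)."""


class FormatError(InputError):
    """Malformed file content (truncated FASTQ, corrupt database, ...)."""


class InternalError(HolotagError):
    """An internal consistency invariant was violated."""
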