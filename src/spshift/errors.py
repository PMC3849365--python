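"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: usage/validation problems exit 1,
problems with otherwise well-formed input data exit 2, anything else
(a bug) exits 3.
"""


class SpshiftError(Exception):
    """Base class for all errors raised by this package."""


class InputError(SpshiftError):
    """Invalid usage or validation failure (bad arguments, malformed spec
    strings, out-of-range coordinates, alphabet violations)."""


class DataError(SpshiftError):
    """Well-formed request on data that cannot support it (primer not found,
    reference-allele mismatch, empty FASTA, enumeration cutoff exceeded)."""
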