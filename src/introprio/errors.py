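"""Exception hierarchy.

Exit-code mapping for the CLI: ConfigurationError -> 2, everything else
derived from IntroprioError -> 3.
"""


class IntroprioError(Exception):
    """Base class for all package errors."""


class ConfigurationError(IntroprioError):
    """Invalid configuration; the message names the offending field."""


class VcfParseError(IntroprioError):
    """Malformed VCF input."""


class CoordinateError(IntroprioError):
    """A position falls outside its declared chromosome."""


class InputError(IntroprioError):
    """Structurally invalid input to an operation (unsorted windows, asymmetric matrix, ...)."""


class InsufficientOverlapError(IntroprioError):
    """A sample pair shares no co-observed genotyped site."""


class ReferenceMismatchError(IntroprioError):
    """A variant's REF allele disagrees with the reference sequence."""


class UnsatisfiableEffectError(IntroprioError):
    """A requested variant effect cannot be realised on the given gene model."""


class NamespaceError(IntroprioError):
    """Chromosome naming differs between two inputs that must share it."""


class CatalogError(IntroprioError):
    """A motif catalog entry is not a valid IUPAC consensus."""
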