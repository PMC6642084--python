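"""Exception hierarchy shared across the package."""


class SkewscanError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SkewscanError):
    """An input file violates the documented tabular/Newick contract."""


class ParameterError(SkewscanError, ValueError):
    """A numeric argument is outside its documented range."""


class EnumerationLimitError(SkewscanError):
    """The exact-test table space exceeds the enumeration guard.

    Raised instead of silently switching to an approximation; callers that
    can tolerate an approximate p-value must opt in explicitly (Monte Carlo
    fallbacks are deliberately not provided).
    """
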