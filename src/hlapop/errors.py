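"""Exception hierarchy shared across the package.

Input/format problems and numerical failures are kept distinct so the CLI
can map them to different exit codes (2 and 3 respectively).
"""


class HlaError(Exception):
    """Base class for all package errors."""


class InputError(HlaError):
    """Malformed or inconsistent user input (parse errors, bad tables)."""


class AlleleParseError(InputError):
    """An HLA allele name could not be parsed."""


class CohortLoadError(InputError):
    """A genotype table could not be loaded."""


class EmptyLocusError(InputError):
    """No individual in the cohort is typed at the requested locus."""


class NumericalError(HlaError):
    """A numerical procedure failed (non-convergence, degenerate system)."""


class EnumerationCapError(NumericalError):
    """Exhaustive enumeration would exceed the configured table cap.

    Callers should fall back to Monte-Carlo sampling.
    """
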