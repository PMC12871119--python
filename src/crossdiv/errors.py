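"""Exception hierarchy.

Readers reject malformed input loudly rather than coercing it; numeric
routines raise on degenerate input rather than returning NaN.
"""


class CrossdivError(Exception):
    """Base class for all package errors."""


class FormatError(CrossdivError):
    """Malformed external input (FASTA, TSV, codeml, FATCAT, config)."""


class ConfigError(CrossdivError):
    """Invalid configuration (bad correlation matrix, bad fractions, ...)."""


class ComputationError(CrossdivError):
    """A computation cannot proceed (no comparable codons, empty join, ...)."""


class DegenerateInputError(ComputationError):
    """Input admits no meaningful estimate (constant values, zero variance)."""


class SingularFitError(ComputationError):
    """Design matrix is rank-deficient; model coefficients are not identifiable."""
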