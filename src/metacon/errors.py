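"""Exception hierarchy.

Every user-facing failure mode raises a distinct, named error so that
callers (and the CLI) can react to, or report, specific conditions.
"""


class MetaconError(Exception):
    """Base class for all errors raised by this package."""


class EmptyInputError(MetaconError):
    """An input file or collection contained no usable records."""


class DuplicateIdError(MetaconError):
    """Two records in one input share the same identifier."""


class IllegalCharacterError(MetaconError):
    """A sequence contains characters outside the {A,C,G,T,N} alphabet."""


class CoverageMismatchError(MetaconError):
    """The coverage table and the contig set do not describe the same contigs."""


class NegativeCoverageError(MetaconError):
    """A coverage value is negative (coverage is a mean read depth, >= 0)."""


class NonNumericCoverageError(MetaconError):
    """A coverage value could not be parsed as a number."""


class NoInformativeBasesError(MetaconError):
    """A contig consists entirely of N, so no nucleotide model exists for it."""


class ZeroVarianceError(MetaconError):
    """A k-mer class has zero binomial variance for some contig.

    Only possible with an unsmoothed nucleotide model in which some base
    has probability 0 or 1.
    """


class NoLongContigsError(MetaconError):
    """Every contig fell below the long/short threshold; phase 1 has no input."""


class DimensionMismatchError(MetaconError):
    """Two arrays that must share a shape (or an axis) do not."""


class EmptyClusteringError(MetaconError):
    """A clustering operation was asked to run on no data or produced no bins."""
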