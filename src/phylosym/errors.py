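"""Exception hierarchy for the phylosym package."""


class PhylosymError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(PhylosymError, ValueError):
    """An argument violates a documented precondition."""


class NewickParseError(PhylosymError, ValueError):
    """Malformed newick input."""


class LeafSetMismatchError(PhylosymError, ValueError):
    """Two trees compared on different leaf-label sets.

    Carries the set differences so callers can report which labels are
    missing from which tree.
    """

    def __init__(self, only_in_first, only_in_second):
        self.only_in_first = sorted(only_in_first)
        self.only_in_second = sorted(only_in_second)
        super().__init__(
            f"leaf sets differ: only in first {self.only_in_first}, "
            f"only in second {self.only_in_second}"
        )


class DepthExceedsSampleError(PhylosymError, ValueError):
    """Requested rarefaction depth exceeds a sample's total count."""

    def __init__(self, sample_id, total, depth):
        self.sample_id = sample_id
        self.total = total
        self.depth = depth
        super().__init__(
            f"sample {sample_id!r} has {total} reads, below requested depth {depth}"
        )


class MissingTaxaError(PhylosymError, ValueError):
    """Observed taxa absent from the reference tree."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"taxa missing from tree: {self.missing}")


class MetadataMismatchError(PhylosymError, ValueError):
    """Sample metadata does not cover, or conflicts with, the data."""


class UndefinedStatisticError(PhylosymError, ValueError):
    """A statistic is undefined for the given input (e.g. all-zero vector)."""
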