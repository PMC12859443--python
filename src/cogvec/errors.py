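"""Exception hierarchy for cogvec."""


class CogvecError(Exception):
    """Base class for all cogvec errors."""


class FormatError(CogvecError):
    """A file does not conform to the expected dialect."""


class EmptyDatasetError(CogvecError):
    """An operation received a dataset with no usable content."""


class AlphabetCapacityError(CogvecError):
    """A requested encoding would exceed the multistate alphabet capacity."""


class ComparabilityError(CogvecError):
    """Models fitted on different data representations cannot be compared."""


class TooFewColumnsError(CogvecError):
    """A character matrix is below the minimum column count for an analysis."""


class TaxaMismatchError(CogvecError):
    """Tree taxa and matrix taxa do not agree."""
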