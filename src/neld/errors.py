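"""Exception hierarchy."""


class NeldError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(NeldError):
    """A simulation or experiment configuration violates its invariants."""


class TooFewSnpPairsError(NeldError):
    """No eligible SNP pairs in the requested pair class.

    Mirrors the hard failure mode of map-based LD estimators on sparse
    per-chromosome data ("too few SNPs").
    """


class EmptySelectionError(NeldError):
    """A stratification or filter selected no individuals."""


class EmptyPanelError(NeldError):
    """A locus filter removed every locus."""


class ParseError(NeldError):
    """Malformed input file; message carries the offending line number."""
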