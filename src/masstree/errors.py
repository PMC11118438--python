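"""Exception hierarchy for masstree."""


class MasstreeError(Exception):
    """Base class for all masstree errors."""


class ParseError(MasstreeError):
    """Malformed input file (MGF block, peak line, USI string)."""


class SchemaError(MasstreeError):
    """Tabular input missing mandatory columns or violating row constraints."""


class EmptySpectrumError(MasstreeError):
    """Spectrum has no peaks left and cannot be searched."""


class ConsistencyError(MasstreeError):
    """Conflicting parentage or duplicate identity in taxonomy input."""


class UnknownTaxonError(MasstreeError):
    """A taxid or file could not be placed on the taxonomic tree."""


class ParameterError(MasstreeError):
    """Out-of-range search or index parameter."""


class ResolverUnavailableError(MasstreeError):
    """A USI was requested but no offline resolver entry exists for it."""
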