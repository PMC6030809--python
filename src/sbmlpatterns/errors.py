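"""Exception hierarchy for the pattern-mining workflow."""


class SbmlPatternsError(Exception):
    """Base class for all workflow errors."""


class FormatError(SbmlPatternsError):
    """An input file does not conform to its expected format (SBML, DOT, JSON)."""


class DataError(SbmlPatternsError):
    """Well-formed input carries values outside the workflow's data model."""


class ConfigError(SbmlPatternsError):
    """Invalid mining/generation configuration."""


class CapacityError(SbmlPatternsError):
    """A resource cap was exceeded; subgraph mining is NP-hard and must be bounded."""


class ContractError(SbmlPatternsError):
    """An operation was called with input violating its precondition."""
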