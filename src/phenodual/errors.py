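"""Exception hierarchy for phenodual."""


class PhenodualError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PhenodualError):
    """An input table is missing a required column."""


class DataValidationError(PhenodualError):
    """A record or dataset violates a domain invariant."""


class ParseError(PhenodualError):
    """A cell could not be parsed; the message carries the 1-based data row."""


class RankDeficiencyError(PhenodualError):
    """The fixed-effect design matrix is rank deficient.

    The message names the collinear column so the offending variable can be
    removed or the dataset inspected.
    """


class FitError(PhenodualError):
    """Model fitting failed (non-convergence or an invalid nested comparison)."""


class PrefixError(PhenodualError):
    """A CURIE prefix could not be resolved against the namespace map."""


class VariableMapError(PhenodualError):
    """Variable/ontology map problem: duplicate id, missing terms, or mismatch."""
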