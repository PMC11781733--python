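"""Exception hierarchy shared across the pipeline."""


class PhenobarError(Exception):
    """Base class for all phenobar errors."""


class FormatError(PhenobarError):
    """A file or table does not conform to the expected layout."""


class ValidationError(PhenobarError):
    """Input values violate a documented contract."""


class ComputationError(PhenobarError):
    """A numeric stage cannot produce a well-defined result."""
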