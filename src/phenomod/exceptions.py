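"""Exception hierarchy shared across the engines."""


class PhenomodError(Exception):
    """Base class for all package errors."""


class ValidationError(PhenomodError):
    """Malformed or inconsistent input data."""


class DegenerateFitError(PhenomodError):
    """Too few usable points (or a constant response) for a regression fit."""


class StressFitError(PhenomodError):
    """No valid bell/quadratic candidate in the stress phase."""


class MetricError(PhenomodError):
    """A metric is undefined for the supplied vectors."""


class UnknownModelError(PhenomodError):
    """A model id not present in the registry was requested."""
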