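"""Exception hierarchy shared across the package."""


class VitdmrError(Exception):
    """Base class for all package errors."""


class SchemaError(VitdmrError):
    """A required column is missing from an input table."""


class TableParseError(VitdmrError):
    """A cell could not be parsed; carries the offending row number."""


class ValidationError(VitdmrError):
    """A record violates a domain invariant (duplicate rsid, bad SE, ...)."""


class HarmonizationError(VitdmrError):
    """Exposure and outcome alleles cannot be reconciled."""


class StrandAmbiguityError(HarmonizationError):
    """Palindromic SNP with allele frequencies too close to 0.5 to resolve strand."""


class ProxyError(VitdmrError):
    """Proxy substitution rejected (LD below the configured minimum)."""


class WeakInstrumentError(VitdmrError):
    """Instrument has a zero exposure effect; the Wald ratio is undefined."""


class HeterogeneityUndefinedError(VitdmrError):
    """Cochran's Q requires at least two instrument-specific estimates."""


class ConvergenceError(VitdmrError):
    """A numerical solve (intercept calibration, effect inversion) failed."""


class DesignError(VitdmrError):
    """Invalid experimental design (overlapping two-sample splits, empty subset)."""
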