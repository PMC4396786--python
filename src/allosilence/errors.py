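"""Exception types raised across the pipeline."""


class AlloSilenceError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AlloSilenceError):
    """An invalid configuration value; the message names the offending field."""


class MalformedRecordError(AlloSilenceError):
    """A sequence record violating its format contract (e.g. seq/qual length mismatch)."""


class FormatError(AlloSilenceError):
    """Unparseable input file."""


class IntegrityError(AlloSilenceError):
    """Cross-references between pipeline artifacts do not line up."""


class DomainError(AlloSilenceError):
    """A numeric argument outside the mathematical domain of an operation."""
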