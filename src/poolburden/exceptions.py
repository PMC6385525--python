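"""Exception hierarchy for the pipeline."""


class PoolBurdenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PoolBurdenError, ValueError):
    """An invalid configuration value (bad threshold, bad distribution, ...)."""


class VariantError(PoolBurdenError, ValueError):
    """An invalid variant representation (bad alleles, ref == alt, ...)."""


class ParseError(PoolBurdenError, ValueError):
    """A malformed input file; message carries the offending location."""


class ValidationError(PoolBurdenError, ValueError):
    """Internally inconsistent data (AC > AN, duplicate keys, conflicting genes)."""
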