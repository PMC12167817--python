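"""Exception hierarchy shared by all pipeline stages."""


class TsetScanError(Exception):
    """Base class for all errors raised by this package."""


class InputIntegrityError(TsetScanError):
    """An input table violates its contract (unknown ids, duplicates, bad joins)."""


class ConfigurationError(TsetScanError):
    """A parameter or configuration value is unusable (empty panel, bad rates)."""


class UndefinedDenominatorError(TsetScanError):
    """A percentage or ratio was requested with a zero/empty denominator."""


class EmptyRankError(TsetScanError):
    """Percentile ranking was requested on an all-missing vector."""
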