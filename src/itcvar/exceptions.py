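"""Exception hierarchy shared across the package."""


class ItcVarError(Exception):
    """Base class for itcvar errors."""


class ConfigError(ItcVarError):
    """Invalid or inconsistent run configuration (CLI exit code 2)."""


class DataError(ItcVarError):
    """Invalid input data (CLI exit code 3)."""


class FitError(ItcVarError):
    """Numerical failure during estimation (CLI exit code 4)."""
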