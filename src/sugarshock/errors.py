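"""Exception hierarchy shared across the package."""


class SugarShockError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SugarShockError, ValueError):
    """Invalid parameter value, variant tag, preset name or config key."""


class DataError(SugarShockError, ValueError):
    """Malformed or degenerate input data (counts, datasets, schedules)."""


class StructuralError(SugarShockError, ValueError):
    """Mismatched structures: species/network mismatch, unequal KDE grids."""
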