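"""Exception hierarchy shared across the package.

``InputError`` and ``ConfigError`` map to CLI exit code 2 (user error);
anything else escaping to the CLI maps to exit code 1 (internal error).
"""


class OligoblockError(Exception):
    """Base class for all package-specific errors."""


class InputError(OligoblockError, ValueError):
    """Invalid user-supplied data (sequences, files, tables)."""


class ConfigError(OligoblockError, ValueError):
    """Invalid or degenerate configuration values."""


class ThermoModelError(OligoblockError):
    """Requested chemistry has no shipped thermodynamic parameterization."""
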