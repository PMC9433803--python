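"""Exception types shared across the package."""


class MeaburstError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MeaburstError, ValueError):
    """Invalid configuration value or unknown configuration key."""


class FormatError(MeaburstError, ValueError):
    """Malformed input file.  Carries the offending line number when known."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class NullModelError(MeaburstError, RuntimeError):
    """Degree-preserving null model could not be constructed."""
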