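"""Exception hierarchy shared across the package."""


class VaxFootprintError(Exception):
    """Base class for all package-specific errors."""


class DomainError(VaxFootprintError, ValueError):
    """A numeric argument is outside its physically meaningful domain."""


class ConfigError(VaxFootprintError, ValueError):
    """A scenario, geography or run configuration is invalid or incomplete."""


class FactorLookupError(ConfigError, KeyError):
    """An emission factor name is not present in the registry."""

    def __init__(self, name: str, available=None):
        self.name = name
        msg = f"unknown emission factor {name!r}"
        if available:
            msg += f"; registry contains: {', '.join(sorted(available))}"
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError would re-quote the message
        return self.args[0]
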