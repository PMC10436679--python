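"""Exception hierarchy for costkit."""


class CostkitError(Exception):
    """Base class for all costkit errors."""


class RegisterValidationError(CostkitError):
    """A site register (or one of its tables) failed validation.

    Carries *all* violations found, not just the first.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        msg = "; ".join(str(v) for v in self.violations)
        super().__init__(f"{len(self.violations)} validation error(s): {msg}")


class RegisterParseError(CostkitError):
    """A register file could not be parsed (names the file and field/line)."""


class CurrencyError(CostkitError):
    """Arithmetic or conversion between incompatible currencies."""


class MissingPriceError(CostkitError):
    """A commodity price required for costing is absent from the price list."""

    def __init__(self, item: str):
        self.item = item
        super().__init__(f"no price for item {item!r}")


class MissingSalaryError(CostkitError):
    """A provider appearing in an activity has no salary entry."""

    def __init__(self, provider):
        self.provider = provider
        super().__init__(f"no salary entry for provider {provider!r}")


class UnknownAttributionKeyError(CostkitError):
    """An attribution fraction was requested for an unknown item key."""

    def __init__(self, key: str):
        self.key = key
        super().__init__(
            f"no attribution fraction configured for {key!r}; "
            "refusing to default silently to 100%"
        )


class ClassificationError(CostkitError):
    """Input outside the domain of a classification rule."""
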