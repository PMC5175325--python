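"""Exception types shared across the package."""


class RegistryFormatError(ValueError):
    """The registry config file is malformed (missing or mistyped blocks)."""


class RegistryValidationError(ValueError):
    """A registry or response matrix violates a structural invariant."""


class CodingError(ValueError):
    """An observed survey cell is not codable as 0/1/missing."""
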