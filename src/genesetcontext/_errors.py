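"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input object or file violates a documented invariant."""


class FormulaError(ValidationError):
    """Raised for unparseable or unresolvable pattern-of-interest formulas."""
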