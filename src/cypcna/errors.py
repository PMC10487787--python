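"""Exception hierarchy for cypcna.

All package-specific failures derive from :class:`CypCnaError` so callers can
catch one base class at the CLI boundary.
"""


class CypCnaError(Exception):
    """Base class for all cypcna errors."""


class SchemaError(CypCnaError):
    """An input table or manifest violates the expected schema."""


class DuplicateRecordError(SchemaError):
    """A record that must be unique appears more than once."""


class MissingDataError(CypCnaError):
    """A required measurement is absent (e.g. no usable Ct replicate)."""


class TooFewReferencesError(CypCnaError):
    """Fewer validated reference genes survive scoring than required."""

    def __init__(self, surviving, required):
        self.surviving = list(surviving)
        self.required = required
        super().__init__(
            f"only {len(self.surviving)} validated reference gene(s) "
            f"{self.surviving} survive scoring; {required} required"
        )


class DegenerateFitError(CypCnaError):
    """A regression cannot be fitted (e.g. constant predictor)."""
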