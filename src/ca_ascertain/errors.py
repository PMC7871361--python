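"""Exception types raised by the ascertainment pipeline."""


class ConfigurationError(ValueError):
    """Invalid synthetic-cohort or pipeline configuration."""


class UnmappedCodeError(KeyError):
    """A SNOMED CT code has no entry in the cross-map table."""

    def __init__(self, snomed_code: str):
        super().__init__(snomed_code)
        self.snomed_code = snomed_code

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return f"SNOMED code not present in cross-map table: {self.snomed_code}"


class CodeValidationError(ValueError):
    """A malformed ICD-10 code or an unknown category value."""


class IntegrityError(ValueError):
    """Cross-table referential integrity violated (e.g. unknown participant)."""


class DomainError(ValueError):
    """A statistic was requested outside its domain (e.g. zero denominator)."""
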