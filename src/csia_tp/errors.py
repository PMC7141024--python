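"""Exception hierarchy for the csia_tp package."""


class CsiaTpError(Exception):
    """Base class for all package errors."""


class FormatError(CsiaTpError):
    """Input table is structurally malformed (e.g. a mandatory column is absent)."""


class IngestError(CsiaTpError):
    """Input rows are structurally fine but semantically invalid (duplicates, unknown codes)."""


class MissingAnalyteError(CsiaTpError):
    """A required amino acid is absent from a specimen's profile."""

    def __init__(self, specimen_id: str, missing: set[str]):
        self.specimen_id = specimen_id
        self.missing = set(missing)
        super().__init__(
            f"specimen {specimen_id!r} is missing required amino acid(s): "
            f"{', '.join(sorted(self.missing))}"
        )


class ParameterError(CsiaTpError):
    """A framework parameter value is invalid (e.g. zero trophic discrimination factor)."""


class ConfigurationError(CsiaTpError):
    """A framework or scenario is internally inconsistent for the requested operation."""
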