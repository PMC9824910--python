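"""Exception hierarchy for glandmark."""


class GlandmarkError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GlandmarkError):
    """A required column is missing or a configuration field is invalid."""


class CohortValidationError(GlandmarkError):
    """Input rows violate the longitudinal data model invariants."""


class ParseError(GlandmarkError):
    """A cell could not be parsed as a number; carries the file location."""


class EmptyLandmarkError(GlandmarkError):
    """A cohort yielded zero eligible landmark rows."""


class DegenerateLocalizationError(GlandmarkError):
    """All kernel distances are zero; localization is undefined."""


class SparseNeighborhoodError(GlandmarkError):
    """Too few events carry positive weight around the query point."""

    def __init__(self, message, effective_events=None, min_events=None,
                 suggested_span=None):
        super().__init__(message)
        self.effective_events = effective_events
        self.min_events = min_events
        self.suggested_span = suggested_span


class CoxFitError(GlandmarkError):
    """The weighted partial likelihood cannot be maximized on these data."""


class MetricError(GlandmarkError):
    """An accuracy metric is undefined (no cases/controls, or IPCW weight 1/0)."""


class SimulationError(GlandmarkError):
    """The simulator configuration produced a degenerate cohort."""


class ConfigError(GlandmarkError):
    """The run configuration file failed schema validation."""
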