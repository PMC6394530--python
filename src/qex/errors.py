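"""Exception hierarchy for the qex package."""


class QexError(Exception):
    """Base class for all qex errors."""


class MoleculeError(QexError):
    """A single structure could not be parsed or sanitized.

    Carries the compound id so callers can implement skip-vs-abort policies.
    """

    def __init__(self, compound_id: str, message: str):
        self.compound_id = compound_id
        super().__init__(f"compound {compound_id!r}: {message}")


class SchemaError(QexError):
    """A tabular input (property CSV, label CSV, model JSON) violates its schema."""


class AlertSetError(QexError):
    """A structural-alert pattern file contains an invalid SMARTS."""


class FitError(QexError):
    """A desirability fit failed (degenerate samples, too few bins, no convergence)."""


class ModelError(QexError):
    """A scoring model is invalid or could not be built."""


class MetricError(QexError):
    """A screening metric is undefined for the given ranking."""


class FixtureError(QexError):
    """A synthetic-data specification is infeasible."""
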