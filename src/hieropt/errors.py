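"""Exception hierarchy for hieropt."""


class HieroptError(Exception):
    """Base class for all hieropt errors."""


class FormatError(HieroptError):
    """A problem file could not be parsed (names the file and, where known, the line)."""


class UnknownIdentifierError(HieroptError):
    """A table or expression references an identifier that does not exist."""


class ValidationError(HieroptError):
    """A problem violates a structural assumption required for estimation.

    Carries the per-group validation report when raised by the
    group-structure validator, so callers can inspect which sharing
    assumption (A1-A4) failed for which group.
    """

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


class DegenerateGroupError(HieroptError):
    """An inner subproblem is unidentifiable (e.g. all model outputs zero in a scaling group)."""

    def __init__(self, group_id, message):
        super().__init__(f"group '{group_id}': {message}")
        self.group_id = group_id


class SimulationError(HieroptError):
    """ODE integration failed; normally mapped to an infinite objective, not raised."""
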