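"""Exception hierarchy shared across the package."""


class RichRosterError(Exception):
    """Base class for all package errors."""


class ValidationError(RichRosterError):
    """Input violates a documented contract (bad ID, bad game code, ...)."""


class MalformedNameError(ValidationError):
    """A photo filename is too short to contain the configured ID slice."""


class CapacityError(ValidationError):
    """Roster does not fit on the requested panel grid."""

    def __init__(self, needed: int, capacity: int):
        self.needed = needed
        self.capacity = capacity
        super().__init__(
            f"{needed} IDs do not fit in {capacity} cells "
            f"(short by {needed - capacity})"
        )


class DegenerateGeometryError(RichRosterError):
    """Corner quad is collinear, non-convex, or mis-ordered."""


class DegenerateCellError(RichRosterError):
    """A cell image has no interior left after border excision."""


class PairingError(ValidationError):
    """Blank and game cell maps do not cover the same recipients."""


class ConflictError(RichRosterError):
    """Two distinct records exist for the same focal x game."""


class MissingDataError(RichRosterError):
    """A payout was requested for a game with no compiled data."""
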