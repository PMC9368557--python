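"""Exception hierarchy shared across the package."""


class PocketDynError(Exception):
    """Base class for all package errors."""


class InputError(PocketDynError, ValueError):
    """Invalid argument values or inconsistent inputs."""


class FormatError(PocketDynError, ValueError):
    """A file could be opened but its content violates the expected format."""


class SelectionParseError(PocketDynError, ValueError):
    """Syntax error in a selection expression; carries the token position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class DegenerateSelectionError(PocketDynError, ValueError):
    """A geometric operation received a degenerate (e.g. collinear) atom set."""
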