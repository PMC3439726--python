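"""Exception hierarchy shared by all modules."""


class OmicsViewError(Exception):
    """Base class for every error raised by this package."""


class InputFormatError(OmicsViewError):
    """A file could not be parsed: malformed cell, bad column count, ...

    Messages always name the offending file and line (and, where it exists,
    the identifier) so a user can fix the input without guessing.
    """

    def __init__(self, path, line, message):
        self.path = str(path)
        self.line = line
        where = f"{self.path}:{line}" if line is not None else self.path
        super().__init__(f"{where}: {message}")


class ValidationError(OmicsViewError):
    """Inputs parsed fine but violate a cross-file or structural invariant."""
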