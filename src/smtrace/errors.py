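"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class FitError(RuntimeError):
    """A model fit failed to converge or the data are degenerate."""


class SchemaError(ValueError):
    """A tabular input violates its schema.

    Carries enough context (file, line, column) to locate the offence.
    """

    def __init__(self, message, path=None, line=None, column=None):
        parts = [message]
        if path is not None:
            parts.append(f"file={path}")
        if line is not None:
            parts.append(f"line={line}")
        if column is not None:
            parts.append(f"column={column}")
        super().__init__("; ".join(str(p) for p in parts))
        self.path = path
        self.line = line
        self.column = column
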