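"""Exception types shared across the package."""


class ShoulderKinError(Exception):
    """Base class for package errors."""


class MissingLandmarkError(ShoulderKinError, KeyError):
    """A named landmark or marker required by an operation is absent."""

    def __init__(self, names, context=""):
        self.names = tuple(names)
        msg = f"missing landmark(s): {', '.join(self.names)}"
        if context:
            msg = f"{context}: {msg}"
        super().__init__(msg)

    def __str__(self):  # KeyError quotes its arg; keep the plain message
        return self.args[0]


class DegenerateGeometryError(ShoulderKinError, ValueError):
    """Input geometry is degenerate (collinear/coplanar/zero-length)."""


class ValidationError(ShoulderKinError, ValueError):
    """A domain invariant is violated (non-rotation matrix, implausible
    anthropometrics, mismatched grids, ...)."""


class CollinearityError(ValidationError):
    """Regression design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = tuple(columns)
        super().__init__(
            "rank-deficient design; linearly dependent column(s): "
            + ", ".join(self.columns)
        )
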