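"""Exception hierarchy shared across the pipeline."""


class BayesconnError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(BayesconnError, ValueError):
    """A scalar argument is outside its valid range."""


class DataError(BayesconnError, ValueError):
    """Input data are malformed (non-finite, wrong shape, degenerate)."""


class DesignMatrixError(BayesconnError, ValueError):
    """Confound design is rank deficient; carries the offending columns."""

    def __init__(self, message: str, collinear: list[str] | None = None):
        super().__init__(message)
        self.collinear = collinear or []


class MatrixError(BayesconnError, ValueError):
    """A matrix argument violates a structural requirement (e.g. not SPD)."""


class ConvergenceError(BayesconnError, RuntimeError):
    """An iterative routine failed to converge; carries iteration count."""

    def __init__(self, message: str, n_iterations: int | None = None,
                 offending_edges: list[tuple[int, int]] | None = None):
        super().__init__(message)
        self.n_iterations = n_iterations
        self.offending_edges = offending_edges or []


class SettingsError(BayesconnError, ValueError):
    """MCMC or pipeline settings are inconsistent."""


class SchemaError(BayesconnError, ValueError):
    """Objects being combined disagree on ROI labels or shapes."""


class ParseError(BayesconnError, ValueError):
    """An artifact file could not be parsed; carries location info."""

    def __init__(self, message: str, path: str | None = None,
                 line: int | None = None):
        loc = "" if path is None else f" [{path}" + ("" if line is None else f":{line}") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line
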