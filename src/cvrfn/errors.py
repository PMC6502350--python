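"""Exception hierarchy for the cvrfn analysis pipeline."""


class CvrfnError(Exception):
    """Base class for all package-specific errors."""


class ProtocolError(CvrfnError):
    """Raised when a scan protocol is internally inconsistent (e.g. the
    CO2 stimulus or task blocks do not fit into the run duration)."""


class ConfigurationError(CvrfnError):
    """Raised for invalid analysis or simulation settings (negative noise,
    filter cutoff above Nyquist, wrong region table, ...)."""


class DimensionError(CvrfnError):
    """Raised when volumes that must be voxel-aligned have different shapes."""


class CoverageError(CvrfnError):
    """Raised when a physiological trace does not span the imaging run
    (no extrapolation beyond one repetition time is permitted)."""


class CollinearityError(CvrfnError):
    """Raised when a GLM design matrix is rank deficient.

    The offending column names are available as ``.columns``.
    """

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; redundant columns: "
            + ", ".join(self.columns)
        )


class LabelingError(CvrfnError):
    """Raised when a label volume contains a region id with no name."""


class DegenerateRegressionError(CvrfnError):
    """Raised when a regression predictor has zero variance."""


class ZeroBaselineError(CvrfnError):
    """Raised when a voxel's baseline-window mean is zero or negative, so
    percent signal change is undefined."""
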