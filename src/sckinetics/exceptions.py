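"""Exception hierarchy shared across the analysis stages."""


class AnalysisError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(AnalysisError):
    """A CSV file or configuration does not match the declared schema."""


class DataError(AnalysisError):
    """Input rows are structurally invalid (duplicates, non-monotone grids)."""


class UndefinedPhaseError(AnalysisError):
    """Phase requested at a frequency where Z_Re = Z_Im = 0."""


class FrequencySelectionError(AnalysisError):
    """No grid frequency close enough (in log space) to the requested target."""


class DegenerateSeriesError(AnalysisError):
    """A response series carries no usable change (EIR_i = EIR_f, constant fit)."""


class FitError(AnalysisError):
    """A regression or nonlinear fit could not be performed."""


class PairingError(AnalysisError):
    """Two series collections cannot be paired on a common time grid."""
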