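"""Exception hierarchy for sparse-sampling design and simulation errors."""


class SparseFMRIError(Exception):
    """Base class for all package-specific errors."""


class InvalidResolutionError(SparseFMRIError):
    """Kernel or timeline temporal resolution is unusable (dt <= 0 or too coarse)."""


class DegenerateKernelError(SparseFMRIError):
    """HRF kernel has no peak to calibrate against."""


class IncompatibleDesignError(SparseFMRIError):
    """TR/ISI geometry cannot host a consistent stimulation pattern."""


class ScheduleFormatError(SparseFMRIError):
    """Events file is malformed (missing columns, bad values)."""


class OverlapError(SparseFMRIError):
    """Two same-condition events overlap on the stimulation timeline."""


class DegenerateRegressorError(SparseFMRIError):
    """Regressor is constant: the design is invisible to the sampling scheme."""


class DegenerateSignalError(SparseFMRIError):
    """Ideal signal is constant; tSNR scaling is undefined."""


class DegenerateNoiseError(SparseFMRIError):
    """Unit noise vector is identically zero."""


class CollinearityError(SparseFMRIError):
    """Design matrix is rank deficient or numerically so.

    ``columns`` lists the offending (near-)dependent column pairs when they
    can be identified.
    """

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class InsufficientSamplesError(SparseFMRIError):
    """Fewer observations than would leave at least one residual dof."""
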