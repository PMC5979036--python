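"""Exception hierarchy for the DSC-MRI pipeline.

Voxel-level failures (degenerate signal, absent bolus, undefined metric)
are distinct from input errors so that volume-level drivers can flag the
voxel invalid and continue instead of aborting the whole run.
"""


class DscError(Exception):
    """Base class for all package errors."""


class InputError(DscError):
    """Malformed or inconsistent user input (bad shapes, bad parameters)."""


class DegenerateVoxelError(DscError):
    """A voxel's signal cannot be converted (non-positive intensities)."""


class NoBolusError(DscError):
    """No bolus passage detectable in a voxel's time-series."""


class UndefinedMetricError(DscError):
    """A perfusion metric is undefined for the fitted parameters (e.g. k=0)."""


class UndefinedSummaryError(DscError):
    """A summary statistic has no valid voxels to aggregate over."""
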