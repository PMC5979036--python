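"""Conversion of raw DSC signal intensities to ΔR2* time-series.

During bolus passage a T2*-weighted signal transiently darkens; the change
in the transverse relaxation rate,

    ΔR2*(t) = -ln(SI_t / SI_0) / TE,

is proportional to the local gadolinium concentration and forms a positive
first-pass peak.  SI_0 is the mean signal over the pre-contrast baseline
window.  The sign is chosen so that the tissue-response curve is a positive
peak, the standard tracer-kinetic convention (an equivalent form without
the leading minus is sometimes printed with SI_t and SI_0 swapped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionParams
from .errors import DegenerateVoxelError, InputError

__all__ = [
    "DscSeries",
    "DeltaR2Series",
    "estimate_baseline",
    "signal_to_delta_r2",
]


@dataclass
class DscSeries:
    """Raw signal intensities of one voxel over all frames.

    ``intensities`` is in arbitrary scanner units; in-brain voxels must be
    strictly positive everywhere for the log-transform to be defined.
    """

    intensities: np.ndarray
    acq: AcquisitionParams

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1:
            raise InputError("intensities must be a 1-D array")
        if self.intensities.size != self.acq.n_frames:
            raise InputError(
                f"series has {self.intensities.size} frames, "
                f"acquisition declares {self.acq.n_frames}"
            )


@dataclass
class DeltaR2Series:
    """ΔR2* values (1/s) per frame, with the baseline intensity used."""

    values: np.ndarray
    si0: float
    acq: AcquisitionParams

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.acq.n_frames:
            raise InputError("values length must equal acq.n_frames")


def estimate_baseline(series: DscSeries) -> float:
    """Mean signal intensity over the first ``baseline_frames`` frames.

    Raises
    ------
    InputError
        If fewer than two baseline frames are configured.
    DegenerateVoxelError
        If any baseline-frame intensity is non-positive.
    """
    nb = series.acq.baseline_frames
    if nb < 2:
        raise InputError("need at least 2 baseline frames to estimate SI_0")
    window = series.intensities[:nb]
    if np.any(window <= 0):
        raise DegenerateVoxelError("non-positive signal in baseline window")
    return float(window.mean())


def signal_to_delta_r2(series: DscSeries) -> DeltaR2Series:
    """Convert a raw signal series to ΔR2* = -ln(SI_t/SI_0)/TE.

    Baseline frames map to approximately zero; the bolus passage appears
    as a positive peak.  Any non-positive intensity makes the voxel
    unconvertible and raises :class:`DegenerateVoxelError` (callers
    operating on volumes catch this and flag the voxel invalid).
    """
    si0 = estimate_baseline(series)
    if np.any(series.intensities <= 0):
        raise DegenerateVoxelError("non-positive signal intensity in series")
    values = -np.log(series.intensities / si0) / series.acq.te
    return DeltaR2Series(values=values, si0=si0, acq=series.acq)
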