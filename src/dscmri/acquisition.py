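"""Acquisition metadata for a DSC-MRI time-series.

A DSC acquisition is described by its echo time TE, repetition time TR
(one volume per TR), the total number of frames, the number of leading
frames averaged to form the pre-contrast baseline intensity SI_0, and the
frame at which the contrast bolus is injected.  The baseline window and
the bolus start are deliberately independent parameters: the signal may
be considered "baseline" acquisition-wise for longer than the window used
to estimate SI_0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError

__all__ = ["AcquisitionParams"]


@dataclass(frozen=True)
class AcquisitionParams:
    """Timing parameters of a DSC-MRI acquisition.

    Parameters
    ----------
    te : float
        Echo time in seconds (e.g. 0.005 for a 5 ms gradient-echo EPI).
    tr : float
        Repetition time in seconds; frame ``i`` is acquired at ``i * tr``.
    n_frames : int
        Number of volumes in the time-series.
    baseline_frames : int
        Number of initial frames averaged to estimate the pre-contrast
        signal intensity SI_0.
    bolus_start_frame : int
        0-based index of the first frame after the baseline period, i.e.
        the frame at which bolus injection begins.
    """

    te: float
    tr: float
    n_frames: int
    baseline_frames: int = 200
    bolus_start_frame: int = 240

    def __post_init__(self) -> None:
        if not (self.te > 0):
            raise InputError(f"te must be positive, got {self.te}")
        if not (self.tr > 0):
            raise InputError(f"tr must be positive, got {self.tr}")
        for name in ("n_frames", "baseline_frames", "bolus_start_frame"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise InputError(f"{name} must be a positive integer, got {v!r}")
        if not (self.baseline_frames < self.bolus_start_frame <= self.n_frames):
            raise InputError(
                "require baseline_frames < bolus_start_frame <= n_frames, got "
                f"{self.baseline_frames}, {self.bolus_start_frame}, {self.n_frames}"
            )

    @property
    def frame_times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame i at i*TR)."""
        return np.arange(self.n_frames, dtype=float) * self.tr
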