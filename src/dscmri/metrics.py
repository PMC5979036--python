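"""Per-voxel perfusion metrics and whole-volume map assembly.

Five quantities are derived for each voxel:

* rCBV — relative cerebral blood volume, the area under the *fitted*
  gamma-variate.  Using the fitted first-pass component rather than the
  raw curve removes the recirculation plateau, which would otherwise
  inflate the area (the reason the mixture model exists).
* MTT — mean transit time, approximated by the full width at half maximum
  of the fitted gamma-variate (seconds), proportional to the true MTT.
* rCBF — relative cerebral blood flow, the central-volume ratio rCBV/MTT.
* TTP — time to peak in frames: the argmax frame of the *raw* ΔR2* series
  minus the index of the last baseline frame.
* BAT — bolus-arrival frame: the first frame of the run, ending at the
  peak, where raw ΔR2* is at least 10% of the voxel maximum.

TTP and BAT deliberately use the raw series and frame indices; rCBV, MTT
and rCBF come from the fitted first-pass component.  All indices are
0-based.  Voxels whose conversion, fit or metric extraction fails are
flagged invalid and written as NaN in the output maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

from .acquisition import AcquisitionParams
from .bolus import (
    BolusMixtureFit,
    FitOptions,
    GammaVariateParams,
    _detect_peak,
    fit_bolus_mixture,
)
from .errors import (
    DegenerateVoxelError,
    DscError,
    InputError,
    NoBolusError,
    UndefinedMetricError,
)
from .signal import DeltaR2Series, DscSeries, signal_to_delta_r2

__all__ = [
    "PerfusionMetrics",
    "PerfusionMaps",
    "gamma_area",
    "gamma_fwhm",
    "time_to_peak",
    "bolus_arrival",
    "voxel_metrics",
    "quantify_volume",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("rcbv", "mtt", "rcbf", "ttp", "bat")


@dataclass
class PerfusionMetrics:
    """The five perfusion quantities of one voxel (NaN when invalid)."""

    rcbv: float
    mtt: float
    rcbf: float
    ttp: float
    bat_frame: float
    valid: bool

    @classmethod
    def invalid(cls) -> "PerfusionMetrics":
        nan = float("nan")
        return cls(rcbv=nan, mtt=nan, rcbf=nan, ttp=nan, bat_frame=nan, valid=False)


@dataclass
class PerfusionMaps:
    """Volumetric perfusion maps sharing the input grid.

    Each metric is a 3-D float array with NaN at voxels outside the
    validity mask; ``valid`` is the boolean mask of successfully fitted
    voxels.  ``counts`` records how many voxels were attempted, fitted,
    rejected as bolus-free, or otherwise failed.
    """

    rcbv: np.ndarray
    mtt: np.ndarray
    rcbf: np.ndarray
    ttp: np.ndarray
    bat: np.ndarray
    valid: np.ndarray
    acq: AcquisitionParams
    affine: Optional[np.ndarray] = None
    counts: dict = field(default_factory=dict)

    def metric_dict(self) -> dict[str, np.ndarray]:
        return {
            "rcbv": self.rcbv,
            "mtt": self.mtt,
            "rcbf": self.rcbf,
            "ttp": self.ttp,
            "bat": self.bat,
        }


def gamma_area(p: GammaVariateParams) -> float:
    """Area under the gamma-variate over [t0, inf), the rCBV surrogate.

    Closed form: k * beta^(alpha+1) * Gamma(alpha+1), evaluated in log
    space for numerical range.
    """
    if p.k == 0:
        return 0.0
    log_area = np.log(p.k) + (p.alpha + 1.0) * np.log(p.beta) + gammaln(p.alpha + 1.0)
    with np.errstate(over="ignore"):
        return float(np.exp(log_area))


def _gamma_shape(x: np.ndarray | float, alpha: float) -> np.ndarray | float:
    """Normalized gamma-variate shape x^alpha e^-x (peak at x=alpha)."""
    return np.where(x > 0, np.exp(alpha * np.log(np.maximum(x, 1e-300)) - x), 0.0)


def gamma_fwhm(p: GammaVariateParams) -> float:
    """Full width at half maximum of the gamma-variate, the MTT surrogate.

    Independent of k and t0; scales linearly with beta.  Roots of
    g(t) = peak/2 are bracketed on either side of the peak and solved
    with Brent's method.

    Raises UndefinedMetricError when k = 0 (no first-pass response).
    """
    if p.k == 0:
        raise UndefinedMetricError("FWHM undefined for a null response (k=0)")
    a = p.alpha
    # work in u = ln x with x = (t - t0)/beta: the normalized log-shape
    # h(u) = a*u - e^u peaks at u = ln a; solve h(u) = h(ln a) - ln 2 on
    # both sides (log-space keeps the left crossing solvable for tiny a)
    log_half = a * np.log(a) - a - np.log(2.0)

    def h(u: float) -> float:
        with np.errstate(over="ignore"):
            return a * u - np.exp(u) - log_half

    u_peak = np.log(a)
    lo = u_peak - max(2.0, 2.0 / np.sqrt(a))
    while h(lo) > 0:
        lo = u_peak - 2.0 * (u_peak - lo)
        if u_peak - lo > 1e6:  # pragma: no cover - unreachable for a > 0
            raise UndefinedMetricError("left half-maximum crossing not found")
    u_left = brentq(h, lo, u_peak)
    hi = u_peak + max(1.0, 1.0 / np.sqrt(a))
    while h(hi) > 0:
        hi = u_peak + 2.0 * (hi - u_peak)
        if hi - u_peak > 1e6:  # pragma: no cover - unreachable for finite a
            raise UndefinedMetricError("right half-maximum crossing not found")
    u_right = brentq(h, u_peak, hi)
    return float((np.exp(u_right) - np.exp(u_left)) * p.beta)


def time_to_peak(dr2: DeltaR2Series, noise_floor: float = 0.0) -> int:
    """TTP in frames: argmax frame minus the last baseline frame index.

    Computed on the raw ΔR2* series.  Raises NoBolusError when the
    maximum is non-positive or falls inside the baseline window.
    """
    i_max = _detect_peak(dr2, noise_floor)
    return int(i_max - (dr2.acq.bolus_start_frame - 1))


def bolus_arrival(dr2: DeltaR2Series, fraction: float = 0.1,
                  noise_floor: float = 0.0) -> int:
    """First tissue-response frame: start of the contiguous run, ending at
    the peak, where ΔR2* >= ``fraction`` of the voxel maximum (inclusive).

    Anchoring the threshold search at the peak and walking backwards makes
    the estimate robust to isolated baseline noise excursions above the
    threshold, while agreeing with a forward scan on clean data.
    """
    v = dr2.values
    i_max = _detect_peak(dr2, noise_floor)
    thr = fraction * v[i_max]
    a = i_max
    while a > 0 and v[a - 1] >= thr:
        a -= 1
    return int(a)


def voxel_metrics(fit: BolusMixtureFit, dr2: DeltaR2Series) -> PerfusionMetrics:
    """Assemble the five metrics for one voxel from its fit and raw series.

    Any component error (undefined FWHM, absent bolus) yields an invalid
    result rather than an exception.
    """
    if not fit.valid:
        return PerfusionMetrics.invalid()
    try:
        rcbv = gamma_area(fit.gamma)
        mtt = gamma_fwhm(fit.gamma)
        rcbf = rcbv / mtt
        ttp = time_to_peak(dr2)
        bat = bolus_arrival(dr2)
    except (DscError, ValueError, ArithmeticError):
        return PerfusionMetrics.invalid()
    if not (rcbv > 0 and mtt > 0 and np.isfinite(rcbv) and np.isfinite(mtt)):
        return PerfusionMetrics.invalid()
    return PerfusionMetrics(
        rcbv=rcbv, mtt=mtt, rcbf=rcbf, ttp=float(ttp), bat_frame=float(bat), valid=True
    )


def quantify_volume(
    data: np.ndarray,
    mask: np.ndarray,
    acq: AcquisitionParams,
    options: FitOptions | None = None,
    affine: Optional[np.ndarray] = None,
    diagnostics_path: Optional[str] = None,
) -> PerfusionMaps:
    """Run conversion → mixture fit → metrics for every in-mask voxel.

    Parameters
    ----------
    data : ndarray, shape (X, Y, Z, T)
        Raw 4-D signal volume, frame axis last.
    mask : ndarray, shape (X, Y, Z)
        Boolean (or 0/1) brain mask on the same grid.
    acq : AcquisitionParams
    options : FitOptions, optional
    affine : ndarray, optional
        Voxel-to-world affine carried through to the output maps.
    diagnostics_path : str, optional
        When given, per-voxel fit diagnostics (parameters, rss,
        convergence, outcome) are written there as CSV for QC.

    Voxels that fail conversion, bolus detection or fitting are flagged
    invalid (NaN in every map) without aborting the run; per-category
    counts are logged and returned in ``maps.counts``.
    """
    data = np.asarray(data)
    mask = np.asarray(mask).astype(bool)
    if data.ndim != 4:
        raise InputError(f"expected 4-D data, got shape {data.shape}")
    if mask.shape != data.shape[:3]:
        raise InputError(
            f"mask shape {mask.shape} does not match data grid {data.shape[:3]}"
        )
    if data.shape[3] != acq.n_frames:
        raise InputError(
            f"data has {data.shape[3]} frames, acquisition declares {acq.n_frames}"
        )
    opts = options or FitOptions()

    shape = data.shape[:3]
    maps = {m: np.full(shape, np.nan) for m in METRIC_NAMES}
    valid = np.zeros(shape, dtype=bool)
    counts = {"masked": 0, "fitted": 0, "no_bolus": 0, "degenerate": 0, "failed": 0}
    diag_rows = [] if diagnostics_path is not None else None

    def record(ix, iy, iz, outcome, fit=None):
        if diag_rows is None:
            return
        row = {"x": ix, "y": iy, "z": iz, "outcome": outcome}
        if fit is not None:
            row.update(
                t0=fit.gamma.t0, k=fit.gamma.k, alpha=fit.gamma.alpha,
                beta=fit.gamma.beta, s=fit.sigmoid.s, tc=fit.sigmoid.tc,
                r=fit.sigmoid.r, rss=fit.rss, converged=fit.converged,
                n_iter=fit.n_iter,
            )
        diag_rows.append(row)

    for idx in np.argwhere(mask):
        ix, iy, iz = (int(i) for i in idx)
        counts["masked"] += 1
        try:
            series = DscSeries(intensities=data[ix, iy, iz, :], acq=acq)
            dr2 = signal_to_delta_r2(series)
            fit = fit_bolus_mixture(dr2, opts)
        except DegenerateVoxelError:
            counts["degenerate"] += 1
            record(ix, iy, iz, "degenerate")
            continue
        except NoBolusError:
            counts["no_bolus"] += 1
            record(ix, iy, iz, "no_bolus")
            continue
        m = voxel_metrics(fit, dr2)
        record(ix, iy, iz, "fitted" if m.valid else "failed", fit)
        if not m.valid:
            counts["failed"] += 1
            continue
        counts["fitted"] += 1
        valid[ix, iy, iz] = True
        maps["rcbv"][ix, iy, iz] = m.rcbv
        maps["mtt"][ix, iy, iz] = m.mtt
        maps["rcbf"][ix, iy, iz] = m.rcbf
        maps["ttp"][ix, iy, iz] = m.ttp
        maps["bat"][ix, iy, iz] = m.bat_frame

    logger.info(
        "quantify_volume: %(masked)d in-mask voxels, %(fitted)d fitted, "
        "%(no_bolus)d without bolus, %(degenerate)d degenerate, %(failed)d failed",
        counts,
    )
    if diag_rows is not None:
        import pandas as pd

        pd.DataFrame(diag_rows).to_csv(diagnostics_path, index=False)
    return PerfusionMaps(
        rcbv=maps["rcbv"],
        mtt=maps["mtt"],
        rcbf=maps["rcbf"],
        ttp=maps["ttp"],
        bat=maps["bat"],
        valid=valid,
        acq=acq,
        affine=affine,
        counts=counts,
    )
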