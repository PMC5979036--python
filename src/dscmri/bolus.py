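"""Recirculation-aware gamma-variate mixture fitting of ΔR2* curves.

The first pass of the contrast bolus through a voxel's vasculature is
modelled by the classical gamma-variate curve

    g(t) = k * (t - t0)^alpha * exp(-(t - t0)/beta)   for t > t0, else 0,

unimodal with its peak at t = t0 + alpha*beta.  In small animals the agent
recirculates quickly, so later passes are not resolved as separate peaks
but accumulate as a monotone plateau underneath the tissue response; this
recirculation is modelled by a logistic sigmoid

    h(t) = s / (1 + exp(-r * (t - tc))).

The measured ΔR2* is fitted voxel-wise as the sum g + h by damped
(Levenberg–Marquardt) nonlinear least squares.  Positivity of k, alpha,
beta, s and r is enforced by optimising their logarithms, which keeps the
problem unconstrained, and the optimiser tolerates rough starting values;
a data-driven initial guess is derived from the peak height, peak time and
peak width of the raw curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .errors import InputError, NoBolusError
from .signal import DeltaR2Series

__all__ = [
    "GammaVariateParams",
    "SigmoidParams",
    "BolusMixtureFit",
    "FitOptions",
    "eval_gamma_variate",
    "eval_sigmoid",
    "eval_mixture",
    "initial_guess",
    "fit_bolus_mixture",
]

# Absolute caps keeping exp()/log() of transformed parameters finite.
_LOG_CAP = 300.0


@dataclass(frozen=True)
class GammaVariateParams:
    """First-pass tissue-response parameters.

    t0 : bolus-arrival time (s); the curve is identically 0 for t <= t0.
    k : amplitude scale (s^-1 per unit of the power term), k >= 0.
    alpha : dimensionless shape, > 0.
    beta : time scale (s), > 0.
    """

    t0: float
    k: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.k < 0 or self.alpha <= 0 or self.beta <= 0 or self.t0 < 0:
            raise InputError(f"invalid gamma-variate parameters: {self}")

    @property
    def peak_time(self) -> float:
        """Location of the maximum, t0 + alpha*beta."""
        return self.t0 + self.alpha * self.beta

    @property
    def peak_value(self) -> float:
        """Height of the maximum, k*(alpha*beta)^alpha*e^-alpha."""
        if self.k == 0:
            return 0.0
        ab = self.alpha * self.beta
        return float(np.exp(np.log(self.k) + self.alpha * (np.log(ab) - 1.0)))


@dataclass(frozen=True)
class SigmoidParams:
    """Logistic recirculation plateau: s / (1 + exp(-r (t - tc))).

    s : plateau amplitude (s^-1), >= 0; tc : centre time (s);
    r : rate (s^-1), > 0.
    """

    s: float
    tc: float
    r: float

    def __post_init__(self) -> None:
        if self.s < 0 or self.r <= 0:
            raise InputError(f"invalid sigmoid parameters: {self}")


@dataclass
class BolusMixtureFit:
    """Result of a voxel-wise mixture fit with convergence diagnostics."""

    gamma: GammaVariateParams
    sigmoid: SigmoidParams
    rss: float
    converged: bool
    n_iter: int
    valid: bool


@dataclass(frozen=True)
class FitOptions:
    """Tunable options for the mixture fit.

    max_iter bounds Levenberg–Marquardt iterations (function-evaluation
    budget is max_iter*(n_params+1) to account for finite-difference
    Jacobians); ftol is the relative decrease of the residual sum of
    squares at which the fit is declared converged; noise_floor is the
    multiple of the baseline ΔR2* standard deviation the post-baseline
    peak must exceed for a bolus to be considered present; fit_from_frame
    optionally restricts the fitted window (default: all frames, so the
    baseline anchors the zero level); n_restarts > 0 adds seeded
    perturbed restarts keeping the best fit.
    """

    max_iter: int = 200
    ftol: float = 1e-6
    xtol: float = 1e-8
    noise_floor: float = 3.0
    fit_from_frame: Optional[int] = None
    n_restarts: int = 0
    restart_seed: int = 0
    bat_fraction: float = 0.1


def eval_gamma_variate(p: GammaVariateParams, t) -> np.ndarray:
    """Evaluate the gamma-variate curve at times ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    dt = t - p.t0
    out = np.zeros_like(dt)
    if p.k == 0:
        return out
    pos = dt > 0
    dtp = dt[pos]
    out[pos] = np.exp(
        np.log(p.k) + p.alpha * np.log(dtp) - dtp / p.beta
    )
    return out


def eval_sigmoid(p: SigmoidParams, t) -> np.ndarray:
    """Evaluate the logistic recirculation term at times ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):
        z = np.clip(-p.r * (t - p.tc), -500.0, 500.0)
    return p.s / (1.0 + np.exp(z))


def eval_mixture(gamma: GammaVariateParams, sigmoid: SigmoidParams, t) -> np.ndarray:
    """Sum of tissue response and recirculation at times ``t``."""
    return eval_gamma_variate(gamma, t) + eval_sigmoid(sigmoid, t)


def _detect_peak(dr2: DeltaR2Series, noise_floor: float) -> int:
    """Return the global argmax frame, raising NoBolusError when the
    series has no detectable post-baseline bolus."""
    v = dr2.values
    acq = dr2.acq
    i_max = int(np.argmax(v))
    vmax = v[i_max]
    if vmax <= 0:
        raise NoBolusError("series maximum is non-positive")
    if i_max < acq.bolus_start_frame:
        raise NoBolusError("series maximum falls inside the baseline window")
    base_sd = float(np.std(v[: acq.baseline_frames]))
    if base_sd > 0 and vmax <= noise_floor * base_sd:
        raise NoBolusError(
            f"peak {vmax:.3g} below noise floor {noise_floor} x {base_sd:.3g}"
        )
    return i_max


def initial_guess(
    dr2: DeltaR2Series, noise_floor: float = 3.0
) -> tuple[GammaVariateParams, SigmoidParams]:
    """Data-driven starting values for the mixture fit.

    The bolus-arrival guess is the first frame of the contiguous run
    (ending at the peak) where ΔR2* is at least 10% of the peak; alpha and
    beta follow from the peak delay and the half-maximum width via the
    Gaussian approximation FWHM ≈ 2.355 sqrt(alpha) beta of the
    gamma-variate; the sigmoid plateau starts from the late-frame mean.

    Raises NoBolusError for flat, negative or baseline-peaked series.
    """
    v = dr2.values
    acq = dr2.acq
    i_max = _detect_peak(dr2, noise_floor)
    h = float(v[i_max])
    tp = i_max * acq.tr

    # walk back from the peak to the start of the >=10% run
    thr = 0.1 * h
    a = i_max
    while a > 0 and v[a - 1] >= thr:
        a -= 1
    t0 = a * acq.tr
    d = max(tp - t0, acq.tr)

    # contiguous half-maximum width around the peak
    half = 0.5 * h
    lo = i_max
    while lo > 0 and v[lo - 1] >= half:
        lo -= 1
    hi = i_max
    while hi < v.size - 1 and v[hi + 1] >= half:
        hi += 1
    w = max((hi - lo + 1) * acq.tr, acq.tr)

    alpha = float(np.clip((2.355 * d / w) ** 2, 1.05, 100.0))
    beta = d / alpha
    log_k = float(np.clip(np.log(h) - alpha * (np.log(d) - 1.0), -_LOG_CAP, _LOG_CAP))
    gamma = GammaVariateParams(t0=t0, k=float(np.exp(log_k)), alpha=alpha, beta=beta)

    n_tail = max(int(0.1 * v.size), 1)
    tail_mean = float(np.mean(v[-n_tail:]))
    s = max(tail_mean, 1e-3 * h)
    sigmoid = SigmoidParams(s=s, tc=tp + w, r=4.0 / w)
    return gamma, sigmoid


def _safe_log(x: float) -> float:
    return float(np.clip(np.log(max(x, np.exp(-_LOG_CAP))), -_LOG_CAP, _LOG_CAP))


def _pack(g: GammaVariateParams, s: SigmoidParams) -> np.ndarray:
    """Transform to the unconstrained fit vector.

    Positive parameters are carried as logarithms; the sigmoid centre is
    carried as log(tc - peak_time), constraining the recirculation
    plateau to centre after the first-pass peak (recirculated agent
    cannot precede the first pass), which removes the degenerate optima
    where the sigmoid absorbs the bolus rise itself.
    """
    dtc = s.tc - g.peak_time
    return np.array(
        [g.t0, _safe_log(g.k), _safe_log(g.alpha), _safe_log(g.beta),
         _safe_log(s.s), _safe_log(max(dtc, 1e-6)), _safe_log(s.r)]
    )


def _unpack(theta: np.ndarray) -> tuple[GammaVariateParams, SigmoidParams]:
    e = np.exp(np.clip(theta[[1, 2, 3, 4, 5, 6]], -_LOG_CAP, _LOG_CAP))
    gamma = GammaVariateParams(
        t0=max(float(theta[0]), 0.0), k=float(e[0]), alpha=float(e[1]), beta=float(e[2])
    )
    tc = gamma.peak_time + float(e[3 + 1])
    sigmoid = SigmoidParams(s=float(e[3]), tc=tc, r=float(e[5]))
    return gamma, sigmoid


def _model(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    t0, lk, la, lb, ls, ldtc, lr = theta
    alpha = np.exp(np.clip(la, -_LOG_CAP, _LOG_CAP))
    beta = np.exp(np.clip(lb, -_LOG_CAP, _LOG_CAP))
    dt = t - t0
    out = np.zeros_like(t)
    pos = dt > 0
    if pos.any():
        dtp = dt[pos]
        expo = np.clip(lk + alpha * np.log(dtp) - dtp / beta, -_LOG_CAP, _LOG_CAP)
        out[pos] = np.exp(expo)
    tc = t0 + alpha * beta + np.exp(np.clip(ldtc, -_LOG_CAP, _LOG_CAP))
    r = np.exp(np.clip(lr, -_LOG_CAP, _LOG_CAP))
    with np.errstate(over="ignore"):
        z = np.clip(-r * (t - tc), -500.0, 500.0)
    s = np.exp(np.clip(ls, -_LOG_CAP, _LOG_CAP))
    out += s / (1.0 + np.exp(z))
    return out


def _jacobian(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the model w.r.t. the transformed parameters.

    Chain rule through the log transforms (d/d log p = p d/dp) and the
    sigmoid-centre reparameterization tc = t0 + alpha*beta + dtc.
    """
    t0, lk, la, lb, ls, ldtc, lr = theta
    alpha = np.exp(np.clip(la, -_LOG_CAP, _LOG_CAP))
    beta = np.exp(np.clip(lb, -_LOG_CAP, _LOG_CAP))
    dtc = np.exp(np.clip(ldtc, -_LOG_CAP, _LOG_CAP))
    r = np.exp(np.clip(lr, -_LOG_CAP, _LOG_CAP))
    s = np.exp(np.clip(ls, -_LOG_CAP, _LOG_CAP))

    n = t.size
    J = np.zeros((n, 7))

    dt = t - t0
    pos = dt > 0
    dtp = dt[pos]
    G = np.zeros(n)
    if pos.any():
        expo = np.clip(lk + alpha * np.log(dtp) - dtp / beta, -_LOG_CAP, _LOG_CAP)
        G[pos] = np.exp(expo)
    Gp = G[pos]

    tc = t0 + alpha * beta + dtc
    with np.errstate(over="ignore"):
        y = np.clip(r * (t - tc), -500.0, 500.0)
    sig = 1.0 / (1.0 + np.exp(-y))
    dS = s * sig * (1.0 - sig)  # dS/dy

    # gamma-variate columns
    J[pos, 0] = Gp * (1.0 / beta - alpha / dtp)
    J[:, 1] = G
    J[pos, 2] = Gp * alpha * np.log(dtp)
    J[pos, 3] = Gp * dtp / beta
    # sigmoid columns (tc depends on t0, alpha, beta, dtc)
    J[:, 0] += -r * dS
    J[:, 2] += -r * dS * alpha * beta
    J[:, 3] += -r * dS * alpha * beta
    J[:, 4] = s * sig
    J[:, 5] = -r * dS * dtc
    J[:, 6] = dS * y
    return J


def _gamma_model(th: np.ndarray, t: np.ndarray) -> np.ndarray:
    t0, lk, la, lb = th
    alpha = np.exp(np.clip(la, -_LOG_CAP, _LOG_CAP))
    beta = np.exp(np.clip(lb, -_LOG_CAP, _LOG_CAP))
    dt = t - t0
    out = np.zeros_like(t)
    pos = dt > 0
    if pos.any():
        dtp = dt[pos]
        expo = np.clip(lk + alpha * np.log(dtp) - dtp / beta, -_LOG_CAP, _LOG_CAP)
        out[pos] = np.exp(expo)
    return out


def _gamma_jac(th: np.ndarray, t: np.ndarray) -> np.ndarray:
    t0, lk, la, lb = th
    alpha = np.exp(np.clip(la, -_LOG_CAP, _LOG_CAP))
    beta = np.exp(np.clip(lb, -_LOG_CAP, _LOG_CAP))
    dt = t - t0
    pos = dt > 0
    dtp = dt[pos]
    G = np.zeros(t.size)
    if pos.any():
        expo = np.clip(lk + alpha * np.log(dtp) - dtp / beta, -_LOG_CAP, _LOG_CAP)
        G[pos] = np.exp(expo)
    J = np.zeros((t.size, 4))
    J[pos, 0] = G[pos] * (1.0 / beta - alpha / dtp)
    J[:, 1] = G
    J[pos, 2] = G[pos] * alpha * np.log(dtp)
    J[pos, 3] = G[pos] * dtp / beta
    return J


def _first_pass_refine(
    g0: GammaVariateParams, dr2: DeltaR2Series, opts: FitOptions
) -> GammaVariateParams:
    """Stage-one gamma-only fit restricted to the first-pass window.

    The window runs from the start of the series through the peak plus one
    half-maximum width, where recirculation is still negligible; fitting
    the four gamma parameters there first gives the joint seven-parameter
    fit a starting point free of the tail/plateau trade-off that traps a
    single-stage fit in local minima.
    """
    v = dr2.values
    acq = dr2.acq
    i_max = int(np.argmax(v))
    w_frames = max(int(round((2.355 * np.sqrt(g0.alpha) * g0.beta) / acq.tr)), 1)
    cut = min(i_max + w_frames, v.size)
    t = acq.frame_times[:cut]
    y = v[:cut]
    th0 = np.array([g0.t0, _safe_log(g0.k), _safe_log(g0.alpha), _safe_log(g0.beta)])
    try:
        res = least_squares(
            lambda th: _gamma_model(th, t) - y,
            th0,
            jac=lambda th: _gamma_jac(th, t),
            method="lm",
            ftol=opts.ftol,
            xtol=opts.xtol,
            max_nfev=opts.max_iter,
        )
    except Exception:
        return g0
    if not np.all(np.isfinite(res.x)):
        return g0
    e = np.exp(np.clip(res.x[1:], -_LOG_CAP, _LOG_CAP))
    try:
        return GammaVariateParams(
            t0=max(float(res.x[0]), 0.0), k=float(e[0]),
            alpha=float(e[1]), beta=float(e[2]),
        )
    except InputError:
        return g0


def fit_bolus_mixture(
    dr2: DeltaR2Series, options: FitOptions | None = None
) -> BolusMixtureFit:
    """Fit the gamma-variate + sigmoid mixture to one voxel's ΔR2* series.

    All seven parameters are fitted jointly; the mixing weights of the
    "linear mixture" are absorbed into the amplitudes k and s.  Fitting
    uses every frame by default so that the baseline frames anchor the
    zero level of the model.

    Returns a :class:`BolusMixtureFit`; optimizer failures are caught and
    reported as ``valid=False`` with the best iterate's parameters.
    NoBolusError from the initial guess propagates to the caller.
    """
    opts = options or FitOptions()
    g0, s0 = initial_guess(dr2, noise_floor=opts.noise_floor)
    g0 = _first_pass_refine(g0, dr2, opts)
    if s0.tc <= g0.peak_time:  # keep the packed dtc positive and sensible
        s0 = SigmoidParams(s=s0.s, tc=g0.peak_time + 4.0 / s0.r, r=s0.r)
    t = dr2.acq.frame_times
    y = dr2.values
    if opts.fit_from_frame is not None:
        t = t[opts.fit_from_frame:]
        y = y[opts.fit_from_frame:]

    def resid(theta: np.ndarray) -> np.ndarray:
        return _model(theta, t) - y

    theta0 = _pack(g0, s0)
    starts = [theta0]
    if opts.n_restarts > 0:
        rng = np.random.default_rng(opts.restart_seed)
        for _ in range(opts.n_restarts):
            starts.append(theta0 + rng.normal(0.0, 0.2, size=theta0.size))

    best = None
    for start in starts:
        try:
            res = least_squares(
                resid,
                start,
                jac=lambda th: _jacobian(th, t),
                method="lm",
                ftol=opts.ftol,
                xtol=opts.xtol,
                max_nfev=opts.max_iter * 2,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None:
        rss0 = float(np.sum(resid(theta0) ** 2))
        return BolusMixtureFit(
            gamma=g0, sigmoid=s0, rss=rss0, converged=False, n_iter=0, valid=False
        )

    gamma, sigmoid = _unpack(best.x)
    rss = float(2.0 * best.cost)
    converged = bool(best.status > 0)
    valid = converged and np.all(np.isfinite(best.x))
    return BolusMixtureFit(
        gamma=gamma,
        sigmoid=sigmoid,
        rss=rss,
        converged=converged,
        n_iter=int(best.nfev),
        valid=bool(valid),
    )
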