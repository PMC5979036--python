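"""Digital 4-D DSC-MRI phantoms with analytic ground truth.

The generator emulates a rodent gradient-echo EPI bolus-tracking
acquisition: TE = 5 ms, TR = 1 s, a 50x50 in-plane matrix with 16 slices,
850 volumes of which the first 240 precede the injection, the bolus being
delivered over roughly 8 volumes.  The brain is an ellipsoid containing
two tissue classes — an outer "cortex" shell and an inner "striatum" core
— each with its own gamma-variate first-pass response, logistic
recirculation plateau and baseline signal level; class arrival times are
staggered by a few frames to mimic the finite injection interval and give
the bolus-arrival map spatial structure.  Out-of-brain voxels carry
baseline-only signal so that masking and bolus-detection logic is
exercised.

The forward model inverts the ΔR2* equation: SI(t) = SI_0 exp(-TE ΔR2*(t)),
with optional additive Gaussian (or Rician) noise on the *signal*, so that
the log-transform's noise propagation is exercised as in magnitude MRI.
Ground-truth metric maps are computed analytically from the class
parameters and are noise-free by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .acquisition import AcquisitionParams
from .bolus import GammaVariateParams, SigmoidParams, eval_mixture
from .errors import InputError
from .metrics import METRIC_NAMES, bolus_arrival, gamma_area, gamma_fwhm, time_to_peak
from .signal import DeltaR2Series

__all__ = [
    "TissueClass",
    "PhantomSpec",
    "PhantomOutput",
    "default_spec",
    "forward_signal",
    "generate_phantom",
    "generate_group_study",
]

# Largest TE*ΔR2* the forward model accepts: keeps SI >= 1% of SI_0 so the
# signal never underflows into the noise floor or below zero.
_MAX_ATTENUATION = float(np.log(100.0))


@dataclass(frozen=True)
class TissueClass:
    """One homogeneous tissue compartment of the phantom."""

    name: str
    gamma: GammaVariateParams
    sigmoid: SigmoidParams
    si0: float

    def __post_init__(self) -> None:
        if self.si0 <= 0:
            raise InputError(f"si0 must be positive for class {self.name!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic ground-truth acquisition.

    noise_sd_frac is the additive signal noise standard deviation as a
    fraction of each class's baseline level SI_0 (default 1%);
    noise_model is "gaussian" or "rician".
    """

    shape: tuple[int, int, int] = (50, 50, 16)
    acq: AcquisitionParams = field(
        default_factory=lambda: AcquisitionParams(
            te=0.005, tr=1.0, n_frames=850,
            baseline_frames=200, bolus_start_frame=240,
        )
    )
    classes: tuple[TissueClass, ...] = ()
    background_si0: float = 300.0
    noise_sd_frac: float = 0.01
    noise_model: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.shape) or len(self.shape) != 3:
            raise InputError(f"invalid phantom shape {self.shape}")
        if self.noise_sd_frac < 0:
            raise InputError("noise sd must be non-negative")
        if self.noise_model not in ("gaussian", "rician"):
            raise InputError(f"unknown noise model {self.noise_model!r}")
        if self.background_si0 <= 0:
            raise InputError("background si0 must be positive")


@dataclass
class PhantomOutput:
    """A generated phantom: 4-D signal, class labels, analytic truth maps.

    ``labels`` is 0 for background (out-of-brain) voxels and 1..n for the
    tissue classes in spec order.  ``truth`` maps are piecewise-constant
    functions of the class parameters only, NaN outside the brain.
    """

    signal: np.ndarray
    labels: np.ndarray
    truth: dict[str, np.ndarray]
    spec: PhantomSpec

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


def _default_classes(acq: AcquisitionParams) -> tuple[TissueClass, ...]:
    """Two-class brain emulating cortex and striatum.

    First-pass peaks of ~20 and ~14 s^-1 (TE*peak ~ 0.1, a realistic
    T2* dip of ~10%), arrival staggered 4 frames across classes within the
    ~8-frame injection interval, recirculation plateaus of ~15% of peak.
    """
    t_bolus = acq.bolus_start_frame * acq.tr

    def k_for_peak(peak: float, alpha: float, beta: float) -> float:
        ab = alpha * beta
        return float(peak * np.exp(-alpha * (np.log(ab) - 1.0)))

    cortex = TissueClass(
        name="cortex",
        gamma=GammaVariateParams(
            t0=t_bolus + 2.0 * acq.tr, k=k_for_peak(20.0, 3.0, 8.0),
            alpha=3.0, beta=8.0,
        ),
        sigmoid=SigmoidParams(s=3.0, tc=t_bolus + 52.0 * acq.tr, r=0.30),
        si0=800.0,
    )
    striatum = TissueClass(
        name="striatum",
        gamma=GammaVariateParams(
            t0=t_bolus + 6.0 * acq.tr, k=k_for_peak(14.0, 2.5, 7.0),
            alpha=2.5, beta=7.0,
        ),
        sigmoid=SigmoidParams(s=2.2, tc=t_bolus + 50.0 * acq.tr, r=0.30),
        si0=900.0,
    )
    return (cortex, striatum)


def default_spec(
    shape: tuple[int, int, int] = (50, 50, 16),
    noise_sd_frac: float = 0.01,
    seed: int = 0,
    acq: Optional[AcquisitionParams] = None,
) -> PhantomSpec:
    """The standard two-class phantom at the emulated acquisition."""
    acq = acq or AcquisitionParams(
        te=0.005, tr=1.0, n_frames=850, baseline_frames=200, bolus_start_frame=240
    )
    return PhantomSpec(
        shape=tuple(shape),
        acq=acq,
        classes=_default_classes(acq),
        noise_sd_frac=noise_sd_frac,
        seed=seed,
    )


def _label_volume(shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoidal brain (label 1) with a central deep-gray column
    (label 2): the column uses only the in-plane radius so that both
    classes survive on thin test grids with few slices."""
    grids = np.meshgrid(*(np.arange(d, dtype=float) for d in shape), indexing="ij")
    norm = []
    for g, d in zip(grids, shape):
        c = (d - 1) / 2.0
        semi = max(0.92 * (d / 2.0), 0.5)
        norm.append(((g - c) / semi) ** 2)
    rho2 = norm[0] + norm[1] + norm[2]
    rho2_xy = norm[0] + norm[1]
    labels = np.zeros(shape, dtype=np.int16)
    labels[rho2 <= 1.0] = 1
    labels[(rho2 <= 1.0) & (rho2_xy <= 0.25)] = 2
    return labels


def true_delta_r2(cls: TissueClass, acq: AcquisitionParams) -> np.ndarray:
    """Noise-free ΔR2* curve of a tissue class on the frame grid."""
    return eval_mixture(cls.gamma, cls.sigmoid, acq.frame_times)


def forward_signal(
    cls: TissueClass,
    acq: AcquisitionParams,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    noise_model: str = "gaussian",
    size: Optional[int] = None,
) -> np.ndarray:
    """Simulate the per-frame signal of a tissue class.

    SI(t) = SI_0 exp(-TE ΔR2*(t)) plus additive noise on the signal.
    With ``size`` given, returns ``(size, n_frames)`` independent noisy
    realisations sharing the same noise-free curve.

    Raises InputError when the response is so large that the signal would
    drop below 1% of SI_0.
    """
    curve = true_delta_r2(cls, acq)
    atten = acq.te * curve
    if atten.max() > _MAX_ATTENUATION:
        raise InputError(
            f"class {cls.name!r}: peak ΔR2* attenuates signal below 1% of SI_0"
        )
    clean = cls.si0 * np.exp(-atten)
    if noise_sd == 0:
        return clean if size is None else np.tile(clean, (size, 1))
    if rng is None:
        raise InputError("rng is required when noise_sd > 0")
    shape = (acq.n_frames,) if size is None else (size, acq.n_frames)
    if noise_model == "gaussian":
        return clean + rng.normal(0.0, noise_sd, size=shape)
    if noise_model == "rician":
        n1 = rng.normal(0.0, noise_sd, size=shape)
        n2 = rng.normal(0.0, noise_sd, size=shape)
        return np.sqrt((clean + n1) ** 2 + n2**2)
    raise InputError(f"unknown noise model {noise_model!r}")


def _truth_maps(spec: PhantomSpec, labels: np.ndarray) -> dict[str, np.ndarray]:
    """Analytic per-class metric values broadcast over the label volume.

    rCBV/MTT/rCBF come from the closed-form area and FWHM of the class
    gamma-variate; TTP and BAT apply the frame-index definitions to the
    noise-free class curve on the acquisition's frame grid, matching the
    raw-series definitions used by the pipeline.
    """
    truth = {m: np.full(spec.shape, np.nan) for m in METRIC_NAMES}
    for lab, cls in enumerate(spec.classes, start=1):
        sel = labels == lab
        if not sel.any():
            continue
        rcbv = gamma_area(cls.gamma)
        mtt = gamma_fwhm(cls.gamma)
        dr2 = DeltaR2Series(
            values=true_delta_r2(cls, spec.acq), si0=cls.si0, acq=spec.acq
        )
        truth["rcbv"][sel] = rcbv
        truth["mtt"][sel] = mtt
        truth["rcbf"][sel] = rcbv / mtt
        truth["ttp"][sel] = time_to_peak(dr2)
        truth["bat"][sel] = bolus_arrival(dr2)
    return truth


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Generate the 4-D signal volume, label map and analytic truth maps.

    All randomness derives from ``spec.seed``; two calls with identical
    specs produce bit-identical output.
    """
    if not spec.classes:
        spec = replace(spec, classes=_default_classes(spec.acq))
    labels = _label_volume(spec.shape)
    n_labels = int(labels.max())
    if n_labels > len(spec.classes):
        # inner core collapses onto the single class if only one is given
        labels[labels > len(spec.classes)] = len(spec.classes)

    rng = np.random.default_rng(spec.seed)
    nt = spec.acq.n_frames
    signal = np.empty(spec.shape + (nt,), dtype=np.float64)

    bg_sd = spec.noise_sd_frac * spec.background_si0
    sel = labels == 0
    n_vox = int(sel.sum())
    bg = np.full((n_vox, nt), spec.background_si0)
    if bg_sd > 0:
        if spec.noise_model == "gaussian":
            bg += rng.normal(0.0, bg_sd, size=bg.shape)
        else:
            n1 = rng.normal(0.0, bg_sd, size=bg.shape)
            n2 = rng.normal(0.0, bg_sd, size=bg.shape)
            bg = np.sqrt((bg + n1) ** 2 + n2**2)
    signal[sel] = bg

    for lab, cls in enumerate(spec.classes, start=1):
        sel = labels == lab
        n_vox = int(sel.sum())
        if n_vox == 0:
            continue
        sd = spec.noise_sd_frac * cls.si0
        signal[sel] = forward_signal(
            cls, spec.acq, noise_sd=sd, rng=rng if sd > 0 else None,
            noise_model=spec.noise_model, size=n_vox,
        )

    return PhantomOutput(
        signal=signal, labels=labels, truth=_truth_maps(spec, labels), spec=spec
    )


def generate_group_study(
    spec: PhantomSpec,
    n_per_group: int,
    effect: Optional[dict[str, float]] = None,
    seed: int = 0,
) -> tuple[list[PhantomOutput], list[PhantomOutput]]:
    """Simulate a two-group study: group B's class parameters are scaled.

    ``effect`` maps parameter names ({t0, k, alpha, beta} for the
    gamma-variate, {s, tc, r} for the sigmoid) to multiplicative factors
    applied to every tissue class of group B; an empty effect yields a
    null study in which the groups differ only by noise.  Each subject
    receives an independent noise stream derived from ``seed``.
    """
    if n_per_group < 2:
        raise InputError("need at least 2 subjects per group")
    effect = effect or {}
    gamma_fields = {"t0", "k", "alpha", "beta"}
    sigmoid_fields = {"s", "tc", "r"}
    unknown = set(effect) - gamma_fields - sigmoid_fields
    if unknown:
        raise InputError(f"unknown effect parameters: {sorted(unknown)}")

    def scaled_classes() -> tuple[TissueClass, ...]:
        out = []
        for cls in spec.classes or _default_classes(spec.acq):
            gkw = {f: getattr(cls.gamma, f) * effect.get(f, 1.0) for f in gamma_fields}
            skw = {f: getattr(cls.sigmoid, f) * effect.get(f, 1.0)
                   for f in sigmoid_fields}
            try:
                out.append(
                    replace(cls, gamma=GammaVariateParams(**gkw),
                            sigmoid=SigmoidParams(**skw))
                )
            except InputError as exc:
                raise InputError(f"effect produces invalid parameters: {exc}") from exc
        return tuple(out)

    base = replace(spec, classes=spec.classes or _default_classes(spec.acq))
    shifted = replace(base, classes=scaled_classes())

    children = np.random.SeedSequence(seed).generate_state(2 * n_per_group)
    group_a = [
        generate_phantom(replace(base, seed=int(children[i]) % (2**31)))
        for i in range(n_per_group)
    ]
    group_b = [
        generate_phantom(replace(shifted, seed=int(children[n_per_group + i]) % (2**31)))
        for i in range(n_per_group)
    ]
    return group_a, group_b
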