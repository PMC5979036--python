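# dscmri

Bolus-tracking perfusion analysis for rodent dynamic
susceptibility-contrast MRI (DSC-MRI), with recirculation-aware
gamma-variate fitting, a digital 4-D perfusion phantom, and permutation
statistics for group comparisons.

## Who this is for

Preclinical imaging groups that acquire T2*-weighted EPI time-series of
the rat (or mouse) brain during a gadolinium bolus and want voxel-wise
perfusion maps without relying on human-oriented clinical software, whose
assumptions (slow recirculation, long transit times) do not hold in small
animals.

## The model

During bolus passage the signal darkens transiently; the change in the
transverse relaxation rate

    ΔR2*(t) = −ln(SI_t / SI_0) / TE

is proportional to the local contrast-agent concentration (SI_0 is the
mean signal over the pre-contrast baseline window).  Because blood
recirculates within seconds in the rat, the measured ΔR2* curve is a
mixture of the first-pass tissue response and an accumulating
recirculation plateau.  Each voxel is fitted with

    ΔR2*(t) ≈ k (t − t0)^α e^{−(t − t0)/β}  +  s / (1 + e^{−r (t − tc)})

by Levenberg–Marquardt nonlinear least squares (log-transformed positive
parameters, analytic Jacobian, two-stage initialisation).  From the fit
and the raw series, five per-voxel quantities are derived:

| metric | definition | units |
|--------|------------|-------|
| rCBV | area under the fitted gamma-variate, k β^{α+1} Γ(α+1) | relative |
| MTT | full width at half maximum of the fitted gamma-variate | s |
| rCBF | rCBV / MTT (central-volume relation) | relative |
| TTP | argmax frame of raw ΔR2* − last baseline frame | frames |
| BAT | first frame of the ≥10%-of-peak run ending at the peak | frame index |

Group comparisons use permutation tests: difference of means for
whole-brain scalars (exact enumeration when feasible) and a voxel-wise
two-sample t with max-statistic family-wise-error correction.

Because no scanner data ships with the package, a phantom generator
(`dscmri.phantom`) synthesises 4-D acquisitions with exact analytic
ground truth: an ellipsoidal two-class brain (cortex / deep gray), class
gamma-variate + sigmoid responses, the inverse signal model
SI(t) = SI_0 e^{−TE·ΔR2*(t)}, and seeded Gaussian (or Rician) signal
noise.  Defaults emulate a rodent protocol: TE 5 ms, TR 1 s, 50×50×16
matrix, 850 volumes, bolus at frame 240 injected over ~8 volumes.

## Worked example

```python
import numpy as np
from dscmri import default_spec, generate_phantom, quantify_volume, whole_brain_mean

spec = default_spec(shape=(10, 10, 4), noise_sd_frac=0.01, seed=42)
phantom = generate_phantom(spec)
maps = quantify_volume(phantom.signal, phantom.brain_mask, spec.acq)
print("voxels fitted:", maps.counts["fitted"], "/", maps.counts["masked"])
for name, value in whole_brain_mean(maps).items():
    print(f"whole-brain mean {name}: {value:.2f}")
cortex = phantom.labels == 1
print("cortex median MTT (s):", round(float(np.nanmedian(maps.mtt[cortex])), 2),
      "| truth:", round(float(phantom.truth['mtt'][cortex][0]), 2))
```

prints

```
voxels fitted: 168 / 168
whole-brain mean rcbv: 595.56
whole-brain mean mtt: 30.71
whole-brain mean rcbf: 19.03
whole-brain mean ttp: 26.55
whole-brain mean bat: 249.40
cortex median MTT (s): 33.81 | truth: 33.05
```

All 168 in-brain voxels of this small noisy phantom fit successfully.
The whole-brain means mix the two tissue classes (cortex MTT ≈ 33 s,
deep gray ≈ 26 s at this time resolution); the cortex median MTT
recovered from 1%-noise signal is within ~2% of the generating truth.
TTP ≈ 27 frames means the average voxel peaks 27 s after the end of the
baseline; BAT ≈ 249 is the frame index where the response first exceeds
10% of its peak (bolus injected at frame 240).

The same pipeline is scriptable from a shell:

```sh
dscmri simulate --out phantom/ --seed 1 --shape 50,50,16
dscmri quantify --in phantom/dsc.nii.gz --te-ms 5 --tr-s 1 --out maps/
dscmri compare --csv whole_brain_ttp.csv --out stats/ --seed 1
```

`quantify` writes one NIfTI per metric (`rcbv.nii.gz`, `mtt.nii.gz`,
`rcbf.nii.gz`, `ttp.nii.gz`, `bat.nii.gz`), a validity mask and a JSON
provenance sidecar.

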