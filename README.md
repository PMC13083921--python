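# stokespol

Quantitative Stokes polarimetric microscopy for histology: a tested
simulation and analysis pipeline for a dual photoelastic-modulator (PEM)
polarimeter that maps collagen birefringence and depolarisation in stained
tissue sections.

## Who this is for

Builders and users of PEM-based polarimetric microscopes who need the
computational half of the instrument: lock-in demodulation, calibration,
per-pixel Stokes reconstruction, birefringence inversion and ROI
statistics — all exercised on synthetic tissue phantoms with known ground
truth, so every stage is verifiable without an instrument or specimens.

## The model

A polarimeter with two PEMs (PEM2's optic axis defines the x-axis, PEM1 at
α ≈ 45°, linear analyser at β ≈ 23°) modulates the incident retardance
sinusoidally, shifting polarisation information onto harmonics of the
resonant frequencies f₁, f₂. Four demodulated signals — the DC level S_DC,
second harmonics S_QU1 (2f₁) and S_QU2 (2f₂), and the first harmonic
S_v (f₁) — are linearly related to the Stokes vector through a 4×4
transformation matrix **K** with the sparsity pattern

```
( I )   ( k1 k2 k3 0  ) ( S_DC  )
( Q ) = ( 0  k4 k5 0  ) ( S_QU1 )
( U )   ( 0  k6 k7 0  ) ( S_QU2 )
( V )   ( 0  0  0  k8 ) ( S_v   )
```

estimated here by least squares from known generator states. From the
Stokes planes the pipeline derives, with I_p = √(Q²+U²+V²):

- normalised components i, q, u, v = (I, Q, U, V)/I_p
- ellipticity angle ε = ½ arcsin(V/I_p) and azimuth θ = ½ atan2(U, Q)
- degree of polarisation P = I_p/I and depolarisation D_p = √(1−P²)

A uniaxial birefringent sample with in-plane optic axis γ, phase
retardation δ_s and depolarisation factor σ = P⁻¹ transforms the
normalised state by a Mueller matrix whose circular-illumination limit
gives the direct inversion

```
q' = −sin 2γ sin δ_s,   u' = cos 2γ sin δ_s,   v' = cos δ_s
```

so δ_s = arccos v′ and γ = ½ atan2(−q′, u′). For near-circular
illumination (the physical source has ellipticity ≈ 41°) a joint
least-squares inversion of all three propagation equations removes the
orientation-dependent bias of the direct estimator.

## Worked example

Simulate a keloid-like phantom (dense, disordered, strongly depolarising
collagen lesion on a weakly retarding substrate), image it through the
instrument model, calibrate, reconstruct and compare lesion to substrate:

```python
import numpy as np
from stokespol import (PhantomSpec, PolarisationState, PolarimeterConfig,
                       RoiSpec, background_correct, calibrate, canonical_states,
                       compare_groups, extract_rois, generate_phantom,
                       recover_sample, render_acquisition,
                       simulate_calibration_set, summarise)

cfg = PolarimeterConfig()              # alpha 45 deg, beta 23 deg, A = 2.405 rad
smap, truth = generate_phantom(PhantomSpec(kind="keloid", shape=(256, 256), seed=7))
acq = render_acquisition(smap, PolarisationState.circular(), cfg)

K = calibrate(simulate_calibration_set(canonical_states(), cfg=cfg)).K
rec = recover_sample(acq, K, mode="circular")

corrected, baseline = background_correct(rec.smap.delta, method="mode")
print(f"baseline retardation:            {baseline:.3f} rad")
print(f"peak retardation above baseline: {np.max(np.asarray(corrected)):.3f} rad")
print(f"maximum depolarisation:          {np.max(np.asarray(rec.dp)):.3f}")

rng = np.random.default_rng(0)
def roi_means(mask, label):
    rows = np.argwhere(mask)
    rows = rows[(rows[:, 0] > 15) & (rows[:, 0] < 240)
                & (rows[:, 1] > 15) & (rows[:, 1] < 240)]
    picks = rows[rng.choice(len(rows), 10, replace=False)]
    specs = [RoiSpec(label, int(c), int(r), side_px=8) for r, c in picks]
    return [summarise(rv.values).mean for rv in extract_rois(np.asarray(rec.dp), specs)]

res = compare_groups(roi_means(truth["tissue_mask"], "keloid"),
                     roi_means(~truth["tissue_mask"], "substrate"),
                     labels=("keloid", "substrate"))
print(res.summary())
```

prints

```
baseline retardation:            0.110 rad
peak retardation above baseline: 1.400 rad
maximum depolarisation:          0.960
keloid (n=10, mean=0.872, SD=0.1098) vs substrate (n=10, mean=0.4434, SD=0.01069): Mann-Whitney U, statistic=100, p=0.0001317 *
```

The recovered maps reproduce the phantom's ground truth: the substrate
baseline (0.11 rad), the lesion's peak retardation above baseline
(1.40 rad) and its maximum depolarisation (0.96); the ten lesion ROIs
depolarise significantly more than ten substrate ROIs (normality-gated
two-group test, p ≤ 0.05 threshold).

The same pipeline runs from the shell:

```bash
stokespol simulate --kind keloid --size 256 --seed 7 --out acq.tif --truth truth.tif
stokespol reconstruct --acq acq.tif --out stokes.tif
stokespol maps --stokes stokes.tif --out-dir maps/
stokespol retard --acq acq.tif --mode circular --out delta.tif
stokespol errorsweep --delta 1.0 --ellipticity-deg 41 --out curve.csv
```

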