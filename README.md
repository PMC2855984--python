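# ventrivol — serial-CT cerebral ventricular volumetry

Hydrocephalus is an accumulation of cerebrospinal fluid (CSF) that enlarges
the cerebral ventricles.  It is usually followed on serial head CT by visual
comparison, which is hard to do accurately: the ventricular system has a
complex shape, and the slice angulation and head position differ between
scans.  `ventrivol` implements a quantitative alternative for researchers in
medical image analysis: it measures the *change* in ventricular volume
between two CT studies of the same head.

The pipeline has three algorithmic stages:

1. **Rigid registration.**  The later study is aligned to the earlier one by
   maximizing a gradient-weighted normalized mutual information,

   ```
   In'(A, B) = G(A, B) · (H(A) + H(B)) / H(A, B),
   ```

   where the joint histogram is built with partial-volume interpolation
   (each reference voxel spreads unit mass over the 8 nearest moving-grid
   intensities with trilinear weights) and `G` sums
   `w(α)·min(|∇A|, |∇B|)` over corresponding points, `w(α) = (cos 2α + 1)/2`.
   The six rigid parameters are found by Nelder–Mead simplex search over a
   coarse-to-fine wavelet pyramid.  Registration makes the partial-volume
   errors of the two studies consistent, so they cancel in the difference.

2. **Adaptive segmentation.**  Each slice is oversegmented by a watershed on
   a modified gradient `G_M = |∇F|/(f_Γ·μ_I) + G_Γ/μ_T` that combines the
   intensity gradient with a texture gradient derived from dual-tree complex
   wavelet (DT-CWT) subband magnitudes (directional median filtering,
   Gaussian-derivative gradients, per-subband normalization), with shallow
   minima removed by the H-minima transform.  Adjacent regions whose pixel
   distributions agree under the two-sample Kolmogorov–Smirnov statistic —
   on the original slice and on a detail-only "texture map" — are then merged:
   `S_ks = S_ks2 · exp(S_ks1 − 1)`.  A user (or an automated stand-in) picks
   the ventricular regions.

3. **Volumetry.**  Per slice, area `a_k = p_s²·n_vk` and volume
   `V_k' = a_k·τ_k` with the slice's own thickness; the study volume is
   `V' = Σ V_k'` and the change is `ΔṼ' = (Ṽ_t2' − V_t1')/V_t1' · 100%`,
   with |ΔṼ'| > 5% flagging a true ventricular change.

Because real ventricular volume cannot be measured in vivo, validation uses
a built-in **digital head phantom**: an ellipsoidal brain matrix containing
a connected CSF cavity (lateral ventricles, foramina of Monro, third
ventricle, aqueduct, fourth ventricle analogues) of exactly known volume,
scanned by a simulated CT with mixed 3/7 mm slices, gantry tilt, rigid head
displacement, partial-volume averaging and noise.

## Worked example

```python
import numpy as np
from ventrivol import (make_phantom, ScanProtocol, scan_phantom, simulate_ct,
                       RigidTransform, register, RegistrationConfig)
from ventrivol.pipeline import PipelineConfig, segment_volume
from ventrivol.metrics import compute_volume, change_in_volume

spec = make_phantom(size_scale=0.951, seed=1)     # cavity V_M ≈ 88.0 cm³
proto = ScanProtocol()                            # 3/7 mm slices, σ=2 noise
scan1, truth1 = scan_phantom(spec, proto, seed=11)

# rescan the same head after a 5° out-of-plane nod and a 3 mm shift
disp = RigidTransform([3.0, 0, 0, 5.0, 0, 0], center=(0., 0., 0.))
scan2 = simulate_ct(spec, proto, displacement=disp, seed=22)

cfg = PipelineConfig(registration=RegistrationConfig(stride=2))
reg = register(scan1, scan2, cfg.registration)
print(np.round(reg.transform.alpha, 2))
# [2.99 0.08 0.01 5.02 0.14 -0.01]   <- the applied displacement, recovered

m1 = segment_volume(scan1, config=cfg, truth_mask=truth1)
m2 = segment_volume(reg.registered, config=cfg, truth_mask=truth1)
r1, r2 = compute_volume(m1, scan1), compute_volume(m2, reg.registered)
ch = change_in_volume(r1, r2)
print(f"V_t1' = {r1.total_cm3:.1f} cm³, Ṽ_t2' = {r2.total_cm3:.1f} cm³, "
      f"ΔṼ' = {ch.percent_change:+.1f}%  change: {ch.hydrocephalus_change}")
# V_t1' = 87.6 cm³, Ṽ_t2' = 89.3 cm³, ΔṼ' = +2.0%  change: False
```

The true change is zero; the pipeline reports +2.0%, well below the 5%
predictor threshold, so the (correct) verdict is "no ventricular change" —
even though the head moved out of plane between the scans.

A command-line interface mirrors the library:

```
ventrivol phantom scan --scale 0.951 --seed 1 --out scan1.nii --truth-out truth1.nii
ventrivol register --fixed scan1.nii --moving scan2.nii --out reg.nii --transform t.json
ventrivol volume --mask mask.nii --ct scan1.nii --out report.json
ventrivol validate --seed 1
```

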