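# ccfd — choriocapillaris flow-deficit quantification for en-face OCTA

The choriocapillaris (CC) is the dense capillary monolayer directly below
Bruch's membrane (BM) that supplies the retinal pigment epithelium and
photoreceptors. Optical coherence tomography angiography (OCTA) resolves
its perfusion *en face*, and CC **flow deficits (FD)** — contiguous regions
without detectable flow — are an emerging biomarker in age-related macular
degeneration. Quantifying them, however, is notoriously sensitive to the
instrument (swept-source vs spectral-domain), volume averaging, the axial
slab projected below BM, shadow compensation and the thresholding window.
`ccfd` implements that whole measurement chain as a tested, reproducible
pipeline, together with a synthetic-scene generator with exact ground
truth so every stage can be validated without patient data.

## The measurement chain

1. **Slab extraction** — project a 3-D OCTA volume over an axial window
   `[BM + z_inner, BM + z_outer]` (mean projection, linear interpolation at
   fractional depths). Five slabs are analysed: the device's automatic
   slab (0–20 µm below BM for the swept-source device, 9–31 µm for the
   spectral-domain device) and the fixed windows 11–21, 21–31, 31–41 and
   16–31 µm.
2. **Compensation** — correct attenuation (drusen shadowing) by
   multiplying the flow image with the Gaussian-blurred *inverse* of the
   structural image: `F' = F · G_σ(1 − S)`, σ = 15 µm by default.
3. **Binarization** — Phansalkar local thresholding over a circular
   window of radius 4 px: a pixel is a deficit iff

   `I ≤ µ · (1 + p·e^(−q·µ) + k·(σ/r − 1))`,  (k, r, p, q) = (0.25, 0.5, 2, 10)

   with µ, σ the local window mean and SD. The `e^(−q·µ)` term boosts the
   threshold in dark regions, which is exactly why results depend on
   slab, device and compensation.
4. **Particle metrics** — connected components (8-connectivity) of the
   deficit mask yield **FD%** (deficit pixels / all pixels), **FD count**,
   **mean FD size** (µm²) and **total FD area** (mm²); with no size filter
   `total area = FD%/100 × scan area` holds exactly.
5. **Statistics** — paired Wilcoxon signed-rank tests between devices
   (exact by sign enumeration for n ≤ 15), ICC(2,1) agreement across
   slabs with its F-based 95% CI, repeated-measures ANOVA with Tukey HSD
   post-hoc across conditions, and mean ± SD comparison tables.

The synthetic generator produces capillary meshes whose dominant spatial
period lies in the physiologic intercapillary-distance band (21–40 µm),
plants pathological deficits at a controlled fraction, and renders
device-specific image pairs (3 × 3 mm; 1024 px swept-source, 400 px
spectral-domain, with four-volume averaging halving the noise SD) under
drusen-like attenuation that multiplies both channels equally.

## Worked example

```python
import numpy as np
from ccfd import (VesselNetworkParams, ShadowField, generate_cc_pattern,
                  render_device_image, get_device, process_pair)

truth = generate_cc_pattern(VesselNetworkParams(target_fd_fraction=0.45, seed=11))
print(f"true deficit fraction: {truth.fd_fraction_true:.4f}")

shadow = ShadowField.generate(n_drusen=8, seed=12)          # drusen shadows
pair = render_device_image(truth, shadow, get_device("ss"), seed=13)
for comp in (True, False):
    m = process_pair(pair.flow, pair.structural, pair.pixel_size_um,
                     apply_compensation=comp)
    tag = "compensated" if comp else "uncompensated"
    print(f"{tag:>13}: FD% = {m.fd_percent:5.2f}  count = {m.fd_count}  "
          f"mean size = {m.mean_fd_size_um2:8.1f} um^2  "
          f"total = {m.total_fd_area_mm2:.2f} mm^2")
```

prints

```
true deficit fraction: 0.4414
  compensated: FD% = 40.78  count = 5370  mean size =    683.5 um^2  total = 3.67 mm^2
uncompensated: FD% = 40.65  count = 5380  mean size =    680.0 um^2  total = 3.66 mm^2
```

The scene was generated with a 44.1% true deficit fraction; the measured
FD% of ~40.8 on the noisy swept-source rendering sits a few points below
it because acquisition noise lifts some deficit pixels above the local
threshold — on noise-free renderings the pipeline recovers the true
fraction to well under one percentage point (see the test suite). Total
FD area is FD%/100 × 9 mm², and mean size × count equals the total area.

A full synthetic cohort (eyes × {SS, SD_V1, SD_V4} × five slabs) with
comparison tables, slab-pair p-value matrices and per-device ICCs:

```bash
ccfd run --out runs/demo            # default 5-eye cohort
ccfd simulate --device sd_v1 --fd-fraction 0.4 --seed 3 --out scene/
ccfd quantify --image scene/enface_flow.tif --pixel-size-um 7.5 --radius 4
```

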