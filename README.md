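# lobulemorph

Quantitative morphometry and radial-stress modelling of the liver lobule.

The liver lobule is organized radially: blood enters at peripheral portal
tracts and drains through sinusoids into the central vein (CV), and
hepatocyte phenotype changes along the same axis (zonation).  This package
implements, as a tested analysis pipeline, the image-based measurement of
that radial organization and the mechanical model it motivates:

* **segmentation** of brightfield sections into vessel lumen, hepatocyte
  cytoplasm and nuclei, with per-object areas and centroids;
* **vessel topology** — skeletonization and detection/classification of
  branch points (triple vs four-plus junctions), the proxy for vessel
  number;
* **radial morphometry** — every metric as a function of the normalized
  radius R (R = 0 at the CV): vessel area fraction α(R), hepatocyte
  fraction, branch counts, vessel area per branch point, hepatocyte area
  per nucleus, plus perivenous/periportal (PV/PP) zone folds;
* **stress model** — the compression field of a pressurized vessel,
  σ_rr(r) = −P_i (r_i/r)², its superposition between vessels, and the
  zone-ratio estimate σ_rr(R_min)/σ_rr(R_max) ≈ (P_i α)(R_min)/(P_i α)(R_max);
* **statistics** — OLS with the nested-model F-test against an
  intercept-only fit, the unpaired t-test on branch-type proportions, and
  the assay formulas (LDH viability %, protein recovery %, 2^−ΔΔCT
  relative expression with housekeeping-gene selection).

Because the underlying pig histology is not publicly deposited, a
first-class **synthetic-lobule generator** reproduces the measured radial
structure (vessel density ~1.9× higher and calibres larger near the CV,
hepatocyte area per nucleus ~0.9× smaller near the CV, branch counts rising
linearly with R, triples dominating) with bit-reproducible ground truth —
masks, objects, branch points and density profiles — against which every
pipeline stage is validated.  See `docs/methods.md` for the model and the
calibration.

## Worked example

```python
import numpy as np
from lobulemorph import synthetic, segmentation, topology, morphometry, stress

# simulate one lobule (500 µm radius, 1 µm/px) and segment its render
lob, image, gt = synthetic.simulate_lobule(seed=0)
masks = segmentation.segment_classes(image, "auto", scale=lob.scale)
print([round(segmentation.iou(getattr(masks, c), getattr(gt.masks, c)), 3)
       for c in ("vessel", "hepatocyte", "nucleus")])
# [0.999, 0.999, 1.0]

# radial profile and PV/PP zone folds from the ground truth
frame = morphometry.LobuleFrame(cv_centroid=lob.cv_centroid,
                                boundary=lob.lobule_radius)
prof = morphometry.radial_profile(gt.objects, gt.branch_points, gt.masks,
                                  frame, n_bins=10)
zones = {z.metric: z for z in morphometry.zonal_summary(prof)}
print(round(zones["alpha"].fold, 2),
      round(zones["hep_area_per_nucleus"].fold, 2))
# 1.75 0.92   (vessel density higher, hepatocytes smaller, near the CV)

# pericentral/peripheral stress ratio from the measured inputs
ratio = stress.stress_ratio(stress.StressRatioInputs(
    alpha_min_over_max=1.9, p_min_over_max=0.7))
print(round(ratio, 2), stress.round_sig(ratio, 2))
# 1.33 1.3   (~30% more radial compression near the central vein)
```

The numbered scripts under `analysis/` run the same stages end to end and
write their tables under `results/`:

```text
01_simulate_lobule.py    geometry, image, masks, ground truth
02_segment.py            segmentation + IoU benchmark          (IoU ≥ 0.999)
03_branch_topology.py    branch counts vs R: slope 59.2, R² 0.74, p = 6.3e-3;
                         triple fraction 0.86 vs quad-plus 0.14, p = 5.8e-22
04_radial_morphometry.py zone folds: α 1.84 (tissue: 1.9), HA/nucleus 0.90
                         (tissue: 0.90); species fold table 10/13 reproduced
05_stress_model.py       σ_rr curves, two-vessel superposition, stress ratio
                         1.33 printed / 1.37 ± 0.04 from the pipeline
```

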