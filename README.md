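# gasig

Quantitative image analysis of gibberellin (GA) signaling in the shoot
apical meristem (SAM), built around a degradation-based ratiometric
biosensor. The SAM is the dome-shaped stem-cell tissue at the shoot tip;
its epidermal layer (L1) contains the central zone (CZ, the CLV3-marked
stem-cell domain), organ primordia (P), and the inter-primordia region
(IPR) between them. The package is for researchers who image such tissues
with a two-fluorophore nuclear sensor — a GA-degradable sensor protein
(VENUS-tagged) co-expressed stoichiometrically with a GA-insensitive
reference (TagBFP) — and want per-cell signaling maps, growth tensors,
division-plane statistics and multi-plant averages from the raw stacks.

## What it computes

* **Per-nucleus GA signaling.** Nuclei are detected on the reference
  channel (multi-scale Laplacian-of-Gaussian in 3D) and signaling activity
  is read out as

  ```
  S = 3 − V/B
  ```

  where `V` and `B` are background-subtracted mean sensor and reference
  intensities: absent degradation gives `V/B ≈ 3` (S ≈ 0), complete sensor
  degradation gives `V/B = 0` (S = 3). Per-image standardization (ratios
  divided by their mean, centring the distribution on 1) supports
  comparisons against constitutive control lines.
* **3D cell segmentation** of the cell-wall (PI) channel by seeded
  watershed, L1 extraction from the outer tissue surface, per-cell surface
  mean curvature, and meristem radius from incipient-primordium (I1/I2)
  annotations.
* **Time-lapse lineage and growth.** Rigid registration (3D translation +
  rotation about the optical axis) on the wall channel, overlap-based
  lineages with expert-correction overrides, and per-cell surface growth:
  relative areal increment per hour, plus growth anisotropy
  `(s1 − s2)/(s1 + s2)` from the principal stretches of the parent-to-
  children footprint map (0 = isotropic, 1/3 = two-fold uniaxial).
* **Division-plane orientation.** New walls are the shared boundaries of
  daughter cells, skeletonized in the top-down projection; the angle to
  the radial axis from the SAM center is folded to [0°, 90°]
  (90° = circumferential/transverse) and tabulated in nine 10° bins.
* **Population atlases and statistics.** Multiple SAMs aligned on the
  CLV3-domain centroid (translation) and a reference primordium azimuth
  (rotation), averaged on a polar grid; Spearman rank correlation,
  two-sample Kolmogorov–Smirnov, Welch and Kruskal–Wallis tests, and PCA
  of per-cell variables.
* **A synthetic SAM generator** (`gasig.synthgen`) that renders multi-
  channel dome tissues, time-lapses with growth, divisions and recorded
  rigid drift, plus full ground truth — every stage of the pipeline is
  validated against it.

## Worked example

```python
import numpy as np
from scipy.spatial import cKDTree
from gasig import (SyntheticSAMSpec, generate_sam_stack,
                   detect_nuclei, measure_intensities)
from gasig.quantify import records_to_dataframe

spec = SyntheticSAMSpec(n_cells_l1=50, noise_sigma=0.0, seed=1)
stack, truth = generate_sam_stack(spec)

records, qc = measure_intensities(stack, detect_nuclei(stack))
df = records_to_dataframe(records)
_, idx = cKDTree(truth.nucleus_table[["z_um", "y_um", "x_um"]].to_numpy()) \
    .query(df[["z_um", "y_um", "x_um"]].to_numpy())
df["region"] = truth.nucleus_table.iloc[idx].region.to_numpy()
print(f"{qc['n_kept']} nuclei quantified")
print(df.groupby("region")["signaling"].agg(["mean", "std", "count"]).round(3))
```

prints

```
50 nuclei quantified
         mean    std  count
region
CZ      1.804  0.002      6
IPR     2.498  0.002     33
P       1.004  0.003     11
```

All 50 nuclei of the noiseless 50-cell dome are found, and the recovered
per-region signaling means reproduce the generator's field (CZ 1.8,
IPR 2.5, P 1.0) to well under 1% — the stoichiometric encoding
`V/B = 3 − S` round-trips through detection, aggregation and the
signaling transform.

The same stages are available from the shell:

```bash
gasig simulate --out scene/ --frames 2 --seed 1
gasig quantify --stack scene/frame00.ome.tif --out q/
gasig segment  --stack scene/frame00.ome.tif --out seg/
gasig track    --frames scene/frame00.ome.tif scene/frame01.ome.tif \
               --labels scene/frame00_labels.tif scene/frame01_labels.tif \
               --spacing 1.0 0.5 0.5 --out t/
```

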