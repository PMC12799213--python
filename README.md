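# syribbon-quant

Quantification pipeline for **synthetic ribbon-type active zones** — the
reconstituted RIBEYE + membrane-anchored-Bassoon ("SyRibbon") structures
expressed in HEK293 cells together with Ca_V1.3 Ca²⁺ channels — and for the
imaging and electrophysiology readouts used to characterize them:

- **3D puncta segmentation & morphometry** — rolling-ball background
  subtraction, Gaussian smoothing at a 0.16 µm surface-detail scale,
  thresholding, connected components, a ≥10-voxel size filter, and per-spot
  volume *V*, surface area *A* and Wadell sphericity
  Ψ = π^⅓(6V)^⅔ / A, with the 0.02–2 µm³ analysis bounds.
- **Proximity classes** — boundary-to-boundary surface distances with the
  two thresholds used to call colocalized structures (≤0.06 µm for
  RIBEYE–Bassoon pairing, ≤0.045 µm for ribbon-associated Ca_V clusters).
- **Pixel colocalization** — Pearson *P_r*, thresholded Manders M1/M2 with
  Costes auto-thresholds, and the Costes block-scramble significance test
  (100 repetitions), evaluated in a 1-µm-thick peripheral ring over at least
  three central planes; plus the periphery:interior intensity ratio and
  tangential line-profile correlation.
- **Stimulus-locked ΔF/F₀** — background subtraction of indicator movies,
  ΔF images (mean of 3 stimulus frames − mean of 5 baseline frames), 2 µm
  circular ROIs assigned blind from the structural channel,
  ΔF_max/F₀ = mean ΔF/F₀ over the three frames at the within-stimulus peak,
  and the paired with/without-SyRibbon comparison across cells.
- **IV curves** — liquid-junction-potential correction, p/10 leak
  subtraction, the 5–10 ms extraction window, QC exclusion rules
  (leak > 50 pA, R_s > 15 MΩ, offset drift > 5 mV, |I_peak| < 49 pA,
  |density| > 60 pA/pF), and a Boltzmann-gated ohmic activation fit
  I(V) = g_max (V − V_rev) / (1 + exp(−(V − V_half)/k)).
- **Statistics** — the decision tree (Jarque-Bera + Kolmogorov-Smirnov
  normality, F-test variance equality; t-test/ANOVA+Tukey vs
  Mann-Whitney/Kruskal-Wallis+Dunn) and box-plot descriptives
  (mean, SD, CV, median, 10/25/75/90 percentiles).
- **Synthetic data generators** — seeded, ground-truth-annotated image
  stacks (ellipsoidal cell with membrane shell, membrane-anchored punctum
  pairs/triples, PSF blur, Poisson+Gaussian noise), Ca²⁺-indicator time
  series with a 500 ms stimulus transient at 20 Hz, and Boltzmann+leak IV
  recordings — so every stage is testable without raw microscope data.

Intended users: groups quantifying fluorescent puncta at the plasma
membrane, presynaptic-reconstitution experiments, and anyone needing a
scriptable, deterministic replacement for interactive surface-detection and
Coloc-2-style analyses.

## Worked example

```python
import numpy as np
from syribbon_quant.synthetic import (SimConfig, random_syribbon_spots,
                                      generate_cell_stack, generate_iv_recording)
from syribbon_quant.spots import (detect_spots, filter_spots,
                                  classify_by_proximity, summarize_spots)
from syribbon_quant.coloc import build_cell_geometry, peripheral_ratio, costes_test
from syribbon_quant.ephys import extract_iv, fit_activation, qc_filter

cfg = SimConfig(seed=1)                       # 80×80×200 nm voxels
spots_gt = random_syribbon_spots(cfg, n_pairs=12, rng=np.random.default_rng(1))
stack, truth = generate_cell_stack(cfg, spots_gt)

ribeye = filter_spots(detect_spots(stack, "RIBEYE"))[0]
bassoon = filter_spots(detect_spots(stack, "Bassoon"))[0]
pairs = classify_by_proximity(ribeye, bassoon, threshold=0.06)

geom = build_cell_geometry(stack, membrane_channel=0)
res = costes_test(stack.channel("RIBEYE"), stack.channel("Bassoon"),
                  geom.ring_mask, n=100, rng=1)

rec = generate_iv_recording(vhalf=-15.0, slope_k=8.0, g_max=2.0, noise_sd=3.0, seed=1)
iv = fit_activation(extract_iv(rec, leak_correct=True))
```

Output:

```
RIBEYE surfaces: 10, volume 0.49 ± 0.22 µm³ (CV 0.46), Ψ 0.94 ± 0.05
paired with Bassoon at ≤0.06 µm: 9/10
peripheral ratio (RIBEYE): 3.91
Pearson r = 0.071, M1 = 0.50, M2 = 1.00, Costes p = 0.00
QC passed: True; V_half = -14.9 mV, k = 8.0 mV
```

Reading this: 10 RIBEYE surfaces survive the size filters with a broad
volume distribution and near-spherical shape; 9 of them sit within 60 nm of
a Bassoon surface (distance-based pairing — the right tool here, since the
two markers are adjacent rather than overlapping, which is also why the
pixelwise Pearson r in the peripheral ring is low even though the Costes
test still flags the spatial association as non-random). The peripheral
ratio ≫ 1 confirms membrane-anchored puncta. The IV fit recovers the
generator's half-activation voltage (−15 mV) and slope (8 mV) from noisy
sweeps after p/10 leak correction.

The same flows are scriptable via the CLI:

```bash
syribbon-quant simulate stack --seed 1 --out demo/
syribbon-quant segment --in demo/stack.ome.tif --out demo/spots.csv
syribbon-quant run --config cfg.yaml
```

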