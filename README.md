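# camquant

Quantification of tumor-induced angiogenesis in CAM-style (chorioallantoic
membrane) assay images:

- **segmentation** — a compact encoder–decoder network (pure NumPy, trained
  with binary cross-entropy, flip/rotation/shift/color augmentation and early
  stopping) producing a per-pixel vessel score in [0, 1], binarized at 0.5;
  tiled inference with feathered blending for large images.
- **morphometry** — four readouts from the binary mask: total vessel area,
  total vessel length (geodesic skeleton length, √2 diagonals), mean vessel
  thickness (2·EDT−1 sampled on the skeleton) and number of branching points
  (clustered degree-≥3 skeleton junctions).
- **perfusion** — LSCI-style analysis of perfusion-unit (PU) map sequences:
  most-stable-window frame averaging, 800–3000 PU band-pass, mean perfusion ×
  perfused area = mean blood flow (PU·mm²).
- **stats** — one-way ANOVA with Tukey HSD, from raw per-sample values or
  from published (mean, SD, n) group summaries.
- **synthetic** — a seeded generator of CAM-like images with analytic ground
  truth: branching vessel trees with per-vertex radii, blurred sub-membrane
  distractor vessels (excluded from truth), tumor-disc occluders,
  illumination gradients, sensor noise, and matching perfusion frames.
  Every downstream stage is testable without any external data.

## CLI

```bash
camquant simulate --n 5 --size 512 --seed 7 --out-dir data/          # synthetic samples + ground truth
camquant train --train-dir data/train --val-dir data/val --out-dir model/
camquant segment --model model/model.npz --out-dir out/ data/*.png   # masks, overlays, morphometrics.csv
camquant quantify --out morph.csv masks/*.png
camquant perfusion --frames frames.tif --out perfusion.csv
camquant stats --summary groups.csv --out pairwise.csv               # or --raw samples.csv
camquant evaluate --truth-dir data/ --out metrics.csv out/*_pred.png
camquant run --config pipeline.json                                  # batch image -> mask -> readouts
```

Images are 8-bit RGB PNG/TIFF; masks 0/255 PNG; perfusion frames multi-page
float32 TIFF with a `calibration.csv` (`pixel_pitch_mm`) sidecar; tables CSV
with one `#` provenance line. Every command writes a `runlog.json` with the
config hash and seed.

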