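# speckleid

Classification of lipid-suspension drugs from laser speckle-pattern images,
built as a tested, reusable pipeline:

1. **simulate** — synthetic dynamic speckle datasets (fully developed speckle:
   unit contrast, exponential intensity) parameterized by a six-product drug
   catalog; per-drug brightness follows lipid concentration × (refractive-index
   contrast)², with frame-to-frame temporal decorrelation and per-session gain
   jitter, laid out as drugs × samples × videos × frames.
2. **preprocess** — center crop (1456×1088 → 224×224 by default),
   crop-representativeness KS test, stratified 80/20 train/test split, and
   per-drug intensity normalization fitted on training frames only.
3. **features** — a 129-value texture descriptor per image: 5 first-order
   statistics + 20 gray-level co-occurrence (GLCM) statistics and 11 run-length
   (GLRLM) statistics per direction θ ∈ {0°, 45°, 90°, 135°}.
4. **select** — classic local-outlier-factor removal of the 10% most anomalous
   training rows (k = 20) and seeded random pruning of feature pairs with
   |Pearson r| ≥ 0.9.
5. **classify** — grid-searched, 10-fold cross-validated Random Forest or MLP,
   evaluated with a 6×6 confusion matrix and macro one-vs-rest
   accuracy / sensitivity / specificity / precision / AUC with 95% bootstrap
   confidence intervals.
6. **explain** — model-agnostic Shapley values (exact enumeration for ≤ 8
   features, permutation sampling otherwise) with global-importance and
   beeswarm-style exports.
7. **stats** — per-drug gray-level distributions, one-way ANOVA, and Tukey HSD
   pairwise comparisons.

## Test

```sh
python -m pytest tests/
```

The suite includes independent brute-force oracles (GLCM/GLRLM enumeration,
O(n²) LOF, permutation-enumerated Shapley values) and an acceptance suite
(`tests/test_acceptance.py`) covering dataset arithmetic, feature arity,
simulator physics, oracle equivalence, parameter recovery on the synthetic
six-class problem, and pipeline determinism. Full run takes about 1–2 minutes
on one CPU.

## CLI

Every stage is exposed under one entry point:

```sh
speckle-id simulate  --config sim.toml --out data/ --seed 1
speckle-id preprocess --in data/ --out prep/ --crop 224 --split 0.8 --seed 1
speckle-id extract   --in data/ --out features.csv --crop 224
speckle-id select    --features features.csv --lof-frac 0.10 --pcc 0.9 \
                     --seed 1 --out selected.csv --mask mask.json
speckle-id train     --features selected.csv --model mlp --seed 1 --out model.bin
speckle-id evaluate  --model model.bin --features selected.csv --report report.json
speckle-id explain   --model model.bin --features selected.csv --out shap.csv
speckle-id stats     --in data/ --out stats.json --unit image
speckle-id run       --config pipeline.toml --out rundir/   # everything at once
```

`speckle-id run` executes the whole chain from a single TOML config (all keys
optional; see `speckleid.pipeline.PipelineConfig` for names and defaults) and
writes `features.csv`, `mask.json`, `report.json`, `shap_importance.csv`,
`stats.json`, and `run.json` stamped with the config hash.

## Notes

- Datasets are written as 8-bit grayscale PNGs under
  `<root>/<drug>/<sample>/<video>/frame_####.png` with a `manifest.csv`.
- All randomness flows from explicit seeds; per-video streams are spawned from
  a single seed sequence, so any frame is reproducible in isolation.
- The frame-level split mirrors the original experimental protocol; a
  grouped `split_unit = "video"` option avoids intra-video leakage and gives
  more conservative test scores.
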