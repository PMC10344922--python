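# slideroi

Region-of-interest (ROI) detection for pyramidal whole-slide images (WSI),
with the downstream pieces needed to exercise it end to end: synthetic slide
generation, tile screening, pathologist-consensus labeling, classification-head
architecture search, a backbone+head tile classifier, HER2 grading from
per-nucleus signal counts, and observer-agreement statistics.

## What's in the box

| module | purpose |
|---|---|
| `slideroi.synthetic_slide` | deterministic synthetic pyramids with planted representative / artifact / blur / fat regions, simulated annotators, Poisson signal-count tables |
| `slideroi.pyramid` | pyramid model, 224×224 non-overlapping tiling, cross-magnification coordinate mapping, ROI-map rendering and (de)serialization |
| `slideroi.tile_screen` | pre-classification gates: bright/empty rule (>75% of pixels above gray level 200, on the 1× rendition), pluggable artifact and sharpness gates |
| `slideroi.annotation_consensus` | all-annotators consensus labeling, balanced 60/20/20 splits (ceil-on-eval rounding), stratified k-folds, flip/rotate/zoom augmentation |
| `slideroi.head_search` | head-architecture generators (9 halving chains + 28 single omissions + 21 contiguous-run omissions = 58), hyperparameter grid enumeration (1152 configs), top-candidate selection |
| `slideroi.roi_classifier` | frozen-backbone + trainable-head classifier (numpy), attention-only fine-tuning for the tiny transformer backbone, metrics, 5-fold cross-validation |
| `slideroi.wsi_pipeline` | tile → screen → classify orchestration, detection-vs-annotators evaluation (3-type false-positive taxonomy), affine coordinate transfer to serial slides |
| `slideroi.her2_grading` | pooled HER2/CEP17 ratio, mean copies per nucleus, Pos/Neg status at the 2.0 cut-off |
| `slideroi.concordance` | MSE (1/n), Pearson correlation, Cohen's kappa, bundled 12-case score tables |

The named ImageNet-scale backbones (VGG16 … DenseNet121, ViT-B/32) are
loadable by name but deliberately unavailable offline; the bundled `tiny-cnn`
and `tiny-vit` backbones fulfil the same contracts at desk scale.

## CLI

```sh
slideroi generate --out slide_dir --width 2240 --height 2240 --seed 1
slideroi tile --slide slide_dir --mag 10
slideroi detect --slide slide_dir --mag 10 --out map.json --overlay overlay.png
slideroi evaluate --map map.json --annotations a1.geojson a2.geojson a3.geojson
slideroi transfer --map map.json --affine t.json --out map_cish.json
slideroi enumerate-heads
slideroi grid
```

`detect` uses a mean-luminance baseline classifier unless `--model` points to
a pickled handle exposing `predict_proba`.

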