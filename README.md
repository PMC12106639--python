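# pathreport

**Desk-scale whole-slide-image report generation, end to end and testable.**

Writing a dermatopathology report from a whole slide image (WSI) is a
slide-level problem: a gigapixel scan is tiled into thousands of patches, yet
the diagnosis, the tumor depth, and the margin status depend on the whole
tissue context. `pathreport` implements a complete, configurable version of a
slide-level vision-language reporting pipeline at desk scale — every
architectural and algorithmic component is real and trainable, while the
pre-trained giants (patch encoders, biomedical language models, external
paraphrasing LLMs) are replaced by pluggable interfaces with small
deterministic defaults, so the entire system runs and is tested on a laptop
CPU against synthetic slides with known ground truth.

## What is inside

- **Synthetic study conditions** (`pathreport.synthetic`): toy slides with a
  fixed epidermis boundary, blob lesions of measurable Breslow-like depth
  (0.01 mm/px), long-tailed multi-class corpora, multi-slide patients
  (z = 0, 1, 2), and templated three-section reports
  (`Final diagnosis: … Microscopic findings: … Critical findings: …`) whose
  keyword content is exact ground truth.
- **Preprocessing** (`pathreport.preprocessing`): non-overlapping tiling with
  integer downsampling, background removal by luminance threshold + Canny edge
  density, per-channel normalization with the standard ImageNet triples
  (0.485, 0.456, 0.406) / (0.229, 0.224, 0.225), pluggable patch encoders, and
  an HDF5 feature container (`features` n×d, `coords` n×3, `slide_ids`).
- **Slide encoder** (`pathreport.slide_encoder`): a Perceiver-style resampler
  compressing any number of patch features into a fixed set of latents
  (640 × 1536 by default), an optional learned factorized (x, y, z) position
  embedding, and supervised multiple-instance-learning (MIL) pretraining with
  a discardable linear head over the mean latent.
- **Language fusion** (`pathreport.fusion_lm`): a causal transformer LM with
  tanh-gated cross-attention blocks (XATTN) interleaved one-per-layer.
  Gates start at 0, so the fused model is *exactly* the bare LM at
  initialization; report fine-tuning freezes everything except the XATTN
  blocks.
- **Training** (`pathreport.training`): AdamW (betas 0.9/0.95, weight decay
  0.1), linear warmup to 1e-4 over 10 epochs then tenfold cosine decay,
  gradient accumulation (32) and global-norm clipping (1.0), plus validated
  report-paraphrase augmentation through a pluggable rewrite provider.
- **Decoding** (`pathreport.generation`): temperature / top-k / top-p
  sampling, Expert Guidance (`"Final diagnosis: <label>."` prompts),
  Classifier Guidance (a small subset-restricted classifier over pooled slide
  latents chooses the prompt), Ensemble Refinement (k stochastic samples with
  derived seeds, aggregated by an ordered sentence union), and structured
  extraction of diagnosis / tumor thickness / margin status.
- **Interpretability** (`pathreport.interpretability`): gradient×attention
  saliency — per-latent patch sensitivities **G** (num_patches × num_latents)
  weighted by the mean cross-attention row of the target tokens from the last
  XATTN layer, min-max normalized to [0, 1] — with RGBA heatmap rendering and
  per-patch TSV export.
- **Evaluation** (`pathreport.report_eval`): dictionary/NER keyword
  extraction, Ratcliff–Obershelp (Gestalt) fuzzy matching at cutoff 0.6 over
  word-aligned windows, keyword Jaccard, embedding cosine similarity, and
  random-pair lower/upper baselines.
- **Pipeline & CLI** (`pathreport.config`, `pathreport.cli`): schema-validated
  YAML configs (unknown keys rejected), per-stage derived seeds, a manifest
  with config hashes, and subcommands
  `simulate · preprocess · pretrain-mil · train · generate · refine · explain
  · evaluate · run`.

The small neural components are built on `pathreport.nn`, a compact numpy
reverse-mode autodiff core (tensors, attention blocks, AdamW, clipping) —
sufficient because every trainable model here is deliberately tiny.

## Worked example

```python
import numpy as np
from pathreport.synthetic import make_toy_slide, make_report
from pathreport.preprocessing import (tile_image, filter_background,
    normalize_patches, encode_patches, ToyPatchEncoder)
from pathreport.slide_encoder import (PerceiverResampler, ResamplerConfig,
    resample_slide)
from pathreport.report_eval import VocabularyExtractor, keyword_jaccard
from pathreport.generation import extract_field

slide = make_toy_slide("basal_cell_carcinoma", size=96, rng_seed=7)
report = make_report([slide], rng_seed=7)
print("thickness_mm:", slide.thickness_mm)
print(report.text)

ps = tile_image(slide.image, patch_size=32, resize_to=None, patient_id="demo")
ps = filter_background(ps)
ps = encode_patches(normalize_patches(ps), ToyPatchEncoder(dim=32))
print("patches kept:", len(ps), "feature dim:", ps.dim)

rs = PerceiverResampler(
    ResamplerConfig(input_dim=32, n_latents=8, latent_dim=32, depth=1, n_heads=4),
    np.random.default_rng(0))
print("slide latents:", resample_slide(ps, rs).shape)
print("parsed thickness:", extract_field(report.text, "thickness_mm"))

ex = VocabularyExtractor(["basal cell carcinoma", "basaloid nests",
                          "peripheral palisading", "scar"])
print("self keyword jaccard:", keyword_jaccard(report, report, ex).jaccard)
```

prints

```
thickness_mm: 0.34
Final diagnosis: Basal cell carcinoma. Microscopic findings: Examination
reveals basal cell carcinoma, basaloid nests and peripheral palisading
throughout the sample. The tumor thickness is 0.3 mm. Critical findings:
Basal cell carcinoma. Partial excision.
patches kept: 6 feature dim: 32
slide latents: (8, 32)
parsed thickness: 0.3
self keyword jaccard: 1.0
```

The lesion reaches 34 px below the epidermis boundary, hence 0.34 mm of
depth; the report template rounds it to one decimal, and the thickness parser
recovers it from the text. Six of the nine tiles survive background
filtering (the slide's white glass margin is removed), and the slide encoder
compresses them into a fixed 8 × 32 latent summary regardless of the patch
count.

A full pipeline — simulate, preprocess, MIL-pretrain, fine-tune the
cross-attention, generate expert-guided reports, and score them — runs with

```bash
pathreport run --seed 1 --out runs/toy
```

and writes `scores.tsv` (per-patient keyword Jaccard against the ground-truth
reports), generated reports, checkpoints, and a reproducibility manifest.

## Scope

Not goals of this package: decoding vendor WSI formats (MRXS/NDPI), stain
normalization or photorealistic texture synthesis, loading real pre-trained
patch encoders or biomedical LMs, machine translation, calling commercial
LLM APIs in tests (the aggregation and paraphrase interfaces accept them in
deployment), and re-implementing syntax metrics (BLEU/ROUGE/METEOR) —
adapter hooks accept established implementations.
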