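# Methods

This note documents the models, parameter choices, and numerical decisions
behind `pathreport`, and what the synthetic benchmarks do and do not show.

## Problem setting

A patient contributes one or more whole-slide-like rasters. Each raster is
tiled into non-overlapping patches; each patch is embedded by a frozen
encoder into a d-dimensional feature vector; the unordered bag of features
(with (x, y, z) grid coordinates, z indexing the slide) is the model input.
The output is a three-section pathology report. Supervision exists at two
levels: a patient-level class label (used once, for slide-encoder
pretraining) and the report text itself (used for the generative phase).

## Slide encoder

The slide encoder is a Perceiver-style resampler: a learned set of m latent
vectors (m = 640, width k = 1536 by default) cross-attends to the n patch
features, so the output size is independent of n. Each of `depth` layers
applies cross-attention (latents as queries, projected patch features as
keys/values), a feed-forward block, and latent self-attention, all pre-norm
with residual paths. Because softmax attention over the patch set is the
only place patches enter, the map is permutation invariant when position
embeddings are off; duplicating a patch does not change the attention's
convex combination, so it does not change the output either.

The number of layers and heads is an open design axis; the defaults
(depth 2, 8 heads, feed-forward multiplier 4) follow the common
cross-attention-plus-self-attention block structure and are config-exposed.
Latents initialize from normal(0, 0.02), seed-controlled.

**Position embedding.** An optional factorized embedding adds
E_x[x] + E_y[y] + E_z[z] (learned lookup tables, one per axis) to the patch
features before resampling, deliberately breaking permutation invariance so
spatial layout can inform the latents. The tables initialize at
normal(0, 0.1) — larger than the projection init — so the positional signal
is not negligible relative to features at initialization; coordinates beyond
the configured table sizes are an error, not a clamp.

**MIL pretraining.** A linear head over the mean latent predicts the
patient-level class; training minimizes cross-entropy with AdamW
(lr 3e-3, 60 epochs by default — chosen for reliable convergence of the
desk-scale configuration on the separable toy corpus). The head is
discarded afterwards; `return_head=True` exists only so the pretraining task
itself can be evaluated on held-out patients. Mean-over-latents pooling is
used both here and for guidance classifiers, keeping one image
representation throughout.

## Language fusion

The language model is pluggable; the shipped default is a 2-layer, 64-dim
causal transformer over a whitespace-token vocabulary. Image information
enters through tanh-gated cross-attention (XATTN) blocks, one inserted after
each LM layer (`xattn_every` exposes sparser placements):

    hidden ← hidden + tanh(g) · CrossAttention(LN(hidden), latents)

with the scalar gate g initialized to 0. At initialization the fused model
is therefore *exactly* the bare LM — a testable identity — and the gate's
gradient is the only nonzero XATTN gradient at step one, after which the
block trains normally. During report fine-tuning everything except the
XATTN blocks (and gates) is frozen; during MIL pretraining only the
resampler (and its head) trains.

The LM loss is mean next-token cross-entropy under an upper-triangular
causal mask; log-probabilities are computed with a max-shifted log-sum-exp
so the gradient path stays stable for confident models.

## Training loop

AdamW with betas (0.9, 0.95), weight decay 0.1, epsilon 1e-8. The learning
rate warms up linearly from zero over 10 epochs to a peak of 1e-4 and then
decays with cosine annealing to one tenth of the peak over the remaining
epochs ("tenfold" is interpreted as final = peak/10 and exposed as
`final_lr_ratio`); beyond the schedule the final value is held. Epoch-based
quantities convert to steps via the loader's steps-per-epoch. One update
aggregates `grad_accum` (default 32) micro-batch gradients scaled to their
mean — a partial window at epoch end is rescaled so the update is still a
mean — then the global gradient norm is clipped at 1.0. Mixed precision is
out of scope: everything is float64 on CPU, which buys bit-reproducibility
for fixed seeds. A non-finite loss aborts with a diagnostic rather than
silently corrupting the run.

**Paraphrase augmentation** happens offline through a rewrite-provider
interface (an external LLM in deployment; identity and deterministic
synonym-swap providers here). Each report yields 9 variants; a variant must
retain the `Microscopic findings:` and `Critical findings:` markers
verbatim, otherwise it is rejected and resampled (bounded retries, original
text as last resort). A missing provider degrades to identity with a
warning.

## Decoding and guidance

`sample_next_token` applies temperature scaling, keeps the top-k logits,
truncates to the smallest probability prefix reaching top-p, renormalizes,
and samples; temperature 0 is greedy argmax. Defaults (0.8 / 0.95 / 50) are
config-exposed conventions, not derived values. Expert Guidance seeds
decoding with `Final diagnosis:` or `Final diagnosis: <label>.`; Classifier
Guidance fits a small scikit-learn classifier (multinomial logistic by
default; a 100-unit single-hidden-layer MLP for one-vs-rest tasks) on pooled
slide latents restricted to a label subset, so its prediction can never
leave the allowed subset. Ensemble Refinement draws k = 10 samples by
default, each with a seed spawned deterministically from the base seed; the
reference aggregator is an ordered per-section sentence union with
exact-duplicate removal (a pluggable slot for an external summarizer), and
an aggregator failure falls back to the sample with the highest
self-likelihood, with a warning.

Field extraction is rule-based and explicit about absence: thickness is the
first decimal number (dot or comma) followed by `mm` near a thickness cue;
margin status is a negation-aware keyword rule over a small configurable
lexicon evaluated in windows around each `margin` mention, negative cues
taking precedence; a missing field returns a NOT_FOUND sentinel, never a
default.

## Gradient-attention saliency

For patch i and latent j, G[i, j] is the L1 norm over feature dimensions of
the gradient of latent j's mean activation with respect to patch i's
feature vector. The per-latent gradient of a latent *vector* with respect
to a patch *vector* is a matrix; collapsing it requires two reductions
(over latent dims and over feature dims), and the choice — differentiate
the mean activation, then L1 over feature dims — is isolated in one
function so L2 or max variants are one-line swaps. The attention weights
come from the last XATTN layer of a forward pass over the report tokens,
averaged over heads and renormalized to the simplex. Given target tokens T,
the latent weight vector is the mean of rows A[T]; the raw patch score is
the mean over latents of G weighted by that vector; min-max normalization
maps scores to [0, 1], with an all-equal raw vector (including n = 1)
defined as all ones to avoid 0/0. Scaling G by c scales raw scores by c and
leaves the normalized map unchanged.

## Evaluation metrics

Keyword extraction is dictionary-based (case-insensitive whole-phrase
matches on word boundaries; overlapping vocabulary entries all count; each
term once) behind a pluggable extractor interface that a biomedical NER
model can implement. Fuzzy occurrence uses Ratcliff–Obershelp similarity —
2M/(|a|+|b|) with M from recursively located longest matching blocks, via
`difflib` with autojunk disabled — over windows of the text with the same
word count as the term, at cutoff 0.6; both sides are lowercased and
whitespace-normalized. Two empty strings are defined as similarity 1.

The keyword score is a Jaccard index. The union is R ∪ G (terms extracted
from either text) and a term is matched when it is fuzzy-findable in *both*
texts; this symmetric completion of the metric is the one deliberate
definitional choice here, and `union_mode="reference_only"` switches to
pure recall against the reference terms. If both term sets are empty the
score is defined as 1 for identical texts and 0 otherwise, flagged as
degenerate. Embedding similarity is the cosine of pluggable text
embeddings (a bag-of-words count embedder ships as the deterministic
reference); zero vectors are an error. Lower/upper baselines score random
cross-diagnosis and same-diagnosis report pairs respectively, returning
per-pair scores with mean ± sd under a fixed seed.

Note that Ratcliff–Obershelp is not symmetric in its arguments for all
inputs (flank recursion order matters), so the test oracle is the recursive
block-count definition itself, compared exactly.

## Synthetic data: what it does and does not show

Toy slides are 96×96 rasters: pink dermis with speckled nuclei (providing
Canny edge texture), a darker epidermis band ending at row 10, a white
glass margin on the right quarter, and — for lesion classes — an ellipse of
class-specific color growing downward from the epidermis, with one pixel
guaranteed at the nominal depth so thickness is exact. Thickness is
(deepest lesion row − 10) × 0.01 mm/px, placing values in the clinically
familiar 0–5 mm range. Class counts follow a deterministic power law
(largest-remainder rounding, minimum one patient per class), so the
rank-frequency slope and near-uniformity at exponent 0 are generator
properties rather than sampling accidents. Reports are templated with the
class's marker keywords always present and class-exclusive, which makes
keyword recall exact by construction.

These conditions validate mechanism, not clinical performance: color-coded
lesions are linearly separable where real histology is not; templated
reports have no linguistic variety beyond the paraphrase providers; the
toy patch encoder is a handcrafted descriptor, not a learned
representation. Passing the suite shows the pipeline's algorithms are
implemented correctly and trainable, not that they reach any particular
accuracy on real slides.

## Benchmark problem sizes

The standing benchmarks use deliberately small instances: a 60-patient
balanced 3-class corpus (45 train / 15 held out) for MIL recovery; a
4-patient, 4-class corpus for the memorization run, where a 2-layer 64-dim
fused model with only its XATTN blocks trainable reaches 100% greedy
token accuracy within 500 updates (peak lr 1e-2 with 10 warmup epochs for
this run — the tiny model tolerates and needs a higher peak than the
full-scale default — and an early stop once accuracy is perfect); 100
random (G, A, span) instances for the saliency oracle; 10,000 draws on a
10-symbol vocabulary for the sampler's chi-square check. The default
640 × 1536 encoder geometry is verified by a single forward pass on 100
random patches.

## Known limitations

- The numpy autodiff core is single-threaded-friendly but allocates per-op;
  it is sized for the desk-scale models here, not for production training.
- `compute_G` runs one backward pass per latent, which is exact but O(m)
  passes; fine for small m, expensive at m = 640.
- The whitespace tokenizer guarantees loss-free round trips only on
  whitespace-normalized text, and its character offsets (used to locate
  saliency targets) assume the report text it is applied to.
- Background filtering recomputes Canny per patch; thresholds (white 0.90,
  edge fraction 0.02) were chosen so toy fixtures split cleanly and are
  config-exposed, as no principled universal values exist.
- Resampler depth/heads and the XATTN inner geometry are conventions, not
  fitted values; both are exposed in configs for ablation.
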