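import numpy as np
import pytest

from pathreport.fusion_lm import (
    CausalLM,
    FusedLM,
    FusionConfig,
    LMConfig,
    WhitespaceTokenizer,
)
from pathreport.preprocessing import (
    ToyPatchEncoder,
    concat_patchsets,
    encode_patches,
    filter_background,
    normalize_patches,
    tile_image,
)
from pathreport.slide_encoder import ResamplerConfig
from pathreport.synthetic import make_corpus


TINY_RESAMPLER = ResamplerConfig(input_dim=32, n_latents=8, latent_dim=32, depth=1, n_heads=4)


def encode_corpus(corpus, dim=32, patch_size=32):
    """Tile, filter, normalize, and encode every patient of a toy corpus."""
    enc = ToyPatchEncoder(dim=dim, seed=0)
    classes = list(corpus.classes)
    out = []
    for p in corpus.patients:
        per_slide = []
        for s in p.slides:
            ps = tile_image(
                s.image, patch_size=patch_size, downsample=1, resize_to=None,
                z=s.slide_index, patient_id=p.patient_id,
            )
            per_slide.append(normalize_patches(filter_background(ps)))
        out.append((encode_patches(concat_patchsets(per_slide), enc), classes.index(p.label)))
    return out


@pytest.fixture(scope="session")
def corpus60():
    """Balanced separable 3-class corpus of 60 patients."""
    return make_corpus(60, 0.0, rng_seed=11)


@pytest.fixture(scope="session")
def encoded60(corpus60):
    return encode_corpus(corpus60)


@pytest.fixture(scope="session")
def corpus4():
    """Four patients, four distinct classes — the memorization workload."""
    return make_corpus(
        4,
        0.0,
        rng_seed=3,
        classes=(
            "background_only",
            "basal_cell_carcinoma",
            "seborrheic_keratosis",
            "melanocytic_nevus",
        ),
    )


def tiny_fused(vocab_size: int, latent_dim: int = 32, dim: int = 64, seed: int = 0):
    rng = np.random.default_rng(seed)
    lm = CausalLM(
        LMConfig(vocab_size=vocab_size, dim=dim, n_layers=2, n_heads=4, max_len=96), rng
    )
    return lm, FusedLM(lm, FusionConfig(latent_dim=latent_dim), rng)


@pytest.fixture()
def tokenizer4(corpus4):
    return WhitespaceTokenizer([p.report.text for p in corpus4.patients])
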