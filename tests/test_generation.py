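"""Decoding, guidance, ensemble refinement, and field extraction."""

import numpy as np
import pytest
from scipy import stats

from pathreport.fusion_lm import SlideReportModel, WhitespaceTokenizer
from pathreport.generation import (
    NOT_FOUND,
    GenerationConfig,
    LabelLookup,
    classifier_guidance,
    ensemble_refine,
    expert_prompt,
    extract_field,
    generate,
    sample_next_token,
    sentence_union_aggregate,
)
from pathreport.nn import Tensor
from pathreport.report import Report
from pathreport.report_eval import VocabularyExtractor, extract_keywords
from pathreport.slide_encoder import PerceiverResampler, ResamplerConfig, SlideLatents

from conftest import tiny_fused


def brute_force_distribution(logits, config):
    """Independent enumeration of the truncated-renormalized distribution."""
    z = logits / config.temperature
    p = np.exp(z - z.max())
    p /= p.sum()
    order = np.argsort(-p, kind="stable")[: config.top_k]
    kept = []
    cum = 0.0
    for idx in order:
        kept.append(idx)
        cum += p[idx]
        if cum >= config.top_p:
            break
    out = np.zeros_like(p)
    for idx in kept:
        out[idx] = p[idx]
    return out / out.sum()


class TestSampler:
    def test_top_k_one_is_argmax(self):
        rng = np.random.default_rng(0)
        logits = np.array([0.1, 3.0, 1.0])
        cfg = GenerationConfig(top_k=1)
        assert all(sample_next_token(logits, cfg, rng) == 1 for _ in range(20))

    def test_temperature_zero_is_argmax(self):
        rng = np.random.default_rng(0)
        assert sample_next_token(np.array([0.0, 5.0, 1.0]), GenerationConfig(temperature=0.0), rng) == 1

    def test_nucleus_smallest_covering_prefix(self):
        rng = np.random.default_rng(1)
        logits = np.log(np.array([0.6, 0.3, 0.1]))
        cfg = GenerationConfig(temperature=1.0, top_p=0.5, top_k=10)
        assert {sample_next_token(logits, cfg, rng) for _ in range(200)} == {0}

    @pytest.mark.parametrize("top_k,top_p", [(10, 1.0), (4, 1.0), (10, 0.7), (3, 0.6)])
    def test_empirical_frequencies_match_brute_force(self, top_k, top_p):
        rng = np.random.default_rng(42)
        logits = np.random.default_rng(5).normal(size=10)
        cfg = GenerationConfig(temperature=1.0, top_p=top_p, top_k=top_k)
        expected = brute_force_distribution(logits, cfg)
        draws = np.array([sample_next_token(logits, cfg, rng) for _ in range(10000)])
        observed = np.bincount(draws, minlength=10)
        support = expected > 0
        assert set(np.flatnonzero(observed)) <= set(np.flatnonzero(support))
        p = stats.chisquare(observed[support], expected[support] * 10000).pvalue
        assert p > 0.01


class TestExpertPrompt:
    def test_bare_marker_without_label(self):
        assert expert_prompt(None) == "Final diagnosis:"

    def test_label_formatted_with_period(self):
        assert expert_prompt("Scar") == "Final diagnosis: Scar."

    def test_empty_string_treated_as_none(self):
        assert expert_prompt("") == "Final diagnosis:"


def _model(vocab_texts, latent_dim=16):
    tok = WhitespaceTokenizer(vocab_texts)
    lm, fused = tiny_fused(vocab_size=tok.vocab_size, latent_dim=latent_dim, dim=32)
    rs = PerceiverResampler(
        ResamplerConfig(input_dim=8, n_latents=4, latent_dim=latent_dim, depth=1, n_heads=2),
        np.random.default_rng(3),
    )
    return SlideReportModel(rs, fused, tok)


class TestGenerate:
    TEXTS = ["Final diagnosis: Scar. Microscopic findings: scar tissue. Critical findings: Scar."]

    def test_fixed_seed_is_deterministic(self):
        model = _model(self.TEXTS)
        lat = SlideLatents(np.random.default_rng(0).normal(size=(4, 16)))
        cfg = GenerationConfig(max_tokens=20, seed=7)
        a = generate(model, lat, "Final diagnosis:", cfg)
        b = generate(model, lat, "Final diagnosis:", cfg)
        assert a.text == b.text

    def test_untrained_fusion_matches_bare_lm_generation(self):
        model = _model(self.TEXTS)
        lat = SlideLatents(np.random.default_rng(1).normal(size=(4, 16)))
        cfg = GenerationConfig(temperature=0.0, max_tokens=15, seed=0)
        fused_out = generate(model, lat, "Final diagnosis:", cfg)
        bare_out = generate(model, None, "Final diagnosis:", cfg)
        assert fused_out.text == bare_out.text

    def test_unencoded_patchset_rejected(self):
        from pathreport.preprocessing import PatchSet

        model = _model(self.TEXTS)
        raw = PatchSet(
            coords=np.array([[0, 0, 0]]),
            patches=np.zeros((1, 8, 8, 3)),
            patch_size_px=8,
        )
        with pytest.raises(ValueError):
            generate(model, raw, "Final diagnosis:", GenerationConfig())


class TestClassifierGuidance:
    def test_separable_features_recovered_and_prompted(self):
        rng = np.random.default_rng(0)
        a = rng.normal(loc=+3, size=(30, 16))
        b = rng.normal(loc=-3, size=(30, 16))
        feats = np.vstack([a, b])
        labels = ["Scar"] * 30 + ["Basal cell carcinoma"] * 30
        lat = SlideLatents(rng.normal(loc=+3, size=(4, 16)))
        prompt = classifier_guidance(lat, ["Scar", "Basal cell carcinoma"], feats, labels)
        assert prompt == "Final diagnosis: Scar."

    def test_prediction_always_inside_subset(self):
        rng = np.random.default_rng(1)
        feats = rng.normal(size=(40, 8))
        labels = ["a"] * 10 + ["b"] * 10 + ["c"] * 20
        for _ in range(25):
            lat = SlideLatents(rng.normal(size=(4, 8)) * 10)
            prompt = classifier_guidance(lat, ["a", "b"], feats, labels)
            assert prompt in ("Final diagnosis: a.", "Final diagnosis: b.")

    def test_mlp_variant_and_label_lookup(self):
        rng = np.random.default_rng(2)
        feats = np.vstack([rng.normal(+2, size=(25, 8)), rng.normal(-2, size=(25, 8))])
        labels = ["0"] * 25 + ["1"] * 25
        lookup = LabelLookup({0: "Melanoma", 1: "Benign melanocytic nevus"})
        lat = SlideLatents(rng.normal(-2, size=(4, 8)))
        prompt = classifier_guidance(lat, ["0", "1"], feats, labels, lookup=lookup, hidden=100)
        assert prompt == "Final diagnosis: Benign melanocytic nevus."

    def test_missing_subset_class_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            classifier_guidance(
                SlideLatents(rng.normal(size=(4, 8))),
                ["a", "b"],
                rng.normal(size=(5, 8)),
                ["a"] * 5,
            )


class TestEnsembleRefine:
    TEXTS = [
        "Final diagnosis: Scar. Microscopic findings: scar tissue with collagen. "
        "Critical findings: Scar."
    ]

    def test_greedy_samples_collapse_to_single_report(self):
        model = _model(self.TEXTS)
        lat = SlideLatents(np.random.default_rng(0).normal(size=(4, 16)))
        cfg = GenerationConfig(temperature=0.0, max_tokens=12, seed=3)
        combined, samples = ensemble_refine(model, lat, "Final diagnosis:", k=4, config=cfg)
        assert len({s.text for s in samples}) == 1
        assert combined.text == sentence_union_aggregate(samples[:1]).text

    def test_k_one_aggregate_equals_sample(self):
        model = _model(self.TEXTS)
        lat = SlideLatents(np.random.default_rng(1).normal(size=(4, 16)))
        cfg = GenerationConfig(max_tokens=12, seed=3)
        combined, samples = ensemble_refine(model, lat, "Final diagnosis:", k=1, config=cfg)
        assert combined.text == sentence_union_aggregate(samples).text

    def test_deterministic_for_fixed_seed(self):
        model = _model(self.TEXTS)
        lat = SlideLatents(np.random.default_rng(2).normal(size=(4, 16)))
        cfg = GenerationConfig(max_tokens=12, seed=9)
        a, _ = ensemble_refine(model, lat, "Final diagnosis:", k=3, config=cfg)
        b, _ = ensemble_refine(model, lat, "Final diagnosis:", k=3, config=cfg)
        assert a.text == b.text

    def test_aggregate_covers_every_sample_keyword(self):
        """Sentence-union aggregation never loses a keyword present in any
        individual sample."""
        vocab = ["scar", "collagen", "acanthosis", "tumor"]
        extractor = VocabularyExtractor(vocab)
        reports = [
            Report("Final diagnosis: Scar. Microscopic findings: scar tissue. Critical findings: Scar."),
            Report("Final diagnosis: Scar. Microscopic findings: collagen and acanthosis. Critical findings: Scar."),
            Report("Final diagnosis: Tumor. Microscopic findings: tumor cells. Critical findings: Tumor."),
        ]
        combined = sentence_union_aggregate(reports)
        union = set()
        for r in reports:
            union |= extract_keywords(r.text, extractor)
        assert extract_keywords(combined.text, extractor) >= union

    def test_failing_aggregator_falls_back_with_warning(self):
        model = _model(self.TEXTS)
        lat = SlideLatents(np.random.default_rng(3).normal(size=(4, 16)))
        cfg = GenerationConfig(max_tokens=10, seed=1)

        def broken(reports):
            raise RuntimeError("remote aggregator unavailable")

        with pytest.warns(UserWarning):
            combined, samples = ensemble_refine(
                model, lat, "Final diagnosis:", k=3, config=cfg, aggregator=broken
            )
        assert combined.text in {s.text for s in samples}


class TestFieldExtraction:
    def test_thickness_sentence_parsed(self):
        assert extract_field("The tumor thickness is 1.2 mm", "thickness_mm") == 1.2

    def test_thickness_comma_decimal_and_no_space(self):
        assert extract_field("Tumor thickness is 0,8mm", "thickness_mm") == 0.8

    def test_unknown_thickness_not_found(self):
        assert extract_field("The tumor thickness is unknown", "thickness_mm") is NOT_FOUND

    def test_diagnosis_delimited_by_next_marker(self):
        text = "Final diagnosis: Scar. Microscopic findings: compact orthohyperkeratosis."
        assert extract_field(text, "diagnosis") == "Scar"

    def test_margin_rules(self):
        assert extract_field("The lateral margin is free of tumor.", "margin_status") == "negative"
        assert extract_field("Tumor extends to the margin; margin involved.", "margin_status") == "positive"
        assert extract_field("No margin is mentioned... actually none", "margin_status") is NOT_FOUND
        assert extract_field("completely unrelated text", "margin_status") is NOT_FOUND

    def test_unknown_field_rejected(self):
        with pytest.raises(ValueError):
            extract_field("text", "grade")
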