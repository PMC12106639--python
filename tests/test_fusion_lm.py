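"""Fusion contracts: gated cross-attention, causal loss, freeze policy."""

import hashlib

import numpy as np
import pytest

from pathreport.fusion_lm import (
    CausalLM,
    FusedLM,
    FusionConfig,
    LMConfig,
    TokenSequence,
    WhitespaceTokenizer,
    XATTNBlock,
    apply_freeze_policy,
    lm_loss,
)
from pathreport.nn import AdamW, Tensor, no_grad
from pathreport.slide_encoder import PerceiverResampler, ResamplerConfig

from conftest import tiny_fused


def state_hash(module):
    h = hashlib.sha256()
    for k, arr in sorted(module.state_dict().items()):
        h.update(k.encode())
        h.update(arr.tobytes())
    return h.hexdigest()


class TestTokenizer:
    def test_round_trip_on_normalized_text(self):
        text = "Final diagnosis: Scar. Microscopic findings: dense collagen."
        tok = WhitespaceTokenizer([text])
        assert tok.decode(tok.encode(text)) == text

    def test_unknown_words_map_to_unk(self):
        tok = WhitespaceTokenizer(["alpha beta"])
        ids = tok.encode("alpha gamma")
        assert ids[1] == tok.unk_id

    def test_offsets_align_with_source(self):
        text = "one  two three"
        tok = WhitespaceTokenizer([text])
        ids, spans = tok.encode_with_offsets(text)
        assert [text[s:e] for s, e in spans] == ["one", "two", "three"]

    def test_token_sequence_validates_range(self):
        with pytest.raises(ValueError):
            TokenSequence(ids=np.array([99]), vocabulary_size=10)


class TestXATTN:
    def test_zero_gate_is_identity(self):
        rng = np.random.default_rng(0)
        blk = XATTNBlock(16, 8, 2, rng, gate_init=0.0)
        hidden = Tensor(rng.normal(size=(5, 16)))
        latents = Tensor(rng.normal(size=(3, 8)))
        out = blk(hidden, latents)
        assert np.array_equal(out.numpy(), hidden.numpy())

    def test_zero_latents_pass_hidden_through(self):
        rng = np.random.default_rng(1)
        blk = XATTNBlock(16, 8, 2, rng, gate_init=2.0)
        blk.attn.v_proj.bias.data[:] = 0.0
        blk.attn.out_proj.bias.data[:] = 0.0
        hidden = Tensor(rng.normal(size=(5, 16)))
        out = blk(hidden, Tensor(np.zeros((3, 8))))
        assert np.allclose(out.numpy(), hidden.numpy(), atol=1e-12)

    def test_gate_weight_saturates_monotonically(self):
        assert np.tanh(0.0) == 0.0
        gates = np.tanh(np.linspace(0, 10, 50))
        assert (np.diff(gates) >= 0).all() and gates[-1] == pytest.approx(1.0, abs=1e-8)


class TestLMLoss:
    def test_uniform_logits_give_log_vocab(self):
        class UniformModel:
            class lm:
                class config:
                    max_len = 64

            def __call__(self, ids, latents=None):
                return Tensor(np.zeros((len(ids), 50)))

        loss = lm_loss(UniformModel(), np.arange(10) % 50)
        assert float(loss.numpy()) == pytest.approx(np.log(50), abs=1e-9)

    def test_causality_earlier_terms_unchanged(self):
        lm, fused = tiny_fused(vocab_size=30)
        ids = np.array([1, 5, 9, 2, 7, 3])
        lat = Tensor(np.random.default_rng(4).normal(size=(6, 32)))

        def per_position_losses(ids):
            with no_grad():
                logits = fused(ids, lat).numpy()
            out = []
            for t in range(len(ids) - 1):
                z = logits[t] - logits[t].max()
                p = np.exp(z) / np.exp(z).sum()
                out.append(-np.log(p[ids[t + 1]]))
            return out

        base = per_position_losses(ids)
        mutated = ids.copy()
        mutated[-1] = 11
        changed = per_position_losses(mutated)
        assert np.allclose(base[:-1], changed[:-1])

    def test_loss_matches_per_position_loop_oracle(self):
        lm, fused = tiny_fused(vocab_size=30)
        ids = np.array([1, 5, 9, 2, 7, 3])
        lat = Tensor(np.random.default_rng(4).normal(size=(6, 32)))
        with no_grad():
            logits = fused(ids, lat).numpy()
        manual = []
        for t in range(len(ids) - 1):
            z = logits[t] - logits[t].max()
            p = np.exp(z) / np.exp(z).sum()
            manual.append(-np.log(p[ids[t + 1]]))
        loss = lm_loss(fused, ids, lat)
        assert float(loss.numpy()) == pytest.approx(np.mean(manual), abs=1e-6)

    def test_length_one_sequence_rejected(self):
        lm, fused = tiny_fused(vocab_size=30)
        with pytest.raises(ValueError):
            lm_loss(fused, np.array([3]))


class TestFusionIdentity:
    def test_fused_equals_bare_lm_at_init(self):
        lm, fused = tiny_fused(vocab_size=40)
        ids = np.array([1, 2, 3, 4])
        lat = Tensor(np.random.default_rng(0).normal(size=(6, 32)))
        with no_grad():
            assert np.array_equal(fused(ids, lat).numpy(), lm(ids).numpy())


class TestFreezePolicy:
    def _model(self):
        from pathreport.fusion_lm import SlideReportModel

        rs = PerceiverResampler(
            ResamplerConfig(input_dim=8, n_latents=4, latent_dim=32, depth=1, n_heads=2),
            np.random.default_rng(0),
        )
        lm, fused = tiny_fused(vocab_size=30)
        tok = WhitespaceTokenizer(["a b c"])
        return SlideReportModel(rs, fused, tok)

    def test_report_finetune_trains_only_xattn(self):
        model = apply_freeze_policy(self._model(), "report_finetune")
        assert not any(p.requires_grad for p in model.resampler.parameters())
        assert not any(p.requires_grad for p in model.fused.lm.parameters())
        for blk in model.fused.xattn_blocks:
            assert all(p.requires_grad for p in blk.parameters())

    def test_trainable_count_equals_xattn_total(self):
        model = apply_freeze_policy(self._model(), "report_finetune")
        trainable = sum(p.data.size for p in model.fused.parameters() if p.requires_grad)
        xattn = sum(p.data.size for blk in model.fused.xattn_blocks for p in blk.parameters())
        assert trainable == xattn

    def test_unknown_phase_rejected(self):
        with pytest.raises(ValueError):
            apply_freeze_policy(self._model(), "contrastive")

    def test_frozen_weights_unchanged_after_updates(self):
        model = apply_freeze_policy(self._model(), "report_finetune")
        lm_hash = state_hash(model.fused.lm)
        rs_hash = state_hash(model.resampler)
        xattn_before = [blk.state_dict() for blk in model.fused.xattn_blocks]
        trainable = [p for p in model.fused.parameters() if p.requires_grad]
        opt = AdamW(trainable, lr=1e-2)
        lat = Tensor(np.random.default_rng(1).normal(size=(4, 32)))
        ids = np.array([1, 4, 2, 9, 3])
        for _ in range(10):
            opt.zero_grad()
            lm_loss(model.fused, ids, lat).backward()
            opt.step()
        assert state_hash(model.fused.lm) == lm_hash
        assert state_hash(model.resampler) == rs_hash
        changed = any(
            not np.array_equal(before[k], after)
            for blk, before in zip(model.fused.xattn_blocks, xattn_before)
            for k, after in blk.state_dict().items()
        )
        assert changed

    def test_gate_receives_gradient(self):
        model = apply_freeze_policy(self._model(), "report_finetune")
        lat = Tensor(np.random.default_rng(2).normal(size=(4, 32)))
        ids = np.array([1, 4, 2, 9, 3])
        lm_loss(model.fused, ids, lat).backward()
        grads = [abs(float(blk.gate.grad)) for blk in model.fused.xattn_blocks if blk.gate.grad is not None]
        assert grads and max(grads) > 0
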