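"""Run configuration and pipeline orchestration.

A :class:`RunConfig` is a schema-validated, nested configuration (unknown
keys are rejected before any stage runs).  :func:`run_pipeline` executes
an ordered stage list — simulate, preprocess, pretrain, train, generate,
evaluate — writing artifacts and a manifest that records the config
hash, derived seeds, and per-stage outputs, so identical config + seed
reproduces identical outputs.

Every stochastic stage consumes a seed derived from the global seed and
the stage name: ``SeedSequence([seed, crc32(stage)])``, reduced mod 2^31.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

logger = logging.getLogger("pathreport")

__all__ = ["RunConfig", "run_pipeline", "derive_seed", "load_config"]

STAGES = ("simulate", "preprocess", "pretrain", "train", "generate", "evaluate")


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSection(_Section):
    n_patients: int = 24
    imbalance_exponent: float = 0.0
    slide_size: int = 96


class PreprocessSection(_Section):
    patch_size: int = 32
    downsample: int = 1
    resize_to: int | None = None
    white_threshold: float = 0.90
    edge_fraction_threshold: float = 0.02
    encoder_dim: int = 32


class ResamplerSection(_Section):
    n_latents: int = 8
    latent_dim: int = 32
    depth: int = 1
    n_heads: int = 4
    use_position_embedding: bool = False


class MILSection(_Section):
    epochs: int = 25
    lr: float = 3e-3


class LMSection(_Section):
    dim: int = 32
    n_layers: int = 2
    n_heads: int = 4
    max_len: int = 160


class TrainingSection(_Section):
    total_epochs: int = 20
    warmup_epochs: int = 2
    peak_lr: float = 1e-2
    final_lr_ratio: float = 0.1
    grad_accum: int = 4
    clip_norm: float = 1.0
    n_augmentations: int = 0


class GenerationSection(_Section):
    temperature: float = 0.8
    top_p: float = 0.95
    top_k: int = 50
    max_tokens: int = 96
    prompt_mode: str = "expert"  # none | expert | classifier


class EvaluationSection(_Section):
    cutoff: float = 0.6


class RunConfig(_Section):
    seed: int = 0
    outdir: str = "runs/toy"
    simulate: SimulateSection = Field(default_factory=SimulateSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    resampler: ResamplerSection = Field(default_factory=ResamplerSection)
    mil: MILSection = Field(default_factory=MILSection)
    lm: LMSection = Field(default_factory=LMSection)
    training: TrainingSection = Field(default_factory=TrainingSection)
    generation: GenerationSection = Field(default_factory=GenerationSection)
    evaluation: EvaluationSection = Field(default_factory=EvaluationSection)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update(overrides)
    return RunConfig(**data)


def derive_seed(global_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


class MissingArtifactError(RuntimeError):
    pass


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"stage {stage!r} requires {path} — run the {produced_by!r} stage first"
        )
    return path


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in order; returns the manifest dict."""
    from . import __version__, synthetic
    from .fusion_lm import (
        CausalLM,
        FusedLM,
        FusionConfig,
        LMConfig,
        SlideReportModel,
        WhitespaceTokenizer,
        apply_freeze_policy,
    )
    from .generation import GenerationConfig, expert_prompt, generate
    from .io import load_checkpoint, save_checkpoint
    from .preprocessing import (
        ToyPatchEncoder,
        concat_patchsets,
        encode_patches,
        filter_background,
        load_features,
        normalize_patches,
        save_features,
        tile_image,
    )
    from .report import Report
    from .report_eval import VocabularyExtractor, keyword_jaccard
    from .slide_encoder import MILTrainSettings, PerceiverResampler, ResamplerConfig, pretrain_mil
    from .training import TrainConfig, train_report_model
    from .nn import Tensor, no_grad

    stages = list(stages) if stages is not None else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "config_hash": config_hash(config),
        "seed": config.seed,
        "stage_seeds": {s: derive_seed(config.seed, s) for s in stages},
        "stages": {},
    }

    rcfg = ResamplerConfig(
        input_dim=config.preprocess.encoder_dim,
        n_latents=config.resampler.n_latents,
        latent_dim=config.resampler.latent_dim,
        depth=config.resampler.depth,
        n_heads=config.resampler.n_heads,
        use_position_embedding=config.resampler.use_position_embedding,
    )
    class_names = list(synthetic.DEFAULT_CORPUS_CLASSES)

    def rebuild_corpus():
        return synthetic.make_corpus(
            config.simulate.n_patients,
            config.simulate.imbalance_exponent,
            rng_seed=derive_seed(config.seed, "simulate"),
            slide_size=config.simulate.slide_size,
        )

    for stage in stages:
        seed = derive_seed(config.seed, stage)
        logger.info("stage=%s seed=%d", stage, seed)
        outputs: list[str] = []

        if stage == "simulate":
            corpus = rebuild_corpus()
            synthetic.write_corpus(corpus, out / "data")
            outputs.append(str(out / "data"))

        elif stage == "preprocess":
            _require(out / "data" / "labels.tsv", stage, "simulate")
            corpus = rebuild_corpus()
            encoder = ToyPatchEncoder(dim=config.preprocess.encoder_dim, seed=seed)
            patchsets = []
            for p in corpus.patients:
                per_slide = []
                for s in p.slides:
                    ps = tile_image(
                        s.image,
                        patch_size=config.preprocess.patch_size,
                        downsample=config.preprocess.downsample,
                        resize_to=config.preprocess.resize_to,
                        z=s.slide_index,
                        patient_id=p.patient_id,
                    )
                    ps = filter_background(
                        ps,
                        config.preprocess.white_threshold,
                        config.preprocess.edge_fraction_threshold,
                    )
                    per_slide.append(normalize_patches(ps))
                merged = concat_patchsets(per_slide)
                patchsets.append(encode_patches(merged, encoder))
            save_features(out / "features.h5", patchsets)
            outputs.append(str(out / "features.h5"))

        elif stage == "pretrain":
            _require(out / "features.h5", stage, "preprocess")
            corpus = rebuild_corpus()
            labels = {p.patient_id: class_names.index(p.label) for p in corpus.patients}
            sets = load_features(out / "features.h5")
            data = [(ps, labels[ps.patient_id]) for ps in sets]
            resampler, log = pretrain_mil(
                data,
                rcfg,
                MILTrainSettings(epochs=config.mil.epochs, lr=config.mil.lr, seed=seed),
                n_classes=len(class_names),
            )
            save_checkpoint(resampler, out / "resampler.npz", rcfg)
            (out / "pretrain_log.json").write_text(json.dumps(log, indent=2))
            outputs += [str(out / "resampler.npz"), str(out / "pretrain_log.json")]

        elif stage == "train":
            _require(out / "resampler.npz", stage, "pretrain")
            corpus = rebuild_corpus()
            rng = np.random.default_rng(seed)
            resampler = load_checkpoint(PerceiverResampler(rcfg, rng), out / "resampler.npz")
            texts = [p.report.text for p in corpus.patients]
            tokenizer = WhitespaceTokenizer(texts)
            lm = CausalLM(
                LMConfig(
                    vocab_size=tokenizer.vocab_size,
                    dim=config.lm.dim,
                    n_layers=config.lm.n_layers,
                    n_heads=config.lm.n_heads,
                    max_len=config.lm.max_len,
                ),
                rng,
            )
            fused = FusedLM(lm, FusionConfig(latent_dim=rcfg.latent_dim), rng)
            model = SlideReportModel(resampler, fused, tokenizer)
            apply_freeze_policy(model, "report_finetune")
            sets = load_features(out / "features.h5")
            pairs = []
            for ps in sets:
                with no_grad():
                    lat = resampler(ps.features, ps.coords).detach()
                pid = ps.patient_id
                report = next(p.report for p in corpus.patients if p.patient_id == pid)
                ids = tokenizer.encode(report.text, add_bos=True, add_eos=True)
                pairs.append((lat, ids))
            tcfg = TrainConfig(
                peak_lr=config.training.peak_lr,
                warmup_epochs=config.training.warmup_epochs,
                total_epochs=config.training.total_epochs,
                final_lr_ratio=config.training.final_lr_ratio,
                grad_accum=config.training.grad_accum,
                clip_norm=config.training.clip_norm,
                seed=seed,
            )
            log = train_report_model(model, pairs, tcfg)
            save_checkpoint(fused, out / "fused.npz")
            from .training import write_train_log

            write_train_log(log, out / "train_log.tsv")
            (out / "tokenizer.json").write_text(json.dumps({"texts": texts}))
            outputs += [str(out / "fused.npz"), str(out / "train_log.tsv")]

        elif stage == "generate":
            _require(out / "fused.npz", stage, "train")
            corpus = rebuild_corpus()
            rng = np.random.default_rng(seed)
            resampler = load_checkpoint(PerceiverResampler(rcfg, rng), out / "resampler.npz")
            texts = json.loads((out / "tokenizer.json").read_text())["texts"]
            tokenizer = WhitespaceTokenizer(texts)
            lm = CausalLM(
                LMConfig(
                    vocab_size=tokenizer.vocab_size,
                    dim=config.lm.dim,
                    n_layers=config.lm.n_layers,
                    n_heads=config.lm.n_heads,
                    max_len=config.lm.max_len,
                ),
                rng,
            )
            fused = load_checkpoint(
                FusedLM(lm, FusionConfig(latent_dim=rcfg.latent_dim), rng), out / "fused.npz"
            )
            model = SlideReportModel(resampler, fused, tokenizer)
            gcfg = GenerationConfig(
                temperature=config.generation.temperature,
                top_p=config.generation.top_p,
                top_k=config.generation.top_k,
                max_tokens=config.generation.max_tokens,
                seed=seed,
            )
            gen_dir = out / "generated"
            gen_dir.mkdir(exist_ok=True)
            sets = load_features(out / "features.h5")
            registry = synthetic.DEFAULT_REGISTRY
            for ps in sets:
                patient = next(p for p in corpus.patients if p.patient_id == ps.patient_id)
                if config.generation.prompt_mode == "expert":
                    prompt = expert_prompt(registry[patient.label].diagnosis)
                else:
                    prompt = expert_prompt(None)
                rep = generate(model, ps, prompt, gcfg)
                (gen_dir / f"{ps.patient_id}.txt").write_text(rep.text, encoding="utf-8")
            outputs.append(str(gen_dir))

        elif stage == "evaluate":
            _require(out / "generated", stage, "generate")
            corpus = rebuild_corpus()
            extractor = VocabularyExtractor(corpus.vocabulary)
            rows = []
            for p in corpus.patients:
                gen_path = out / "generated" / f"{p.patient_id}.txt"
                if not gen_path.exists():
                    continue
                res = keyword_jaccard(
                    p.report,
                    Report(gen_path.read_text(encoding="utf-8")),
                    extractor,
                    cutoff=config.evaluation.cutoff,
                )
                rows.append(
                    {
                        "patient_id": p.patient_id,
                        "label": p.label,
                        "jaccard": res.jaccard,
                        "n_reference_terms": len(res.reference_terms),
                        "n_matched": len(res.matched),
                    }
                )
            import pandas as pd

            df = pd.DataFrame(rows)
            summary = {
                "patient_id": "MEAN",
                "label": "",
                "jaccard": df["jaccard"].mean(),
                "n_reference_terms": df["n_reference_terms"].mean(),
                "n_matched": df["n_matched"].mean(),
            }
            pd.concat([df, pd.DataFrame([summary])]).to_csv(
                out / "scores.tsv", sep="\t", index=False
            )
            outputs.append(str(out / "scores.tsv"))

        manifest["stages"][stage] = {"seed": seed, "outputs": outputs}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
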