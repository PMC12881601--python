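"""End-to-end wiring of the six segmentation/classification pipelines.

Pipeline naming follows the augmentation placement and the classifier input:

========================  =========================  ==========================
name                      segmentation training      classification input
========================  =========================  ==========================
Normal                    real images                original images
Nor_RES_DCGAN             real images                original + GAN augment
ROI                       real images                mask x image product (ROI)
ROI_RES_DCGAN             real images                ROI + GAN augment
RES_DCGAN_Nor             real + GAN augment         original images
RES_DCGAN_ROI             real + GAN augment         ROI
========================  =========================  ==========================

Augmentation placed before segmentation also flows into the classification
training pool; generated images never reach a test split (asserted on every
run).  Generated images used to train the segmenter receive automated
pseudo-masks, flagged as such in the manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify as clf
from . import gan as ganmod
from .fid import RandomProjectionEmbedding, compute_fid
from .metrics import ClfMetricReport, SegMetricReport, clf_metrics, pixel_confusion, seg_metrics
from .phantoms import LabeledSample
from .preprocess import apply_roi, binarize_prediction, resize_normalize, threshold_mask_from_image
from .splits import MixPolicy, SplitPlan, assert_no_generated_in_test, mix_for_stage, split_generated, split_real
from .unet import SegModelConfig, TrainConfig, build_unet, predict_mask, train_segmenter

__all__ = ["PIPELINE_NAMES", "PipelineConfig", "RunReport", "run_pipeline",
           "compare_pipelines", "desk_scale_config"]

PIPELINE_NAMES = ("Normal", "Nor_RES_DCGAN", "ROI", "ROI_RES_DCGAN",
                  "RES_DCGAN_Nor", "RES_DCGAN_ROI")

_PLACEMENT = {
    "Normal": "none",
    "Nor_RES_DCGAN": "after_segmentation",
    "ROI": "none",
    "ROI_RES_DCGAN": "after_segmentation",
    "RES_DCGAN_Nor": "before_segmentation",
    "RES_DCGAN_ROI": "before_segmentation",
}
_ROI_INPUT = {"ROI", "ROI_RES_DCGAN", "RES_DCGAN_ROI"}


@dataclass(frozen=True)
class PipelineConfig:
    pipeline: str
    image_size: int = 64
    seg_model: SegModelConfig = field(default_factory=lambda: SegModelConfig(
        input_size=64, depth=3, base_filters=8, norm="group", groups=8,
        encoder_dilation=2))
    seg_train: TrainConfig = field(default_factory=lambda: TrainConfig(
        max_epochs=20, stop_at_val_dice=0.97))
    gan_generator: ganmod.GeneratorConfig | None = None
    gan_discriminator: ganmod.DiscriminatorConfig | None = None
    gan_train: ganmod.GanTrainConfig | None = None
    generated_per_class: int = 40
    clf_modes: tuple = ("single_resnet",)
    clf_train: clf.ClfTrainConfig = field(default_factory=lambda: clf.ClfTrainConfig(
        max_epochs=30))
    split_plan: SplitPlan | None = None
    normal_input: str = "original"   # {original, predicted_mask, overlay}
    seed: int = 0

    def __post_init__(self):
        if self.pipeline not in PIPELINE_NAMES:
            raise ValueError(f"unknown pipeline {self.pipeline!r}")
        needs_gan = "RES_DCGAN" in self.pipeline
        if needs_gan and self.gan_generator is None:
            raise ValueError(f"{self.pipeline} requires a GAN configuration")
        for mode in self.clf_modes:
            if mode not in ("single_resnet", "voting", "concat_ensemble"):
                raise ValueError(f"unknown clf_mode {mode!r}")


def desk_scale_config(pipeline: str, seed: int = 0, image_size: int = 32,
                      clf_modes=("single_resnet",), **overrides) -> PipelineConfig:
    """A configuration small enough to run a full pipeline on a desk CPU."""
    gan_needed = "RES_DCGAN" in pipeline
    kw = dict(
        pipeline=pipeline, image_size=image_size,
        seg_model=SegModelConfig(input_size=image_size, depth=2, base_filters=6,
                                 norm="group", groups=6, encoder_dilation=2,
                                 dropout_rate=0.2),
        seg_train=TrainConfig(max_epochs=12, batch_size=18,
                              stop_at_val_dice=0.96, seed=seed),
        clf_modes=clf_modes,
        clf_train=clf.ClfTrainConfig(max_epochs=25, seed=seed),
        split_plan=SplitPlan(seed=seed),
        seed=seed,
    )
    if gan_needed:
        kw.update(
            gan_generator=ganmod.GeneratorConfig(
                latent_dim=32, seed_spatial=image_size // 16,
                stage_filters=(64, 32, 16, 8), output_size=image_size),
            gan_discriminator=ganmod.DiscriminatorConfig(
                input_size=image_size, layer_filters=(8, 16, 32, 64, 128)),
            gan_train=ganmod.GanTrainConfig(batch_size=16, steps=150,
                                            learning_rate=4e-4, seed=seed),
            generated_per_class=30,
        )
    kw.update(overrides)
    return PipelineConfig(**kw)


@dataclass
class RunReport:
    pipeline: str
    segmentation: SegMetricReport
    classification: dict            # clf_mode -> ClfMetricReport
    fid_per_class: dict             # class -> FID value (GAN pipelines only)
    provenance: dict

    def to_json(self) -> str:
        d = {
            "pipeline": self.pipeline,
            "segmentation": self.segmentation.as_percent_row(),
            "classification": {m: r.as_percent_row()
                               for m, r in self.classification.items()},
            "fid_per_class": self.fid_per_class,
            "provenance": self.provenance,
        }
        return json.dumps(d, indent=2, default=str)


def _train_per_class_gans(cfg: PipelineConfig, train_pool, classes, rng):
    """One generator per class, trained on that class's train+val real images."""
    gens = {}
    fids = {}
    emb = RandomProjectionEmbedding(dim=32, seed=0)
    for c in classes:
        imgs = np.stack([s.image for s in train_pool if s.label == c])
        size = cfg.gan_generator.output_size
        if imgs.shape[1] != size:
            imgs = np.stack([resize_normalize(im, size) for im in imgs])
        sub = int(rng.integers(2 ** 31))
        gen = ganmod.build_generator(cfg.gan_generator, np.random.default_rng(sub))
        disc = ganmod.build_discriminator(cfg.gan_discriminator,
                                          np.random.default_rng(sub + 1))
        gan_cfg = dataclasses.replace(cfg.gan_train, seed=sub)
        gen, _ = ganmod.train_gan(gen, disc, imgs, gan_cfg)
        gens[c] = gen
        fake = ganmod.sample_images(gen, len(imgs), seed=sub + 2)
        fids[c] = compute_fid(imgs, fake, embedding=emb).value
    return gens, fids


def _generated_samples(cfg: PipelineConfig, gens, classes, rng, with_masks):
    out = []
    for c in classes:
        n = cfg.generated_per_class
        imgs = ganmod.sample_images(gens[c], n, seed=int(rng.integers(2 ** 31)))
        for im in imgs:
            if im.shape[0] != cfg.image_size:
                im = resize_normalize(im, cfg.image_size)
            if with_masks:
                mask, _ = threshold_mask_from_image(im, threshold=0.1)
            else:
                mask = np.zeros(im.shape[:2], dtype=np.uint8)
            out.append(LabeledSample(image=im.astype(np.float32), mask=mask,
                                     label=c,
                                     meta={"origin": "generated",
                                           "mask_kind": "pseudo_threshold"
                                           if with_masks else "none"}))
    return out


def _clf_input(samples, masks_pred, pipeline, normal_input):
    """Classifier input images for one split, given predicted cell masks."""
    xs = []
    for s, m in zip(samples, masks_pred):
        if pipeline in _ROI_INPUT:
            xs.append(apply_roi(s.image, m))
        elif normal_input == "predicted_mask":
            xs.append(np.repeat(m[..., None].astype(np.float32), 3, axis=-1))
        elif normal_input == "overlay":
            xs.append(0.5 * s.image + 0.5 * m[..., None].astype(np.float32))
        else:
            xs.append(s.image)
    return np.stack(xs)


def _predict_masks_for(seg_model, samples):
    if not samples:
        return []
    x = np.stack([s.image for s in samples]).astype(np.float32)
    prob = predict_mask(seg_model, x)
    return [binarize_prediction(prob[i, ..., 0]) for i in range(len(samples))]


def run_pipeline(cfg: PipelineConfig, data, seg_cache: dict | None = None) -> RunReport:
    """Execute one named pipeline end to end on a labelled dataset.

    ``seg_cache`` (optional) shares trained segmentation stages between
    pipelines whose segmentation inputs and seed are identical, mirroring the
    reporting convention that such pipelines have one segmentation score.
    """
    for s in data:
        if s.mask is None:
            raise ValueError("every sample needs a ground-truth mask")
    classes = sorted({s.label for s in data}, key=str)
    label_ix = {c: i for i, c in enumerate(classes)}
    plan = cfg.split_plan or SplitPlan(seed=cfg.seed)
    real = split_real(data, plan)
    r_train, r_val, r_test = real
    assert_no_generated_in_test(r_test)
    rng = np.random.default_rng(cfg.seed)
    policy = MixPolicy(placement=_PLACEMENT[cfg.pipeline])

    # --- GAN augmentation (generated pool with 80/20 split)
    gen_split = ([], [])
    fids = {}
    if policy.placement != "none":
        gan_rng = np.random.default_rng([cfg.seed, 1])
        gens, fids = _train_per_class_gans(cfg, r_train + r_val, classes, gan_rng)
        with_masks = policy.placement == "before_segmentation"
        gen_samples = _generated_samples(cfg, gens, classes, gan_rng, with_masks)
        gen_split = split_generated(gen_samples, plan)

    # --- segmentation stage (cached across pipelines sharing it)
    seg_train_set, seg_val_set, seg_test_set = mix_for_stage(
        real, gen_split, policy, "segmentation")
    cache_key = (cfg.seg_model, cfg.seg_train, policy.applies("segmentation"),
                 cfg.seed)
    if seg_cache is not None and cache_key in seg_cache:
        seg_model, seg_report = seg_cache[cache_key]
    else:
        seg_model = build_unet(cfg.seg_model)
        seg_model, _hist = train_segmenter(seg_model, seg_train_set, seg_val_set,
                                           cfg.seg_train)
        test_masks = _predict_masks_for(seg_model, seg_test_set)
        conf = pixel_confusion(np.stack([s.mask for s in seg_test_set]),
                               np.stack(test_masks))
        seg_report = seg_metrics(conf)
        if seg_cache is not None:
            seg_cache[cache_key] = (seg_model, seg_report)

    # --- classification stage
    c_train, c_val, c_test = mix_for_stage(real, gen_split, policy, "classification")
    assert_no_generated_in_test(c_test)
    masks = {k: _predict_masks_for(seg_model, split)
             for k, split in (("train", c_train), ("val", c_val), ("test", c_test))}
    x_tr = _clf_input(c_train, masks["train"], cfg.pipeline, cfg.normal_input)
    x_va = _clf_input(c_val, masks["val"], cfg.pipeline, cfg.normal_input)
    x_te = _clf_input(c_test, masks["test"], cfg.pipeline, cfg.normal_input)
    y_tr = np.array([label_ix[s.label] for s in c_train])
    y_va = np.array([label_ix[s.label] for s in c_val])
    y_te = np.array([label_ix[s.label] for s in c_test])
    n_classes = len(classes)

    reports = {}
    for mode in cfg.clf_modes:
        mode_seed = int(np.random.default_rng([cfg.seed, 2]).integers(2 ** 31))
        tc = dataclasses.replace(cfg.clf_train, seed=mode_seed)
        if mode == "single_resnet":
            model = clf.build_single_classifier(
                clf.BackboneSpec("ResNet50V2", frozen=False), n_classes,
                input_size=cfg.image_size, rng=np.random.default_rng(mode_seed))
            model, _ = clf.train_classifier(model, x_tr, y_tr, x_va, y_va,
                                            tc, n_classes)
            y_hat = clf.predict(model, x_te).argmax(1)
        elif mode == "voting":
            votes = []
            for j, name in enumerate(clf.VOTING_MEMBER_NAMES):
                m = clf.build_single_classifier(
                    clf.BackboneSpec(name, frozen=False), n_classes,
                    input_size=cfg.image_size,
                    rng=np.random.default_rng(mode_seed + j))
                m, _ = clf.train_classifier(
                    m, x_tr, y_tr, x_va, y_va,
                    dataclasses.replace(tc, seed=mode_seed + j), n_classes)
                votes.append(clf.predict(m, x_te).argmax(1))
            y_hat = clf.majority_vote(np.stack(votes, axis=1))
        else:  # concat_ensemble
            ecfg = clf.ConcatEnsembleConfig(n_classes=n_classes,
                                            input_size=cfg.image_size)
            model = clf.build_concat_ensemble(ecfg, np.random.default_rng(mode_seed))
            model, _ = clf.train_classifier(model, x_tr, y_tr, x_va, y_va,
                                            tc, n_classes)
            y_hat = clf.predict(model, x_te).argmax(1)
        reports[mode] = clf_metrics(y_te, y_hat, n_classes)

    provenance = {
        "seed": cfg.seed,
        "pipeline": cfg.pipeline,
        "n_samples": len(data),
        "classes": classes,
        "split_sizes": {"train": len(r_train), "val": len(r_val),
                        "test": len(r_test)},
        "generated": {"train": len(gen_split[0]), "val": len(gen_split[1])},
        "placement": policy.placement,
    }
    return RunReport(pipeline=cfg.pipeline, segmentation=seg_report,
                     classification=reports, fid_per_class=fids,
                     provenance=provenance)


def compare_pipelines(cfgs: list[PipelineConfig], data) -> pd.DataFrame:
    """One row per pipeline: segmentation and classification metric columns.

    Pipelines sharing an identical segmentation stage report the shared score
    once; repeated rows carry the same value (the table notes the group).
    """
    if not cfgs:
        raise ValueError("need at least one pipeline config")
    seg_cache: dict = {}
    rows = []
    for cfg in cfgs:
        rep = run_pipeline(cfg, data, seg_cache=seg_cache)
        row = {"pipeline": rep.pipeline}
        row.update({f"seg_{k}": v for k, v in
                    rep.segmentation.as_percent_row().items()})
        for mode, r in rep.classification.items():
            row.update({f"{mode}_{k}": v for k, v in r.as_percent_row().items()})
        rows.append(row)
    return pd.DataFrame(rows)
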