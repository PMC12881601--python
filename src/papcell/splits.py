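"""Train/val/test partitioning and the GAN-augmentation mixing policy.

Real data is split 64/16/20 (train/val/test) and generated data 80/20
(train/val).  Generated images are only ever mixed into training and
validation sets; the real test set stays free of synthetic images so that it
can also certify GAN hygiene (it is never shown to the GAN either).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SplitPlan", "MixPolicy", "split_real", "split_generated",
           "mix_for_stage", "round_half_up", "split_manifest",
           "assert_no_generated_in_test"]


def round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class SplitPlan:
    real_fractions: tuple[float, float, float] = (0.64, 0.16, 0.20)
    generated_fractions: tuple[float, float] = (0.80, 0.20)
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.real_fractions) - 1) > 1e-9:
            raise ValueError("real fractions must sum to 1")
        if abs(sum(self.generated_fractions) - 1) > 1e-9:
            raise ValueError("generated fractions must sum to 1")


VALID_PLACEMENTS = ("before_segmentation", "after_segmentation", "none")


@dataclass(frozen=True)
class MixPolicy:
    placement: str = "none"

    def __post_init__(self):
        if self.placement not in VALID_PLACEMENTS:
            raise ValueError(f"placement must be one of {VALID_PLACEMENTS}")

    def applies(self, stage: str) -> bool:
        """Augmentation placed before segmentation also reaches the
        classification stage (the segmenter's training pool flows downstream);
        placed after segmentation it only augments classification."""
        if stage not in ("segmentation", "classification"):
            raise ValueError(f"unknown stage {stage!r}")
        return (self.placement, stage) in {
            ("before_segmentation", "segmentation"),
            ("before_segmentation", "classification"),
            ("after_segmentation", "classification"),
        }


def _labels_of(samples):
    return [getattr(s, "label", None) for s in samples]


def _largest_remainder(class_sizes: dict, total: int) -> dict:
    """Allocate ``total`` among classes proportionally to size (exact sum)."""
    n = sum(class_sizes.values())
    quotas = {c: total * sz / n for c, sz in class_sizes.items()} if n else {}
    alloc = {c: int(np.floor(q)) for c, q in quotas.items()}
    short = total - sum(alloc.values())
    order = sorted(quotas, key=lambda c: (-(quotas[c] - alloc[c]), str(c)))
    for c in order[:short]:
        alloc[c] += 1
    return alloc


def split_real(samples, plan: SplitPlan):
    """Partition real samples into (train, val, test).

    Test and validation sizes are rounded half-up from the plan fractions and
    the train set takes the remainder; stratification allocates per-class
    counts by largest remainder, keeping class proportions within +-1.
    """
    n = len(samples)
    ftr, fva, fte = plan.real_fractions
    n_test = round_half_up(fte * n)
    n_val = round_half_up(fva * n)
    rng = np.random.default_rng(plan.seed)
    idx = np.arange(n)
    if plan.stratified:
        labels = _labels_of(samples)
        classes = sorted(set(labels), key=str)
        by_class = {c: [i for i in idx if labels[i] == c] for c in classes}
        if any(len(v) < 5 for v in by_class.values()):
            raise ValueError("stratified split needs >= 5 samples per class")
        sizes = {c: len(v) for c, v in by_class.items()}
        test_alloc = _largest_remainder(sizes, n_test)
        val_alloc = _largest_remainder(sizes, n_val)
        tr, va, te = [], [], []
        for c in classes:
            order = rng.permutation(by_class[c])
            t, v = test_alloc[c], val_alloc[c]
            te.extend(order[:t])
            va.extend(order[t:t + v])
            tr.extend(order[t + v:])
    else:
        order = rng.permutation(idx)
        te = order[:n_test]
        va = order[n_test:n_test + n_val]
        tr = order[n_test + n_val:]
    pick = lambda ix: [samples[i] for i in sorted(ix)]
    return pick(tr), pick(va), pick(te)


def split_generated(samples, plan: SplitPlan):
    """Partition generated samples into (train, val): round(0.8 n) train."""
    n = len(samples)
    n_train = round_half_up(plan.generated_fractions[0] * n)
    rng = np.random.default_rng(plan.seed + 1)
    order = rng.permutation(n)
    tr = [samples[i] for i in sorted(order[:n_train])]
    va = [samples[i] for i in sorted(order[n_train:])]
    return tr, va


def assert_no_generated_in_test(test_samples):
    """Hygiene guard: raise if any test sample is of generated origin."""
    for s in test_samples:
        if getattr(s, "meta", {}).get("origin") == "generated":
            raise ValueError("generated samples must never appear in a test set")


def mix_for_stage(real_split, gen_split, policy: MixPolicy, stage: str):
    """Combine splits for a stage; generated data never enters the test set."""
    r_train, r_val, r_test = real_split
    g_train, g_val = gen_split
    assert_no_generated_in_test(r_test)
    if policy.applies(stage):
        return list(r_train) + list(g_train), list(r_val) + list(g_val), list(r_test)
    return list(r_train), list(r_val), list(r_test)


def split_manifest(splits: dict, origins: dict | None = None) -> pd.DataFrame:
    """CSV-ready manifest: one row per sample with (filename, class, split, origin)."""
    rows = []
    for split_name, samples in splits.items():
        for i, s in enumerate(samples):
            rows.append({
                "filename": s.meta.get("filename", f"{split_name}_{i:05d}.png")
                if hasattr(s, "meta") else f"{split_name}_{i:05d}.png",
                "class": getattr(s, "label", ""),
                "split": split_name,
                "origin": (origins or {}).get(split_name, "real"),
            })
    return pd.DataFrame(rows, columns=["filename", "class", "split", "origin"])
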