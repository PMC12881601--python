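"""Classify phantoms with the 8-backbone concatenation ensemble and compare
against 7-member majority voting.

Backbones are compact frozen feature extractors (one per canonical name), so
only the 256/64 head trains; the voting ensemble trains seven single-backbone
classifiers and takes the modal prediction.
Run:  python examples/05_ensemble_classification.py   (~1 minute on one CPU)
"""

import numpy as np

from papcell.classify import (VOTING_MEMBER_NAMES, BackboneSpec,
                              ClfTrainConfig, ConcatEnsembleConfig,
                              build_concat_ensemble, build_single_classifier,
                              majority_vote, predict, train_classifier)
from papcell.metrics import clf_metrics
from papcell.phantoms import PhantomSpec, generate_dataset
from papcell.splits import SplitPlan, split_real

spec = PhantomSpec(image_size=32)
samples, _ = generate_dataset(spec, {"normal": 60, "abnormal": 60}, seed=3)
train, val, test = split_real(samples, SplitPlan(seed=0))
ix = {"abnormal": 0, "normal": 1}
arr = lambda ss: (np.stack([s.image for s in ss]),
                  np.array([ix[s.label] for s in ss]))
(x_tr, y_tr), (x_va, y_va), (x_te, y_te) = arr(train), arr(val), arr(test)

ens = build_concat_ensemble(ConcatEnsembleConfig(n_classes=2, input_size=32),
                            np.random.default_rng(0))
print(f"concat ensemble: {len(ens.backbones)} frozen backbones, "
      f"{ens.concat_dim} concatenated features")
ens, _ = train_classifier(ens, x_tr, y_tr, x_va, y_va,
                          ClfTrainConfig(max_epochs=30, seed=0), 2)
rep = clf_metrics(y_te, predict(ens, x_te).argmax(1), 2)
print("concat ensemble test metrics (%):", rep.as_percent_row())

votes = []
for j, name in enumerate(VOTING_MEMBER_NAMES):
    m = build_single_classifier(BackboneSpec(name, frozen=False), 2,
                                input_size=32, rng=np.random.default_rng(10 + j))
    m, _ = train_classifier(m, x_tr, y_tr, x_va, y_va,
                            ClfTrainConfig(max_epochs=15, seed=10 + j), 2)
    votes.append(predict(m, x_te).argmax(1))
y_vote = majority_vote(np.stack(votes, axis=1))
rep = clf_metrics(y_te, y_vote, 2)
print(f"majority voting ({len(votes)} members) test metrics (%):",
      rep.as_percent_row())
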