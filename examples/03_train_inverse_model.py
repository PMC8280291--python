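"""Train a small bidirectional LSTM to invert CMAPs into CV histograms.

Builds a reduced corpus (12 groups x 50 sets), trains a scaled-down
2-layer bidirectional LSTM, and reports held-out metrics.  Runtime is a
couple of minutes on one CPU; scale `n_per_group`, `hidden_units` and
`max_epochs` up for better accuracy.
"""

import numpy as np

from cmapcv import (
    ModelSpec,
    SimConfig,
    TrainConfig,
    build_corpus,
    build_model,
    dominant_bin_accuracy,
    predict_histogram,
    split_corpus,
    synthetic_smup,
    train,
)
from cmapcv.simulate import corpus_arrays

template = synthetic_smup(seed=0)
cfg = SimConfig(n_per_group=50)
corpus = build_corpus(template, cfg, seed=0)
split = split_corpus(corpus, cfg, seed=0)
print(f"corpus: {len(corpus)} sets -> {len(split.train)} train / {len(split.test)} test")

spec = ModelSpec("lstm", bidirectional=True, n_layers=2, hidden_units=32)
model = build_model(spec, seed=0)
print(f"model: {spec.name}, {model.n_parameters:,} parameters")

result = train(model, split, TrainConfig(max_epochs=10, batch_size=64,
                                         learning_rate=3e-3, seed=0))
print(f"stopped at epoch {result.stopped_epoch}")
print(f"train loss {result.final_training_loss:.1f}  "
      f"val loss {result.final_validation_loss:.1f}  "
      f"val dominant-bin accuracy {result.final_validation_accuracy:.3f}")

# inspect one held-out prediction
s = split.test[0]
pred = predict_histogram(model, s.waveform)
true_nz = {int(cv): int(n) for cv, n in zip(pred.bin_centers, s.label) if n}
pred_nz = {int(cv): int(n) for cv, n in zip(pred.bin_centers, pred.counts) if n}
print(f"example set (group {s.group_id}):")
print(f"  true      {true_nz}")
print(f"  predicted {pred_nz}")

Xte, Yte, _ = corpus_arrays(split.test)
print(f"held-out accuracy recomputed: "
      f"{dominant_bin_accuracy(model.predict(Xte), Yte):.3f} (chance = 1/28 = 0.036)")
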