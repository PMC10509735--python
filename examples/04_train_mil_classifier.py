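"""Train the attention-MIL head on feature stacks and inspect a prediction.

The 1D-CNN z-integrator collapses each tile's feature stack to one vector,
attention weights the tiles, and a linear-softmax head scores the specimen.
"""

import numpy as np

from stackmil import (build_encoder, desk_scale, extract_bag_features,
                      generate_cohort, predict_bag, standardize_features,
                      train_classifier)

cfg = desk_scale(seed=3)
bags, _ = generate_cohort(cfg.synth, 24, 0.5, seed=3)
labels = {b.specimen_id: b.labels["ER"] for b in bags}

encoder = build_encoder(cfg.encoder, seed=3)
encoder.eval()
features = extract_bag_features(encoder, bags)
features = standardize_features(features, list(features))

model, loss_trace, _ = train_classifier(features, labels, cfg.classifier,
                                        cfg.zintegrator)
print(f"training loss: {loss_trace[0]:.3f} -> {loss_trace[-1]:.3f} "
      f"over {len(loss_trace)} epochs")

correct = 0
for sid, arr in features.items():
    probs, scores = predict_bag(model, arr)
    correct += (probs[1] > 0.5) == labels[sid]
print(f"training accuracy: {correct}/{len(features)}")

sid = bags[0].specimen_id
probs, scores = predict_bag(model, features[sid])
print(f"{sid}: P(positive) = {probs[1]:.3f}, attention weights = "
      f"{np.round(scores.weights, 3)} (sum {scores.weights.sum():.3f})")
# Attention weights are a softmax over the bag's tiles: nonnegative, sum 1,
# and highlight the tiles the prediction leans on.
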