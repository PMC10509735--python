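"""Interpretation outputs: Grad-CAM slice importance and attention heatmaps.

Slice importance asks which focal planes carry the model's evidence; the
heatmap paints min-max-normalized attention over each tile's footprint.
"""

import numpy as np

from stackmil import (attention_heatmap, build_encoder, desk_scale,
                      extract_bag_features, generate_cohort, predict_bag,
                      slice_importance, standardize_features,
                      train_classifier)

cfg = desk_scale(seed=6)
bags, _ = generate_cohort(cfg.synth, 16, 0.5, seed=6)
labels = {b.specimen_id: b.labels["ER"] for b in bags}
encoder = build_encoder(cfg.encoder, seed=6)
encoder.eval()
features = extract_bag_features(encoder, bags)
features = standardize_features(features, list(features))
model, _, _ = train_classifier(features, labels, cfg.classifier,
                               cfg.zintegrator)

imp = slice_importance(model, encoder, bags[:4])
print(f"slice importance (sums to {imp.importance.sum():.3f}):")
print("  " + " ".join(f"{v:.3f}" for v in imp.importance))

sid = bags[0].specimen_id
probs, scores = predict_bag(model, features[sid])
overlay = attention_heatmap(bags[0], scores, downscale=1)
print(f"{sid}: P(positive) = {probs[1]:.3f}; "
      f"tile intensities {np.round(overlay.tile_intensities, 2)}")
print(f"overlay thumbnail {overlay.render().shape}, "
      f"colormap {overlay.colormap}")
# Importance is a probability vector over focal planes; heatmap intensities
# are the attention weights min-max normalized per specimen.
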