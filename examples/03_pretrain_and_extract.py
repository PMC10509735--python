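"""Contrastively pretrain the per-slice encoder and extract feature stacks.

Two augmented views of each tile slice are pulled together under the
temperature-scaled InfoNCE objective; the frozen encoder then maps each
(H, W, 3, Z) tile to a D x Z feature stack.
"""

from stackmil import desk_scale, extract_features, generate_cohort, train_ssl
from stackmil.contrastive import slices_from_bags

cfg = desk_scale(seed=2)
bags, _ = generate_cohort(cfg.synth, 8, 0.5, seed=2)
corpus = slices_from_bags(bags)
print(f"pretraining corpus: {len(corpus)} slices "
      f"from {len(bags)} specimens")

encoder, loss_trace, consumed = train_ssl(corpus, cfg.encoder, cfg.ssl,
                                          cfg.augment)
print(f"contrastive loss per epoch: "
      f"{', '.join(f'{x:.3f}' for x in loss_trace)}")

stack = extract_features(encoder, bags[0].tiles[0])
print(f"feature stack: {stack.values.shape} (one column per focal plane)")
# The loss should drift downward; the feature stack is what the MIL head
# consumes — slices are encoded independently, so column z describes plane z.
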