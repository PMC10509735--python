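"""Cross-validated evaluation with fold-consistent pretraining.

Each fold pretrains its own encoder on the training specimens only, trains
the MIL head on the same split, and scores the held-out specimens; the
report carries per-fold AUCs and the consumption audit that proves no
held-out specimen leaked into training.
"""

from stackmil import cross_validate, desk_scale, generate_cohort

cfg = desk_scale(seed=4)
bags, _ = generate_cohort(cfg.synth, 40, 0.5, seed=4)

report = cross_validate(bags, marker="ER", mode="attention",
                        encoder_spec=cfg.encoder, ssl_config=cfg.ssl,
                        aug_config=cfg.augment, zspec=cfg.zintegrator,
                        clf_config=cfg.classifier, k=4, seed=4, use_ssl=True)

print(f"fold AUCs: {[f'{a:.3f}' for a in report.fold_aucs]}")
print(f"mean AUC {report.mean_auc:.3f} ± {report.sd_auc:.3f}")
for fold, record in report.audit.items():
    overlap = set(record["test_ids"]) & set(record["ssl_consumed"])
    print(f"  {fold}: {len(record['test_ids'])} held out, "
          f"leakage overlap {len(overlap)}")
# With the strong synthetic morphology signal the mean AUC sits well above
# chance; every fold's leakage overlap must be zero.
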