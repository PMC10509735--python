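"""End-to-end staged pipeline with content-hash caching.

Stages run in order — simulate, preprocess, pretrain, extract, train,
evaluate, explain — each writing its artifacts under ``<out>/<stage>/`` with
a stamp file recording the hash of the config sections and upstream stages it
consumed.  A rerun skips any stage whose stamp still matches, so changing,
say, the contrastive seed reruns pretraining and everything downstream while
the simulated cohort stays cached.
"""

from __future__ import annotations

import dataclasses
import json
import shutil
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as smio
from .config import PlatformConfig, report_dimension_stats, save_config
from .contrastive import extract_bag_features, load_encoder, save_encoder, slices_from_bags, train_ssl
from .errors import StackMilError
from .evaluate import FoldSplit, RunReport, compute_auc, make_folds, standardize_features
from .interpret import attention_heatmap, embed_2d, slice_importance
from .mil import MilModel, predict_bag, train_classifier
from .preprocess import register_stack, select_best_focus, summarize_labels
from .simulate import apply_misalignment, generate_specimen, MARKERS
from .utils import content_hash, derive_rng, derive_seed

__all__ = ["run_pipeline", "STAGES"]

STAGES = ("simulate", "preprocess", "pretrain", "extract", "train",
          "evaluate", "explain")


def _stamp_path(stage_dir: Path) -> Path:
    return stage_dir / ".stage.json"


def _is_cached(stage_dir: Path, input_hash: str) -> bool:
    stamp = _stamp_path(stage_dir)
    if not stamp.exists():
        return False
    try:
        data = json.loads(stamp.read_text())
    except json.JSONDecodeError:
        return False
    return data.get("input_hash") == input_hash and data.get("completed", False)


def _write_stamp(stage_dir: Path, input_hash: str, extra: dict | None = None) -> None:
    payload = {"input_hash": input_hash, "completed": True, **(extra or {})}
    _stamp_path(stage_dir).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _fresh_dir(stage_dir: Path) -> Path:
    if stage_dir.exists():
        shutil.rmtree(stage_dir)
    stage_dir.mkdir(parents=True)
    return stage_dir


class _Runner:
    def __init__(self, config: PlatformConfig, out_root: Path, log):
        self.cfg = config
        self.out = out_root
        self.log = log
        self.hashes: dict[str, str] = {}
        self.executed: list[str] = []
        self.skipped: list[str] = []

    def stage(self, name: str, sections: list[str], build) -> Path:
        deps = [self.hashes[s] for s in STAGES if s in self.hashes
                and STAGES.index(s) < STAGES.index(name)]
        input_hash = content_hash({
            "sections": {s: self.cfg.to_dict()[s] for s in sections},
            "seed": self.cfg.seed, "deps": deps,
        })
        stage_dir = self.out / name
        if _is_cached(stage_dir, input_hash):
            self.log(f"[{name}] cached")
            self.skipped.append(name)
        else:
            self.log(f"[{name}] running")
            _fresh_dir(stage_dir)
            try:
                extra = build(stage_dir) or {}
            except Exception:
                # leave partial outputs for inspection, but no stamp
                raise
            _write_stamp(stage_dir, input_hash, extra)
            self.executed.append(name)
        self.hashes[name] = input_hash
        return stage_dir


def run_pipeline(config: PlatformConfig, out_root: str | Path | None = None,
                 log=print) -> dict:
    """Execute all stages, resuming from cached outputs; returns an artifact
    tree description (per-stage directories, executed vs cached, report)."""
    out = Path(out_root if out_root is not None else config.out_root)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.resolved.yaml")
    dims = report_dimension_stats(config)
    log(f"[run] per-slice {dims['per_slice_input_dim']} -> "
        f"{dims['per_slice_feature_dim']} "
        f"(reduction x{dims['reduction_factor']:.0f}); config hash "
        f"{content_hash(config.to_dict())[:12]}")
    r = _Runner(config, out, log)

    sim_dir = r.stage("simulate", ["synth", "cohort"], lambda d: _simulate(config, d))
    pre_dir = r.stage("preprocess", ["preprocess", "synth"],
                      lambda d: _preprocess(config, sim_dir, d))
    pt_dir = r.stage("pretrain", ["ssl", "augment", "encoder", "evaluate"],
                     lambda d: _pretrain(config, pre_dir, d))
    ex_dir = r.stage("extract", ["encoder", "evaluate"],
                     lambda d: _extract(config, pre_dir, pt_dir, d))
    tr_dir = r.stage("train", ["zintegrator", "classifier", "evaluate"],
                     lambda d: _train(config, pre_dir, pt_dir, ex_dir, d))
    ev_dir = r.stage("evaluate", ["evaluate"],
                     lambda d: _evaluate(config, tr_dir, d))
    xp_dir = r.stage("explain", ["interpret", "evaluate"],
                     lambda d: _explain(config, pre_dir, pt_dir, ex_dir, tr_dir, d))

    report_path = ev_dir / "run_report.json"
    return {
        "out_root": str(out),
        "stages": {s: str(out / s) for s in STAGES},
        "executed": r.executed,
        "skipped": r.skipped,
        "report": json.loads(report_path.read_text()) if report_path.exists() else None,
    }


# ---------------------------------------------------------------------------
# stage bodies
# ---------------------------------------------------------------------------

def _simulate(cfg: PlatformConfig, stage_dir: Path) -> dict:
    synth = dataclasses.replace(cfg.synth, seed=derive_seed(cfg.seed, "synth",
                                                            cfg.synth.seed))
    n = cfg.cohort.n_specimens
    n_pos = int(round(n * cfg.cohort.positive_fraction))
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    derive_rng(cfg.seed, "cohort-order").shuffle(labels)
    bags, rows, transforms = [], [], {}
    for i, lab in enumerate(labels):
        sid = f"S{i:05d}"
        bag = generate_specimen(synth, int(lab), specimen_seed=i, specimen_id=sid)
        if synth.misalignment_px > 0 or synth.misalignment_deg > 0:
            bag, tfs = apply_misalignment(bag, synth, seed=i)
            transforms[sid] = tfs
        bags.append(bag)
        rows.append({"specimen_id": sid, **{m: int(lab) for m in MARKERS}})
    table = pd.DataFrame(rows, columns=["specimen_id", *MARKERS])
    smio.write_cohort(bags, table, stage_dir, transforms=transforms or None)
    return {"n_specimens": n, "n_positive": int(n_pos)}


def _preprocess(cfg: PlatformConfig, sim_dir: Path, stage_dir: Path) -> dict:
    bags, table = smio.read_cohort(sim_dir)
    registered = 0
    if cfg.preprocess.register and (cfg.synth.misalignment_px > 0
                                    or cfg.synth.misalignment_deg > 0):
        for bag in bags:
            for i, tile in enumerate(bag.tiles):
                aligned, _ = register_stack(tile)
                bag.tiles[i] = aligned
                registered += 1
    smio.write_cohort(bags, table, stage_dir)
    focus_rows = []
    for bag in bags:
        for i, tile in enumerate(bag.tiles):
            focus_rows.append({"specimen_id": bag.specimen_id,
                               "tile_id": f"{bag.specimen_id}_t{i:03d}",
                               "best_focus_slice": select_best_focus(tile)})
    pd.DataFrame(focus_rows).to_csv(stage_dir / "best_focus.csv", index=False)
    smio.write_json(summarize_labels(table), stage_dir / "label_summary.json")
    return {"registered_tiles": registered}


def _folds_for(cfg: PlatformConfig, pre_dir: Path) -> tuple[FoldSplit, dict]:
    _, table = smio.read_cohort(pre_dir)
    marker = cfg.evaluate.marker
    labels = {row["specimen_id"]: int(row[marker]) for _, row in table.iterrows()}
    folds = make_folds(sorted(labels), cfg.evaluate.k, labels,
                       seed=cfg.seed, marker=marker)
    return folds, labels


def _pretrain(cfg: PlatformConfig, pre_dir: Path, stage_dir: Path) -> dict:
    bags, _ = smio.read_cohort(pre_dir)
    by_sid = {b.specimen_id: b for b in bags}
    folds, _ = _folds_for(cfg, pre_dir)
    audit = {}
    for fi in range(folds.k):
        train_ids, _ = folds.train_test(fi)
        fold_seed = derive_seed(cfg.seed, "ssl", cfg.ssl.seed, "fold", fi)
        if cfg.evaluate.use_ssl:
            ssl_cfg = dataclasses.replace(cfg.ssl, seed=fold_seed)
            corpus = slices_from_bags([by_sid[i] for i in train_ids])
            encoder, trace, consumed = train_ssl(corpus, cfg.encoder, ssl_cfg,
                                                 cfg.augment)
        else:
            from .contrastive import build_encoder
            encoder = build_encoder(cfg.encoder, seed=fold_seed)
            encoder.eval()
            trace, consumed = [], set()
        save_encoder(encoder, stage_dir / f"encoder_fold{fi}.npz",
                     ssl_config=cfg.ssl, fold=fi)
        smio.write_json({"loss_trace": trace}, stage_dir / f"loss_fold{fi}.json")
        audit[f"fold{fi}"] = sorted(consumed)
    smio.write_json(audit, stage_dir / "ssl_consumed.json")
    return {"k": folds.k}


def _extract(cfg: PlatformConfig, pre_dir: Path, pt_dir: Path,
             stage_dir: Path) -> dict:
    bags, _ = smio.read_cohort(pre_dir)
    folds, _ = _folds_for(cfg, pre_dir)
    for fi in range(folds.k):
        encoder = load_encoder(pt_dir / f"encoder_fold{fi}.npz")
        features = extract_bag_features(encoder, bags)
        np.savez(stage_dir / f"features_fold{fi}.npz", **features)
    return {"n_tiles": int(sum(b.n_tiles for b in bags))}


def _train(cfg: PlatformConfig, pre_dir: Path, pt_dir: Path, ex_dir: Path,
           stage_dir: Path) -> dict:
    folds, labels = _folds_for(cfg, pre_dir)
    marker, mode = cfg.evaluate.marker, cfg.evaluate.mode
    pred_rows, audit = [], {}
    for fi in range(folds.k):
        with np.load(ex_dir / f"features_fold{fi}.npz") as archive:
            features = {k: archive[k] for k in archive.files}
        train_ids, test_ids = folds.train_test(fi)
        features = standardize_features(features, train_ids)
        fold_seed = derive_seed(cfg.seed, "clf", cfg.classifier.seed, "fold", fi)
        clf_cfg = dataclasses.replace(cfg.classifier, aggregation_mode=mode,
                                      seed=fold_seed)
        model, trace, consumed = train_classifier(
            {i: features[i] for i in train_ids}, labels, clf_cfg, cfg.zintegrator)
        np.savez(stage_dir / f"model_fold{fi}.npz", **model.state_dict())
        smio.write_json({"marker": marker, "mode": mode, "fold": fi,
                         "loss_trace": trace,
                         "zspec": dataclasses.asdict(cfg.zintegrator),
                         "clf_config": dataclasses.asdict(clf_cfg)},
                        stage_dir / f"model_fold{fi}.npz.json")
        for sid in test_ids:
            probs, _ = predict_bag(model, features[sid])
            pred_rows.append({"specimen_id": sid, "marker": marker, "fold": fi,
                              "prob_positive": float(probs[1]),
                              "label": labels[sid]})
        audit[f"fold{fi}"] = {"classifier_consumed": sorted(consumed),
                              "test_ids": sorted(test_ids)}
    pd.DataFrame(pred_rows).to_csv(stage_dir / "predictions.csv", index=False)
    smio.write_json(audit, stage_dir / "clf_consumed.json")
    return {"n_predictions": len(pred_rows)}


def _evaluate(cfg: PlatformConfig, tr_dir: Path, stage_dir: Path) -> dict:
    preds = pd.read_csv(tr_dir / "predictions.csv")
    fold_aucs = []
    for fi, group in preds.groupby("fold"):
        try:
            fold_aucs.append(compute_auc(group["label"].tolist(),
                                         group["prob_positive"].tolist()))
        except StackMilError:
            fold_aucs.append(None)
    defined = [a for a in fold_aucs if a is not None]
    report = RunReport(
        marker=cfg.evaluate.marker, mode=cfg.evaluate.mode, fold_aucs=fold_aucs,
        mean_auc=float(np.mean(defined)) if defined else float("nan"),
        sd_auc=float(np.std(defined)) if defined else float("nan"),
        config=cfg.to_dict(), seed=cfg.seed,
        predictions=preds.to_dict("records"))
    smio.write_json(report.to_dict(), stage_dir / "run_report.json")
    lines = [f"# Run report — {report.marker} / {report.mode}", "",
             f"mean AUC {report.mean_auc:.4f} ± {report.sd_auc:.4f} "
             f"over {len(defined)} folds", "",
             "| fold | AUC |", "| --- | --- |"]
    lines += [f"| {i} | {a if a is None else f'{a:.4f}'} |"
              for i, a in enumerate(fold_aucs)]
    (stage_dir / "run_report.md").write_text("\n".join(lines) + "\n")

    # per-fold ROC points and a fold-AUC box plot
    from sklearn.metrics import roc_curve
    roc_rows = []
    for fi, group in preds.groupby("fold"):
        if group["label"].nunique() < 2:
            continue
        fpr, tpr, thr = roc_curve(group["label"], group["prob_positive"])
        roc_rows += [{"fold": fi, "fpr": f, "tpr": t, "threshold": th}
                     for f, t, th in zip(fpr, tpr, thr)]
    pd.DataFrame(roc_rows).to_csv(stage_dir / "roc_points.csv", index=False)
    if defined:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(3, 4))
        ax.boxplot([defined], tick_labels=[report.marker])
        ax.set_ylabel("held-out AUC per fold")
        fig.tight_layout()
        fig.savefig(stage_dir / "fold_auc_boxplot.png", dpi=120)
        plt.close(fig)
    return {"mean_auc": report.mean_auc}


def _explain(cfg: PlatformConfig, pre_dir: Path, pt_dir: Path, ex_dir: Path,
             tr_dir: Path, stage_dir: Path) -> dict:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bags, _ = smio.read_cohort(pre_dir)
    by_sid = {b.specimen_id: b for b in bags}
    folds, labels = _folds_for(cfg, pre_dir)
    fi = 0
    train_ids, test_ids = folds.train_test(fi)
    encoder = load_encoder(pt_dir / f"encoder_fold{fi}.npz")
    with np.load(ex_dir / f"features_fold{fi}.npz") as archive:
        features = {k: archive[k] for k in archive.files}
    features = standardize_features(features, train_ids)
    sidecar = json.loads((tr_dir / f"model_fold{fi}.npz.json").read_text())
    from .mil import ClassifierConfig, ZIntegratorSpec
    clf_cfg = ClassifierConfig(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in sidecar["clf_config"].items()})
    zspec = ZIntegratorSpec(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in sidecar["zspec"].items()})
    feature_dim = next(iter(features.values())).shape[1]
    model = MilModel(feature_dim, zspec, clf_cfg)
    with np.load(tr_dir / f"model_fold{fi}.npz") as archive:
        model.load_state_dict({k: archive[k] for k in archive.files})
    model.eval()

    # slice-wise Grad-CAM importance on the held-out fold
    test_bags = [by_sid[i] for i in test_ids]
    imp = slice_importance(model, encoder, test_bags)
    pd.DataFrame({"slice_index": np.arange(len(imp.importance)),
                  "importance": imp.importance, "sd": imp.sd}
                 ).to_csv(stage_dir / "slice_importance.csv", index=False)
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.errorbar(np.arange(len(imp.importance)), imp.importance, yerr=imp.sd,
                marker="o")
    ax.set_xlabel("slice index"); ax.set_ylabel("normalized importance")
    fig.tight_layout(); fig.savefig(stage_dir / "slice_importance.png", dpi=120)
    plt.close(fig)

    # attention heatmaps for a few held-out specimens
    heat_rows = []
    for sid in test_ids[:cfg.interpret.n_heatmaps]:
        probs, scores = predict_bag(model, features[sid])
        if scores is None:
            continue
        overlay = attention_heatmap(by_sid[sid], scores,
                                    downscale=cfg.interpret.downscale,
                                    colormap=cfg.interpret.colormap,
                                    provenance={"marker": cfg.evaluate.marker,
                                                "fold": fi})
        from PIL import Image
        Image.fromarray(overlay.render()).save(stage_dir / f"heatmap_{sid}.png")
        for ti, w in enumerate(scores.weights):
            heat_rows.append({"specimen_id": sid,
                              "tile_id": f"{sid}_t{ti:03d}", "weight": float(w)})
    if heat_rows:
        pd.DataFrame(heat_rows).to_csv(stage_dir / "attention_scores.csv",
                                       index=False)

    # 2D embedding of per-tile z-averaged features
    mats, labs = [], []
    for sid, arr in features.items():
        mats.append(arr.mean(axis=2))  # (N, D)
        labs += [labels[sid]] * arr.shape[0]
    x = np.concatenate(mats, axis=0)
    if x.shape[0] >= 10:
        coords, sil = embed_2d(x, labs, seed=cfg.seed)
        pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1], "label": labs}
                     ).to_csv(stage_dir / "embedding.csv", index=False)
        fig, ax = plt.subplots(figsize=(4, 4))
        labs_arr = np.asarray(labs)
        for lab, color in ((0, "tab:blue"), (1, "tab:red")):
            sel = labs_arr == lab
            ax.scatter(coords[sel, 0], coords[sel, 1], s=8, c=color,
                       label=f"label {lab}")
        ax.legend(); ax.set_title(f"silhouette {sil:.3f}")
        fig.tight_layout(); fig.savefig(stage_dir / "embedding.png", dpi=120)
        plt.close(fig)
    return {"n_heatmaps": len(set(r["specimen_id"] for r in heat_rows))}
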