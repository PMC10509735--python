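"""Cross-validated evaluation: stratified folds shared between pretraining
and classification, AUC machinery, the data-fraction learning curve, and the
stack-versus-virtual-stack ablation.

Fold hygiene is explicit: the encoder for fold k is pretrained only on fold
k's training specimens, and every stage records the specimen ids it consumed
so leakage can be audited after the fact.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contrastive import (AugmentationConfig, EncoderSpec, SslConfig,
                          build_encoder, extract_bag_features, slices_from_bags,
                          train_ssl)
from .errors import ConfigurationError, MetricError
from .mil import ClassifierConfig, ZIntegratorSpec, predict_bag, train_classifier
from .preprocess import select_best_focus
from .simulate import SpecimenBag, SynthConfig, generate_cohort, make_virtual_stack
from .utils import content_hash, derive_rng, derive_seed

__all__ = [
    "FoldSplit", "RunReport", "make_folds", "compute_auc", "cross_validate",
    "standardize_features",
    "data_fraction_experiment", "stack_vs_virtual_experiment",
]


@dataclass(frozen=True)
class FoldSplit:
    """K disjoint, exhaustive, stratified specimen-id lists."""

    folds: tuple[tuple[str, ...], ...]
    marker: str
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def train_test(self, fold_index: int) -> tuple[list[str], list[str]]:
        test = list(self.folds[fold_index])
        train = [sid for j, f in enumerate(self.folds) if j != fold_index for sid in f]
        return train, test


@dataclass
class RunReport:
    """Cross-validation result: per-fold AUCs, their mean and SD, the full
    config snapshot and seeds, and the fold-hygiene audit log."""

    marker: str
    mode: str
    fold_aucs: list[float | None]
    mean_auc: float
    sd_auc: float
    config: dict
    seed: int
    audit: dict = field(default_factory=dict)
    predictions: list[dict] = field(default_factory=list)

    @property
    def report_hash(self) -> str:
        return content_hash({
            "marker": self.marker, "mode": self.mode,
            "fold_aucs": self.fold_aucs, "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc, "config": self.config, "seed": self.seed,
        })

    def to_dict(self) -> dict:
        return {
            "marker": self.marker, "mode": self.mode, "fold_aucs": self.fold_aucs,
            "mean_auc": self.mean_auc, "sd_auc": self.sd_auc, "config": self.config,
            "seed": self.seed, "audit": {k: sorted(v) if isinstance(v, (set, list))
                                         else v for k, v in self.audit.items()},
            "predictions": self.predictions, "report_hash": self.report_hash,
        }


def make_folds(specimen_ids: Sequence[str], k: int, marker_labels: Mapping[str, int],
               seed: int, marker: str = "ER") -> FoldSplit:
    """Stratified K folds: ids are shuffled within each class and dealt
    round-robin with a fold pointer that continues across classes, so fold
    sizes differ by at most one and per-fold class counts are within one of
    proportional."""
    ids = list(specimen_ids)
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if len(ids) < k:
        raise ConfigurationError(f"cannot split {len(ids)} specimens into {k} folds")
    rng = derive_rng(seed, "folds", marker)
    folds: list[list[str]] = [[] for _ in range(k)]
    pointer = 0
    for cls in (1, 0):
        cls_ids = sorted(i for i in ids if marker_labels[i] == cls)
        order = rng.permutation(len(cls_ids))
        for j in order:
            folds[pointer % k].append(cls_ids[int(j)])
            pointer += 1
    return FoldSplit(folds=tuple(tuple(f) for f in folds), marker=marker, seed=seed)


def compute_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Mann-Whitney concordance AUC: the probability a random positive
    outscores a random negative, ties counted 0.5.  Computed with midranks,
    which is exactly pairwise concordance counting."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise MetricError("AUC undefined: both classes must be present")
    from scipy.stats import rankdata
    ranks = rankdata(s)  # midranks handle ties as 0.5 concordance
    rank_sum = ranks[y == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _fit_fold_encoder(train_bags: list[SpecimenBag], encoder_spec: EncoderSpec,
                      ssl_config: SslConfig, aug_config: AugmentationConfig,
                      use_ssl: bool, fold_seed: int):
    """Fold encoder: contrastively pretrained on training-fold slices, or a
    frozen randomly initialized encoder as the no-pretraining baseline."""
    if not use_ssl:
        enc = build_encoder(encoder_spec, seed=fold_seed)
        enc.eval()
        return enc, [], set()
    cfg = dataclasses.replace(ssl_config, seed=fold_seed)
    corpus = slices_from_bags(train_bags)
    return train_ssl(corpus, encoder_spec, cfg, aug_config)


def _best_focus_bags(bags: list[SpecimenBag]) -> list[SpecimenBag]:
    """2D baseline: collapse each tile to its single best-focused slice."""
    out = []
    for bag in bags:
        tiles = []
        for t in bag.tiles:
            z = select_best_focus(t)
            tiles.append(dataclasses.replace(t, pixels=t.pixels[:, :, :, z:z + 1]))
        out.append(SpecimenBag(specimen_id=bag.specimen_id, tiles=tiles,
                               labels=dict(bag.labels)))
    return out


def standardize_features(features: dict[str, np.ndarray], fit_ids: Sequence[str]
                         ) -> dict[str, np.ndarray]:
    """Per-dimension z-scoring with statistics from the training split only."""
    ref = np.concatenate([features[i] for i in fit_ids], axis=0)
    mu = ref.mean(axis=(0, 2), keepdims=True)
    sd = ref.std(axis=(0, 2), keepdims=True) + 1e-8
    return {k: (v - mu) / sd for k, v in features.items()}


def cross_validate(bags: Sequence[SpecimenBag], marker: str = "ER",
                   mode: str = "attention", *, encoder_spec: EncoderSpec,
                   ssl_config: SslConfig, aug_config: AugmentationConfig,
                   zspec: ZIntegratorSpec, clf_config: ClassifierConfig,
                   k: int = 5, seed: int = 0, use_ssl: bool = True,
                   standardize: bool = True,
                   folds: FoldSplit | None = None,
                   train_id_subset: Mapping[int, Sequence[str]] | None = None,
                   ) -> RunReport:
    """K-fold cross-validation with fold-consistent pretraining.

    Per fold: the encoder is pretrained on that fold's training specimens,
    the MIL head is trained on the same specimens' feature stacks, and the
    held-out specimens are scored.  Folds whose test split is single-class
    are reported as undefined with a warning and excluded from the mean.
    ``train_id_subset`` optionally restricts fold k's training ids (the
    data-fraction experiment); test sets are never restricted.
    """
    bags = list(bags)
    by_sid = {b.specimen_id: b for b in bags}
    labels = {b.specimen_id: int(b.labels[marker]) for b in bags}
    if folds is None:
        folds = make_folds(sorted(by_sid), k, labels, seed=seed, marker=marker)

    fold_aucs: list[float | None] = []
    audit: dict = {}
    predictions: list[dict] = []
    for fi in range(folds.k):
        train_ids, test_ids = folds.train_test(fi)
        if train_id_subset is not None:
            allowed = set(train_id_subset[fi])
            train_ids = [i for i in train_ids if i in allowed]
        train_bags = [by_sid[i] for i in train_ids]
        fold_seed = derive_seed(seed, "fold", fi)
        encoder, _, ssl_consumed = _fit_fold_encoder(
            train_bags, encoder_spec, ssl_config, aug_config, use_ssl, fold_seed)
        features = extract_bag_features(encoder, bags)
        if standardize:
            features = standardize_features(features, train_ids)
        train_features = {i: features[i] for i in train_ids}
        clf_cfg = dataclasses.replace(clf_config, aggregation_mode=mode,
                                      seed=fold_seed)
        model, _, clf_consumed = train_classifier(train_features, labels,
                                                  clf_cfg, zspec)
        y_true, y_score = [], []
        for sid in test_ids:
            probs, _ = predict_bag(model, features[sid])
            y_true.append(labels[sid])
            y_score.append(float(probs[1]))
            predictions.append({"specimen_id": sid, "marker": marker, "fold": fi,
                                "prob_positive": float(probs[1]),
                                "label": labels[sid]})
        audit[f"fold{fi}"] = {
            "test_ids": sorted(test_ids),
            "ssl_consumed": sorted(ssl_consumed),
            "classifier_consumed": sorted(clf_consumed),
        }
        try:
            fold_aucs.append(compute_auc(y_true, y_score))
        except MetricError:
            warnings.warn(f"fold {fi} test split is single-class; AUC undefined",
                          stacklevel=2)
            fold_aucs.append(None)

    defined = [a for a in fold_aucs if a is not None]
    config_snapshot = {
        "encoder_spec": dataclasses.asdict(encoder_spec),
        "ssl_config": dataclasses.asdict(ssl_config),
        "aug_config": dataclasses.asdict(aug_config),
        "zspec": dataclasses.asdict(zspec),
        "clf_config": dataclasses.asdict(clf_config),
        "k": folds.k, "use_ssl": use_ssl,
    }
    return RunReport(marker=marker, mode=mode, fold_aucs=fold_aucs,
                     mean_auc=float(np.mean(defined)) if defined else float("nan"),
                     sd_auc=float(np.std(defined)) if defined else float("nan"),
                     config=config_snapshot, seed=seed, audit=audit,
                     predictions=predictions)


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def _nested_subsets(train_ids: Sequence[str], labels: Mapping[str, int],
                    fractions: Sequence[float], seed: int) -> dict[float, list[str]]:
    """Stratified nested subsets: each id gets a seeded priority per class and
    a fraction takes the per-class prefix, so smaller subsets are contained
    in larger ones."""
    rng = derive_rng(seed, "fractions")
    pos = [i for i in train_ids if labels[i] == 1]
    neg = [i for i in train_ids if labels[i] == 0]
    pos = [pos[int(j)] for j in rng.permutation(len(pos))]
    neg = [neg[int(j)] for j in rng.permutation(len(neg))]
    out = {}
    for f in fractions:
        n_pos = int(f * len(pos))
        n_neg = int(f * len(neg))
        out[f] = pos[:max(n_pos, 1)] + neg[:max(n_neg, 1)]
    return out


def data_fraction_experiment(bags: Sequence[SpecimenBag], fractions: Sequence[float],
                             marker: str = "ER", **cv_kwargs) -> pd.DataFrame:
    """Learning curve: cross-validate with nested stratified subsets of each
    fold's training cases (test folds untouched).  ``n_cases`` reports the
    cohort-scale subset size floor(fraction * n_specimens); ``n_train_fold0``
    the per-fold training count actually used."""
    fractions = sorted(fractions)
    if any(not (0.0 < f <= 1.0) for f in fractions):
        raise ConfigurationError("fractions must lie in (0, 1]")
    bags = list(bags)
    labels = {b.specimen_id: int(b.labels[marker]) for b in bags}
    seed = cv_kwargs.get("seed", 0)
    k = cv_kwargs.get("k", 5)
    folds = make_folds(sorted(labels), k, labels, seed=seed, marker=marker)
    per_fold_subsets: dict[float, dict[int, list[str]]] = {f: {} for f in fractions}
    for fi in range(folds.k):
        train_ids, _ = folds.train_test(fi)
        subsets = _nested_subsets(train_ids, labels, fractions,
                                  seed=derive_seed(seed, "fraction-fold", fi))
        for f in fractions:
            subset = subsets[f]
            if sum(labels[i] == 1 for i in subset) < 2 or \
               sum(labels[i] == 0 for i in subset) < 2:
                raise ConfigurationError(
                    f"fraction {f} leaves fewer than 2 specimens per class")
            per_fold_subsets[f][fi] = subset
    rows = []
    for f in fractions:
        report = cross_validate(bags, marker=marker, folds=folds,
                                train_id_subset=per_fold_subsets[f], **cv_kwargs)
        rows.append({"fraction": f, "n_cases": int(f * len(bags)),
                     "n_train_fold0": len(per_fold_subsets[f][0]),
                     "mean_auc": report.mean_auc, "sd_auc": report.sd_auc})
    return pd.DataFrame(rows)


def _virtual_twin(bag: SpecimenBag, config: SynthConfig) -> SpecimenBag:
    """Replace each tile by the virtual stack built from its best-focus slice."""
    tiles = []
    for t in bag.tiles:
        z = select_best_focus(t)
        vt = make_virtual_stack(t.pixels[:, :, :, z], config,
                                specimen_id=t.specimen_id, origin_xy=t.origin_xy)
        tiles.append(vt)
    return SpecimenBag(specimen_id=bag.specimen_id, tiles=tiles,
                       labels=dict(bag.labels))


def stack_vs_virtual_experiment(config: SynthConfig, n_specimens: int,
                                seeds: Sequence[int], marker: str = "ER",
                                positive_fraction: float = 0.5,
                                include_best_focus_2d: bool = False,
                                **cv_kwargs) -> dict:
    """Paired ablation: true z-stacks versus virtual stacks rebuilt from each
    tile's best-focus slice, identical folds and seeds in both arms.

    With the class signal localized away from the best-focus plane the
    virtual arm destroys it by construction; with the signal in the
    best-focus plane both arms retain it (negative control).  Optionally a
    third arm evaluates the single best-focus slice (the 2D baseline).
    """
    per_seed = []
    for s in seeds:
        bags, _ = generate_cohort(config, n_specimens, positive_fraction, seed=s)
        virtual_bags = [_virtual_twin(b, config) for b in bags]
        labels = {b.specimen_id: int(b.labels[marker]) for b in bags}
        folds = make_folds(sorted(labels), cv_kwargs.get("k", 2), labels,
                           seed=s, marker=marker)
        kwargs = {k_: v for k_, v in cv_kwargs.items() if k_ not in ("k", "seed")}
        rep_true = cross_validate(bags, marker=marker, folds=folds, seed=s, **kwargs)
        rep_virt = cross_validate(virtual_bags, marker=marker, folds=folds,
                                  seed=s, **kwargs)
        row = {"seed": s, "auc_true": rep_true.mean_auc,
               "auc_virtual": rep_virt.mean_auc,
               "folds_hash": content_hash([list(f) for f in folds.folds])}
        if include_best_focus_2d:
            rep_2d = cross_validate(_best_focus_bags(bags), marker=marker,
                                    folds=folds, seed=s, **kwargs)
            row["auc_2d"] = rep_2d.mean_auc
        per_seed.append(row)
    out = {"per_seed": per_seed,
           "mean_auc_true": float(np.mean([r["auc_true"] for r in per_seed])),
           "mean_auc_virtual": float(np.mean([r["auc_virtual"] for r in per_seed]))}
    out["difference"] = out["mean_auc_true"] - out["mean_auc_virtual"]
    if include_best_focus_2d:
        out["mean_auc_2d"] = float(np.mean([r["auc_2d"] for r in per_seed]))
    return out
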