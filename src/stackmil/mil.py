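"""Specimen-level prediction: 1D-convolutional z-integration of each tile's
feature stack, tile aggregation (attention, mean or max pooling), and a
linear-softmax classifier, trained end to end with cross-entropy.

A specimen is a bag of tiles; only the bag carries a label.  The z-integrator
treats the D x Z feature stack as a multichannel 1D signal over focal planes
and reduces it to one vector per tile; the attention head then scores each
tile's contribution before the weighted bag representation is classified.
Bags have varying size, so training uses batch size 1 (one optimizer step per
specimen) with minority oversampling for class balance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import nn
from .errors import ConfigurationError, DataError, ValidationError
from .utils import derive_rng, derive_seed

__all__ = [
    "ZIntegratorSpec", "ClassifierConfig", "AttentionScores", "ZIntegrator",
    "AttentionPool", "MilModel", "integrate_z", "attention_scores", "aggregate",
    "classify", "oversample_minority", "train_classifier", "predict_bag",
]

AGGREGATION_MODES = ("meanpool", "maxpool", "attention")


@dataclass(frozen=True)
class ZIntegratorSpec:
    """Two 1D conv + ReLU blocks over the z axis, then a length-agnostic
    collapse of z to one vector.  'same' padding keeps any Z >= 1 valid;
    'select' collapse (keep one plane) exists for attribution diagnostics.

    With ``z_decompose`` the input stack is split into its across-z mean and
    the residual axial profile, stacked as parallel channels.  This is
    information-preserving but makes cross-slice contrasts (the axial signal)
    linearly accessible instead of entangled with slice-shared content.
    """

    n_blocks: int = 2
    kernel_size: int = 3
    channels: tuple[int, ...] = (32, 32)
    z_collapse: str = "mean"  # mean | max | select
    select_index: int | None = None
    z_decompose: bool = True

    def __post_init__(self):
        if self.n_blocks < 1 or len(self.channels) != self.n_blocks:
            raise ConfigurationError("channels must list one width per block")
        if self.z_collapse not in ("mean", "max", "select"):
            raise ConfigurationError("z_collapse must be mean, max or select")
        if self.z_collapse == "select" and self.select_index is None:
            raise ConfigurationError("select collapse needs select_index")


@dataclass(frozen=True)
class ClassifierConfig:
    """MIL head training settings.  Batch size is fixed at one specimen
    because bags have varying tile counts."""

    aggregation_mode: str = "attention"
    learning_rate: float = 0.0001
    epochs: int = 100
    early_stop_patience: int = 10
    oversample_minority: bool = True
    attention_hidden: int = 16
    weight_decay: float = 0.0
    restarts: int = 1  # independent inits; keep the lowest-training-loss run
    seed: int = 0

    batch_size: int = 1  # fixed; one specimen per step

    def __post_init__(self):
        if self.aggregation_mode not in AGGREGATION_MODES:
            raise ConfigurationError(
                f"aggregation_mode must be one of {AGGREGATION_MODES}")
        if self.batch_size != 1:
            raise ConfigurationError("batch_size is fixed at 1 specimen")


@dataclass
class AttentionScores:
    """Nonnegative per-tile weights over a bag, summing to 1."""

    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 1 or self.weights.size < 1:
            raise ValidationError("weights must be a length-N vector")
        if np.any(self.weights < -1e-12):
            raise ValidationError("attention weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-6:
            raise ValidationError("attention weights must sum to 1")


class ZIntegrator(nn.Module):
    """(N, D, Z) feature stacks -> (N, C) tile representations."""

    def __init__(self, in_dim: int, spec: ZIntegratorSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        eff_in = 2 * in_dim if spec.z_decompose else in_dim
        widths = [eff_in, *spec.channels]
        self.blocks = []
        for i in range(spec.n_blocks):
            conv = nn.Conv1d(widths[i], widths[i + 1], spec.kernel_size, rng=rng,
                             padding="same")
            self.blocks.append(conv)
            setattr(self, f"block{i}", conv)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h = x
        if self.spec.z_decompose:
            zmean = h.mean(axis=2, keepdims=True)
            ones = nn.Tensor(np.ones((1, 1, h.shape[2])))
            h = nn.concatenate([h - zmean * ones, zmean * ones], axis=1)
        for conv in self.blocks:
            h = conv(h).relu()
        if self.spec.z_collapse == "mean":
            return h.mean(axis=2)
        if self.spec.z_collapse == "max":
            return h.max(axis=2)
        return h[:, :, self.spec.select_index]


class AttentionPool(nn.Module):
    """Tanh-gated two-layer scoring followed by softmax over the bag."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.v = nn.Linear(in_dim, hidden, rng=rng)
        self.w = nn.Linear(hidden, 1, rng=rng)

    def forward(self, tile_reprs: nn.Tensor) -> nn.Tensor:
        raw = self.w(self.v(tile_reprs).tanh()).reshape(-1)  # (N,)
        return nn.softmax(raw, axis=0)


class MilModel(nn.Module):
    """z-integrator + aggregation + linear-softmax classifier for one marker."""

    def __init__(self, feature_dim: int, zspec: ZIntegratorSpec,
                 config: ClassifierConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else derive_rng(config.seed, "mil-init")
        self.config = config
        self.zspec = zspec
        self.integrator = ZIntegrator(feature_dim, zspec, rng)
        d_repr = zspec.channels[-1]
        self.attention = AttentionPool(d_repr, config.attention_hidden, rng)
        self.classifier = nn.Linear(d_repr, 2, rng=rng)

    def forward(self, bag_features: nn.Tensor
                ) -> tuple[nn.Tensor, nn.Tensor | None]:
        """(N, D, Z) -> (class probabilities (2,), attention weights (N,) or None)."""
        reprs = self.integrator(bag_features)  # (N, C)
        mode = self.config.aggregation_mode
        weights = None
        if mode == "attention":
            weights = self.attention(reprs)
            bag = (weights.reshape(-1, 1) * reprs).sum(axis=0)
        elif mode == "meanpool":
            bag = reprs.mean(axis=0)
        else:
            bag = reprs.max(axis=0)
        logits = self.classifier(bag)
        return nn.softmax(logits, axis=0), weights

    def forward_logits(self, bag_features: nn.Tensor) -> nn.Tensor:
        reprs = self.integrator(bag_features)
        mode = self.config.aggregation_mode
        if mode == "attention":
            weights = self.attention(reprs)
            bag = (weights.reshape(-1, 1) * reprs).sum(axis=0)
        elif mode == "meanpool":
            bag = reprs.mean(axis=0)
        else:
            bag = reprs.max(axis=0)
        return self.classifier(bag)


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def integrate_z(features: np.ndarray, integrator: ZIntegrator) -> np.ndarray:
    """One tile's (D, Z) feature stack -> representation vector."""
    arr = np.asarray(features, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError("features must be (D, Z)")
    with nn.no_grad():
        out = integrator(nn.Tensor(arr[None]))
    return out.data[0].copy()


def attention_scores(tile_reprs: np.ndarray, attention: AttentionPool
                     ) -> AttentionScores:
    """Softmax-normalized per-tile importance; permutation-equivariant."""
    arr = np.asarray(tile_reprs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValidationError("tile_reprs must be (N, D')")
    with nn.no_grad():
        w = attention(nn.Tensor(arr))
    return AttentionScores(weights=w.data.copy())


def aggregate(tile_reprs: np.ndarray, mode: str,
              scores: AttentionScores | None = None) -> np.ndarray:
    """Bag representation: column means (meanpool), column maxima (maxpool),
    or attention-weighted column sums."""
    arr = np.asarray(tile_reprs, dtype=np.float64)
    if mode not in AGGREGATION_MODES:
        raise ConfigurationError(f"unknown aggregation mode {mode!r}")
    if mode == "attention":
        if scores is None:
            raise ValidationError("attention aggregation requires scores")
        if scores.weights.shape[0] != arr.shape[0]:
            raise ValidationError("scores length must match tile count")
        return scores.weights @ arr
    if mode == "meanpool":
        return arr.mean(axis=0)
    return arr.max(axis=0)


def classify(bag_repr: np.ndarray, classifier: nn.Linear) -> np.ndarray:
    """Probability vector over (negative, positive); sums to 1."""
    arr = np.asarray(bag_repr, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("bag representation must be finite")
    with nn.no_grad():
        p = nn.softmax(classifier(nn.Tensor(arr)), axis=0)
    return p.data.copy()


def oversample_minority(specimen_ids: Sequence[str], labels: Mapping[str, int],
                        seed: int) -> list[str]:
    """Per-epoch training multiset with balanced classes: every majority id
    once, minority ids drawn with replacement up to the majority count.
    Balanced input is returned unchanged."""
    ids = list(specimen_ids)
    pos = [i for i in ids if labels[i] == 1]
    neg = [i for i in ids if labels[i] == 0]
    if not pos or not neg:
        raise DataError("oversampling requires both classes present")
    if len(pos) == len(neg):
        return ids
    minority, majority = (pos, neg) if len(pos) < len(neg) else (neg, pos)
    rng = derive_rng(seed, "oversample")
    draws = [minority[int(k)] for k in rng.integers(0, len(minority), size=len(majority))]
    return list(majority) + draws


def train_classifier(features_by_specimen: Mapping[str, np.ndarray],
                     labels: Mapping[str, int], config: ClassifierConfig,
                     zspec: ZIntegratorSpec,
                     ) -> tuple[MilModel, list[float], set[str]]:
    """End-to-end training of integrator, attention and classifier on frozen
    feature stacks (no feature augmentation), one optimizer step per specimen.

    With ``restarts`` > 1 the run is repeated from independent
    initializations and the model with the lowest final training loss is
    kept (a standard guard against bad small-model inits).

    Returns (model, per-epoch mean loss trace, consumed specimen ids) — the
    consumed set is the fold-hygiene audit record.
    """
    best = None
    for r in range(max(1, config.restarts)):
        cfg_r = dataclasses.replace(config, restarts=1,
                                    seed=derive_seed(config.seed, "restart", r)) \
            if config.restarts > 1 else config
        result = _train_once(features_by_specimen, labels, cfg_r, zspec)
        if best is None or result[1][-1] < best[1][-1]:
            best = result
    return best


def _train_once(features_by_specimen: Mapping[str, np.ndarray],
                labels: Mapping[str, int], config: ClassifierConfig,
                zspec: ZIntegratorSpec,
                ) -> tuple[MilModel, list[float], set[str]]:
    ids = sorted(features_by_specimen)
    if not ids:
        raise DataError("empty training set")
    n_pos = sum(labels[i] == 1 for i in ids)
    n_neg = len(ids) - n_pos
    if min(n_pos, n_neg) < 2:
        raise DataError("need at least 2 specimens per class to train")
    feature_dim = next(iter(features_by_specimen.values())).shape[1]
    model = MilModel(feature_dim, zspec, config)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate,
                  weight_decay=config.weight_decay)
    rng = derive_rng(config.seed, "clf-train")
    consumed: set[str] = set()

    trace: list[float] = []
    best = np.inf
    stale = 0
    for epoch in range(config.epochs):
        if config.oversample_minority and n_pos != n_neg:
            epoch_ids = oversample_minority(ids, labels, seed=config.seed + epoch)
        else:
            epoch_ids = list(ids)
        order = rng.permutation(len(epoch_ids))
        losses = []
        for k in order:
            sid = epoch_ids[int(k)]
            consumed.add(sid)
            x = nn.Tensor(features_by_specimen[sid])
            logits = model.forward_logits(x)
            loss = nn.cross_entropy(logits, int(labels[sid]))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        mean_loss = float(np.mean(losses))
        trace.append(mean_loss)
        if mean_loss < best - 1e-4:
            best = mean_loss
            stale = 0
        else:
            stale += 1
            if stale >= config.early_stop_patience:
                break
    model.eval()
    return model, trace, consumed


def predict_bag(model: MilModel, bag_features: np.ndarray
                ) -> tuple[np.ndarray, AttentionScores | None]:
    """Inference on one bag: (probability vector, attention scores or None).

    Deterministic, and invariant to tile order (probabilities identical,
    scores permuted consistently with the tiles).
    """
    arr = np.asarray(bag_features, dtype=np.float64)
    if arr.ndim != 3:
        raise ValidationError("bag features must be (N, D, Z)")
    with nn.no_grad():
        probs, weights = model(nn.Tensor(arr))
    scores = AttentionScores(weights=weights.data.copy()) if weights is not None else None
    return probs.data.copy(), scores
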