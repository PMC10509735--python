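"""Platform configuration: one YAML document with per-stage sections, strict
key checking, full-scale defaults, and a desk-scale preset for CPU runs.

Full-scale defaults mirror the emulated study settings (256 px tiles, 17
planes at 0.5 µm, contrastive batch 256 for 250 epochs at lr 3e-4, MIL head
at lr 1e-4 with one specimen per step, 5-fold cross-validation).  The
desk-scale preset shrinks tiles, stack depth and training budgets so the full
pipeline runs in minutes on one CPU while exercising identical code paths.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, get_origin

import yaml

from .contrastive import AugmentationConfig, EncoderSpec, SslConfig
from .errors import ConfigurationError
from .mil import ClassifierConfig, ZIntegratorSpec
from .simulate import SynthConfig
from .utils import content_hash

__all__ = [
    "CohortConfig", "PreprocessConfig", "EvaluateConfig", "InterpretConfig",
    "PlatformConfig", "load_config", "save_config", "report_dimension_stats",
    "desk_scale",
]


@dataclass(frozen=True)
class CohortConfig:
    n_specimens: int = 20
    positive_fraction: float = 0.5

    def __post_init__(self):
        if self.n_specimens < 2:
            raise ConfigurationError("n_specimens must be >= 2")
        if not (0.0 < self.positive_fraction < 1.0):
            raise ConfigurationError("positive_fraction must be in (0, 1)")


@dataclass(frozen=True)
class PreprocessConfig:
    tile_size: int = 256
    register: bool = True

    def __post_init__(self):
        if self.tile_size < 1:
            raise ConfigurationError("tile_size must be >= 1")


@dataclass(frozen=True)
class EvaluateConfig:
    k: int = 5
    marker: str = "ER"
    mode: str = "attention"
    use_ssl: bool = True

    def __post_init__(self):
        if self.k < 2:
            raise ConfigurationError("k must be >= 2")


@dataclass(frozen=True)
class InterpretConfig:
    downscale: int = 4
    colormap: str = "inferno"
    n_heatmaps: int = 3


@dataclass(frozen=True)
class PlatformConfig:
    """Nested per-stage sections plus global seed and output root."""

    seed: int = 0
    deterministic: bool = True
    out_root: str = "runs"
    synth: SynthConfig = field(default_factory=SynthConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    encoder: EncoderSpec = field(default_factory=EncoderSpec)
    ssl: SslConfig = field(default_factory=SslConfig)
    augment: AugmentationConfig = field(default_factory=AugmentationConfig)
    zintegrator: ZIntegratorSpec = field(default_factory=ZIntegratorSpec)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)
    interpret: InterpretConfig = field(default_factory=InterpretConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def section_hash(self, *sections: str) -> str:
        d = self.to_dict()
        return content_hash({s: d[s] for s in sections})


_TUPLE_FIELDS_OK = (list, tuple)


def _coerce(value: Any, ftype: Any, path: str) -> Any:
    origin = get_origin(ftype)
    if origin is tuple and isinstance(value, _TUPLE_FIELDS_OK):
        return tuple(value)
    if ftype is float and isinstance(value, int) and not isinstance(value, bool):
        return float(value)
    if ftype in (int, float, str, bool) and not isinstance(value, ftype):
        # allow Optional[int]-style unions to fall through
        if origin is None:
            raise ConfigurationError(
                f"type mismatch at {path}: expected {getattr(ftype, '__name__', ftype)}, "
                f"got {type(value).__name__}")
    return value


def _build_section(dc_cls: type, data: dict | None, path: str):
    if data is None:
        return dc_cls()
    if not isinstance(data, dict):
        raise ConfigurationError(f"section {path} must be a mapping")
    import typing
    hints = typing.get_type_hints(dc_cls)
    field_names = {f.name for f in dataclasses.fields(dc_cls)}
    unknown = set(data) - field_names
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigurationError(f"unknown key {path}.{key}")
    kwargs = {}
    for name, value in data.items():
        kwargs[name] = _coerce(value, hints.get(name, Any), f"{path}.{name}")
    return dc_cls(**kwargs)


_SECTIONS: dict[str, type] = {
    "synth": SynthConfig, "cohort": CohortConfig, "preprocess": PreprocessConfig,
    "encoder": EncoderSpec, "ssl": SslConfig, "augment": AugmentationConfig,
    "zintegrator": ZIntegratorSpec, "classifier": ClassifierConfig,
    "evaluate": EvaluateConfig, "interpret": InterpretConfig,
}


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> PlatformConfig:
    """Build a PlatformConfig from a YAML file (empty or missing sections take
    defaults) with strict schema checking: unknown keys and type mismatches
    raise a configuration error naming the offending key path."""
    doc: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError("config root must be a mapping")
        doc = loaded
    if overrides:
        for key, value in overrides.items():
            section, _, leaf = key.partition(".")
            if leaf:
                doc.setdefault(section, {})[leaf] = value
            else:
                doc[key] = value

    known_top = {"seed", "deterministic", "out_root", *_SECTIONS}
    unknown = set(doc) - known_top
    if unknown:
        raise ConfigurationError(f"unknown key {sorted(unknown)[0]}")
    kwargs: dict[str, Any] = {}
    for name in ("seed", "deterministic", "out_root"):
        if name in doc:
            kwargs[name] = _coerce(doc[name], {"seed": int, "deterministic": bool,
                                               "out_root": str}[name], name)
    for name, dc_cls in _SECTIONS.items():
        kwargs[name] = _build_section(dc_cls, doc.get(name), name)
    return PlatformConfig(**kwargs)


def save_config(config: PlatformConfig, path: str | Path) -> Path:
    """Echo of the fully resolved config, written beside run outputs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    d = config.to_dict()
    d["config_hash"] = content_hash(config.to_dict())
    path.write_text(yaml.safe_dump(d, sort_keys=True, default_flow_style=False))
    return path


def report_dimension_stats(config: PlatformConfig) -> dict[str, float]:
    """Per-slice dimensionality bookkeeping: a tile slice of tile_size^2 x 3
    raw values is encoded into feature_dim numbers, a reduction by
    tile_size^2 * 3 / feature_dim (192x at 256 px tiles and 1024-dim
    features)."""
    tile = config.synth.tile_size
    d = config.ssl.feature_dim
    per_slice_input = tile * tile * 3
    return {
        "per_slice_input_dim": per_slice_input,
        "per_slice_feature_dim": d,
        "reduction_factor": per_slice_input / d,
    }


def desk_scale(seed: int = 0, *, n_specimens: int = 20, n_slices: int = 5,
               tile_size: int = 32, marker: str = "ER",
               mode: str = "attention") -> PlatformConfig:
    """Desk-scale preset: the full pipeline at CPU-minutes cost.

    32 px tiles, a 5-plane stack, a 3-block encoder with 32-dim features,
    two contrastive epochs over a capped slice budget, and a 30-epoch MIL
    head.  Scene geometry (nucleus radius ~3 px, ~10 nuclei/tile) scales the
    default histology to the smaller tile.
    """
    return PlatformConfig(
        seed=seed,
        synth=SynthConfig(tile_size=tile_size, n_slices=n_slices,
                          nuclei_density=10.0, nucleus_radius_px=3.0,
                          nucleus_radius_sd=0.6, morphology_effect=2.5,
                          tiles_per_specimen_range=(3, 6), seed=seed),
        cohort=CohortConfig(n_specimens=n_specimens, positive_fraction=0.5),
        preprocess=PreprocessConfig(tile_size=tile_size),
        encoder=EncoderSpec(input_size=tile_size, feature_dim=32,
                            conv_widths=(8, 16, 32)),
        ssl=SslConfig(batch_size=32, epochs=2, learning_rate=0.001,
                      projection_dim=16, feature_dim=32,
                      max_slices_per_epoch=256, seed=seed),
        # milder view menu than the full-scale defaults: at 32 px the
        # strongest crops/solarization make positives unmatchable for a
        # small encoder and contrastive training stalls
        augment=AugmentationConfig(crop_scale_range=(0.7, 1.0),
                                   brightness=0.2, contrast=0.2, saturation=0.2,
                                   hue=0.05, color_jitter_prob=0.5,
                                   grayscale_prob=0.0, gaussian_blur_prob=0.2,
                                   blur_sigma_range=(0.1, 0.8),
                                   solarize_prob=0.0, output_size=tile_size),
        zintegrator=ZIntegratorSpec(channels=(16, 16), z_collapse="max"),
        classifier=ClassifierConfig(learning_rate=0.003, epochs=30, seed=seed,
                                    attention_hidden=16, weight_decay=0.02),
        evaluate=EvaluateConfig(k=5, marker=marker, mode=mode),
        interpret=InterpretConfig(downscale=1),
    )


def ablation_scale(seed: int = 0) -> dict:
    """Study conditions of the stack-vs-virtual ablation at desk scale.

    The class signal is a fine-textured granule pinned to the first focal
    plane of a 9-plane stack at 1.5 µm spacing, with no morphology signal;
    nuclei anchor the best-focus metric to the central plane.  The MIL head
    is kept deliberately small (8-channel integrator, max z-collapse, weight
    decay, two restarts) because the axial signal is subtle at this scale,
    and the encoder is the frozen random baseline: contrastive pretraining
    with blur augmentations would train away defocus sensitivity, which is
    the very signal under study.
    """
    import dataclasses as _dc
    base = desk_scale(seed=seed)
    synth_signal = SynthConfig(
        tile_size=32, n_slices=9, slice_interval=1.5, nuclei_density=14.0,
        nucleus_radius_px=3.0, nucleus_radius_sd=0.6, morphology_effect=0.0,
        signal_slice_bias=0, signal_granules=3,
        tiles_per_specimen_range=(4, 4), distractor_rate=0.3, seed=seed)
    synth_control = _dc.replace(synth_signal, signal_slice_bias=4)
    cv_kwargs = dict(
        mode="meanpool",
        encoder_spec=base.encoder, ssl_config=base.ssl, aug_config=base.augment,
        zspec=_dc.replace(base.zintegrator, channels=(8, 8)),
        clf_config=_dc.replace(base.classifier, epochs=100, weight_decay=0.1,
                               attention_hidden=8,
                               aggregation_mode="meanpool", restarts=2),
        use_ssl=False, k=2)
    return {"synth_signal": synth_signal, "synth_control": synth_control,
            "n_specimens": 150, "cv_kwargs": cv_kwargs}
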