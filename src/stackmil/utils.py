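"""Seeding discipline and content hashing shared by all stages.

Every stochastic component derives its generator from a global seed plus a
fixed stage tag, so one integer reproduces an entire run and independent
stages never share a stream.
"""

from __future__ import annotations

import hashlib
import json
from typing import Any

import numpy as np

__all__ = ["derive_rng", "derive_seed", "content_hash"]


def _tag_entropy(tag: str) -> int:
    digest = hashlib.sha256(tag.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big")


def derive_seed(seed: int, *tags: str | int) -> int:
    """A deterministic child seed (< 2**31) from a root seed and tags."""
    parts = [int(seed)] + [_tag_entropy(str(t)) for t in tags]
    ss = np.random.SeedSequence(parts)
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def derive_rng(seed: int, *tags: str | int) -> np.random.Generator:
    """Generator for stage ``tags`` under global ``seed``; pure in its inputs."""
    parts = [int(seed)] + [_tag_entropy(str(t)) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(parts))


def _canonical(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _canonical(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def content_hash(obj: Any) -> str:
    """Stable sha256 hex digest of a JSON-serializable object tree."""
    payload = json.dumps(_canonical(obj), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()
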