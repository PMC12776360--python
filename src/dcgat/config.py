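"""Structured run configuration: YAML file merged with CLI overrides.

Every artifact-producing run writes the fully resolved configuration next
to its outputs together with a content hash, so results can always be
traced back to an exact parameterization.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional, Tuple

import yaml

__all__ = ["RunConfig", "load_config", "resolved_hash", "write_resolved"]


@dataclass
class RunConfig:
    # model
    hidden_dim: int = 32
    n_layers: int = 2
    n_heads: int = 2
    cns_hidden: int = 16
    temperature: float = 1.0
    threshold_percentile: float = 10.0
    threshold_absolute: Optional[float] = None
    normalize_embeddings: bool = False
    include_self: bool = True
    share_cns: bool = False
    delta: float = 1.0
    gamma: float = 1.0
    lam: float = 0.1
    tau_c: float = 0.5
    contrastive_similarity: str = "cosine"
    head_hidden: Tuple[int, ...] = (64, 32)
    dropout: float = 0.0
    # optimization
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 200
    patience: int = 20
    # protocol
    split: str = "warm"
    ratios: Tuple[float, float, float] = (0.79, 0.01, 0.20)
    negative_ratio: int = 1
    repeats: int = 10
    seed: int = 0
    variant: str = "full"

    def model_params(self) -> dict:
        keys = (
            "hidden_dim", "n_layers", "n_heads", "cns_hidden", "temperature",
            "threshold_percentile", "threshold_absolute", "normalize_embeddings",
            "include_self", "share_cns", "delta", "gamma", "lam", "tau_c",
            "contrastive_similarity", "head_hidden", "dropout", "learning_rate",
            "batch_size", "max_epochs", "patience", "variant",
        )
        d = asdict(self)
        return {k: d[k] for k in keys}


def load_config(path: Optional[str] = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus overrides (flags win)."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    valid = {f.name for f in fields(RunConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    for key in ("ratios", "head_hidden"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return RunConfig(**data)


def resolved_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_resolved(cfg: RunConfig, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = asdict(cfg)
    payload["config_hash"] = resolved_hash(cfg)
    path = out_dir / "resolved_config.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    return path
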