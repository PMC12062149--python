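"""Validated run configuration (YAML) shared by the CLI subcommands.

Defaults reproduce the standard analysis settings of the 40-target
paradigm: the nine parieto-occipital channels, five reference harmonics,
five sub-bands, 0.14 s visual latency, 1 s analysis window.  Unknown keys
are rejected so typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .simulate import OCCIPITAL_CHANNELS

__all__ = ["ClusteringConfig", "RunConfig", "load_config", "config_hash"]


class ClusteringConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    h_range: list[int] = Field(default_factory=lambda: [2, 3, 4, 5, 6, 7, 8])
    restarts: int = 3


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    channels: list[str] = Field(default_factory=lambda: list(OCCIPITAL_CHANNELS))
    window_s: float = 1.0
    latency_s: float = 0.14
    n_harmonics: int = 5
    n_subbands: int = 5
    method: str = "htrcca"
    gaze_shift_s: float = 0.0
    seed: int = 0
    clustering: ClusteringConfig = Field(default_factory=ClusteringConfig)


def load_config(path=None) -> RunConfig:
    """Load and validate a YAML run configuration; defaults when path is None."""
    if path is None:
        return RunConfig()
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return RunConfig(**raw)


def config_hash(config: RunConfig) -> str:
    """Short stable hash of a configuration, for provenance tagging."""
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
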