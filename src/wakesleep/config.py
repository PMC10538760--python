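"""Experiment configuration: schema-validated YAML/JSON with defaults."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["ExperimentConfig", "load_config"]


@dataclass
class ExperimentConfig:
    """Everything a run needs; unknown keys are rejected by name."""

    algorithm: str = "wake_sleep"          # wake_sleep | oscillatory | elbo
    # data
    n_images: int = 4096
    image_size: int = 16
    n_classes: int = 5
    idx_images: str | None = None          # optional real-MNIST IDX path
    idx_labels: str | None = None
    # architecture
    latent_dim: int = 16
    hidden_dim: int = 64
    disc_hidden: int = 64
    n_cells: int = 4
    subset_frac: float = 0.5
    recurrence_steps: int = 1
    # optimization
    batch_size: int = 128
    epochs: int = 30
    model_lr: float = 1e-4
    disc_lr: float = 4e-4
    lam: float = 1.0
    feature_coef: float = 1.0
    decay_factor: float = 0.96
    decay_window: tuple = (200, 250)
    # evaluation
    n_eval: int = 5000
    n_x_units: int = 16
    n_z_units: int = 16
    # toy experiment
    toy_steps: int = 2000
    toy_batch: int = 256
    toy_seeds: int = 5
    toy_w_bc: float = 1.0
    # bookkeeping
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self):
        if self.algorithm not in ("wake_sleep", "oscillatory", "elbo"):
            raise ValueError(f"invalid key 'algorithm': {self.algorithm!r}")
        self.decay_window = tuple(self.decay_window)
        for key in ("epochs", "batch_size", "n_images", "toy_steps"):
            if getattr(self, key) < 1:
                raise ValueError(f"invalid key '{key}': must be >= 1")

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["decay_window"] = list(d["decay_window"])
        return d


def load_config(path=None, overrides=None):
    """Load a YAML or JSON config; missing keys take documented defaults.

    Unknown keys raise a ValueError naming the offending key. The
    resolved config round-trips through ``to_dict``/``load_config``
    unchanged.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        if text.strip():
            raw = (json.loads(text) if str(path).endswith(".json")
                   else yaml.safe_load(text))
            if raw is None:
                raw = {}
            if not isinstance(raw, dict):
                raise ValueError("config must be a mapping")
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in dataclasses.fields(ExperimentConfig)}
    for key in raw:
        if key not in valid:
            raise ValueError(f"unknown config key: '{key}'")
    return ExperimentConfig(**raw)
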