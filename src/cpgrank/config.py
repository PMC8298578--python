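"""Run configuration: YAML (JSON is valid YAML) with validated defaults."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Thresholds and sizes governing a full run.

    p_pos: EWAS p-value at or below which an array CpG enters the
      positive training set (the study design uses 1e-7..1e-5).
    p_neg: p-value above which (in every trait) a CpG is eligible as a
      matched negative.
    neg_pos_ratio: matched negatives per positive.
    top_k_rank / top_k_consensus: per-learner ranking depth and the
      consensus feature-set size.
    outer_folds / inner_folds: nested cross-validation layout.
    tuning_budget: hyperparameter configurations evaluated per learner
      per outer fold.
    max_beta_diff: guard on the beta-value distance of a matched pair.
    cluster_gap_bp: CpGs closer than this are merged into one validation
      cluster.
    detached_spacing_bp: minimum distance between top loci reported
      genome-wide.
    """

    p_pos: float = 1e-5
    p_neg: float = 0.40
    neg_pos_ratio: int = 10
    top_k_rank: int = 100
    top_k_consensus: int = 60
    outer_folds: int = 10
    inner_folds: int = 3
    tuning_budget: int = 50
    threshold: float = 0.5
    max_beta_diff: float = 0.1
    cluster_gap_bp: int = 500
    detached_spacing_bp: int = 10_000
    composite: str = "sum"
    seed: int = 0

    def validate(self) -> "RunConfig":
        if self.neg_pos_ratio <= 0:
            raise ValueError(f"neg_pos_ratio must be positive, got {self.neg_pos_ratio}")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError(
                f"cross-validation needs >=2 folds (outer={self.outer_folds}, inner={self.inner_folds})"
            )
        if not (0 < self.p_pos <= 1) or not (0 < self.p_neg < 1):
            raise ValueError("p thresholds must lie in (0,1)")
        if self.composite not in ("sum", "mean", "max"):
            raise ValueError(f"unknown composite rule {self.composite!r}")
        return self

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML/JSON config, applying defaults for absent keys.

    Unknown keys produce a warning, not an error, so configs written by
    newer versions still load.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        if text.strip():
            try:
                data = yaml.safe_load(text)
            except yaml.YAMLError:
                data = json.loads(text)
            if data is None:
                data = {}
            if not isinstance(data, dict):
                raise ValueError(f"{path}: config must be a key-value mapping")
    if overrides:
        data.update(overrides)
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    for key in sorted(unknown):
        log.warning("ignoring unknown config key %r", key)
    # YAML 1.1 reads bare scientific notation ("1e-6") as a string; coerce
    # every known key to its declared field type
    types = {f.name: f.type for f in fields(RunConfig)}
    casts = {"float": float, "int": int, "str": str}
    kwargs = {}
    for k, v in data.items():
        if k in known:
            kwargs[k] = casts.get(types[k], lambda x: x)(v)
    cfg = RunConfig(**kwargs)
    return cfg.validate()
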