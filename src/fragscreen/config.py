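"""Run configuration, defaults and deterministic seed derivation.

One global ``rng_seed`` reproduces an entire run: per-stage seeds are the
first word of a child of ``numpy.random.SeedSequence(rng_seed)``, spawned
in the fixed stage order below, reduced mod 2**31.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .augment import AugmentationConfig
from .screen import HitFilterCriteria
from .synth import AssayGeneratorConfig, SARGeneratorConfig
from .train import SplitSpec, TrainConfig

STAGE_NAMES = ("sar", "library", "augment", "split", "train", "screen", "assay")


def derive_stage_seeds(rng_seed: int) -> dict:
    children = np.random.SeedSequence(rng_seed).spawn(len(STAGE_NAMES))
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(STAGE_NAMES, children)}


@dataclass
class RunConfig:
    # input paths; None means "synthesize in demo mode"
    seeds_path: str | None = None
    library_path: str | None = None
    assay_path: str | None = None
    demo: bool = False
    demo_n_active: int = 30
    demo_n_inactive: int = 20
    demo_library_size: int = 300
    train_fraction: float = 0.75
    paper_mode: bool = False       # augment the training side only
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        cv_folds=10, grid={"n_estimators": [200], "max_depth": [None]}))
    filters: HitFilterCriteria = field(default_factory=HitFilterCriteria)
    edge_threshold: float = 0.4
    tsne_perplexity: float = 30.0
    r2_min: float = 0.18
    rng_seed: int = 0
    log_level: str = "INFO"

    def stage_seeds(self) -> dict:
        return derive_stage_seeds(self.rng_seed)

    def split_spec(self) -> SplitSpec:
        return SplitSpec(test_fraction=1.0 - self.train_fraction,
                         rng_seed=self.stage_seeds()["split"],
                         group_by_parent=True)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, klass in (("augmentation", AugmentationConfig),
                           ("train", TrainConfig),
                           ("filters", HitFilterCriteria)):
            if key in d and isinstance(d[key], dict):
                sub = {k: (tuple(v) if isinstance(v, list) else v)
                       for k, v in d[key].items()}
                d[key] = klass(**sub)
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_assay_configs(rng_seed: int) -> list[AssayGeneratorConfig]:
    """Demo assay fixtures: one clear partial inhibitor, one flat curve."""
    return [
        AssayGeneratorConfig(min_resp=40.0, max_resp=100.0, ic50=10.0,
                             hill=1.0, compound="demo_inhibitor",
                             rng_seed=rng_seed),
        AssayGeneratorConfig(min_resp=100.0, max_resp=100.0, ic50=10.0,
                             hill=1.0, compound="demo_inactive",
                             rng_seed=rng_seed + 1),
    ]


def default_sar_config(cfg: RunConfig) -> SARGeneratorConfig:
    return SARGeneratorConfig(n_active=cfg.demo_n_active,
                              n_inactive=cfg.demo_n_inactive,
                              rng_seed=cfg.stage_seeds()["sar"])
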