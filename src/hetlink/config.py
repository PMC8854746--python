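"""Pipeline configuration: dataclasses with the documented defaults plus YAML loading.

Every knob the pipeline exposes lives here so that the published ablations
(KNet / KJNet / KBNet / full) and negative-sampling strategies are reachable
from configuration alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import yaml

VARIANTS = ("KNet", "KJNet", "KBNet", "full")


@dataclass
class SplitConfig:
    ratio: float = 0.9        # train fraction; published protocol is 9:1
    repeats: int = 3          # independent random re-splits
    seed: int = 0


@dataclass
class SimilarityConfig:
    lnc_jaccard_threshold: float = 0.5
    prot_jaccard_threshold: float = 0.0
    lnc_evalue_cutoff: float = 1e-3
    prot_evalue_cutoff: float = 1e-2
    orientation: str = "either"      # asymmetric-hit rule: "either" | "both"
    training_only: bool = True       # association sets from train split only


@dataclass
class WalkConfig:
    num_walks: int = 10
    length: int = 80
    schemes: tuple[str, ...] = ("LPLPL", "LLPPLL")


@dataclass
class EmbedConfig:
    dim: int = 64
    window: int = 5
    epochs: int = 5
    negative: int = 5        # negative samples per skip-gram update
    alpha: float = 0.025     # initial SGD learning rate
    min_alpha: float = 1e-4
    seed: int = 0


@dataclass
class NegativesConfig:
    strategy: str = "subcellular"   # "random" | "subcellular" | "distance"
    distance_min: int | None = None
    distance_max: int | None = None
    resample_per_repeat: bool = True
    seed: int = 0


@dataclass
class ClassifierConfig:
    C: float = 1.0
    gamma: float | str = "scale"
    seed: int = 0


@dataclass
class PipelineConfig:
    variant: str = "full"
    split: SplitConfig = field(default_factory=SplitConfig)
    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)
    walk: WalkConfig = field(default_factory=WalkConfig)
    embed: EmbedConfig = field(default_factory=EmbedConfig)
    negatives: NegativesConfig = field(default_factory=NegativesConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Return a copy with every stage seed derived from one base seed."""
        return replace(
            self,
            split=replace(self.split, seed=seed),
            embed=replace(self.embed, seed=seed),
            negatives=replace(self.negatives, seed=seed),
            classifier=replace(self.classifier, seed=seed),
        )

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        sections = {
            "split": SplitConfig,
            "similarity": SimilarityConfig,
            "walk": WalkConfig,
            "embed": EmbedConfig,
            "negatives": NegativesConfig,
            "classifier": ClassifierConfig,
        }
        kwargs: dict[str, Any] = {}
        for key, value in data.items():
            if key in sections:
                if key == "walk" and "schemes" in value:
                    value = dict(value, schemes=tuple(value["schemes"]))
                kwargs[key] = sections[key](**value)
            elif key == "variant":
                kwargs[key] = value
            else:
                raise ValueError(f"unknown config section {key!r}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
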