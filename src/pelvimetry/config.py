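"""Merged run configuration with JSON (de)serialization.

A :class:`RunConfig` bundles every knob a pipeline run needs --
preprocessing, heatmap targets, localizer training, split parameters
and the global seed -- and round-trips through a single human-readable
JSON file so each run can emit its resolved configuration alongside its
outputs.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .heatmap import HeatmapConfig
from .localizer import LocalizerConfig
from .phantom import PhantomConfig
from .preprocess import PreprocessConfig


@dataclass(frozen=True)
class RunConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    heatmap: HeatmapConfig = field(default_factory=HeatmapConfig)
    localizer: LocalizerConfig = field(default_factory=LocalizerConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    k_folds: int = 5
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)

        def tup(d):
            # every sequence-valued config field is a tuple; JSON stores lists
            return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}

        return cls(
            preprocess=PreprocessConfig(**tup(raw.get("preprocess", {}))),
            heatmap=HeatmapConfig(**tup(raw.get("heatmap", {}))),
            localizer=LocalizerConfig(**tup(raw.get("localizer", {}))),
            phantom=PhantomConfig(**tup(raw.get("phantom", {}))),
            k_folds=raw.get("k_folds", 5),
            seed=raw.get("seed", 0),
        )

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())

    @classmethod
    def tiny(cls, seed: int = 0) -> "RunConfig":
        """CPU-scale phantom-study preset (see methods note)."""
        phantom = PhantomConfig()
        return cls(
            preprocess=PreprocessConfig(
                reference_spacing=phantom.spacing, clip=False
            ),
            heatmap=HeatmapConfig(sigma_voxels=3.0),
            localizer=LocalizerConfig.tiny(seed=seed),
            phantom=phantom,
            seed=seed,
        )
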