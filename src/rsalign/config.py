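"""Pipeline configuration: validated settings with canonical defaults.

Defaults reproduce the canonical analysis grid: five bands
(theta/alpha/beta/gamma/high-gamma with 3/4/5/6/6 wavelet cycles), three
post-stimulus windows (50-250, 150-350, 250-450 ms), baseline -500..-100 ms,
10,000 permutations per probe and 1000 half-size subsets per ROI.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .types import (
    BandSpec,
    DEFAULT_BANDS,
    DEFAULT_BASELINE,
    DEFAULT_WINDOWS,
    LAYER_NAMES,
    VISUAL_AREA_ORDER,
)

#: Diagonal-style planted map used by the synthetic default configuration.
DEFAULT_AREA_LAYER_MAP: dict[str, int] = {"17": 1, "18": 2, "19": 4, "37": 6, "20": 7}


@dataclass
class SynthConfig:
    """Synthetic-generator settings (the study conditions being emulated)."""

    n_stimuli: int = 250
    probes_per_area: int = 10
    snr: float = 10.0
    chain_strength: float = 0.9
    block_break_after: int | None = 5
    area_layer_map: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_AREA_LAYER_MAP)
    )
    distractor_areas: list[str] = field(default_factory=list)
    contacts_per_shaft: int = 5
    fs: float = 1024.0
    apply_bipolar: bool = False


@dataclass
class PipelineConfig:
    bands: list[BandSpec] = field(default_factory=lambda: list(DEFAULT_BANDS))
    windows: list[tuple[float, float]] = field(
        default_factory=lambda: [tuple(w) for w in DEFAULT_WINDOWS]
    )
    baseline: tuple[float, float] = DEFAULT_BASELINE
    alpha_perm: float = 0.001
    fdr_q: float = 0.05
    alpha_align: float = 0.005
    alpha_pairwise: float = 0.005
    n_perm: int = 10_000
    n_perm_align: int = 10_000
    n_subsets: int = 1000
    subset_fraction: float = 0.5
    grid_step: float = 1.0
    seed: int = 0
    area_order: list[str] = field(default_factory=lambda: list(VISUAL_AREA_ORDER))
    layer_names: list[str] = field(default_factory=lambda: list(LAYER_NAMES))
    synth: SynthConfig = field(default_factory=SynthConfig)

    def validate(self) -> None:
        if not self.bands:
            raise ValueError("at least one band required")
        if not self.windows:
            raise ValueError("at least one window required")
        for lo, hi in self.windows:
            if lo >= hi:
                raise ValueError(f"bad window ({lo}, {hi})")
        if self.baseline[1] > 0:
            raise ValueError("baseline must precede stimulus onset")
        for a in (self.alpha_perm, self.fdr_q, self.alpha_align, self.alpha_pairwise):
            if not 0 < a < 1:
                raise ValueError("significance levels must lie in (0, 1)")
        if self.n_perm < 99:
            raise ValueError("n_perm must be at least 99")
        for area in self.synth.area_layer_map:
            if area not in self.area_order:
                raise ValueError(f"planted area {area} not in declared hierarchy")
        for l in self.synth.area_layer_map.values():
            if not 0 <= l < len(self.layer_names):
                raise ValueError(f"planted layer {l} out of range")
        if self.synth.fs < 4 * max(b.f_hi for b in self.bands):
            raise ValueError("fs must be at least 4x the highest band edge")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = [asdict(b) for b in self.bands]
        d["windows"] = [list(w) for w in self.windows]
        d["baseline"] = list(self.baseline)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "bands" in d:
            d["bands"] = [BandSpec(**b) for b in d["bands"]]
        if "windows" in d:
            d["windows"] = [tuple(w) for w in d["windows"]]
        if "baseline" in d:
            d["baseline"] = tuple(d["baseline"])
        if "synth" in d and isinstance(d["synth"], dict):
            d["synth"] = SynthConfig(**d["synth"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def demo_config(seed: int = 0) -> PipelineConfig:
    """A small synthetic configuration that runs end-to-end in minutes."""
    return PipelineConfig(
        seed=seed,
        n_perm=1000,
        n_perm_align=3000,
        n_subsets=100,
        grid_step=3.0,
        synth=SynthConfig(n_stimuli=60, probes_per_area=4, snr=10.0),
    )
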