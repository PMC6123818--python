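"""Core data containers shared across the pipeline.

The pipeline's central objects are small and explicit: epoched recordings
(:class:`EpochSet`), scalar baseline-normalised band-power responses
(:class:`ResponseMatrix`), representational dissimilarity matrices
(:class:`RDM`), ordered layer activation sets (:class:`LayerActivationSet`)
and the per-probe / per-area mapping results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Ordered ventral-stream hierarchy (Brodmann areas, early to late).
VISUAL_AREA_ORDER: tuple[str, ...] = ("17", "18", "19", "37", "20")

#: Default layer names: pixel space followed by five convolutional and
#: three fully connected stages of increasing feature complexity.
LAYER_NAMES: tuple[str, ...] = (
    "pixels", "conv1", "conv2", "conv3", "conv4",
    "conv5", "fc6", "fc7", "fc8",
)


class DegenerateRDMError(ValueError):
    """Raised when a rank correlation is requested on a constant RDM."""


@dataclass(frozen=True)
class BandSpec:
    """A frequency band with its wavelet time-frequency trade-off.

    ``cycles`` is the ratio f0/sigma_f of the Morlet wavelet used for this
    band; the wavelet's temporal width is sigma_t = cycles / (2*pi*f0).
    """

    name: str
    f_lo: float
    f_hi: float
    cycles: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(f"need 0 < f_lo < f_hi, got {self.f_lo}, {self.f_hi}")
        if self.cycles <= 0:
            raise ValueError("cycles must be positive")

    def freqs(self, step: float = 1.0) -> np.ndarray:
        """Discrete frequency grid covering [f_lo, f_hi]."""
        return np.arange(self.f_lo, self.f_hi + step / 2, step)

    @property
    def f_center(self) -> float:
        """Geometric-mean frequency of the band."""
        return float(np.sqrt(self.f_lo * self.f_hi))


#: The five analysis bands with their per-band cycle counts.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("theta", 5, 8, 3),
    BandSpec("alpha", 9, 14, 4),
    BandSpec("beta", 15, 30, 5),
    BandSpec("gamma", 31, 70, 6),
    BandSpec("high_gamma", 71, 150, 6),
)

#: Post-stimulus analysis windows in ms.
DEFAULT_WINDOWS: tuple[tuple[float, float], ...] = ((50, 250), (150, 350), (250, 450))

#: Pre-stimulus baseline window in ms.
DEFAULT_BASELINE: tuple[float, float] = (-500, -100)


@dataclass(frozen=True)
class ROISpec:
    """One region of interest: a frequency band paired with a time window."""

    band: BandSpec
    window: tuple[float, float]
    baseline: tuple[float, float] = DEFAULT_BASELINE

    def __post_init__(self) -> None:
        if self.window[0] >= self.window[1]:
            raise ValueError("window start must precede end")
        if self.baseline[1] > 0:
            raise ValueError("baseline must precede stimulus onset")

    @property
    def roi_id(self) -> str:
        return f"{self.band.name}_{int(self.window[0])}"


@dataclass
class EpochSet:
    """Epoched multi-probe recordings: probe x stimulus x time sample."""

    data: np.ndarray
    fs: float
    t_start: float = -500.0
    probe_ids: Sequence[str] = None
    stimulus_ids: Sequence[str] = None
    valid_mask: np.ndarray = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be probe x stimulus x time")
        n_probes, n_stimuli, _ = self.data.shape
        if self.probe_ids is None:
            self.probe_ids = [f"probe{i}" for i in range(n_probes)]
        if self.stimulus_ids is None:
            self.stimulus_ids = [f"stim{i}" for i in range(n_stimuli)]
        if self.valid_mask is None:
            self.valid_mask = np.ones((n_probes, n_stimuli), dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != (n_probes, n_stimuli):
            raise ValueError("valid_mask shape mismatch")
        if not (self.t_start <= 0 <= self.t_start + self.epoch_length_ms):
            raise ValueError("stimulus onset (t=0) must lie inside the epoch")

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        return self.t_start + np.arange(self.n_times) * 1000.0 / self.fs

    @property
    def epoch_length_ms(self) -> float:
        return self.data.shape[2] * 1000.0 / self.fs


@dataclass
class ResponseMatrix:
    """Scalar response of every probe to every stimulus.

    Each entry is one number per probe per stimulus: for real recordings the
    baseline-normalised band power in a given ROI; for synthetic data the
    planted scalar response. Invalid (artifact-masked) entries are NaN.
    """

    values: np.ndarray
    probe_ids: Sequence[str] = None
    stimulus_ids: Sequence[str] = None
    roi: ROISpec | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be probe x stimulus")
        if self.probe_ids is None:
            self.probe_ids = [f"probe{i}" for i in range(self.values.shape[0])]
        if self.stimulus_ids is None:
            self.stimulus_ids = [f"stim{i}" for i in range(self.values.shape[1])]
        if len(self.probe_ids) != self.values.shape[0]:
            raise ValueError("probe_ids length mismatch")
        if len(self.stimulus_ids) != self.values.shape[1]:
            raise ValueError("stimulus_ids length mismatch")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[1]


@dataclass
class RDM:
    """Representational dissimilarity matrix over stimuli.

    Symmetric, zero-diagonal, non-negative. ``metric`` records how distances
    were computed ("euclidean" for multivariate feature spaces, "absdiff"
    for scalar probe responses — the Euclidean distance between scalars).
    """

    matrix: np.ndarray
    metric: str = "euclidean"
    source: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("RDM must be square")
        if not np.isfinite(m).all():
            raise ValueError("RDM must be finite")
        if np.abs(m - m.T).max(initial=0.0) > 1e-10:
            raise ValueError("RDM must be symmetric")
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 0.0)
        if (m < 0).any():
            raise ValueError("RDM must be non-negative")
        self.matrix = m

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def upper(self) -> np.ndarray:
        """Upper-triangle entries (excluding the diagonal), row-major."""
        iu = np.triu_indices(self.n, k=1)
        return self.matrix[iu]

    @property
    def is_degenerate(self) -> bool:
        """True when all off-diagonal entries are equal (no rank information)."""
        u = self.upper()
        return bool(u.size == 0 or np.ptp(u) == 0)


@dataclass
class LayerActivationSet:
    """Ordered activation matrices, one stimulus x feature matrix per layer.

    Index 0 is the input (pixel) space; deeper indices hold increasingly
    complex feature representations.
    """

    layer_names: Sequence[str]
    activations: Sequence[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.layer_names) != len(self.activations):
            raise ValueError("one name per layer required")
        self.activations = [np.asarray(a, dtype=float) for a in self.activations]
        n_stim = {a.shape[0] for a in self.activations}
        if len(n_stim) > 1:
            raise ValueError("all layers must share n_stimuli")
        for name, a in zip(self.layer_names, self.activations):
            if a.ndim != 2:
                raise ValueError(f"layer {name}: activations must be 2-D")
            if not np.isfinite(a).all():
                raise ValueError(f"layer {name}: non-finite activations")

    @property
    def n_layers(self) -> int:
        return len(self.activations)

    @property
    def n_stimuli(self) -> int:
        return self.activations[0].shape[0]


@dataclass
class ProbePlan:
    """Probe metadata: shaft geometry, area labels and planted targets.

    ``table`` columns: probe_id, shaft_id, contact_index (1 = deepest),
    area, target_layer (NaN = no planted signal), snr.
    """

    table: pd.DataFrame
    area_order: Sequence[str] = VISUAL_AREA_ORDER

    REQUIRED = ("probe_id", "shaft_id", "contact_index", "area", "target_layer", "snr")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"probe plan missing column: {col}")
        dup = self.table.duplicated(subset=["shaft_id", "contact_index"])
        if dup.any():
            raise ValueError("contact indices must be unique within a shaft")
        if (self.table["snr"] < 0).any():
            raise ValueError("snr must be non-negative")
        self.table = self.table.reset_index(drop=True)

    @property
    def n_probes(self) -> int:
        return len(self.table)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table["probe_id"])


@dataclass
class SyntheticTruth:
    """Ground truth planted by the synthetic generators.

    Fully determines regeneration: area -> layer map, per-probe targets,
    the seed and every generator parameter.
    """

    area_layer_map: dict[str, int]
    probe_targets: dict[str, int | None]
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "area_layer_map": self.area_layer_map,
                "probe_targets": self.probe_targets,
                "seed": self.seed,
                "params": self.params,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        targets = {k: (None if v is None else int(v)) for k, v in d["probe_targets"].items()}
        return cls(
            area_layer_map={k: int(v) for k, v in d["area_layer_map"].items()},
            probe_targets=targets,
            seed=int(d["seed"]),
            params=d.get("params", {}),
        )


@dataclass
class ProbeMapping:
    """Per-probe layer correlation profile with permutation significance.

    ``table`` is long-format with one row per (probe, layer): columns
    probe_id, area, layer (int index), rho, p, significant.
    """

    table: pd.DataFrame
    layer_names: Sequence[str] = LAYER_NAMES
    area_order: Sequence[str] = VISUAL_AREA_ORDER
    n_perm: int = 0
    alpha: float = 0.001
    seed: int | None = None
    degenerate_probes: list[str] = field(default_factory=list)

    REQUIRED = ("probe_id", "area", "layer", "rho", "p", "significant")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"mapping table missing column: {col}")
        t = self.table
        ok = t["rho"].abs().le(1 + 1e-12) | t["rho"].isna()
        if not ok.all():
            raise ValueError("rho must lie in [-1, 1]")
        if ((t["p"] <= 0) | (t["p"] > 1)).any():
            raise ValueError("empirical p must lie in (0, 1]")
        bad = t["significant"] & ~((t["p"] < self.alpha) & (t["rho"] > 0))
        if bad.any():
            raise ValueError("significance flags inconsistent with p/rho")
        self.table = t.reset_index(drop=True)

    @property
    def n_probes(self) -> int:
        return self.table["probe_id"].nunique()

    def significant_pairs(self) -> pd.DataFrame:
        """Rows that passed the permutation screen (positive rho)."""
        return self.table[self.table["significant"]].copy()


@dataclass
class MappingMatrix:
    """Area x layer aggregate of significant probe-layer correlations."""

    scores: pd.DataFrame
    sig_counts: pd.DataFrame
    probes_significant: pd.Series
    probes_total: pd.Series
    normalization: str = "significant"

    def __post_init__(self) -> None:
        zero_count = self.sig_counts.values == 0
        if (np.asarray(self.scores.values)[zero_count] != 0).any():
            raise ValueError("score must be 0 where count is 0")


@dataclass
class AlignmentResult:
    """Hierarchy alignment: Spearman correlation between area and layer codes."""

    rho: float
    p: float
    n_pairs: int
    area_codes: np.ndarray
    layer_codes: np.ndarray
    n_perm: int = 0
    method: str = "permutation"

    def __post_init__(self) -> None:
        if len(self.area_codes) != self.n_pairs or len(self.layer_codes) != self.n_pairs:
            raise ValueError("code vectors must have n_pairs entries")
        if not (-1 - 1e-12 <= self.rho <= 1 + 1e-12):
            raise ValueError("rho must lie in [-1, 1]")


@dataclass
class SubsampleDistribution:
    """Alignment scores over random half-size probe subsets of one ROI."""

    roi_id: str
    values: np.ndarray
    subset_fraction: float
    seed: int | None = None
    n_resampled: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (np.abs(self.values) > 1 + 1e-12).any():
            raise ValueError("alignment values must lie in [-1, 1]")

    @property
    def n_subsets(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.values.size > 1 else 0.0
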