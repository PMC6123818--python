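"""Cross-ROI comparison via subsampled alignment distributions.

For every ROI (frequency band x time window) the alignment score is
recomputed on many random probe subsets of half the dataset, giving a
distribution of alignment estimates. One-sided Mann-Whitney U tests between
ROI pairs, Bonferroni-corrected over all ordered pairs, identify ROIs whose
alignment is reliably higher than others'.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .types import ProbeMapping, SubsampleDistribution

__all__ = ["subsample_alignment", "pairwise_roi_tests", "bonferroni"]


def _subset_alignment(mapping: ProbeMapping, probes: np.ndarray, code: dict) -> float:
    """rho_align over the significant pairs of a probe subset; NaN if degenerate."""
    sig = mapping.table[
        mapping.table["significant"] & mapping.table["probe_id"].isin(probes)
    ]
    a = sig["area"].astype(str).map(code).to_numpy(dtype=float)
    l = sig["layer"].to_numpy(dtype=float)
    if len(a) < 2 or len(np.unique(a)) < 2 or len(np.unique(l)) < 2:
        return float("nan")
    ra, rl = rankdata(a), rankdata(l)
    return float(np.corrcoef(ra, rl)[0, 1])


def subsample_alignment(
    mapping: ProbeMapping,
    roi_id: str = "",
    n_subsets: int = 1000,
    fraction: float = 0.5,
    seed: int | None = None,
    max_redraws: int = 1000,
) -> SubsampleDistribution:
    """Alignment distribution over random probe subsets of one ROI.

    Each subset draws ``fraction`` of the mapped probes without replacement
    and recomputes rho_align on their significant pairs. Degenerate draws
    (a single area or layer among the subset's significant pairs) are
    redrawn, and the redraw count is reported in ``n_resampled``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    probes = np.asarray(sorted(mapping.table["probe_id"].unique()))
    k = max(2, int(round(fraction * len(probes))))
    code = {str(a): i for i, a in enumerate(mapping.area_order)}
    rng = np.random.default_rng(seed)
    values = np.empty(n_subsets)
    redraws = 0
    for s in range(n_subsets):
        for _ in range(max_redraws):
            pick = probes if fraction == 1.0 else rng.choice(probes, k, replace=False)
            v = _subset_alignment(mapping, pick, code)
            if np.isfinite(v):
                values[s] = v
                break
            redraws += 1
        else:
            raise RuntimeError(
                "could not draw a non-degenerate subset; too few significant "
                "probes to retain >= 2 areas"
            )
    return SubsampleDistribution(
        roi_id=roi_id, values=values, subset_fraction=fraction,
        seed=seed, n_resampled=redraws,
    )


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-comparison threshold alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be a positive count")
    return alpha / m


def pairwise_roi_tests(
    distributions: list[SubsampleDistribution], alpha: float = 0.005
) -> pd.DataFrame:
    """One-sided Mann-Whitney tests between every ordered pair of ROIs.

    For each ordered pair (i, j), tests whether ROI i's subsampled alignment
    exceeds ROI j's. Pairs are flagged when p falls below the Bonferroni
    threshold alpha / n_roi^2 (self-pairs and both directions counted in the
    correction, matching the printed thresholds).
    """
    if len(distributions) < 2:
        raise ValueError("need at least 2 ROI distributions")
    n = len(distributions)
    thr = bonferroni(alpha, n * n)
    rows = []
    for i, di in enumerate(distributions):
        for j, dj in enumerate(distributions):
            if i == j:
                continue
            if np.ptp(di.values) == 0 and np.ptp(dj.values) == 0 and \
                    di.values[0] == dj.values[0]:
                u, p = float(di.n_subsets * dj.n_subsets / 2), 1.0
            else:
                res = mannwhitneyu(di.values, dj.values, alternative="greater")
                u, p = float(res.statistic), float(res.pvalue)
            rows.append(
                {
                    "roi_a": di.roi_id, "roi_b": dj.roi_id,
                    "mean_a": di.mean, "mean_b": dj.mean,
                    "U": u, "p": p, "significant": p < thr,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["threshold"] = thr
    out.attrs["alpha"] = alpha
    out.attrs["m"] = n * n
    return out


def comparison_summary(
    distributions: list[SubsampleDistribution], tests: pd.DataFrame
) -> pd.DataFrame:
    """Per-ROI summary: mean +/- sd alignment and the ROIs it exceeds."""
    rows = []
    for d in distributions:
        beats = tests[(tests["roi_a"] == d.roi_id) & tests["significant"]]
        rows.append(
            {
                "roi": d.roi_id,
                "mean": d.mean,
                "sd": d.sd,
                "n_subsets": d.n_subsets,
                "exceeds": ",".join(beats["roi_b"]),
            }
        )
    return pd.DataFrame(rows)
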