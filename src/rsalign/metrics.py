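"""Aggregate quantifiers of the probe-to-layer mapping.

Volume (total significant correlation), visual specificity (fraction of
volume in ventral-stream areas), the complexity ratio (fraction of volume in
high-complexity layers), and the hierarchy alignment score rho_align: the
Spearman correlation between probes' positions in the cortical area
hierarchy and the layer positions they significantly map to.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import rankdata, spearmanr

from .types import AlignmentResult, ProbeMapping, VISUAL_AREA_ORDER

__all__ = [
    "volume",
    "visual_specificity",
    "complexity_ratio",
    "alignment_score",
    "alignment_pairs",
]

#: Layer indices counted as high-complexity in the complexity ratio
#: (conv5, fc6, fc7 under the default 0 = pixels indexing).
COMPLEX_LAYERS: tuple[int, ...] = (5, 6, 7)
#: Layers entering the complexity ratio at all; conv4 (transition) and fc8
#: (class probabilities) are omitted.
COMPLEXITY_DENOM_LAYERS: tuple[int, ...] = (1, 2, 3, 5, 6, 7)


class DegenerateAlignmentError(ValueError):
    """Raised when the alignment pairs span a single area or a single layer."""


def volume(
    mapping: ProbeMapping,
    areas: set[str] | None = None,
    layers: set[int] | None = None,
) -> float:
    """Total sum of significant (positive) probe-layer correlations.

    Restricted to the given area and layer subsets; None means all. Additive
    over disjoint area sets and monotone under set enlargement.
    """
    sig = mapping.significant_pairs()
    if areas is not None:
        sig = sig[sig["area"].isin({str(a) for a in areas})]
    if layers is not None:
        sig = sig[sig["layer"].isin({int(l) for l in layers})]
    return float(sig["rho"].sum())


def visual_specificity(
    mapping: ProbeMapping, visual_areas=VISUAL_AREA_ORDER
) -> float:
    """Fraction of total volume located in the ventral-stream areas.

    NaN (with a warning) when the total volume is zero.
    """
    total = volume(mapping)
    if total <= 0:
        warnings.warn("zero total volume: specificity undefined")
        return float("nan")
    return volume(mapping, areas=set(visual_areas)) / total


def complexity_ratio(
    mapping: ProbeMapping,
    areas: set[str] | None = None,
    complex_layers=COMPLEX_LAYERS,
    denom_layers=COMPLEXITY_DENOM_LAYERS,
) -> float:
    """Fraction of volume mapped to high-complexity layers.

    volume(areas, {conv5, fc6, fc7}) / volume(areas, {conv1..3, conv5, fc6, fc7});
    the transition layer conv4 and the class-readout layer fc8 are omitted
    from both sums. NaN (with a warning) when the denominator is zero.
    """
    denom = volume(mapping, areas=areas, layers=set(denom_layers))
    if denom <= 0:
        warnings.warn("zero denominator volume: complexity ratio undefined")
        return float("nan")
    return volume(mapping, areas=areas, layers=set(complex_layers)) / denom


def alignment_pairs(
    mapping: ProbeMapping,
    area_order=None,
    layers: set[int] | None = None,
    areas: set[str] | None = None,
    pairs: str = "all",
) -> tuple[np.ndarray, np.ndarray]:
    """(area code, layer code) pairs from significant probe-layer entries.

    Areas are coded by their rank in the declared hierarchy (0..n_areas-1),
    layers by their index (0..L-1). With ``pairs="all"`` a probe significant
    at several layers contributes one pair per layer; with ``pairs="best"``
    only its highest-rho significant layer.
    """
    if area_order is None:
        area_order = list(mapping.area_order)
    code = {str(a): k for k, a in enumerate(area_order)}
    sig = mapping.significant_pairs()
    sig = sig[sig["area"].astype(str).isin(code)]
    if areas is not None:
        sig = sig[sig["area"].astype(str).isin({str(a) for a in areas})]
    if layers is not None:
        sig = sig[sig["layer"].isin({int(l) for l in layers})]
    if pairs == "best":
        sig = sig.loc[sig.groupby("probe_id")["rho"].idxmax()]
    elif pairs != "all":
        raise ValueError("pairs must be 'all' or 'best'")
    a = sig["area"].astype(str).map(code).to_numpy(dtype=float)
    l = sig["layer"].to_numpy(dtype=float)
    return a, l


def alignment_score(
    mapping: ProbeMapping,
    area_order=None,
    layers: set[int] | None = None,
    areas: set[str] | None = None,
    n_perm: int = 100_000,
    seed: int | np.random.Generator | None = None,
    method: str = "permutation",
    pairs: str = "all",
) -> AlignmentResult:
    """Hierarchy alignment rho_align with one-sided significance.

    rho_align = Spearman(area codes, layer codes) over all significant
    (probe, layer) pairs. Significance of positive alignment is assessed by
    permuting the layer codes against the area codes (``method="permutation"``,
    assumption-free for the heavily tied integer codes) or by the analytic
    large-sample Spearman test (``method="analytic"``).
    """
    a, l = alignment_pairs(mapping, area_order, layers=layers, areas=areas, pairs=pairs)
    if len(np.unique(a)) < 2 or len(np.unique(l)) < 2:
        raise DegenerateAlignmentError(
            "alignment undefined: significant pairs span a single area or layer"
        )
    if method == "analytic":
        res = spearmanr(a, l, alternative="greater")
        return AlignmentResult(
            rho=float(res.statistic), p=float(res.pvalue), n_pairs=len(a),
            area_codes=a, layer_codes=l, n_perm=0, method="analytic",
        )
    if method != "permutation":
        raise ValueError("method must be 'permutation' or 'analytic'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ra, rl = rankdata(a), rankdata(l)
    za = (ra - ra.mean()) / ra.std()
    zl = (rl - rl.mean()) / rl.std()
    n = len(a)
    rho = float(za @ zl / n)
    exceed = 0
    block = max(1, 20_000_000 // n)
    done = 0
    while done < n_perm:
        nb = min(block, n_perm - done)
        perms = np.empty((nb, n), dtype=np.int64)
        for i in range(nb):
            perms[i] = rng.permutation(n)
        null = (zl[perms] @ za) / n
        exceed += int((null >= rho - 1e-15).sum())
        done += nb
    p = (1 + exceed) / (1 + n_perm)
    return AlignmentResult(
        rho=rho, p=float(p), n_pairs=n, area_codes=a, layer_codes=l,
        n_perm=n_perm, method="permutation",
    )
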