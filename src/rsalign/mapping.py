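"""Per-probe representational similarity mapping onto layer hierarchies.

Each probe's scalar responses define a stimulus x stimulus RDM of absolute
differences; Spearman rank correlation between its upper triangle and each
layer RDM's upper triangle gives the probe's layer profile
(rho_pixels ... rho_fc8). Significance is assessed with a permutation test
that reshuffles the response vector, destroying the stimulus-response
pairing, and rebuilds the probe RDM each time. Significant correlations are
aggregated into an area x layer mapping matrix.

The permutation null exploits an exact identity: the RDM of a permuted
response vector is a joint row/column permutation of the original RDM, so
its upper-triangle rank vector is a permutation of the original ranks. Each
null Spearman correlation is then a dot product of standardised rank
vectors, which vectorises over permutations and layers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .types import (
    DegenerateRDMError,
    LayerActivationSet,
    MappingMatrix,
    ProbeMapping,
    ProbePlan,
    RDM,
    ResponseMatrix,
    VISUAL_AREA_ORDER,
)
from .layers import compute_layer_rdm

__all__ = [
    "probe_rdm",
    "rdm_spearman",
    "permutation_layer_test",
    "map_probes",
    "aggregate_area_layer",
]

# permutation index rows processed per block, to bound memory
_PERM_BLOCK_ELEMS = 40_000_000


def probe_rdm(responses: np.ndarray, source: str = "") -> RDM:
    """RDM of a scalar response vector: |r_i - r_j| (Euclidean in 1-D).

    A constant vector yields an all-zero RDM; check ``RDM.is_degenerate``
    before correlating.
    """
    r = np.asarray(responses, dtype=float).ravel()
    if r.size < 2:
        raise ValueError("need at least 2 stimuli")
    if not np.isfinite(r).all():
        raise ValueError("responses must be finite")
    return RDM(matrix=np.abs(r[:, None] - r[None, :]), metric="absdiff", source=source)


def rdm_spearman(a: RDM, b: RDM) -> float:
    """Spearman rank correlation between two RDMs' upper triangles."""
    if a.n != b.n:
        raise ValueError("RDMs must have the same size")
    if a.is_degenerate or b.is_degenerate:
        raise DegenerateRDMError("constant RDM has no rank structure")
    return float(spearmanr(a.upper(), b.upper()).statistic)


def _rank_standardise(x: np.ndarray) -> np.ndarray:
    """Average-tie ranks, centred and scaled to unit population variance."""
    from scipy.stats import rankdata

    r = rankdata(x)
    sd = r.std()
    if sd == 0:
        raise DegenerateRDMError("constant vector has no rank structure")
    return (r - r.mean()) / sd


class _LayerRDMBank:
    """Precomputed standardised rank vectors for a fixed set of layer RDMs."""

    def __init__(self, layer_rdms: list[RDM]):
        if not layer_rdms:
            raise ValueError("need at least one layer RDM")
        n = layer_rdms[0].n
        if any(r.n != n for r in layer_rdms):
            raise ValueError("layer RDMs must share n_stimuli")
        for r in layer_rdms:
            if r.is_degenerate:
                raise DegenerateRDMError(f"layer RDM {r.source!r} is constant")
        self.n = n
        self.rdms = list(layer_rdms)
        self.iu = np.triu_indices(n, k=1)
        self.m = len(self.iu[0])
        self.z = np.stack([_rank_standardise(r.upper()) for r in layer_rdms])
        # pair -> upper-triangle position lookup (symmetric)
        M = np.zeros((n, n), dtype=np.int64)
        M[self.iu] = np.arange(self.m)
        self.pair_index = M + M.T

    @classmethod
    def from_layers(cls, layers: LayerActivationSet) -> "_LayerRDMBank":
        rdms = [compute_layer_rdm(a, source=nm)
                for a, nm in zip(layers.activations, layers.layer_names)]
        return cls(rdms)


def _as_bank(layer_rdms) -> _LayerRDMBank:
    if isinstance(layer_rdms, _LayerRDMBank):
        return layer_rdms
    if isinstance(layer_rdms, LayerActivationSet):
        return _LayerRDMBank.from_layers(layer_rdms)
    return _LayerRDMBank(list(layer_rdms))


def permutation_layer_test(
    responses: np.ndarray,
    layer_rdms,
    n_perm: int = 10_000,
    alpha: float = 0.001,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed rho per layer with a shared-permutation empirical null.

    The response vector is reshuffled ``n_perm`` times; each reshuffle
    rebuilds the probe RDM and recomputes Spearman against every layer RDM
    (the same permutation set is shared across layers). One-sided empirical
    p = (1 + #{null >= observed}) / (1 + n_perm); a layer is flagged iff
    p < alpha (which implies positive rho under the one-sided null).

    Returns (rho, p, flags), each of length n_layers. A degenerate
    (constant) response vector yields rho = NaN, p = 1, no flags.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    bank = _as_bank(layer_rdms)
    r = np.asarray(responses, dtype=float).ravel()
    if r.size != bank.n:
        raise ValueError("responses length must match layer RDM size")
    L = bank.z.shape[0]
    if np.ptp(r) == 0:
        return (np.full(L, np.nan), np.ones(L), np.zeros(L, dtype=bool))

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = np.abs(r[:, None] - r[None, :])[bank.iu]
    zp = _rank_standardise(d)
    rho = bank.z @ zp / bank.m

    exceed = np.zeros(L, dtype=np.int64)
    block = max(1, _PERM_BLOCK_ELEMS // bank.m)
    done = 0
    while done < n_perm:
        nb = min(block, n_perm - done)
        perms = np.empty((nb, bank.n), dtype=np.int64)
        for i in range(nb):
            perms[i] = rng.permutation(bank.n)
        a = perms[:, bank.iu[0]]
        b = perms[:, bank.iu[1]]
        idx = bank.pair_index[a, b]
        null = (zp[idx] @ bank.z.T) / bank.m  # nb x L
        exceed += (null >= rho[None, :] - 1e-15).sum(axis=0)
        done += nb
    p = (1 + exceed) / (1 + n_perm)
    flags = (p < alpha) & (rho > 0)
    return rho, p, flags


def map_probes(
    responses: ResponseMatrix,
    layer_rdms,
    areas: ProbePlan | dict | pd.Series,
    n_perm: int = 10_000,
    alpha: float = 0.001,
    seed: int | None = None,
    layer_names=None,
    area_order=None,
) -> ProbeMapping:
    """Run the permutation layer test for every (screened) probe.

    ``areas`` supplies each probe's area label (a ProbePlan or a
    probe_id -> area mapping). Each probe gets an independent child seed
    derived from the master ``seed``. Probes with constant responses are
    recorded as degenerate and carry no significant layers. Stimuli masked
    as NaN for a probe are excluded from that probe's RDM and null.
    """
    if isinstance(areas, ProbePlan):
        if area_order is None:
            area_order = list(areas.area_order)
        areas = dict(zip(areas.table["probe_id"], areas.table["area"]))
    elif isinstance(areas, pd.Series):
        areas = areas.to_dict()
    bank = _as_bank(layer_rdms)
    L = bank.z.shape[0]
    if layer_names is None:
        layer_names = [f"layer{l}" for l in range(L)]
    if area_order is None:
        area_order = list(VISUAL_AREA_ORDER)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(max(responses.n_probes, 1))
    rows = []
    degenerate = []
    for i, pid in enumerate(responses.probe_ids):
        r = responses.values[i]
        rng = np.random.default_rng(children[i])
        valid = np.isfinite(r)
        if valid.sum() < 4 or np.ptp(r[valid]) == 0:
            degenerate.append(pid)
            rho = np.full(L, np.nan)
            p = np.ones(L)
            flags = np.zeros(L, dtype=bool)
        elif valid.all():
            rho, p, flags = permutation_layer_test(r, bank, n_perm, alpha, rng)
        else:
            sub = _subset_bank(bank, np.where(valid)[0])
            rho, p, flags = permutation_layer_test(r[valid], sub, n_perm, alpha, rng)
        for l in range(L):
            rows.append(
                {
                    "probe_id": pid,
                    "area": areas.get(pid, "unknown"),
                    "layer": l,
                    "rho": rho[l],
                    "p": p[l],
                    "significant": bool(flags[l]),
                }
            )
    table = pd.DataFrame(
        rows, columns=["probe_id", "area", "layer", "rho", "p", "significant"]
    )
    return ProbeMapping(
        table=table,
        layer_names=list(layer_names),
        area_order=list(area_order),
        n_perm=n_perm,
        alpha=alpha,
        seed=seed,
        degenerate_probes=degenerate,
    )


def _subset_bank(bank: _LayerRDMBank, keep: np.ndarray) -> _LayerRDMBank:
    """Restrict a layer RDM bank to a subset of stimuli (artifact masking)."""
    sub = [
        RDM(matrix=r.matrix[np.ix_(keep, keep)], metric=r.metric, source=r.source)
        for r in bank.rdms
    ]
    return _LayerRDMBank(sub)


def aggregate_area_layer(
    mapping: ProbeMapping, normalization: str = "significant"
) -> MappingMatrix:
    """Aggregate significant probe-layer correlations into an area x layer grid.

    cell(a, l) = sum of significant rho of area-a probes at layer l, divided
    by the number of area-a probes significant for at least one layer
    (``normalization="significant"``) or by the number of mapped (responsive)
    area-a probes (``normalization="responsive"``). A probe significant at
    several layers contributes to each of those cells but counts once in the
    denominator.
    """
    if len(mapping.table) == 0:
        raise ValueError("empty mapping")
    if normalization not in ("significant", "responsive"):
        raise ValueError("normalization must be 'significant' or 'responsive'")
    areas = list(mapping.area_order)
    L = len(mapping.layer_names)
    t = mapping.table
    extra = [a for a in t["area"].unique() if a not in areas]
    areas = areas + sorted(extra)

    sig = t[t["significant"]]
    sums = np.zeros((len(areas), L))
    counts = np.zeros((len(areas), L), dtype=int)
    for (a, l), grp in sig.groupby(["area", "layer"]):
        ai = areas.index(a)
        sums[ai, int(l)] = grp["rho"].sum()
        counts[ai, int(l)] = len(grp)

    total = t.groupby("area")["probe_id"].nunique()
    sig_probes = sig.groupby("area")["probe_id"].nunique()
    probes_total = pd.Series([int(total.get(a, 0)) for a in areas], index=areas)
    probes_sig = pd.Series([int(sig_probes.get(a, 0)) for a in areas], index=areas)

    denom = probes_sig if normalization == "significant" else probes_total
    scores = np.zeros_like(sums)
    for ai in range(len(areas)):
        if denom.iloc[ai] > 0:
            scores[ai] = sums[ai] / denom.iloc[ai]
    cols = list(range(L))
    return MappingMatrix(
        scores=pd.DataFrame(scores, index=areas, columns=cols),
        sig_counts=pd.DataFrame(counts, index=areas, columns=cols),
        probes_significant=probes_sig,
        probes_total=probes_total,
        normalization=normalization,
    )
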