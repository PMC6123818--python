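"""Layer-side representational geometry.

Layer RDMs (pairwise Euclidean distances between stimulus activation
vectors), the untrained random-weight control network, and the inter-layer
RDM similarity analysis that exposes the two-block (convolutional vs fully
connected) structure of a trained hierarchy.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from .types import LayerActivationSet, RDM

__all__ = [
    "compute_layer_rdm",
    "random_network_activations",
    "layer_rdm_similarity",
]


def compute_layer_rdm(activations: np.ndarray, source: str = "") -> RDM:
    """Pairwise Euclidean distances between stimulus activation vectors."""
    a = np.asarray(activations, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2:
        raise ValueError("need a stimulus x feature matrix with >= 2 stimuli")
    if not np.isfinite(a).all():
        raise ValueError("activations must be finite")
    return RDM(matrix=squareform(pdist(a, metric="euclidean")),
               metric="euclidean", source=source)


def random_network_activations(
    stimulus_features: np.ndarray,
    layer_dims: list[int],
    seed: int | None = None,
    weight_sd: float = 0.01,
) -> LayerActivationSet:
    """Untrained control hierarchy: random linear maps with rectification.

    Layer 0 is the input feature matrix itself; each subsequent layer is
    relu(X @ W) with weights drawn i.i.d. Normal(0, weight_sd^2). An
    untrained stack provides the hierarchy-without-learned-features control
    against which trained-hierarchy alignment is contrasted.
    """
    X = np.asarray(stimulus_features, dtype=float)
    if X.ndim != 2:
        raise ValueError("stimulus_features must be stimulus x feature")
    if not layer_dims:
        raise ValueError("layer_dims must be non-empty")
    if any(d < 1 for d in layer_dims):
        raise ValueError("zero-dimensional layer")
    rng = np.random.default_rng(seed)
    acts = [X]
    names = ["input"]
    for k, d in enumerate(layer_dims, start=1):
        W = rng.normal(0.0, weight_sd, size=(acts[-1].shape[1], d))
        acts.append(np.maximum(acts[-1] @ W, 0.0))
        names.append(f"random{k}")
    return LayerActivationSet(layer_names=names, activations=acts)


def layer_rdm_similarity(layers: LayerActivationSet) -> np.ndarray:
    """L x L Spearman correlations between layer RDM upper triangles.

    Diagonal is 1; entries involving a degenerate (constant) RDM are NaN.
    """
    if layers.n_layers < 2:
        raise ValueError("need at least 2 layers")
    rdms = [compute_layer_rdm(a, source=n)
            for a, n in zip(layers.activations, layers.layer_names)]
    uppers = [r.upper() for r in rdms]
    degen = [r.is_degenerate for r in rdms]
    L = layers.n_layers
    out = np.eye(L)
    for i in range(L):
        for j in range(i + 1, L):
            if degen[i] or degen[j]:
                out[i, j] = out[j, i] = np.nan
            else:
                out[i, j] = out[j, i] = spearmanr(uppers[i], uppers[j]).statistic
        if degen[i]:
            out[i, i] = np.nan
    return out
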