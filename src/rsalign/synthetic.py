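"""Synthetic data with planted, parameterised structure.

Every downstream stage of the pipeline can be verified against a known
ground truth: a layer hierarchy with a latent factor chain (adjacent layers
represent similar stimulus geometry, with an optional block break emulating
the convolutional / fully-connected split), a probe plan assigning probes to
areas and target layers, scalar responses obtained by projecting layer
activations onto random directions, and raw epoched time series carrying the
planted band-power modulation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import (
    BandSpec,
    EpochSet,
    LayerActivationSet,
    ProbePlan,
    ResponseMatrix,
    SyntheticTruth,
    VISUAL_AREA_ORDER,
)

__all__ = [
    "make_layer_hierarchy",
    "make_probe_plan",
    "simulate_band_responses",
    "simulate_null_responses",
    "simulate_lfp_epochs",
]


def make_layer_hierarchy(
    n_stimuli: int = 250,
    n_layers: int = 9,
    dims: list[int] | None = None,
    chain_strength: float = 0.9,
    block_break_after: int | None = 5,
    n_latent: int = 32,
    noise_scale: float = 1.0,
    spectrum_decay: float = 1.0,
    seed: int | None = None,
    layer_names: list[str] | None = None,
) -> LayerActivationSet:
    """Generate an ordered layer hierarchy with chained representational geometry.

    Latent stimulus factors follow an AR(1)-style chain over layers,
    F_l = c * F_{l-1} + sqrt(1 - c^2) * eps, so adjacent layers share most of
    their representational geometry while distant layers drift apart. The
    chain is re-initialised after ``block_break_after``, producing two blocks
    of mutually similar layers (the convolutional-like block 0..break and the
    fully-connected-like block break+1..L-1). Each layer embeds its latent
    factors into its own feature space and adds idiosyncratic noise.

    Parameters
    ----------
    n_stimuli : number of stimuli (rows of every activation matrix).
    n_layers : number of layers, index 0 = input/pixel space.
    dims : per-layer feature counts; defaults to a decreasing profile.
    chain_strength : c in [0, 1]; 1 makes all layers share one geometry.
    block_break_after : last layer index of the first block, or None for a
        single unbroken chain.
    n_latent : dimensionality of the latent factor space.
    noise_scale : standard deviation of per-layer idiosyncratic noise
        relative to unit-variance latent factors.
    spectrum_decay : power-law exponent of the latent variance spectrum
        (component k has variance k**-decay). Real network-layer
        representations are strongly anisotropic; a decaying spectrum makes
        one-dimensional readouts (scalar probes) informative about the
        layer's geometry, which an isotropic space would not be.
    """
    if n_stimuli < 4:
        raise ValueError("need at least 4 stimuli")
    if not 0 <= chain_strength <= 1:
        raise ValueError("chain_strength must lie in [0, 1]")
    if dims is None:
        # decreasing feature counts, all >= n_latent so the latent geometry
        # embeds isometrically into every layer
        dims = [int(d) for d in np.linspace(4 * n_latent, n_latent, n_layers)]
    if len(dims) != n_layers:
        raise ValueError("dims must have one entry per layer")
    if any(d < 2 for d in dims):
        raise ValueError("all layer dims must be >= 2")
    if block_break_after is not None and not (0 <= block_break_after < n_layers):
        raise ValueError("block_break_after out of range")
    if layer_names is None:
        layer_names = [f"layer{l}" for l in range(n_layers)]
        layer_names[0] = "pixels"
    if len(layer_names) != n_layers:
        raise ValueError("layer_names length mismatch")

    rng = np.random.default_rng(seed)
    c = chain_strength
    scale = np.arange(1, n_latent + 1) ** (-spectrum_decay / 2.0)
    acts = []
    latent = rng.standard_normal((n_stimuli, n_latent))
    for l in range(n_layers):
        if block_break_after is not None and l == block_break_after + 1:
            latent = rng.standard_normal((n_stimuli, n_latent))
        elif l > 0:
            eps = rng.standard_normal((n_stimuli, n_latent))
            latent = c * latent + np.sqrt(1 - c**2) * eps
        # Idiosyncratic noise is added in the latent space (a low-rank
        # perturbation of the geometry) and then embedded together with the
        # shared factors: high-dimensional white feature noise would
        # concentrate and leave distance ranks essentially unchanged,
        # producing no layer distinctness.
        private = noise_scale * rng.standard_normal((n_stimuli, n_latent))
        if dims[l] >= n_latent:
            # isometric embedding: latent distances are preserved exactly
            q, _ = np.linalg.qr(rng.standard_normal((dims[l], n_latent)))
            embed = q.T
        else:
            embed = rng.standard_normal((n_latent, dims[l])) / np.sqrt(n_latent)
        acts.append(((latent + private) * scale) @ embed)
    return LayerActivationSet(layer_names=list(layer_names), activations=acts)


def make_probe_plan(
    area_layer_map: dict[str, int],
    probes_per_area: int = 10,
    snr: float = 10.0,
    distractor_areas: list[str] | None = None,
    contacts_per_shaft: int = 5,
    area_order: list[str] | None = None,
    seed: int | None = None,
) -> tuple[ProbePlan, SyntheticTruth]:
    """Lay out probes over areas with planted target layers.

    Probes are assigned round-robin to shafts of ``contacts_per_shaft``
    contacts (contact 1 = deepest). Areas in ``area_layer_map`` get probes
    targeting the mapped layer; ``distractor_areas`` get probes with no
    target (pure noise downstream).
    """
    if area_order is None:
        area_order = list(VISUAL_AREA_ORDER)
    distractor_areas = list(distractor_areas or [])
    for a in distractor_areas:
        if a not in area_order:
            area_order = area_order + [a]
    unknown = set(area_layer_map) - set(area_order)
    if unknown:
        raise ValueError(f"areas not in declared hierarchy: {sorted(unknown)}")
    if probes_per_area == 0:
        warnings.warn("probes_per_area is 0: returning an empty plan")

    rows = []
    shaft_counter = 0
    probe_targets: dict[str, int | None] = {}
    for area in list(area_layer_map) + distractor_areas:
        target = area_layer_map.get(area)
        for k in range(probes_per_area):
            if k % contacts_per_shaft == 0:
                shaft_counter += 1
                shaft_id = f"shaft{shaft_counter}"
            probe_id = f"a{area}_p{k}"
            rows.append(
                {
                    "probe_id": probe_id,
                    "shaft_id": shaft_id,
                    "contact_index": k % contacts_per_shaft + 1,
                    "area": area,
                    "target_layer": np.nan if target is None else target,
                    "snr": snr,
                }
            )
            probe_targets[probe_id] = target
    table = pd.DataFrame(
        rows,
        columns=["probe_id", "shaft_id", "contact_index", "area", "target_layer", "snr"],
    )
    plan = ProbePlan(table=table, area_order=area_order)
    truth = SyntheticTruth(
        area_layer_map=dict(area_layer_map),
        probe_targets=probe_targets,
        seed=-1 if seed is None else int(seed),
        params={
            "probes_per_area": probes_per_area,
            "snr": snr,
            "distractor_areas": distractor_areas,
            "contacts_per_shaft": contacts_per_shaft,
            "area_order": area_order,
        },
    )
    return plan, truth


def simulate_band_responses(
    layers: LayerActivationSet,
    plan: ProbePlan,
    seed: int | None = None,
    max_attempts: int = 10,
) -> ResponseMatrix:
    """Plant scalar per-stimulus responses by projecting layer activations.

    A probe targeting layer ``l`` responds with r = X_l u / ||X_l u|| plus
    Gaussian noise whose variance is var(signal) / snr, where u is a seeded
    random unit direction in layer-l feature space. Probes without a target
    produce pure noise. The resulting probe RDM (|r_i - r_j|) inherits the
    geometry of layer l, which the mapping stage should recover.
    """
    rng = np.random.default_rng(seed)
    n_stim = layers.n_stimuli
    values = np.empty((plan.n_probes, n_stim))
    for i, row in plan.table.iterrows():
        target = row["target_layer"]
        if np.isnan(target):
            values[i] = rng.standard_normal(n_stim)
            continue
        l = int(target)
        if l >= layers.n_layers:
            raise ValueError(f"target layer {l} out of range")
        X = layers.activations[l]
        signal = None
        for _ in range(max_attempts):
            u = rng.standard_normal(X.shape[1])
            u /= np.linalg.norm(u)
            proj = X @ u
            norm = np.linalg.norm(proj)
            if norm > 1e-12 and np.ptp(proj) > 1e-12:
                signal = proj / norm
                break
        if signal is None:
            raise RuntimeError(
                f"degenerate activations: zero-variance projection for probe "
                f"{row['probe_id']} after {max_attempts} attempts"
            )
        snr = row["snr"]
        if np.isinf(snr):
            noise = 0.0
        elif snr == 0:
            signal = np.zeros(n_stim)
            noise = rng.standard_normal(n_stim) / np.sqrt(n_stim)
        else:
            sigma = np.std(signal) / np.sqrt(snr)
            noise = rng.normal(0, sigma, n_stim)
        values[i] = signal + noise
    if not np.isfinite(values).all():
        raise RuntimeError("non-finite synthetic responses")
    return ResponseMatrix(
        values=values,
        probe_ids=plan.probe_ids,
        stimulus_ids=[f"stim{i}" for i in range(n_stim)],
    )


def simulate_null_responses(
    n_probes: int, n_stimuli: int, seed: int | None = None
) -> ResponseMatrix:
    """I.i.d. Gaussian responses with no stimulus structure (type-I calibration)."""
    if n_stimuli < 4:
        raise ValueError("need at least 4 stimuli")
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_probes, n_stimuli))
    return ResponseMatrix(values=values)


def responses_to_power_ratios(
    responses: ResponseMatrix, ratio_span: float = 3.0, ratio_floor: float = 1.0
) -> ResponseMatrix:
    """Map arbitrary scalar responses to positive post/baseline power ratios.

    Applies a per-probe positive affine transform onto
    [ratio_floor, ratio_floor + ratio_span]. Absolute-difference RDMs are
    invariant (up to positive scale) under this transform, so planted rank
    structure is preserved while the values become valid power ratios for
    epoch synthesis.
    """
    v = responses.values.copy()
    for i in range(v.shape[0]):
        lo, hi = np.nanmin(v[i]), np.nanmax(v[i])
        span = hi - lo
        if span <= 0:
            v[i] = ratio_floor
        else:
            v[i] = ratio_floor + ratio_span * (v[i] - lo) / span
    return ResponseMatrix(
        values=v,
        probe_ids=responses.probe_ids,
        stimulus_ids=responses.stimulus_ids,
        roi=responses.roi,
    )


def simulate_lfp_epochs(
    plan: ProbePlan,
    responses: ResponseMatrix,
    carrier_band: BandSpec,
    fs: float = 1024.0,
    epoch: tuple[float, float] = (-500.0, 1000.0),
    burst: tuple[float, float] = (0.0, 500.0),
    carrier_amp: float = 1.0,
    noise_amp: float = 0.05,
    ramp_ms: float = 20.0,
    artifact_rate: float = 0.0,
    artifact_sigma: float = 15.0,
    seed: int | None = None,
) -> EpochSet:
    """Synthesise raw epochs whose band-power ratio equals the planted response.

    Each epoch carries a carrier oscillation at the band's geometric-mean
    frequency with unit baseline amplitude, scaled to sqrt(response) inside
    the post-stimulus burst window (power scales with amplitude squared, so
    the post/baseline band-power ratio equals the response). Broadband
    1/f-shaped background noise is added at low amplitude, and optional spike
    artifacts exceeding ``artifact_sigma`` standard deviations are injected
    for testing the rejection stage.

    ``responses`` must hold strictly positive power ratios (see
    :func:`responses_to_power_ratios`).
    """
    if carrier_band.f_hi >= fs / 2:
        raise ValueError("carrier band above Nyquist")
    if fs < 4 * carrier_band.f_hi:
        raise ValueError("fs must be at least 4x the band's upper edge")
    if responses.n_probes != plan.n_probes:
        raise ValueError("responses rows must match the probe plan")
    if (responses.values <= 0).any() or not np.isfinite(responses.values).all():
        raise ValueError("responses must be strictly positive power ratios")

    rng = np.random.default_rng(seed)
    t_start, t_end = epoch
    n_times = int(round((t_end - t_start) * fs / 1000.0))
    times = t_start + np.arange(n_times) * 1000.0 / fs
    f_c = carrier_band.f_center

    # smooth amplitude envelope template: 1 outside the burst, g inside
    def envelope(gain: float) -> np.ndarray:
        env = np.ones(n_times)
        rise = (times >= burst[0]) & (times < burst[0] + ramp_ms)
        inside = (times >= burst[0] + ramp_ms) & (times <= burst[1] - ramp_ms)
        fall = (times > burst[1] - ramp_ms) & (times <= burst[1])
        frac_r = (times[rise] - burst[0]) / ramp_ms
        frac_f = (burst[1] - times[fall]) / ramp_ms
        env[rise] = 1 + (gain - 1) * 0.5 * (1 - np.cos(np.pi * frac_r))
        env[fall] = 1 + (gain - 1) * 0.5 * (1 - np.cos(np.pi * frac_f))
        env[inside] = gain
        return env

    n_probes, n_stimuli = responses.values.shape
    data = np.empty((n_probes, n_stimuli, n_times))
    t_sec = times / 1000.0
    for i in range(n_probes):
        for j in range(n_stimuli):
            phase = rng.uniform(0, 2 * np.pi)
            gain = np.sqrt(responses.values[i, j])
            carrier = carrier_amp * envelope(gain) * np.cos(2 * np.pi * f_c * t_sec + phase)
            data[i, j] = carrier + noise_amp * _pink_noise(n_times, rng)

    if artifact_rate > 0:
        probe_sd = data.std(axis=(1, 2))
        for i in range(n_probes):
            hit = rng.random(n_stimuli) < artifact_rate
            for j in np.where(hit)[0]:
                k = rng.integers(0, n_times)
                data[i, j, k] += 2 * artifact_sigma * probe_sd[i]

    return EpochSet(
        data=data,
        fs=fs,
        t_start=t_start,
        probe_ids=list(responses.probe_ids),
        stimulus_ids=list(responses.stimulus_ids),
    )


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with approximately 1/f amplitude spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x
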