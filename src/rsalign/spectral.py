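"""From raw epochs to scalar baseline-normalised band-power responses.

Pipeline order is fixed by contract: linear detrend + artifact rejection,
bipolar re-referencing along each shaft, Morlet time-frequency decomposition,
band-power averaging with baseline-ratio normalisation, and a
Wilcoxon/Benjamini-Hochberg responsiveness screen that keeps only probes
whose post-stimulus band power exceeds baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import BandSpec, EpochSet, ProbePlan, ResponseMatrix, ROISpec

__all__ = [
    "reject_artifacts",
    "bipolar_rereference",
    "morlet_tfr",
    "band_power",
    "band_power_from_epochs",
    "screen_responsive",
    "TFRResult",
]


def reject_artifacts(epochs: EpochSet, sigma_mult: float = 10.0) -> EpochSet:
    """Detrend each epoch and mask epochs containing extreme samples.

    Per probe, sigma is the standard deviation over all samples of all that
    probe's (detrended, currently valid) epochs. Any epoch containing a
    sample with absolute value >= sigma_mult * sigma is masked. The sigma is
    per probe, so rescaling one probe never affects another's rejections.
    """
    if epochs.data.size == 0:
        raise ValueError("empty epoch set")
    detr = sps.detrend(epochs.data, axis=-1, type="linear")
    mask = epochs.valid_mask.copy()
    for i in range(epochs.n_probes):
        valid = mask[i]
        if not valid.any():
            continue
        sigma = detr[i, valid].std()
        if sigma == 0:
            continue
        peak = np.abs(detr[i]).max(axis=-1)
        mask[i] &= peak < sigma_mult * sigma
    dead = ~mask.any(axis=1)
    if dead.any():
        names = [epochs.probe_ids[i] for i in np.where(dead)[0]]
        warnings.warn(f"probes with all epochs rejected: {names}")
    return EpochSet(
        data=detr,
        fs=epochs.fs,
        t_start=epochs.t_start,
        probe_ids=list(epochs.probe_ids),
        stimulus_ids=list(epochs.stimulus_ids),
        valid_mask=mask,
    )


def bipolar_rereference(
    epochs: EpochSet, plan: ProbePlan
) -> tuple[EpochSet, ProbePlan]:
    """Re-reference each contact against its inward (deeper) neighbour.

    On every shaft, ordered by contact_index with 1 the deepest, the output
    channel for contact k (k >= 2) is signal_k - signal_{k-1}; the deepest
    contact yields no output channel. Shafts with a single contact produce no
    channels (warned). Returns the re-referenced epochs and the matching
    reduced probe plan.
    """
    id_to_idx = {pid: i for i, pid in enumerate(epochs.probe_ids)}
    out_rows, out_data, out_mask = [], [], []
    for shaft, grp in plan.table.groupby("shaft_id", sort=False):
        grp = grp.sort_values("contact_index")
        if len(grp) < 2:
            warnings.warn(f"shaft {shaft} has a single contact: no bipolar channel")
            continue
        idx = [id_to_idx[p] for p in grp["probe_id"]]
        for k in range(1, len(grp)):
            cur, ref = idx[k], idx[k - 1]
            out_data.append(epochs.data[cur] - epochs.data[ref])
            out_mask.append(epochs.valid_mask[cur] & epochs.valid_mask[ref])
            row = grp.iloc[k].copy()
            out_rows.append(row)
    if not out_rows:
        raise ValueError("no bipolar channels could be formed")
    table = pd.DataFrame(out_rows).reset_index(drop=True)
    new_plan = ProbePlan(table=table, area_order=plan.area_order)
    new_epochs = EpochSet(
        data=np.stack(out_data),
        fs=epochs.fs,
        t_start=epochs.t_start,
        probe_ids=list(table["probe_id"]),
        stimulus_ids=list(epochs.stimulus_ids),
        valid_mask=np.stack(out_mask),
    )
    return new_epochs, new_plan


def _morlet_kernel(f0: float, cycles: float, fs: float) -> np.ndarray:
    """Complex Morlet wavelet, Gaussian sd sigma_t = cycles / (2 pi f0).

    Support truncated at +/- 5 sigma_t; unit L2 norm so that power is
    comparable across frequencies (ratio normalisation removes the scale
    anyway).
    """
    sigma_t = cycles / (2 * np.pi * f0)
    half = int(np.ceil(5 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(2j * np.pi * f0 * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    return w / np.linalg.norm(w)


@dataclass
class TFRResult:
    """Time-frequency power with per-frequency edge-reliability flags."""

    power: np.ndarray  # probe x stimulus x freq x time
    freqs: np.ndarray
    times: np.ndarray  # ms
    reliable: np.ndarray  # freq x time bool, False within 2 sigma_t of edges
    valid_mask: np.ndarray  # probe x stimulus
    probe_ids: list | None = None
    stimulus_ids: list | None = None


def morlet_tfr(
    epochs: EpochSet, freqs: np.ndarray, cycles: float | np.ndarray
) -> TFRResult:
    """Morlet time-frequency decomposition: P(t, f0) = |w(t, f0) * s(t)|^2.

    ``cycles`` is the f0/sigma_f ratio, scalar or per frequency. Convolution
    is same-length; samples within 2 sigma_t of either epoch edge are flagged
    unreliable in ``reliable``.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    cyc = np.broadcast_to(np.asarray(cycles, dtype=float), freqs.shape)
    if freqs.max() >= epochs.fs / 2:
        raise ValueError("frequency at or above Nyquist")
    n_t = epochs.n_times
    times = epochs.times
    power = np.empty((epochs.n_probes, epochs.n_stimuli, len(freqs), n_t))
    reliable = np.ones((len(freqs), n_t), dtype=bool)
    flat = epochs.data.reshape(-1, n_t)
    for k, (f0, c) in enumerate(zip(freqs, cyc)):
        w = _morlet_kernel(f0, c, epochs.fs)
        conv = sps.fftconvolve(flat, w[np.newaxis, :], mode="same", axes=-1)
        power[:, :, k, :] = (np.abs(conv) ** 2).reshape(
            epochs.n_probes, epochs.n_stimuli, n_t
        )
        sigma_t_ms = 1000.0 * c / (2 * np.pi * f0)
        reliable[k] = (times >= times[0] + 2 * sigma_t_ms) & (
            times <= times[-1] - 2 * sigma_t_ms
        )
    return TFRResult(
        power=power,
        freqs=freqs,
        times=times,
        reliable=reliable,
        valid_mask=epochs.valid_mask.copy(),
        probe_ids=list(epochs.probe_ids),
        stimulus_ids=list(epochs.stimulus_ids),
    )


def band_power(
    tfr: TFRResult, roi: ROISpec
) -> tuple[np.ndarray, np.ndarray, ResponseMatrix]:
    """Average band power in the ROI window and baseline; ratio-normalise.

    Returns (post, base, response) where post and base are probe x stimulus
    mean powers over the band's frequencies within the respective windows and
    response = post / base. Masked epochs yield NaN responses.
    """
    band = roi.band
    fsel = (tfr.freqs >= band.f_lo) & (tfr.freqs <= band.f_hi)
    if not fsel.any():
        raise ValueError(f"no frequencies within band {band.name}")
    post_t = (tfr.times >= roi.window[0]) & (tfr.times <= roi.window[1])
    base_t = (tfr.times >= roi.baseline[0]) & (tfr.times <= roi.baseline[1])
    if not post_t.any() or not base_t.any():
        raise ValueError("ROI window or baseline outside the epoch")
    if not tfr.reliable[np.ix_(fsel, post_t)].all():
        warnings.warn("ROI window overlaps edge-unreliable samples")
    post = tfr.power[:, :, fsel][:, :, :, post_t].mean(axis=(2, 3))
    base = tfr.power[:, :, fsel][:, :, :, base_t].mean(axis=(2, 3))
    if (base[tfr.valid_mask] <= 0).any():
        raise ValueError("zero baseline power: cannot normalise")
    resp = np.where(tfr.valid_mask, post / base, np.nan)
    return post, base, ResponseMatrix(
        values=resp, probe_ids=tfr.probe_ids, stimulus_ids=tfr.stimulus_ids, roi=roi
    )


def band_power_from_epochs(
    epochs: EpochSet,
    band: BandSpec,
    windows: list[tuple[float, float]],
    baseline: tuple[float, float] = (-500.0, -100.0),
    grid_step: float = 1.0,
) -> dict[tuple[float, float], tuple[np.ndarray, np.ndarray, ResponseMatrix]]:
    """Memory-bounded band power: stream over the band's frequency grid.

    Computes the same quantities as :func:`morlet_tfr` followed by
    :func:`band_power` for several windows at once, but holds only one
    frequency's power in memory at a time. Returns a dict mapping each
    window to its (post, base, response) triple.
    """
    freqs = band.freqs(grid_step)
    if freqs.max() >= epochs.fs / 2:
        raise ValueError("band above Nyquist")
    times = epochs.times
    base_t = (times >= baseline[0]) & (times <= baseline[1])
    post_ts = {w: (times >= w[0]) & (times <= w[1]) for w in windows}
    for w, sel in post_ts.items():
        if not sel.any():
            raise ValueError(f"window {w} outside the epoch")
    if not base_t.any():
        raise ValueError("baseline outside the epoch")
    n_p, n_s, n_t = epochs.data.shape
    flat = epochs.data.reshape(-1, n_t)
    post_acc = {w: np.zeros((n_p, n_s)) for w in windows}
    base_acc = np.zeros((n_p, n_s))
    for f0 in freqs:
        w_kernel = _morlet_kernel(f0, band.cycles, epochs.fs)
        conv = sps.fftconvolve(flat, w_kernel[np.newaxis, :], mode="same", axes=-1)
        p = (np.abs(conv) ** 2).reshape(n_p, n_s, n_t)
        base_acc += p[:, :, base_t].mean(axis=2)
        for w in windows:
            post_acc[w] += p[:, :, post_ts[w]].mean(axis=2)
    base = base_acc / len(freqs)
    if (base[epochs.valid_mask] <= 0).any():
        raise ValueError("zero baseline power: cannot normalise")
    out = {}
    for w in windows:
        post = post_acc[w] / len(freqs)
        resp = np.where(epochs.valid_mask, post / base, np.nan)
        roi = ROISpec(band=band, window=w, baseline=baseline)
        out[w] = (
            post,
            base,
            ResponseMatrix(
                values=resp,
                probe_ids=list(epochs.probe_ids),
                stimulus_ids=list(epochs.stimulus_ids),
                roi=roi,
            ),
        )
    return out


def screen_responsive(
    post: np.ndarray,
    base: np.ndarray,
    fdr_q: float = 0.05,
    valid_mask: np.ndarray | None = None,
    probe_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Keep probes whose post-stimulus band power exceeds baseline.

    Per probe, a two-sided Wilcoxon signed-rank test pairs the per-stimulus
    (post, base) values; p-values are Benjamini-Hochberg corrected across
    probes, and a probe is kept iff the corrected p is below ``fdr_q`` AND
    the median post-minus-base difference is positive (negative responders
    are deliberately dropped).

    Returns a report with columns probe_id, p_raw, p_fdr, median_diff, kept.
    """
    post = np.asarray(post, dtype=float)
    base = np.asarray(base, dtype=float)
    n_probes, n_stim = post.shape
    if valid_mask is None:
        valid_mask = np.ones_like(post, dtype=bool)
    if probe_ids is None:
        probe_ids = [f"probe{i}" for i in range(n_probes)]
    p_raw = np.full(n_probes, np.nan)
    med = np.full(n_probes, np.nan)
    for i in range(n_probes):
        sel = valid_mask[i]
        d = post[i, sel] - base[i, sel]
        if sel.sum() < 8:
            continue
        med[i] = np.median(d)
        if np.all(d == 0):
            continue  # signed-rank undefined
        p_raw[i] = stats.wilcoxon(d, alternative="two-sided").pvalue
    p_fdr = np.full(n_probes, np.nan)
    kept = np.zeros(n_probes, dtype=bool)
    ok = np.isfinite(p_raw)
    if ok.any():
        rej, p_adj, _, _ = multipletests(p_raw[ok], alpha=fdr_q, method="fdr_bh")
        p_fdr[ok] = p_adj
        kept[ok] = rej & (med[ok] > 0)
    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "p_raw": p_raw,
            "p_fdr": p_fdr,
            "median_diff": med,
            "kept": kept,
        }
    )
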