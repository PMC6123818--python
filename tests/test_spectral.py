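"""Spectral stage: artifact rejection, re-referencing, Morlet power, screening."""

import numpy as np
import pandas as pd
import pytest

import rsalign as ra
from rsalign.spectral import _morlet_kernel


def _white_epochs(n_probes=3, n_stimuli=20, fs=256.0, seed=0):
    rng = np.random.default_rng(seed)
    n_t = int(1.5 * fs)
    return ra.EpochSet(data=rng.standard_normal((n_probes, n_stimuli, n_t)), fs=fs)


class TestRejectArtifacts:
    def test_spiked_epoch_masked(self):
        ep = _white_epochs(seed=1)
        ep.data[1, 4, 100] = 15 * ep.data[1].std()
        out = ra.reject_artifacts(ep)
        assert not out.valid_mask[1, 4]
        assert out.valid_mask.sum() == out.valid_mask.size - 1

    def test_white_noise_rarely_rejected(self):
        out = ra.reject_artifacts(_white_epochs(n_stimuli=50, seed=2))
        # P(|N(0,1)| >= 10) is ~1.5e-23 per sample; no epoch should trip it
        assert out.valid_mask.all()

    def test_sigma_is_per_probe(self):
        ep = _white_epochs(seed=3)
        ep2 = ra.EpochSet(data=ep.data.copy(), fs=ep.fs)
        ep2.data[0] *= 100.0
        m1 = ra.reject_artifacts(ep).valid_mask
        m2 = ra.reject_artifacts(ep2).valid_mask
        np.testing.assert_array_equal(m1[1:], m2[1:])

    def test_detrend_removes_linear_ramp(self):
        ep = _white_epochs(seed=4)
        ramp = np.linspace(0, 50, ep.n_times)
        ep.data += ramp
        out = ra.reject_artifacts(ep)
        assert abs(out.data.mean()) < 0.1
        assert out.valid_mask.all()


class TestBipolarRereference:
    def _plan(self, contacts, n_shafts=1):
        rows = []
        for s in range(n_shafts):
            for c in range(contacts):
                rows.append({"probe_id": f"s{s}c{c+1}", "shaft_id": f"s{s}",
                             "contact_index": c + 1, "area": "17",
                             "target_layer": np.nan, "snr": 1.0})
        return ra.ProbePlan(table=pd.DataFrame(rows))

    def test_five_contacts_give_four_channels(self):
        plan = self._plan(5)
        ep = _white_epochs(n_probes=5, seed=5)
        ep.probe_ids = plan.probe_ids
        out, out_plan = ra.bipolar_rereference(ep, plan)
        assert out.n_probes == 4 and out_plan.n_probes == 4

    def test_identical_signals_cancel(self):
        plan = self._plan(2)
        base = _white_epochs(n_probes=1, seed=6)
        ep = ra.EpochSet(data=np.repeat(base.data, 2, axis=0), fs=base.fs,
                         probe_ids=plan.probe_ids)
        out, _ = ra.bipolar_rereference(ep, plan)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_no_cross_shaft_differencing(self):
        plan = self._plan(3, n_shafts=2)
        ep = _white_epochs(n_probes=6, seed=7)
        ep.probe_ids = plan.probe_ids
        out, out_plan = ra.bipolar_rereference(ep, plan)
        assert out.n_probes == 4
        assert set(out_plan.table["shaft_id"]) == {"s0", "s1"}

    def test_single_contact_shaft_warns(self):
        plan = self._plan(1, n_shafts=2)
        ep = _white_epochs(n_probes=2, seed=8)
        ep.probe_ids = plan.probe_ids
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                ra.bipolar_rereference(ep, plan)


class TestMorletTfr:
    def test_pure_tone_peaks_at_its_frequency(self):
        fs = 512.0
        t = np.arange(int(1.5 * fs)) / fs - 0.5
        sig = np.cos(2 * np.pi * 40 * t)[None, None, :]
        ep = ra.EpochSet(data=sig, fs=fs)
        freqs = np.arange(31.0, 71.0)
        tfr = ra.morlet_tfr(ep, freqs, cycles=6)
        good = tfr.reliable.all(axis=0)
        profile = tfr.power[0, 0][:, good].mean(axis=1)
        assert abs(freqs[profile.argmax()] - 40.0) <= 1.0

    def test_zero_signal_zero_power(self):
        ep = ra.EpochSet(data=np.zeros((1, 2, 300)), fs=200.0)
        tfr = ra.morlet_tfr(ep, [20.0], cycles=5)
        np.testing.assert_allclose(tfr.power, 0.0, atol=1e-20)

    def test_power_is_quadratic_in_amplitude(self):
        ep = _white_epochs(n_probes=1, n_stimuli=2, seed=9)
        ep2 = ra.EpochSet(data=2 * ep.data, fs=ep.fs)
        p1 = ra.morlet_tfr(ep, [15.0, 30.0], cycles=5).power
        p2 = ra.morlet_tfr(ep2, [15.0, 30.0], cycles=5).power
        np.testing.assert_allclose(p2, 4 * p1, rtol=1e-10)

    def test_frequency_above_nyquist_rejected(self):
        ep = _white_epochs(fs=100.0)
        with pytest.raises(ValueError):
            ra.morlet_tfr(ep, [60.0], cycles=5)

    def test_matches_mne_morlet_power_shape(self):
        """Cross-check against MNE's Morlet TFR (same sigma_t convention)."""
        mne = pytest.importorskip("mne")
        fs = 256.0
        rng = np.random.default_rng(10)
        data = rng.standard_normal((2, 3, int(1.5 * fs)))
        ep = ra.EpochSet(data=data, fs=fs)
        freqs = np.array([10.0, 20.0, 40.0])
        tfr = ra.morlet_tfr(ep, freqs, cycles=5)
        mne_p = mne.time_frequency.tfr_array_morlet(
            data.transpose(1, 0, 2), sfreq=fs, freqs=freqs,
            n_cycles=5, output="power", zero_mean=False,
        ).transpose(1, 0, 2, 3)
        # normalisations differ per frequency; compare shape-normalised
        # time courses away from the edges
        good = tfr.reliable.all(axis=0)
        for k in range(len(freqs)):
            a = tfr.power[0, 0, k, good]
            b = mne_p[0, 0, k, good]
            assert np.corrcoef(a, b)[0, 1] > 0.999


class TestBandPower:
    def test_flat_signal_ratio_one(self):
        fs = 512.0
        t = np.arange(int(1.5 * fs)) / fs - 0.5
        sig = np.cos(2 * np.pi * 45 * t)[None, None, :] * np.ones((2, 3, 1))
        ep = ra.EpochSet(data=sig, fs=fs)
        gamma = ra.DEFAULT_BANDS[3]
        tfr = ra.morlet_tfr(ep, gamma.freqs(2.0), cycles=gamma.cycles)
        roi = ra.ROISpec(band=gamma, window=(150, 350))
        _, _, resp = ra.band_power(tfr, roi)
        np.testing.assert_allclose(resp.values, 1.0, rtol=0.05)

    def test_amplitude_ratio_two_gives_power_four(self):
        gamma = ra.DEFAULT_BANDS[3]
        plan, _ = ra.make_probe_plan({"17": 1}, probes_per_area=2, seed=11)
        resp_in = ra.ResponseMatrix(values=np.full((2, 10), 4.0),
                                    probe_ids=plan.probe_ids)
        ep = ra.simulate_lfp_epochs(plan, resp_in, gamma, fs=1024, seed=12)
        out = ra.band_power_from_epochs(ep, gamma, [(150, 350)], grid_step=2.0)
        med = np.median(out[(150, 350)][2].values)
        assert med == pytest.approx(4.0, rel=0.10)

    def test_band_restricted_to_declared_edges(self):
        gamma = ra.DEFAULT_BANDS[3]
        f = gamma.freqs(1.0)
        assert f.min() == 31 and f.max() == 70

    def test_zero_baseline_rejected(self):
        ep = ra.EpochSet(data=np.zeros((1, 2, 512)), fs=512.0)
        gamma = ra.DEFAULT_BANDS[3]
        with pytest.raises(ValueError, match="baseline"):
            ra.band_power_from_epochs(ep, gamma, [(150, 350)], grid_step=5.0)


class TestScreenResponsive:
    def _post_base(self, n_probes=20, n_stim=40, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.8, 1.2, (n_probes, n_stim))
        return base.copy(), base

    def test_equal_post_base_keeps_nothing(self):
        post, base = self._post_base()
        rep = ra.screen_responsive(post, base)
        assert not rep["kept"].any()

    def test_positive_shift_kept(self):
        post, base = self._post_base(seed=1)
        post = base + 1.0
        rep = ra.screen_responsive(post, base)
        assert rep["kept"].all()

    def test_negative_responders_dropped(self):
        post, base = self._post_base(seed=2)
        post = base - 1.0
        rep = ra.screen_responsive(post, base)
        assert not rep["kept"].any()
        assert (rep["p_fdr"] < 0.05).all()  # significant but negative

    def test_null_false_positive_rate_bounded(self):
        rng = np.random.default_rng(3)
        keeps = []
        for s in range(10):
            base = rng.uniform(0.8, 1.2, (30, 40))
            post = base + rng.normal(0, 0.1, base.shape)
            keeps.append(ra.screen_responsive(post, base)["kept"].mean())
        assert np.mean(keeps) <= 0.05 + 0.02
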