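"""Preprocessing chain: referencing, filtering, ocular regression,
epoching, amplitude review."""

import numpy as np
import pytest

from entrainflow.preproc import (EEGRecording, bandpass, correct_ocular,
                                 epoch, preprocess, reject_amplitude,
                                 rereference_mastoids)


def _rec(data, labels, rate=500.0, events=()):
    return EEGRecording(np.asarray(data, dtype=float), rate, list(labels),
                        events=list(events))


class TestRereference:
    def test_zero_mastoids_leave_data_unchanged(self, rng):
        data = np.vstack([rng.standard_normal((2, 100)), np.zeros((2, 100))])
        rec = _rec(data, ["Cz", "Pz", "M1", "M2"])
        out = rereference_mastoids(rec)
        assert np.allclose(out.data[:2], data[:2])

    def test_channels_equal_to_mastoid_mean_become_zero(self, rng):
        m1 = rng.standard_normal(100)
        m2 = rng.standard_normal(100)
        ref = 0.5 * (m1 + m2)
        rec = _rec([ref, ref, m1, m2], ["Cz", "Pz", "M1", "M2"])
        out = rereference_mastoids(rec)
        assert np.allclose(out.data[:2], 0.0)

    def test_matches_per_sample_loop_oracle(self, rng):
        data = rng.standard_normal((5, 40))
        rec = _rec(data, ["Fz", "Cz", "Pz", "M1", "M2"])
        out = rereference_mastoids(rec)
        for i in range(3):
            expected = [data[i, t] - 0.5 * (data[3, t] + data[4, t])
                        for t in range(40)]
            assert np.allclose(out.data[i], expected)

    def test_missing_mastoid_error_names_the_label(self, rng):
        rec = _rec(rng.standard_normal((2, 10)), ["Cz", "M1"])
        with pytest.raises(ValueError, match="M2"):
            rereference_mastoids(rec)


class TestBandpass:
    def _sine(self, f, rate=500.0, dur=20.0):
        t = np.arange(int(dur * rate)) / rate
        return np.sin(2 * np.pi * f * t)

    def test_passband_tone_survives(self):
        rec = _rec([self._sine(1.0)], ["Cz"])
        out = bandpass(rec)
        mid = slice(2000, -2000)
        ratio = out.data[0, mid].std() / rec.data[0, mid].std()
        assert ratio > 0.95

    def test_sixty_hz_attenuated_by_forty_db(self):
        # evaluate the designed transfer function at 60 Hz (forward pass
        # alone; the forward-backward application only attenuates further)
        from scipy import signal as sig
        from entrainflow.preproc import _band_sos
        sos = _band_sos(0.1, 30.0, 500.0, order=8)
        _, h = sig.sosfreqz(sos, worN=[60 / 250 * np.pi])
        assert 20 * np.log10(np.abs(h[0])) < -40
        # and the realized filter suppresses the 60 Hz component itself
        rec = _rec([self._sine(60.0)], ["Cz"])
        out = bandpass(rec)
        t = np.arange(rec.n_samples) / 500.0
        basis = np.stack([np.sin(2 * np.pi * 60 * t),
                          np.cos(2 * np.pi * 60 * t)])
        amp60 = np.hypot(*(2 * basis @ out.data[0] / rec.n_samples))
        assert 20 * np.log10(amp60) < -40

    def test_dc_offset_removed(self):
        rec = _rec([np.full(10000, 7.3)], ["Cz"])
        out = bandpass(rec)
        assert abs(out.data[0, 2000:-2000].mean()) < 1e-3

    def test_zero_phase_impulse_response_is_symmetric(self):
        x = np.zeros(20001)
        x[10000] = 1.0
        out = bandpass(_rec([x], ["Cz"])).data[0]
        # symmetric to ~1e-4 of peak (near-unit-circle 0.1 Hz poles limit
        # double-precision commutativity of the two passes)
        assert np.allclose(out, out[::-1], atol=1e-4 * np.abs(out).max())

    def test_invalid_band_raises(self):
        rec = _rec([np.zeros(100)], ["Cz"])
        with pytest.raises(ValueError):
            bandpass(rec, hp_hz=40.0, lp_hz=30.0)


class TestOcular:
    def _with_eog(self, scalp_rows, heog, veog, labels):
        data = np.vstack(scalp_rows + [heog, veog])
        return _rec(data, labels + ["HEOG", "VEOG"])

    def test_exact_propagation_recovered(self, rng):
        veog = rng.standard_normal(2000)
        heog = rng.standard_normal(2000)
        rec = self._with_eog([0.5 * veog], heog, veog, ["Cz"])
        out, table = correct_ocular(rec)
        assert abs(table.loc["Cz", "b_VEOG"] - 0.5) < 0.02
        assert out.channel("Cz").std() < 0.05 * veog.std()

    def test_orthogonal_channel_untouched(self):
        t = np.arange(4000) / 500.0
        brain = np.sin(2 * np.pi * 3.0 * t)
        heog = np.sin(2 * np.pi * 0.25 * t)
        veog = np.cos(2 * np.pi * 0.25 * t)
        rec = self._with_eog([brain], heog, veog, ["Cz"])
        out, _ = correct_ocular(rec)
        assert np.allclose(out.channel("Cz"), brain, atol=1e-3)

    def test_known_mixing_matrix_recovered_within_5pct(self, rng):
        heog = rng.standard_normal(5000)
        veog = rng.standard_normal(5000)
        mix = {"Fz": (0.4, 0.8), "Cz": (0.2, 0.3), "Pz": (-0.1, 0.05)}
        rows = [0.1 * rng.standard_normal(5000) + bh * heog + bv * veog
                for bh, bv in mix.values()]
        rec = self._with_eog(rows, heog, veog, list(mix))
        _, table = correct_ocular(rec)
        for ch, (bh, bv) in mix.items():
            assert table.loc[ch, "b_HEOG"] == pytest.approx(bh, abs=0.05)
            assert table.loc[ch, "b_VEOG"] == pytest.approx(bv, abs=0.05)

    def test_flat_eog_warns_and_zeroes_factors(self):
        rec = self._with_eog([np.random.default_rng(0).random(100)],
                             np.zeros(100), np.zeros(100), ["Cz"])
        with pytest.warns(UserWarning):
            _, table = correct_ocular(rec)
        assert np.all(table.to_numpy() == 0)


class TestEpoching:
    def test_single_event_yields_2500_samples(self, rng):
        rec = _rec(rng.standard_normal((2, 4000)), ["Cz", "Pz"],
                   events=[(100, 1)])
        ep = epoch(rec)
        assert ep.data.shape == (1, 2, 2500)
        assert not ep.rejection_mask[0]

    def test_no_events_gives_empty_set(self):
        rec = _rec(np.zeros((1, 1000)), ["Cz"])
        ep = epoch(rec)
        assert ep.n_trials == 0

    def test_overlapping_events_extracted_independently(self, rng):
        data = rng.standard_normal((1, 4000))
        rec = _rec(data, ["Cz"], events=[(0, 1), (500, 2)])
        ep = epoch(rec)
        assert np.allclose(ep.data[0, 0], data[0, :2500])
        assert np.allclose(ep.data[1, 0], data[0, 500:3000])

    def test_event_near_end_flagged_not_dropped(self, rng):
        rec = _rec(rng.standard_normal((1, 3000)), ["Cz"],
                   events=[(0, 1), (2000, 2)])
        ep = epoch(rec)
        assert ep.n_trials == 2
        assert not ep.rejection_mask[0]
        assert ep.rejection_mask[1]


class TestAmplitudeReview:
    def _epochs(self, data):
        rec = _rec(data, ["Cz"], events=[(0, 1)])
        return epoch(rec, window_s=(0.0, data.shape[1] / 500.0))

    def test_quiet_trials_pass(self):
        ep = self._epochs(np.full((1, 500), 10.0))
        assert not reject_amplitude(ep).rejection_mask.any()

    def test_single_excursion_flags_exactly_that_trial(self, rng):
        data = rng.uniform(-10, 10, size=(2, 3, 500))
        data[1, 0, 250] = 80.0
        ep_ok = epoch(_rec(data[0], ["Cz", "Pz", "Oz"], events=[(0, 1)]),
                      window_s=(0, 1))
        ep_bad = epoch(_rec(data[1], ["Cz", "Pz", "Oz"], events=[(0, 1)]),
                       window_s=(0, 1))
        assert not reject_amplitude(ep_ok).rejection_mask[0]
        assert reject_amplitude(ep_bad).rejection_mask[0]

    def test_flags_match_brute_force_scan(self, rng):
        data = rng.uniform(-80, 80, size=(6, 2, 400))
        from entrainflow.preproc import EpochSet
        import pandas as pd
        ep = EpochSet(data, 500.0, ["Cz", "Pz"],
                      pd.DataFrame({"trial": range(6)}),
                      np.zeros(6, dtype=bool), window_s=(0, 0.8))
        out = reject_amplitude(ep, limit_uv=75.0)
        expected = [bool((np.abs(data[t]) > 75).any()) for t in range(6)]
        assert list(out.rejection_mask) == expected


def test_full_chain_is_reproducible(rng):
    from entrainflow.synth import SynthSpec, make_eeg, make_flow_series
    spec = SynthSpec(seed=21)
    flow = make_flow_series(spec, 0)
    rec = make_eeg(spec, flow, "a01", "direct")
    a = preprocess(rec.copy())
    b = preprocess(rec.copy())
    assert np.array_equal(a.data, b.data)
    assert np.array_equal(a.rejection_mask, b.rejection_mask)
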